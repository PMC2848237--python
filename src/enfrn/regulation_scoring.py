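"""From a trained network to a regulation call (up / down / none) and scores.

Each gene's series is discretized into *linguistic labels*: the index, in
ascending order of center, of the fuzzy set with maximal membership at each
time point.  The regulation score (RS) is the lag-1 consistency between
input-label changes and the direction of the following output-label change:
an input change across transition t (between points t-1 and t) is paired
with the output transition t+1, contributes sign(out[t+1] - out[t]), and the
sum is normalized by the number of qualifying input changes N_IC.  RS > 0
means up-regulation, RS < 0 down-regulation, RS == 0 (or no qualifying input
change) no stable regulation.  With several regulators all of them must
change labels simultaneously for a transition to qualify.

The composite score blends model error with RS-inconsistency,
CS = n * RMSE + (1 - n) * (1 - |RS|), default n = 0.6; lower is better and
edges are kept below a CS threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_network import ENFRNModel, FuzzySet, gaussian_membership, sequence_rmse

UP, DOWN, NONE = "up", "down", "none"


@dataclass
class LabelSequence:
    """Per-time-point fuzzy-set indices (ascending-center order) of one gene."""

    labels: np.ndarray
    variable_name: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class RegulationResult:
    """Scored (regulator-set, target) call."""

    regulators: list[str]
    target: str
    rs_raw: float | None
    n_ic: int
    regulation_type: str
    model_error: float
    composite_score: float
    rs_inconsistency: float = field(init=False)

    def __post_init__(self) -> None:
        self.rs_inconsistency = 1.0 - (abs(self.rs_raw) if self.rs_raw is not None else 0.0)


def label_sequence(model: ENFRNModel, series, variable) -> LabelSequence:
    """Labels of a series under one variable's fuzzy partition.

    ``variable`` is an input index, or "output" for the target partition.
    Memberships are computed directly from the values (no recurrence), so
    labels are a property of the data and the partition alone.  Ties break
    to the lower ascending-center index.
    """
    if variable == "output":
        sets = [FuzzySet(o.center, o.width) for o in model.outputs]
        name = model.output_name
    else:
        var = model.inputs[int(variable)]
        sets = var.sets
        name = model.input_names[int(variable)] if model.input_names else str(variable)
    if not sets:
        raise ValueError("variable has no fuzzy sets")
    order = np.argsort([s.center for s in sets], kind="stable")
    ordered = [sets[j] for j in order]
    series = np.asarray(series, dtype=float)
    labels = np.empty(len(series), dtype=int)
    for t, v in enumerate(series):
        memb = np.array([gaussian_membership(float(v), s) for s in ordered])
        labels[t] = int(np.argmax(memb))  # argmax takes the first max
    return LabelSequence(labels=labels, variable_name=name)


def input_change_indicator(labels_in: list[LabelSequence], t: int) -> int:
    """1 iff EVERY regulator's label changed across transition t (between
    time points t-1 and t), else 0."""
    if t < 1:
        raise ValueError("transition index starts at 1")
    for seq in labels_in:
        if seq.labels[t] == seq.labels[t - 1]:
            return 0
    return 1


def regulation_score(labels_in: list[LabelSequence], labels_out: LabelSequence):
    """(rs_raw, N_IC) over lag-1 transitions.

    Input changes across transition t (t = 1..T-2) are paired with the NEXT
    output transition (t+1); an input change at the final transition has no
    following output transition and is excluded from both the sum and N_IC.
    Returns (None, 0) when no qualifying change exists.
    """
    T = len(labels_out)
    for seq in labels_in:
        if len(seq) != T:
            raise ValueError("label sequences must share the same length")
    if T < 3:
        raise ValueError("need at least 3 time points")
    out = labels_out.labels
    total = 0
    n_ic = 0
    for t in range(1, T - 1):
        if input_change_indicator(labels_in, t):
            n_ic += 1
            total += int(np.sign(out[t + 1] - out[t]))
    if n_ic == 0:
        return None, 0
    return total / n_ic, n_ic


def regulation_type(rs_raw) -> str:
    """Sign convention: positive RS = up-regulation, negative = down,
    zero or undefined = none."""
    if rs_raw is None or rs_raw == 0:
        return NONE
    return UP if rs_raw > 0 else DOWN


def composite_score(model_error: float, rs_raw, n: float = 0.6) -> float:
    """CS = n * model_error + (1 - n) * (1 - |RS|); lower is better.

    |RS| is taken as 0 when RS is undefined.  CS can exceed 1 when the model
    error does.
    """
    if not 0.0 <= n <= 1.0:
        raise ValueError("weight n must lie in [0, 1]")
    if model_error < 0:
        raise ValueError("model_error must be >= 0")
    mag = abs(rs_raw) if rs_raw is not None else 0.0
    return n * model_error + (1.0 - n) * (1.0 - mag)


def score_model(model: ENFRNModel, inputs, target, *, cs_weight: float = 0.6,
                model_error: float | None = None) -> RegulationResult:
    """Full regulation call for a trained model on a dataset.

    ``inputs`` is (n_inputs, T), ``target`` length T.  ``model_error``
    defaults to the model's own lag-1 RMSE on this data.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if model_error is None:
        model_error = sequence_rmse(model, inputs, target)
    labels_in = [
        label_sequence(model, inputs[i], i) for i in range(model.n_inputs)
    ]
    labels_out = label_sequence(model, target, "output")
    rs_raw, n_ic = regulation_score(labels_in, labels_out)
    return RegulationResult(
        regulators=list(model.input_names),
        target=model.output_name,
        rs_raw=rs_raw,
        n_ic=n_ic,
        regulation_type=regulation_type(rs_raw),
        model_error=float(model_error),
        composite_score=composite_score(model_error, rs_raw, cs_weight),
    )
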