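"""Five-layer recurrent neuro-fuzzy network (ENFRN) and its forward pass.

The network maps the expression of one or more regulator genes at time t to a
prediction of a target gene's expression at time t+1.  Layer 1 passes inputs
through; layer 2 holds one Gaussian linguistic term (fuzzy set) per node and
implements the recurrence -- each term node remembers its previous membership
output and feeds it back, scaled by a link weight, into its next input; layer
3 holds the fuzzy rules (product AND over one term per input variable); layer
4 sums the firing strengths routed to each output linguistic node; layer 5
defuzzifies by a width-weighted average of the output-node centers.

This module is the *semantic reference*: the forward pass is written as a
plain per-step loop.  The vectorized batch evaluators used by the swarm
optimizers live in :mod:`enfrn.swarm_optimization` and are tested for exact
agreement with this path.
"""

from __future__ import annotations

import copy
import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: floor applied everywhere a fuzzy-set width is created or updated;
#: widths are swarm-tuned and can otherwise collapse to zero
SIGMA_MIN = 1e-3

#: defuzzification denominator below this is treated as numerical underflow
DENOM_FLOOR = 1e-12

SERIALIZATION_VERSION = 1


class InvalidModelError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class FuzzySet:
    """One Gaussian linguistic term: membership exp(-((v - center)/width)^2)."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise InvalidModelError(f"fuzzy-set width must be > 0, got {self.width}")
        self.width = max(float(self.width), SIGMA_MIN)
        self.center = float(self.center)


@dataclass
class InputVariable:
    """All linguistic terms of one input gene, with their recurrent links.

    ``state[j]`` is the membership output of term ``j`` at the previous time
    step (the memory of the term node); ``feedback_weights[j]`` scales it into
    the term's next input.
    """

    sets: list[FuzzySet] = field(default_factory=list)
    feedback_weights: list[float] = field(default_factory=list)
    state: list[float] = field(default_factory=list)

    def validate(self) -> None:
        if not (len(self.sets) == len(self.feedback_weights) == len(self.state)):
            raise InvalidModelError("sets/feedback_weights/state length mismatch")


@dataclass
class Rule:
    """Fuzzy rule: one term index per input variable, one consequent node."""

    precondition: list[int]
    consequent: int


@dataclass
class OutputNode:
    """One Gaussian linguistic term partitioning the output space."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise InvalidModelError(f"output-node width must be > 0, got {self.width}")
        self.width = max(float(self.width), SIGMA_MIN)
        self.center = float(self.center)


@dataclass
class ENFRNModel:
    """Full network: input terms + recurrence, rules, output terms."""

    inputs: list[InputVariable]
    rules: list[Rule] = field(default_factory=list)
    outputs: list[OutputNode] = field(default_factory=list)
    input_names: list[str] = field(default_factory=list)
    output_name: str = ""
    #: free-form notes attached during training (e.g. degenerate-data flags)
    warnings: list[str] = field(default_factory=list)
    #: optional per-gene (min, max) used to normalize the training data
    normalization: dict | None = None
    #: mean online prediction error of the structure-learning pass
    training_error: float | None = None

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def n_outputs(self) -> int:
        return len(self.outputs)

    def validate(self) -> None:
        for var in self.inputs:
            var.validate()
        for rule in self.rules:
            if len(rule.precondition) != self.n_inputs:
                raise InvalidModelError("rule precondition arity mismatch")
            for i, j in enumerate(rule.precondition):
                if not 0 <= j < len(self.inputs[i].sets):
                    raise InvalidModelError(
                        f"rule references missing set {j} of input {i}"
                    )
            if not 0 <= rule.consequent < self.n_outputs:
                raise InvalidModelError("rule references missing output node")

    def copy(self) -> "ENFRNModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# layer operations


def gaussian_membership(value: float, fset: FuzzySet) -> float:
    """Membership degree of ``value`` in a Gaussian term; 1 iff at the center."""
    if not fset.width > 0:
        raise InvalidModelError("non-positive fuzzy-set width")
    z = (value - fset.center) / fset.width
    return math.exp(-z * z)


def recurrent_layer2_input(x: float, prev_membership: float, beta: float) -> float:
    """Term-node input with additive recurrent feedback: x + beta * psi(t-1)."""
    return x + beta * prev_membership


def rule_firing(model: ENFRNModel, rule: Rule, layer2_outputs: list[np.ndarray]) -> float:
    """Product-AND of the rule's precondition memberships (in (0, 1])."""
    strength = 1.0
    for i, j in enumerate(rule.precondition):
        memb = layer2_outputs[i]
        if j >= len(memb):
            raise InvalidModelError(f"rule references missing set {j} of input {i}")
        strength *= float(memb[j])
    return strength


def _layer2(model: ENFRNModel, x_t, *, update_state: bool) -> list[np.ndarray]:
    """Memberships of every term of every input variable at this step."""
    out: list[np.ndarray] = []
    for i, var in enumerate(model.inputs):
        memb = np.empty(len(var.sets))
        for j, fset in enumerate(var.sets):
            phi = recurrent_layer2_input(float(x_t[i]), var.state[j], var.feedback_weights[j])
            memb[j] = gaussian_membership(phi, fset)
        if update_state:
            var.state = [float(m) for m in memb]
        out.append(memb)
    return out


def forward_step(model: ENFRNModel, x_t) -> float:
    """One recurrent step: consume x_t, update term memories, defuzzify.

    Returns y = sum_j w_j c_j a_j / sum_j w_j a_j where a_j is the layer-4
    sum of firing strengths routed to output node j.  When the denominator
    underflows, falls back to the consequent center of the max-firing rule.
    """
    if model.n_rules == 0:
        raise InvalidModelError("model has no rules")
    if len(x_t) != model.n_inputs:
        raise InvalidModelError("input vector length mismatch")
    layer2 = _layer2(model, x_t, update_state=True)
    firing = np.array([rule_firing(model, r, layer2) for r in model.rules])
    a = np.zeros(model.n_outputs)
    for r, f in zip(model.rules, firing):
        a[r.consequent] += f
    w = np.array([o.width for o in model.outputs])
    c = np.array([o.center for o in model.outputs])
    den = float(np.sum(w * a))
    if den < DENOM_FLOOR:
        best = int(np.argmax(firing))
        logger.warning("defuzzification underflow; falling back to nearest rule")
        return model.outputs[model.rules[best].consequent].center
    return float(np.sum(w * c * a) / den)


def forward_sequence(model: ENFRNModel, series) -> np.ndarray:
    """Run the recurrent forward pass over a (n_inputs, T) series.

    The state is reset before the first step; prediction at step t depends
    only on inputs at steps <= t.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] != model.n_inputs:
        raise InvalidModelError("series row count != number of input variables")
    reset_state(model)
    T = series.shape[1]
    preds = np.empty(T)
    for t in range(T):
        preds[t] = forward_step(model, series[:, t])
    return preds


def reset_state(model: ENFRNModel) -> None:
    """Zero every term node's memory (idempotent)."""
    for var in model.inputs:
        var.state = [0.0] * len(var.sets)


def sequence_rmse(model: ENFRNModel, inputs, target) -> float:
    """Lag-1 RMSE: prediction from x_t is compared with target at t+1."""
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    target = np.asarray(target, dtype=float)
    T = inputs.shape[1]
    if T < 2:
        raise ValueError("need at least 2 time points for a lag-1 error")
    preds = forward_sequence(model, inputs)
    resid = preds[: T - 1] - target[1:]
    return float(np.sqrt(np.mean(resid**2)))


# ---------------------------------------------------------------------------
# serialization


def model_to_dict(model: ENFRNModel) -> dict:
    return {
        "format": "enfrn-model",
        "version": SERIALIZATION_VERSION,
        "input_names": list(model.input_names),
        "output_name": model.output_name,
        "inputs": [
            {
                "centers": [s.center for s in var.sets],
                "widths": [s.width for s in var.sets],
                "feedback_weights": list(var.feedback_weights),
            }
            for var in model.inputs
        ],
        "rules": [
            {"precondition": list(r.precondition), "consequent": r.consequent}
            for r in model.rules
        ],
        "outputs": [{"center": o.center, "width": o.width} for o in model.outputs],
        "normalization": model.normalization,
    }


def model_from_dict(doc: dict) -> ENFRNModel:
    if doc.get("format") != "enfrn-model":
        raise ValueError("not an ENFRN model document")
    if doc.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model version {doc.get('version')!r}")
    inputs = []
    for spec in doc["inputs"]:
        sets = [FuzzySet(c, w) for c, w in zip(spec["centers"], spec["widths"])]
        inputs.append(
            InputVariable(
                sets=sets,
                feedback_weights=[float(b) for b in spec["feedback_weights"]],
                state=[0.0] * len(sets),
            )
        )
    model = ENFRNModel(
        inputs=inputs,
        rules=[Rule(list(r["precondition"]), int(r["consequent"])) for r in doc["rules"]],
        outputs=[OutputNode(o["center"], o["width"]) for o in doc["outputs"]],
        input_names=list(doc.get("input_names", [])),
        output_name=doc.get("output_name", ""),
        normalization=doc.get("normalization"),
    )
    model.validate()
    return model


def save_model(model: ENFRNModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> ENFRNModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
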