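"""Phase-1 self-organized construction of the initial ENFRN structure.

Rules (input-space clusters) are created online while streaming lag-1
training patterns (x_t, y_{t+1}).  A new rule is created only when the
current pattern is both poorly predicted (error above ``error_threshold``)
and far from every existing cluster (max firing strength below
``firing_threshold``).  New Gaussian terms are centered on the pattern with a
width proportional (factor ``overlap_delta``) to the distance to the nearest
existing center, redundant terms are merged by an overlap/union similarity
measure, and output-space clusters are created by the same two-criterion
test, so several rules may share one consequent.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .core_network import (
    SIGMA_MIN,
    ENFRNModel,
    FuzzySet,
    InputVariable,
    OutputNode,
    Rule,
    forward_step,
    gaussian_membership,
    reset_state,
)

logger = logging.getLogger(__name__)

_SQRT_PI = math.sqrt(math.pi)


@dataclass
class StructureConfig:
    """Knobs of the self-organizing phase (all on [0,1]-normalized data).

    error_threshold
        Prediction-error level above which a pattern counts as badly handled.
    firing_threshold
        Firing strength below which a pattern counts as far from every
        cluster; both conditions must hold for a new rule.
    overlap_delta
        Cluster-overlap constant: new term width = overlap_delta * distance
        to the nearest existing center in that dimension.
    similarity_threshold
        Term pairs with overlap/union similarity above this are merged.
    max_rules
        Hard cap on the number of rules created in one pass.
    """

    error_threshold: float = 0.1
    firing_threshold: float = 0.7
    overlap_delta: float = 0.2
    similarity_threshold: float = 0.8
    max_rules: int = 30

    def __post_init__(self) -> None:
        if self.error_threshold <= 0 or self.overlap_delta <= 0:
            raise ValueError("error_threshold and overlap_delta must be > 0")
        if not 0 < self.firing_threshold < 1:
            raise ValueError("firing_threshold must lie in (0, 1)")
        if not 0 < self.similarity_threshold < 1:
            raise ValueError("similarity_threshold must lie in (0, 1)")
        if self.max_rules < 1:
            raise ValueError("max_rules must be a positive integer")

    @classmethod
    def from_dict(cls, doc: dict | None) -> "StructureConfig":
        return cls(**(doc or {}))


def prediction_error(y_pred: float, y_obs: float) -> float:
    """Absolute prediction error |y_pred - y_obs| (symmetric, >= 0)."""
    return abs(float(y_pred) - float(y_obs))


def _stateless_layer2(model: ENFRNModel, x) -> list[np.ndarray]:
    """Memberships of raw x (no recurrence) -- cluster geometry only."""
    out = []
    for i, var in enumerate(model.inputs):
        out.append(
            np.array([gaussian_membership(float(x[i]), s) for s in var.sets])
        )
    return out


def nearest_rule(model: ENFRNModel, x) -> tuple[int, float]:
    """Rule with maximal recurrence-free firing strength for pattern x.

    Max firing is the monotone inverse of the Mahalanobis distance to the
    rule center, so max-firing == min-distance.  Ties break to the lowest
    rule index.
    """
    if model.n_rules == 0:
        raise LookupError("model has no rules yet")
    layer2 = _stateless_layer2(model, x)
    best_idx, best_f = 0, -1.0
    for k, rule in enumerate(model.rules):
        f = 1.0
        for i, j in enumerate(rule.precondition):
            f *= float(layer2[i][j])
        if f > best_f:
            best_idx, best_f = k, f
    return best_idx, best_f


def should_create_rule(E_k: float, max_firing: float, config: StructureConfig) -> bool:
    """True iff the pattern is badly predicted AND far from every cluster."""
    return E_k > config.error_threshold and max_firing < config.firing_threshold


# ---------------------------------------------------------------------------
# similarity of Gaussian terms


def _gauss_integral(c: float, s: float, lo: float, hi: float) -> float:
    """Integral of exp(-((x-c)/s)^2) over [lo, hi] (infs allowed)."""
    zlo = -1.0 if lo == -math.inf else erf((lo - c) / s)
    zhi = 1.0 if hi == math.inf else erf((hi - c) / s)
    return 0.5 * s * _SQRT_PI * (zhi - zlo)


def fuzzy_set_similarity(a: FuzzySet, b: FuzzySet) -> float:
    """Overlap/union similarity of two Gaussian terms, in [0, 1].

    overlap = integral of min(mu_a, mu_b), computed exactly between the
    crossing points of the two bells; union = area_a + area_b - overlap with
    Gaussian areas sigma*sqrt(pi).  Equals 1 iff the terms coincide.
    """
    ca, sa, cb, sb = a.center, a.width, b.center, b.width
    area_a, area_b = sa * _SQRT_PI, sb * _SQRT_PI
    if math.isclose(ca, cb, abs_tol=1e-15) and math.isclose(sa, sb, rel_tol=1e-12):
        return 1.0
    # crossing points of ((x-ca)/sa)^2 = ((x-cb)/sb)^2
    if math.isclose(sa, sb, rel_tol=1e-12):
        cuts = [0.5 * (ca + cb)]
    else:
        # quadratic (1/sa^2 - 1/sb^2) x^2 - 2(ca/sa^2 - cb/sb^2) x + ... = 0
        p = 1.0 / sa**2 - 1.0 / sb**2
        q = -2.0 * (ca / sa**2 - cb / sb**2)
        r = ca**2 / sa**2 - cb**2 / sb**2
        disc = q * q - 4.0 * p * r
        if disc <= 0:
            cuts = []
        else:
            sq = math.sqrt(disc)
            cuts = sorted([(-q - sq) / (2 * p), (-q + sq) / (2 * p)])
    edges = [-math.inf, *cuts, math.inf]
    overlap = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        # smaller membership == larger squared z-score; comparing z avoids
        # ties when both memberships underflow to 0.0 far from the centers.
        # A probe can still tie exactly (e.g. at a shared center), so try a
        # second probe point before defaulting
        for mid in _interval_probes(lo, hi):
            za = ((mid - ca) / sa) ** 2
            zb = ((mid - cb) / sb) ** 2
            if za != zb:
                break
        if za >= zb:
            overlap += _gauss_integral(ca, sa, lo, hi)
        else:
            overlap += _gauss_integral(cb, sb, lo, hi)
    union = area_a + area_b - overlap
    return min(1.0, max(0.0, overlap / union))


def _interval_probes(lo: float, hi: float) -> tuple[float, float]:
    if lo == -math.inf and hi == math.inf:
        return 0.0, 1.0
    if lo == -math.inf:
        return hi - 1.0, hi - 2.0
    if hi == math.inf:
        return lo + 1.0, lo + 2.0
    return 0.5 * (lo + hi), lo + 0.75 * (hi - lo)


def merge_similar_sets(model: ENFRNModel, threshold: float) -> ENFRNModel:
    """Merge, per input dimension, term pairs with similarity > threshold.

    Merged term: center = mean of centers, width = max of widths (coverage
    never shrinks).  Rule preconditions are re-pointed; the number of rules
    never changes.  Repeats until no pair exceeds the threshold.
    """
    for i, var in enumerate(model.inputs):
        changed = True
        while changed and len(var.sets) > 1:
            changed = False
            best_pair, best_sim = None, threshold
            for a, b in itertools.combinations(range(len(var.sets)), 2):
                sim = fuzzy_set_similarity(var.sets[a], var.sets[b])
                if sim > best_sim:
                    best_pair, best_sim = (a, b), sim
            if best_pair is not None:
                a, b = best_pair
                merged = FuzzySet(
                    center=0.5 * (var.sets[a].center + var.sets[b].center),
                    width=max(var.sets[a].width, var.sets[b].width),
                )
                beta = 0.5 * (var.feedback_weights[a] + var.feedback_weights[b])
                # drop b, replace a, remap rule preconditions
                var.sets[a] = merged
                var.feedback_weights[a] = beta
                del var.sets[b]
                del var.feedback_weights[b]
                var.state = [0.0] * len(var.sets)
                for rule in model.rules:
                    j = rule.precondition[i]
                    if j == b:
                        rule.precondition[i] = a
                    elif j > b:
                        rule.precondition[i] = j - 1
                changed = True
    return model


# ---------------------------------------------------------------------------
# rule / output-cluster creation


def assign_output_cluster(
    model: ENFRNModel,
    y: float,
    E_k: float,
    config: StructureConfig,
    *,
    output_span: float = 1.0,
) -> int:
    """Pick (or create) the output node for a rule under creation.

    A new output cluster is created only when no node exists yet, or when the
    prediction error exceeds the threshold AND y's membership in the nearest
    output node falls below the firing threshold (the firing-threshold
    closeness test expressed in the output space).
    """
    # one shared initial width: widths weight the defuzzification, so
    # creation-order asymmetries would otherwise bias it toward early nodes
    width = max(config.overlap_delta * max(output_span, SIGMA_MIN), SIGMA_MIN)
    if model.n_outputs == 0:
        model.outputs.append(OutputNode(center=y, width=width))
        return 0
    dists = [abs(y - o.center) for o in model.outputs]
    nearest = int(np.argmin(dists))
    memb = gaussian_membership(y, FuzzySet(model.outputs[nearest].center, model.outputs[nearest].width))
    if E_k > config.error_threshold and memb < config.firing_threshold:
        model.outputs.append(OutputNode(center=y, width=width))
        return model.n_outputs - 1
    return nearest


def create_rule(
    model: ENFRNModel,
    x,
    y: float,
    config: StructureConfig,
    *,
    E_k: float = math.inf,
    input_spans=None,
    output_span: float = 1.0,
) -> ENFRNModel:
    """Add one rule centered on pattern (x, y); merge redundant terms after.

    Per input dimension a new Gaussian term is created with center x_i and
    width overlap_delta * (distance from x_i to the nearest existing center
    in that dimension); the first-ever term uses the variable's observed
    span.  The new recurrent link weight starts at 0.
    """
    if model.n_rules >= config.max_rules:
        logger.warning("max_rules=%d reached; rule not created", config.max_rules)
        return model
    if input_spans is None:
        input_spans = [1.0] * model.n_inputs
    # d_min = distance from the pattern to the nearest existing cluster
    # (rule center vector), one scalar shared by every dimension's new width
    d_min = None
    if model.rules:
        d_min = min(
            math.sqrt(sum(
                (float(x[i]) - model.inputs[i].sets[j].center) ** 2
                for i, j in enumerate(r.precondition)
            ))
            for r in model.rules
        )
    precondition = []
    for i, var in enumerate(model.inputs):
        xi = float(x[i])
        if d_min is not None:
            width = config.overlap_delta * d_min
        else:
            width = config.overlap_delta * max(float(input_spans[i]), SIGMA_MIN)
        var.sets.append(FuzzySet(center=xi, width=max(width, SIGMA_MIN)))
        var.feedback_weights.append(0.0)
        var.state.append(0.0)
        precondition.append(len(var.sets) - 1)
    consequent = assign_output_cluster(model, float(y), E_k, config, output_span=output_span)
    model.rules.append(Rule(precondition=precondition, consequent=consequent))
    merge_similar_sets(model, config.similarity_threshold)
    model.validate()
    return model


def build_initial_structure(inputs, output, config: StructureConfig | None = None,
                            *, input_names=None, output_name: str = "") -> ENFRNModel:
    """Single streamed pass over lag-1 patterns; returns the phase-1 model.

    ``inputs`` is (n_inputs, T), ``output`` length T, both [0,1]-normalized.
    The recurrent state is carried across the pass; rule count grows with
    problem complexity and never decreases.  Deterministic given data and
    config.
    """
    config = config or StructureConfig()
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    output = np.asarray(output, dtype=float)
    n_in, T = inputs.shape
    if T < 2 or output.shape[0] != T:
        raise ValueError("need an (n_inputs, T>=2) input matrix and length-T output")
    model = ENFRNModel(
        inputs=[InputVariable() for _ in range(n_in)],
        input_names=list(input_names) if input_names else [f"x{i}" for i in range(n_in)],
        output_name=output_name,
    )
    spans = [float(np.ptp(inputs[i])) or 1.0 for i in range(n_in)]
    out_span = float(np.ptp(output)) or 1.0
    for i in range(n_in):
        if np.ptp(inputs[i]) == 0.0:
            model.warnings.append(f"input series {i} is constant (zero variance)")
    if np.ptp(output) == 0.0:
        model.warnings.append("output series is constant (zero variance)")

    errors = []
    for t in range(T - 1):
        x_t, y_t = inputs[:, t], float(output[t + 1])
        if model.n_rules == 0:
            create_rule(model, x_t, y_t, config,
                        input_spans=spans, output_span=out_span)
            forward_step(model, x_t)  # prime the recurrent state
            continue
        y_pred = forward_step(model, x_t)
        E_k = prediction_error(y_pred, y_t)
        errors.append(E_k)
        _, max_firing = nearest_rule(model, x_t)
        if should_create_rule(E_k, max_firing, config):
            create_rule(model, x_t, y_t, config, E_k=E_k,
                        input_spans=spans, output_span=out_span)
    reset_state(model)
    model.validate()
    # mean online prediction error over the pass (bootstrap step excluded)
    model.training_error = float(np.mean(errors)) if errors else None
    return model
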