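"""Phase-2 binary-PSO rule pruning and phase-3 continuous-PSO fine-tuning.

Both phases are global-best particle swarms.  Phase 2 searches over binary
rule masks with fitness MSE / (M - N + 1) (M initial rules, N kept rules),
which decreases with both fewer rules and lower error.  Phase 3 searches over
the flat parameter vector of the network (input-term centers and widths,
output-node centers and widths, recurrent link weights) with RMSE fitness;
the swarm is seeded at the current parameters plus Gaussian jitter, so the
returned model is never worse than its input.

Fitness evaluation is the hot path, so both phases evaluate the whole swarm
at once with vectorized forward passes; the reference per-model path in
:mod:`enfrn.core_network` defines the semantics and the test suite asserts
exact agreement between the two.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core_network import (
    DENOM_FLOOR,
    SIGMA_MIN,
    ENFRNModel,
    InvalidModelError,
    forward_sequence,
    reset_state,
)

logger = logging.getLogger(__name__)


@dataclass
class SwarmConfig:
    """PSO settings.  c1/c2 are the cognitive/social pulls, inertia the
    velocity carry-over, v_max the per-component velocity clip.  Defaults are
    the standard constriction-equivalent constants."""

    n_particles: int = 20
    n_iterations: int = 100
    c1: float = 1.494
    c2: float = 1.494
    inertia: float = 0.729
    v_max: float = 4.0
    seed: int = 0
    early_stop_tol: float = 1e-6
    early_stop_patience: int = 25

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1 and c2 must be positive")

    @classmethod
    def bpso_defaults(cls, seed: int = 0) -> "SwarmConfig":
        return cls(n_particles=20, n_iterations=100, seed=seed,
                   early_stop_patience=20)

    @classmethod
    def pso_defaults(cls, seed: int = 0) -> "SwarmConfig":
        return cls(n_particles=30, n_iterations=300, seed=seed)

    @classmethod
    def from_dict(cls, doc: dict | None, **overrides) -> "SwarmConfig":
        merged = dict(doc or {})
        merged.update(overrides)
        return cls(**merged)


@dataclass
class Particle:
    """One swarm member (real-valued or binary position)."""

    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float = math.inf


# ---------------------------------------------------------------------------
# elementary PSO updates (per-particle reference forms)


def pso_velocity_update(p: Particle, global_best, config: SwarmConfig, rng) -> np.ndarray:
    """v' = inertia*v + c1*n1*(B_i - X) + c2*n2*(B_G - X), clipped to v_max.

    n1, n2 are uniform(0,1) draws, fresh per component.
    """
    d = p.position.shape[0]
    n1 = rng.random(d)
    n2 = rng.random(d)
    v = (
        config.inertia * p.velocity
        + config.c1 * n1 * (p.best_position - p.position)
        + config.c2 * n2 * (np.asarray(global_best) - p.position)
    )
    return np.clip(v, -config.v_max, config.v_max)


def pso_position_update(p: Particle) -> np.ndarray:
    """X' = X + v (velocity assumed already updated)."""
    return p.position + p.velocity


def bpso_step(p: Particle, global_best, config: SwarmConfig, rng) -> np.ndarray:
    """Binary-PSO move: update velocity, then set each bit to 1 with
    probability sigmoid(v), using a fresh uniform draw per component."""
    p.velocity = pso_velocity_update(p, global_best, config, rng)
    prob = 1.0 / (1.0 + np.exp(-p.velocity))
    n3 = rng.random(p.position.shape[0])
    return (n3 < prob).astype(float)


# ---------------------------------------------------------------------------
# generic batched swarms


@dataclass
class SwarmResult:
    best_position: np.ndarray
    best_fitness: float
    history: list = field(default_factory=list)  # global best per iteration
    n_iterations: int = 0


def minimize_pso(objective, init_positions, config: SwarmConfig, rng,
                 project=None) -> SwarmResult:
    """Global-best continuous PSO.  ``objective(X)`` maps a (P, D) position
    matrix to a length-P fitness vector; ``project`` optionally maps
    positions back into the feasible set after every move."""
    X = np.array(init_positions, dtype=float)
    if project is not None:
        X = project(X)
    P, D = X.shape
    V = np.zeros_like(X)
    fit = np.asarray(objective(X), dtype=float)
    B = X.copy()
    bfit = fit.copy()
    g = int(np.argmin(bfit))
    gbest, gfit = B[g].copy(), float(bfit[g])
    history = [gfit]
    stalled = 0
    it = 0
    for it in range(1, config.n_iterations + 1):
        n1 = rng.random((P, D))
        n2 = rng.random((P, D))
        V = (config.inertia * V
             + config.c1 * n1 * (B - X)
             + config.c2 * n2 * (gbest[None, :] - X))
        np.clip(V, -config.v_max, config.v_max, out=V)
        X = X + V
        if project is not None:
            X = project(X)
        fit = np.asarray(objective(X), dtype=float)
        improved = fit < bfit
        B[improved] = X[improved]
        bfit[improved] = fit[improved]
        g = int(np.argmin(bfit))
        if bfit[g] < gfit - config.early_stop_tol:
            stalled = 0
        else:
            stalled += 1
        if bfit[g] < gfit:
            gbest, gfit = B[g].copy(), float(bfit[g])
        history.append(gfit)
        if stalled >= config.early_stop_patience:
            break
    return SwarmResult(gbest, gfit, history, it)


def minimize_bpso(objective, init_positions, config: SwarmConfig, rng) -> SwarmResult:
    """Global-best binary PSO over bit vectors (same velocity dynamics).

    Binary swarms collapse onto the global best quickly, so instead of
    stopping early a stalled swarm (no improvement for
    ``early_stop_patience`` iterations) is re-randomized -- personal bests
    and velocities reset, global best kept -- and the iteration budget is
    always used in full.
    """
    X = np.array(init_positions, dtype=float)
    P, D = X.shape
    V = np.zeros_like(X)
    fit = np.asarray(objective(X), dtype=float)
    B = X.copy()
    bfit = fit.copy()
    g = int(np.argmin(bfit))
    gbest, gfit = B[g].copy(), float(bfit[g])
    history = [gfit]
    stalled = 0
    it = 0
    for it in range(1, config.n_iterations + 1):
        n1 = rng.random((P, D))
        n2 = rng.random((P, D))
        V = (config.inertia * V
             + config.c1 * n1 * (B - X)
             + config.c2 * n2 * (gbest[None, :] - X))
        np.clip(V, -config.v_max, config.v_max, out=V)
        prob = 1.0 / (1.0 + np.exp(-V))
        X = (rng.random((P, D)) < prob).astype(float)
        fit = np.asarray(objective(X), dtype=float)
        improved = fit < bfit
        B[improved] = X[improved]
        bfit[improved] = fit[improved]
        g = int(np.argmin(bfit))
        if bfit[g] < gfit - config.early_stop_tol:
            stalled = 0
        else:
            stalled += 1
        if bfit[g] < gfit:
            gbest, gfit = B[g].copy(), float(bfit[g])
        history.append(gfit)
        if stalled >= config.early_stop_patience:
            X = (rng.random((P, D)) < 0.5).astype(float)
            V = np.zeros_like(X)
            B = X.copy()
            bfit = np.asarray(objective(X), dtype=float)
            stalled = 0
    return SwarmResult(gbest, gfit, history, it)


# ---------------------------------------------------------------------------
# compiled (array) view of a model for batched forward passes


class _Template:
    """Flat-array view of a model's shape and parameters."""

    def __init__(self, model: ENFRNModel):
        self.n_inputs = model.n_inputs
        self.n_sets = [len(v.sets) for v in model.inputs]
        self.S = sum(self.n_sets)
        offsets = np.cumsum([0] + self.n_sets)
        self.inp_of_set = np.concatenate(
            [np.full(n, i, dtype=int) for i, n in enumerate(self.n_sets)]
        ) if self.S else np.zeros(0, dtype=int)
        self.set_centers = np.array(
            [s.center for v in model.inputs for s in v.sets])
        self.set_widths = np.array(
            [s.width for v in model.inputs for s in v.sets])
        self.betas = np.array(
            [b for v in model.inputs for b in v.feedback_weights])
        self.rule_sets = np.array(
            [[offsets[i] + j for i, j in enumerate(r.precondition)]
             for r in model.rules], dtype=int)
        self.consequent = np.array([r.consequent for r in model.rules], dtype=int)
        self.out_centers = np.array([o.center for o in model.outputs])
        self.out_widths = np.array([o.width for o in model.outputs])
        self.M = model.n_rules
        self.n_out = model.n_outputs

    @property
    def n_params(self) -> int:
        return 3 * self.S + 2 * self.n_out

    def theta_slices(self):
        S, No = self.S, self.n_out
        return {
            "set_centers": slice(0, S),
            "set_widths": slice(S, 2 * S),
            "out_centers": slice(2 * S, 2 * S + No),
            "out_widths": slice(2 * S + No, 2 * S + 2 * No),
            "betas": slice(2 * S + 2 * No, 3 * S + 2 * No),
        }


def encode_parameters(model: ENFRNModel) -> np.ndarray:
    """Flatten all tunable parameters: input-term centers and widths, output
    centers and widths, recurrent link weights (in that order)."""
    t = _Template(model)
    return np.concatenate(
        [t.set_centers, t.set_widths, t.out_centers, t.out_widths, t.betas]
    )


def decode_parameters(model: ENFRNModel, theta) -> ENFRNModel:
    """Rebuild a model with parameters from ``theta``; widths are floored at
    SIGMA_MIN so every decoded model is valid."""
    theta = np.asarray(theta, dtype=float)
    t = _Template(model)
    if theta.shape != (t.n_params,):
        raise InvalidModelError(
            f"parameter vector length {theta.shape} != expected ({t.n_params},)")
    sl = t.theta_slices()
    out = model.copy()
    k = 0
    centers = theta[sl["set_centers"]]
    widths = np.maximum(theta[sl["set_widths"]], SIGMA_MIN)
    betas = theta[sl["betas"]]
    for var in out.inputs:
        for j in range(len(var.sets)):
            var.sets[j].center = float(centers[k])
            var.sets[j].width = float(widths[k])
            var.feedback_weights[j] = float(betas[k])
            k += 1
    oc = theta[sl["out_centers"]]
    ow = np.maximum(theta[sl["out_widths"]], SIGMA_MIN)
    for j, node in enumerate(out.outputs):
        node.center = float(oc[j])
        node.width = float(ow[j])
    reset_state(out)
    return out


# ---------------------------------------------------------------------------
# phase 2: structure simplification


def apply_rule_mask(model: ENFRNModel, mask) -> ENFRNModel:
    """Sub-model keeping the masked-in rules; orphan output nodes and orphan
    input terms are dropped and all indices remapped."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape[0] != model.n_rules:
        raise InvalidModelError("mask length != number of rules")
    if not mask.any():
        raise InvalidModelError("mask keeps no rules")
    out = model.copy()
    out.rules = [r for r, keep in zip(out.rules, mask) if keep]
    # drop orphan output nodes
    used_out = sorted({r.consequent for r in out.rules})
    remap_out = {old: new for new, old in enumerate(used_out)}
    out.outputs = [out.outputs[j] for j in used_out]
    for r in out.rules:
        r.consequent = remap_out[r.consequent]
    # drop orphan input terms
    for i, var in enumerate(out.inputs):
        used = sorted({r.precondition[i] for r in out.rules})
        remap = {old: new for new, old in enumerate(used)}
        var.sets = [var.sets[j] for j in used]
        var.feedback_weights = [var.feedback_weights[j] for j in used]
        var.state = [0.0] * len(var.sets)
        for r in out.rules:
            r.precondition[i] = remap[r.precondition[i]]
    out.validate()
    return out


def _mse(model: ENFRNModel, inputs, target) -> float:
    preds = forward_sequence(model, inputs)
    T = np.asarray(target).shape[0]
    resid = preds[: T - 1] - np.asarray(target, dtype=float)[1:]
    return float(np.mean(resid**2))


def structure_fitness(model: ENFRNModel, mask, data) -> float:
    """MSE/(M - N + 1) of the sub-model keeping the masked-in rules; an
    empty mask is never selectable (+inf)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return math.inf
    sub = apply_rule_mask(model, mask)
    inputs, target = data
    M, N = model.n_rules, int(mask.sum())
    return _mse(sub, inputs, target) / (M - N + 1)


def _firing_matrix(model: ENFRNModel, inputs) -> np.ndarray:
    """Recurrent firing strengths F[t, r] for t = 0..T-2 (lag-1 patterns).

    Layer-2 memberships (and hence firing) do not depend on which rules are
    kept, so one pass serves every mask.
    """
    t = _Template(model)
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    T = inputs.shape[1]
    Tp = T - 1
    F = np.empty((Tp, t.M))
    state = np.zeros(t.S)
    for step in range(Tp):
        xv = inputs[t.inp_of_set, step]
        phi = xv + t.betas * state
        memb = np.exp(-(((phi - t.set_centers) / t.set_widths) ** 2))
        state = memb
        fir = memb[t.rule_sets[:, 0]]
        for i in range(1, t.n_inputs):
            fir = fir * memb[t.rule_sets[:, i]]
        F[step] = fir
    return F


def mask_fitness_batch(model: ENFRNModel, masks, data) -> np.ndarray:
    """Vectorized structure_fitness for a (P, M) matrix of masks."""
    inputs, target = data
    target = np.asarray(target, dtype=float)
    t = _Template(model)
    F = _firing_matrix(model, inputs)
    masks = np.asarray(masks, dtype=float)
    w = t.out_widths[t.consequent]
    wc = w * t.out_centers[t.consequent]
    num = F @ (masks * wc).T  # (Tp, P)
    den = F @ (masks * w).T
    y = np.empty_like(num)
    ok = den >= DENOM_FLOOR
    y[ok] = num[ok] / den[ok]
    if not ok.all():
        bad_t, bad_p = np.nonzero(~ok)
        for tt, pp in zip(bad_t, bad_p):
            fm = F[tt] * masks[pp]
            y[tt, pp] = t.out_centers[t.consequent[int(np.argmax(fm))]]
    resid = y - target[1:, None]
    mse = np.mean(resid**2, axis=0)
    N = masks.sum(axis=1)
    fitness = np.where(N > 0, mse / (t.M - N + 1), math.inf)
    return fitness


def exhaustive_best_mask(model: ENFRNModel, data) -> tuple[np.ndarray, float]:
    """Brute-force minimum of the pruning fitness over all non-empty masks
    (2^M - 1 candidates; guarded to M <= 16)."""
    M = model.n_rules
    if M > 16:
        raise ValueError("exhaustive search guarded to <= 16 rules")
    codes = np.arange(1, 2**M)
    masks = ((codes[:, None] >> np.arange(M)[None, :]) & 1).astype(float)
    fitness = mask_fitness_batch(model, masks, data)
    best = int(np.argmin(fitness))
    return masks[best], float(fitness[best])


def simplify_structure(model: ENFRNModel, data, config: SwarmConfig | None = None,
                       rng=None) -> ENFRNModel:
    """Binary-PSO rule pruning; returns the sub-model of the best mask found.

    Particle 0 starts at the all-ones mask, so the unpruned model is always a
    candidate and the result is never worse than the input.
    """
    config = config or SwarmConfig.bpso_defaults()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    inputs, target = data
    T = np.atleast_2d(np.asarray(inputs)).shape[1]
    if T < 3:
        logger.warning("series too short (<3 points) for pruning; model unchanged")
        return model.copy()
    M = model.n_rules
    if M <= 1:
        return model.copy()
    init = (rng.random((config.n_particles, M)) < 0.5).astype(float)
    init[0] = 1.0
    result = minimize_bpso(
        lambda masks: mask_fitness_batch(model, masks, data), init, config, rng
    )
    return apply_rule_mask(model, result.best_position)


# ---------------------------------------------------------------------------
# phase 3: parameter fine-tuning


def parameter_fitness(model: ENFRNModel, theta, data) -> float:
    """RMSE of the model decoded from ``theta`` on the lag-1 patterns."""
    decoded = decode_parameters(model, theta)
    inputs, target = data
    return math.sqrt(_mse(decoded, inputs, target))


def _param_rmse_batch(template: _Template, thetas, inputs, target) -> np.ndarray:
    """Vectorized RMSE for a (P, D) matrix of parameter vectors."""
    t = template
    thetas = np.asarray(thetas, dtype=float)
    P = thetas.shape[0]
    sl = t.theta_slices()
    C = thetas[:, sl["set_centers"]]
    W = np.maximum(thetas[:, sl["set_widths"]], SIGMA_MIN)
    B = thetas[:, sl["betas"]]
    OC = thetas[:, sl["out_centers"]]
    OW = np.maximum(thetas[:, sl["out_widths"]], SIGMA_MIN)
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    target = np.asarray(target, dtype=float)
    T = inputs.shape[1]
    Tp = T - 1
    state = np.zeros((P, t.S))
    wr = np.take_along_axis(OW, np.broadcast_to(t.consequent, (P, t.M)), axis=1)
    wcr = wr * np.take_along_axis(OC, np.broadcast_to(t.consequent, (P, t.M)), axis=1)
    sse = np.zeros(P)
    for step in range(Tp):
        xv = inputs[t.inp_of_set, step]
        phi = xv[None, :] + B * state
        memb = np.exp(-(((phi - C) / W) ** 2))
        state = memb
        fir = memb[:, t.rule_sets[:, 0]]
        for i in range(1, t.n_inputs):
            fir = fir * memb[:, t.rule_sets[:, i]]
        num = np.einsum("pm,pm->p", fir, wcr)
        den = np.einsum("pm,pm->p", fir, wr)
        y = np.empty(P)
        ok = den >= DENOM_FLOOR
        y[ok] = num[ok] / den[ok]
        if not ok.all():
            for p in np.nonzero(~ok)[0]:
                y[p] = OC[p, t.consequent[int(np.argmax(fir[p]))]]
        sse += (y - target[step + 1]) ** 2
    return np.sqrt(sse / Tp)


def train_parameters(model: ENFRNModel, data, config: SwarmConfig | None = None,
                     rng=None, jitter: float = 0.1) -> ENFRNModel:
    """Continuous-PSO fine-tuning of all centers, widths and link weights.

    The swarm starts at the model's own encoding (particle 0) plus Gaussian
    jitter, so the returned model's RMSE never exceeds the input's.
    """
    config = config or SwarmConfig.pso_defaults()
    if config.n_iterations == 0:
        return model.copy()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    inputs, target = data
    t = _Template(model)
    theta0 = encode_parameters(model)
    init = theta0[None, :] + rng.normal(0.0, jitter, (config.n_particles, theta0.shape[0]))
    init[0] = theta0
    sl = t.theta_slices()

    def project(X):
        X = np.array(X, dtype=float)
        X[:, sl["set_widths"]] = np.maximum(X[:, sl["set_widths"]], SIGMA_MIN)
        X[:, sl["out_widths"]] = np.maximum(X[:, sl["out_widths"]], SIGMA_MIN)
        return X

    result = minimize_pso(
        lambda X: _param_rmse_batch(t, X, inputs, target), project(init), config,
        rng, project=project,
    )
    return decode_parameters(model, result.best_position)
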