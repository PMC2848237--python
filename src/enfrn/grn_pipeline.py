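"""Three-stage regulator search and network assembly over a gene set.

For every target gene: (1) every other gene is fitted alone through the
cheap self-organizing phase and the best ``n_candidates`` regulators are
kept by composite score; (2) all non-empty subsets of the candidates are
fitted the same way and the ``n_best_subsets`` lowest-error subsets survive;
(3) the surviving subsets are pruned (binary PSO) and fine-tuned
(continuous PSO), rescored, and the ``n_final`` best configurations become
the target's regulators.  Edges carry the configuration's composite score
and each member regulator's own single-regulator sign; edges scoring above
the composite-score threshold, or with no stable regulation type, are
dropped.

Also hosts the tab-delimited expression-matrix reader (first column gene
identifier, header row time labels), per-gene min-max normalization to
[0, 1], missing-value interpolation, and the TSV/SIF network writers.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .core_network import ENFRNModel, sequence_rmse
from .regulation_scoring import NONE, RegulationResult, score_model
from .structure_learning import StructureConfig, build_initial_structure
from .swarm_optimization import SwarmConfig, simplify_structure, train_parameters

logger = logging.getLogger(__name__)

MAX_MISSING_FRACTION = 0.3


@dataclass
class ExpressionDataset:
    """Normalized genes x time matrix with inversion metadata."""

    gene_names: list[str]
    times: list[str]
    values: np.ndarray  # (G, T), per-gene min-max normalized to [0, 1]
    normalization: list[tuple[float, float]]  # per-gene (min, max)
    missing: np.ndarray | None = None  # pre-interpolation NaN flags

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def series(self, gene: str) -> np.ndarray:
        return self.values[self.index(gene)]

    def matrix(self, genes) -> np.ndarray:
        return np.vstack([self.series(g) for g in genes])


def dataset_from_frame(frame: pd.DataFrame, gene_subset=None) -> ExpressionDataset:
    """Preprocess a genes x time DataFrame: subset, interpolate missing
    values over time (genes with > 30% missing are dropped), min-max
    normalize each gene to [0, 1]."""
    if frame.index.duplicated().any():
        dupes = sorted(set(frame.index[frame.index.duplicated()]))
        raise ValueError(f"duplicate gene identifiers: {', '.join(map(str, dupes))}")
    if frame.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    if gene_subset is not None:
        missing_genes = [g for g in gene_subset if g not in frame.index]
        if missing_genes:
            raise ValueError(f"genes not in matrix: {', '.join(missing_genes)}")
        frame = frame.loc[list(gene_subset)]
    values = frame.to_numpy(dtype=float)
    missing = np.isnan(values)
    keep = missing.mean(axis=1) <= MAX_MISSING_FRACTION
    for g in frame.index[~keep]:
        logger.warning("dropping gene %s (> %.0f%% missing)", g, 100 * MAX_MISSING_FRACTION)
    frame = frame.loc[keep]
    missing = missing[keep]
    interp = frame.astype(float).interpolate(axis=1, limit_direction="both")
    if interp.isna().any().any():
        bad = sorted(interp.index[interp.isna().any(axis=1)])
        raise ValueError(f"genes with no observed values: {', '.join(map(str, bad))}")
    values = interp.to_numpy(dtype=float)
    norm = []
    normalized = np.empty_like(values)
    for i in range(values.shape[0]):
        lo, hi = float(values[i].min()), float(values[i].max())
        norm.append((lo, hi))
        if hi > lo:
            normalized[i] = (values[i] - lo) / (hi - lo)
        else:
            logger.warning("gene %s is constant; normalized to 0.5", frame.index[i])
            normalized[i] = 0.5
    return ExpressionDataset(
        gene_names=[str(g) for g in frame.index],
        times=[str(c) for c in frame.columns],
        values=normalized,
        normalization=norm,
        missing=missing,
    )


def load_expression(path, gene_subset=None) -> ExpressionDataset:
    """Read a tab-delimited matrix (first column gene ID, header row time
    labels; empty cells are missing values)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - message shaping
        raise ValueError(f"cannot parse expression matrix {path}: {exc}") from exc
    non_numeric = [c for c in frame.columns
                   if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric expression columns: {', '.join(non_numeric)}")
    return dataset_from_frame(frame, gene_subset)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Regulator-search settings (see module docstring for the stages)."""

    n_candidates: int = 5
    n_best_subsets: int = 5
    n_final: int = 1
    cs_weight: float = 0.6
    cs_threshold: float = 0.6
    seed: int = 0
    structure: StructureConfig = field(default_factory=StructureConfig)
    bpso: SwarmConfig = field(default_factory=SwarmConfig.bpso_defaults)
    pso: SwarmConfig = field(default_factory=SwarmConfig.pso_defaults)

    def __post_init__(self) -> None:
        if self.n_final > self.n_best_subsets:
            raise ValueError("n_final must be <= n_best_subsets")
        if not 1 <= self.n_candidates <= 12:
            raise ValueError("n_candidates must lie in 1..12 (2^N subsets are enumerated)")

    @classmethod
    def from_dict(cls, doc: dict | None, **overrides) -> "PipelineConfig":
        doc = dict(doc or {})
        kwargs = dict(doc.get("pipeline", {}))
        kwargs.update(overrides)
        bpso = {**SwarmConfig.bpso_defaults().__dict__, **(doc.get("bpso") or {})}
        pso = {**SwarmConfig.pso_defaults().__dict__, **(doc.get("pso") or {})}
        return cls(
            structure=StructureConfig.from_dict(doc.get("structure")),
            bpso=SwarmConfig(**bpso),
            pso=SwarmConfig(**pso),
            **kwargs,
        )

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc, **overrides)

    def to_dict(self) -> dict:
        doc = asdict(self)
        return {
            "pipeline": {k: v for k, v in doc.items()
                         if k not in ("structure", "bpso", "pso")},
            "structure": doc["structure"],
            "bpso": doc["bpso"],
            "pso": doc["pso"],
        }


def _stage_rng(seed: int, target: str, stage: int, extra: int = 0):
    """Per-(target, stage) RNG stream, independent of gene iteration order."""
    key = [int(seed) & 0x7FFFFFFF, zlib.crc32(target.encode()), stage, extra]
    return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# the three stages


def fit_phase1(data: ExpressionDataset, regulators, target: str,
               structure: StructureConfig) -> ENFRNModel:
    """Cheap self-organizing fit of target ~ regulators (no swarm phases)."""
    model = build_initial_structure(
        data.matrix(regulators), data.series(target), structure,
        input_names=list(regulators), output_name=target,
    )
    return model


def stage1_rank_candidates(data: ExpressionDataset, target: str,
                           config: PipelineConfig
                           ) -> tuple[list[str], dict[str, RegulationResult]]:
    """Rank every other gene alone by composite score; keep the best
    ``n_candidates`` (ties break on gene name)."""
    others = [g for g in data.gene_names if g != target]
    if len(others) < 1:
        raise ValueError("need at least one candidate regulator")
    results: dict[str, RegulationResult] = {}
    for gene in others:
        model = fit_phase1(data, [gene], target, config.structure)
        results[gene] = score_model(
            model, data.matrix([gene]), data.series(target),
            cs_weight=config.cs_weight,
        )
    ranked = sorted(others, key=lambda g: (results[g].composite_score, g))
    return ranked[: config.n_candidates], results


def stage2_select_subsets(data: ExpressionDataset, target: str,
                          candidates, config: PipelineConfig
                          ) -> list[tuple[tuple[str, ...], float]]:
    """Enumerate all 2^N_k - 1 non-empty candidate subsets, fit each through
    the self-organizing phase only, keep the ``n_best_subsets`` lowest-RMSE
    subsets."""
    if not candidates:
        raise ValueError("no candidate regulators")
    scored = []
    for r in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            subset = tuple(sorted(combo))
            model = fit_phase1(data, list(subset), target, config.structure)
            rmse = sequence_rmse(model, data.matrix(list(subset)), data.series(target))
            scored.append((subset, rmse))
    scored.sort(key=lambda item: (item[1], item[0]))
    return scored[: config.n_best_subsets]


def stage3_finalize(data: ExpressionDataset, target: str, subsets,
                    config: PipelineConfig, test_data: ExpressionDataset | None = None
                    ) -> list[tuple[tuple[str, ...], RegulationResult, ENFRNModel]]:
    """Prune and fine-tune each surviving subset, rescore with the trained
    model, return the ``n_final`` lowest-CS configurations."""
    finals = []
    for k, (subset, _) in enumerate(subsets):
        X = data.matrix(list(subset))
        y = data.series(target)
        model = fit_phase1(data, list(subset), target, config.structure)
        model = simplify_structure(
            model, (X, y), config.bpso, rng=_stage_rng(config.seed, target, 2, k))
        model = train_parameters(
            model, (X, y), config.pso, rng=_stage_rng(config.seed, target, 3, k))
        if test_data is not None:
            Xs = test_data.matrix(list(subset))
            ys = test_data.series(target)
        else:
            Xs, ys = X, y
        result = score_model(model, Xs, ys, cs_weight=config.cs_weight)
        finals.append((subset, result, model))
    finals.sort(key=lambda item: (item[1].composite_score, item[0]))
    return finals[: config.n_final]


# ---------------------------------------------------------------------------
# network assembly and I/O


@dataclass(frozen=True)
class GRNEdge:
    regulator: str
    target: str
    type: str  # "+" activation, "-" repression
    rs_raw: float
    composite_score: float

    @property
    def sign(self) -> int:
        return +1 if self.type == "+" else -1


def find_regulators(data: ExpressionDataset, target: str, config: PipelineConfig,
                    test_data: ExpressionDataset | None = None):
    """Run the three stages for one target; returns (finals, stage1 results)."""
    candidates, s1 = stage1_rank_candidates(data, target, config)
    subsets = stage2_select_subsets(data, target, candidates, config)
    finals = stage3_finalize(data, target, subsets, config, test_data)
    return finals, s1


def reconstruct_network(data: ExpressionDataset, config: PipelineConfig | None = None,
                        test_data: ExpressionDataset | None = None) -> list[GRNEdge]:
    """Infer a signed network over the whole dataset.

    Every gene is taken as target in turn; each winning configuration emits
    one edge per member regulator, signed by that regulator's single-input
    regulation score and weighted by the configuration's composite score.
    Edges above the composite-score threshold or typed "none" are dropped;
    self-edges cannot arise.
    """
    config = config or PipelineConfig()
    if data.n_genes < 3:
        raise ValueError("need at least 3 genes to reconstruct a network")
    edges: list[GRNEdge] = []
    for target in data.gene_names:
        logger.info("target %s: searching regulators", target)
        finals, s1 = find_regulators(data, target, config, test_data)
        for subset, result, _model in finals:
            if result.composite_score > config.cs_threshold:
                continue
            for reg in subset:
                single = s1[reg]
                if single.regulation_type == NONE:
                    continue
                edges.append(GRNEdge(
                    regulator=reg,
                    target=target,
                    type="+" if single.regulation_type == "up" else "-",
                    rs_raw=float(single.rs_raw),
                    composite_score=result.composite_score,
                ))
    edges.sort(key=lambda e: (e.target, e.composite_score, e.regulator))
    return edges


_TSV_HEADER = "regulator\ttarget\ttype\trs_raw\tcomposite_score"


def write_network(edges, path, format: str = "tsv") -> None:
    """Write edges as TSV (6 significant digits) or SIF
    (activates/represses), stably sorted by (target, composite score)."""
    edges = sorted(edges, key=lambda e: (e.target, e.composite_score, e.regulator))
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write(_TSV_HEADER + "\n")
            for e in edges:
                fh.write(f"{e.regulator}\t{e.target}\t{e.type}\t"
                         f"{e.rs_raw:.6g}\t{e.composite_score:.6g}\n")
        elif format == "sif":
            for e in edges:
                relation = "activates" if e.type == "+" else "represses"
                fh.write(f"{e.regulator}\t{relation}\t{e.target}\n")
        else:
            raise ValueError(f"unknown network format {format!r}")


def read_network(path) -> list[GRNEdge]:
    """Read back a TSV edge list written by :func:`write_network`."""
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError("not an edge-list TSV")
        for line in fh:
            reg, tgt, etype, rs, cs = line.rstrip("\n").split("\t")
            edges.append(GRNEdge(reg, tgt, etype, float(rs), float(cs)))
    return edges
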