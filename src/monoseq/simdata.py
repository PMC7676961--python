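"""Synthetic expression cohorts with planted monotone genes.

The generator emulates the structure of staged bulk-expression cohorts: a
few thousand genes on a log-like scale (microarray summaries or
log2(FPKM+1)), 4-5 ordered groups of a handful to a few dozen samples
each, a sparse symmetric gene-interaction network, and a minority of genes
whose stage means drift monotonically.  Background genes are i.i.d.
Gaussian around a common baseline; a planted monotonically increasing (MI)
gene at stage k has mean ``baseline + k * effect_step * noise_sd``, and a
planted decreasing (MD) gene mirrors it.  Ground truth travels with the
data so detector sensitivity and false-discovery proportion are measurable
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import GeneNetwork, _network_from_edges
from .megdetect import StageDesign

__all__ = [
    "SimTruth",
    "simulate_network",
    "simulate_expression",
    "default_truth",
    "hub_planted_truth",
]


@dataclass
class SimTruth:
    """Planted-signal ground truth and simulation parameters.

    ``effect_step`` is the per-stage mean shift in units of ``noise_sd``,
    so effect_step = 1 plants a one-standard-deviation step per stage.
    """

    mi_genes: frozenset[str]
    md_genes: frozenset[str]
    stage_sizes: dict[int, int]
    effect_step: float = 1.0
    noise_sd: float = 1.0
    baseline: float = 8.0
    seed: int = 0
    shape: str = "linear"

    def __post_init__(self) -> None:
        self.mi_genes = frozenset(self.mi_genes)
        self.md_genes = frozenset(self.md_genes)
        if self.mi_genes & self.md_genes:
            raise ValueError("a gene cannot be planted both MI and MD")
        if self.effect_step < 0:
            raise ValueError("effect_step must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not self.stage_sizes:
            raise ValueError("stage_sizes must not be empty")
        if any(n < 1 for n in self.stage_sizes.values()):
            raise ValueError("every stage needs at least one sample")
        if self.shape not in ("linear", "plateau"):
            raise ValueError(f"unknown effect shape {self.shape!r}")


def simulate_network(
    p: int,
    model: str = "scale_free",
    density_or_attachment: float | int = 2,
    seed: int = 0,
) -> GeneNetwork:
    """Random interaction network over genes ``G0000..G<p-1>``.

    ``model='erdos_renyi'`` uses ``density_or_attachment`` as the edge
    probability; ``'scale_free'`` uses it as the Barabasi-Albert attachment
    count m, giving the heavy-tailed degree distribution typical of
    protein-interaction networks (edge count m*(p-m) for p > m).
    """
    if p < 2:
        raise ValueError("need at least 2 genes")
    genes = [f"G{k:04d}" for k in range(p)]
    if model == "erdos_renyi":
        prob = float(density_or_attachment)
        if not 0.0 <= prob <= 1.0:
            raise ValueError("edge probability must be in [0, 1]")
        g = nx.gnp_random_graph(p, prob, seed=seed)
    elif model == "scale_free":
        m = int(density_or_attachment)
        if not 1 <= m < p:
            raise ValueError("attachment count must satisfy 1 <= m < p")
        g = nx.barabasi_albert_graph(p, m, seed=seed)
    else:
        raise ValueError(f"unknown network model {model!r}")
    edges = {(min(a, b), max(a, b)) for a, b in g.edges() if a != b}
    return _network_from_edges(genes, edges)


def _stage_offsets(stages: np.ndarray, truth: SimTruth) -> np.ndarray:
    """Per-sample mean offset multiplier (in noise-sd units) for an MI gene."""
    if truth.shape == "linear":
        return stages.astype(float)
    # plateau: rises for the first half of the stage range, then flat —
    # still satisfies the non-strict monotone chain, exercising ties
    levels = np.unique(stages)
    knee = levels[len(levels) // 2]
    return np.minimum(stages, knee).astype(float)


def simulate_expression(
    truth: SimTruth, p: int, gene_prefix: str = "G"
) -> tuple["ExpressionMatrix", StageDesign]:
    """Draw a genes-by-samples matrix plus stage design from ``truth``.

    Genes are named ``G0000..``; planted identifiers in ``truth`` must be a
    subset of that universe.  Reproducible: the same truth (including its
    seed) yields a bit-identical matrix.
    """
    from .io import ExpressionMatrix

    n_planted = len(truth.mi_genes) + len(truth.md_genes)
    if p < n_planted:
        raise ValueError(f"p={p} smaller than {n_planted} planted genes")
    genes = [f"{gene_prefix}{k:04d}" for k in range(p)]
    universe = set(genes)
    missing = (truth.mi_genes | truth.md_genes) - universe
    if missing:
        raise ValueError(f"planted genes outside universe: {sorted(missing)[:5]}")

    stage_codes = sorted(truth.stage_sizes)
    stages = np.concatenate(
        [np.full(truth.stage_sizes[k], k, dtype=np.int64) for k in stage_codes]
    )
    samples = [f"S{j:04d}" for j in range(len(stages))]

    rng = np.random.default_rng(truth.seed)
    V = rng.normal(truth.baseline, truth.noise_sd, size=(p, len(stages)))
    offset = _stage_offsets(stages, truth) * truth.effect_step * truth.noise_sd
    for i, g in enumerate(genes):
        if g in truth.mi_genes:
            V[i] += offset
        elif g in truth.md_genes:
            V[i] -= offset
    expr = ExpressionMatrix(genes, samples, V, scale_note="synthetic log-like")
    design = StageDesign(samples, stages)
    return expr, design


def default_truth(
    p: int = 1000,
    n_mi: int = 50,
    n_md: int = 50,
    stage_sizes: dict[int, int] | None = None,
    effect_step: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 7,
    shape: str = "linear",
) -> SimTruth:
    """Study-scale default: 4 stages x 15 samples, 50 MI + 50 MD in 1000 genes.

    Planted genes occupy the first ``n_mi + n_md`` identifier slots (MI
    first), which keeps truth bookkeeping trivial; gene order carries no
    information for any detector in this package.
    """
    if stage_sizes is None:
        stage_sizes = {1: 15, 2: 15, 3: 15, 4: 15}
    mi = frozenset(f"G{k:04d}" for k in range(n_mi))
    md = frozenset(f"G{k:04d}" for k in range(n_mi, n_mi + n_md))
    return SimTruth(
        mi_genes=mi,
        md_genes=md,
        stage_sizes=stage_sizes,
        effect_step=effect_step,
        noise_sd=noise_sd,
        seed=seed,
        shape=shape,
    )


def hub_planted_truth(net: GeneNetwork, n_mi: int, n_md: int, **kwargs) -> SimTruth:
    """Plant signal on the network's highest-degree genes (hubs first).

    Exercises the intended behaviour of the network weighting: monotone
    signal carried by well-connected genes is reinforced by their
    neighbours' scores, whereas degree-agnostic placement leaves the
    weighting nothing to exploit.  Remaining keyword arguments go to
    :class:`SimTruth`.
    """
    order = np.argsort(-net.degree, kind="stable")
    picked = [net.genes[i] for i in order[: n_mi + n_md]]
    kwargs.setdefault("stage_sizes", {1: 15, 2: 15, 3: 15, 4: 15})
    return SimTruth(
        mi_genes=frozenset(picked[:n_mi]),
        md_genes=frozenset(picked[n_mi:]),
        **kwargs,
    )
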