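"""Monotone differential-expression screen across ordered stages.

Three steps per gene: (1) a Kruskal-Wallis test of expression (raw or
network-weighted) across the ordinal stage groups; (2) multiple-testing
adjustment across genes (Benjamini-Hochberg by default); (3) for genes
passing the adjusted-p threshold, classification of the stage-mean profile
as monotonically increasing (MI), monotonically decreasing (MD), or
neither.  A stage coded 0 denotes a normal-control group and, when present,
contributes the first mean of the monotonicity chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "StageDesign",
    "kruskal_wallis",
    "adjust_pvalues",
    "monotonic_direction",
    "identify_megs",
    "meg_counts",
]


@dataclass
class StageDesign:
    """Per-sample ordinal stage assignment.

    Stage codes are nonnegative integers; 0 is reserved for a normal
    control group, 1..K for pathologic stages in progression order.
    ``stage_labels`` optionally maps codes to display names (e.g.
    ``{1: "IA", 2: "IB", 3: "IIA", 4: "IIB"}``).
    """

    samples: list[str]
    stage: np.ndarray
    stage_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        self.stage = np.asarray(self.stage, dtype=np.int64)
        if self.stage.shape != (len(self.samples),):
            raise ValueError("one stage code required per sample")
        if (self.stage < 0).any():
            raise ValueError("stage codes must be nonnegative integers")
        levels, counts = np.unique(self.stage, return_counts=True)
        if len(levels) < 2:
            raise ValueError("at least 2 distinct stages are required")
        for lev, cnt in zip(levels, counts):
            if cnt < 3:
                logger.warning("stage %d has only %d sample(s)", lev, cnt)

    @property
    def stages_present(self) -> np.ndarray:
        """Sorted distinct stage codes."""
        return np.unique(self.stage)

    @property
    def has_control(self) -> bool:
        return 0 in self.stage

    @property
    def n_stages(self) -> int:
        return len(self.stages_present)

    def groups(self) -> list[np.ndarray]:
        """Sample indices per stage, in ascending stage order."""
        return [np.flatnonzero(self.stage == k) for k in self.stages_present]

    def subset(self, idx: Sequence[int]) -> "StageDesign":
        idx = np.asarray(idx)
        return StageDesign(
            [self.samples[i] for i in idx], self.stage[idx], self.stage_labels
        )


def kruskal_wallis(values: np.ndarray, design: StageDesign) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p across stages.

    A gene with zero rank variation (all observations tied) returns
    ``(0.0, 1.0)`` instead of erroring, so constant genes stay in the
    multiple-testing denominator.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.shape[0] != len(design.samples):
        raise ValueError("values length does not match design")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite expression values")
    groups = [v[g] for g in design.groups()]
    if any(len(g) == 0 for g in groups):
        raise ValueError("a stage has no observations")
    if np.all(v == v[0]):
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def adjust_pvalues(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Adjust p-values across genes: BH step-up (default), Bonferroni, or none."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    method = method.lower()
    if method == "none":
        return p.copy()
    if method in ("bh", "fdr_bh"):
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def monotonic_direction(stage_means: np.ndarray) -> str:
    """Classify a stage-mean profile as 'MI', 'MD', or 'none'.

    MI requires a nondecreasing chain with at least one strict increase;
    MD the mirror image.  An all-equal profile satisfies both non-strict
    chains but carries no trend, so it returns 'none'.
    """
    m = np.asarray(stage_means, dtype=float).ravel()
    if m.shape[0] < 2:
        raise ValueError("need at least 2 stage means")
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite stage mean")
    diffs = np.diff(m)
    if np.all(diffs >= 0) and np.any(diffs > 0):
        return "MI"
    if np.all(diffs <= 0) and np.any(diffs < 0):
        return "MD"
    return "none"


def identify_megs(
    expr_or_rank,
    design: StageDesign,
    alpha: float = 0.1,
    adjust: str = "BH",
    include_control_in_test: bool = True,
) -> pd.DataFrame:
    """Run the three-step monotone screen on every gene of a matrix.

    Parameters
    ----------
    expr_or_rank
        An ``ExpressionMatrix`` or ``GeneRankMatrix`` (anything with
        ``genes``, ``samples`` and ``values`` attributes); sample axis must
        match ``design.samples``.
    design
        Ordinal stage assignment for the samples.
    alpha
        Adjusted-p threshold; only genes at or below it get an MI/MD label.
    adjust
        Multiple-testing method passed to :func:`adjust_pvalues`.
    include_control_in_test
        When a control group (stage 0) is present, whether it forms its own
        group in the Kruskal-Wallis test.  It always contributes the first
        mean of the monotonicity chain.

    Returns
    -------
    pandas.DataFrame
        One row per gene in input order, columns ``gene``, ``kw_statistic``,
        ``p_raw``, ``p_adjusted``, ``mean_stage<k>`` for each stage present,
        and ``direction`` in {MI, MD, none}.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if list(expr_or_rank.samples) != list(design.samples):
        raise ValueError("sample axes of matrix and stage design do not match")
    V = np.asarray(expr_or_rank.values, dtype=float)
    genes = list(expr_or_rank.genes)
    stages = design.stages_present
    groups = design.groups()

    if design.has_control and not include_control_in_test:
        test_idx = np.flatnonzero(design.stage > 0)
        test_design = design.subset(test_idx)
    else:
        test_idx = None
        test_design = design

    n_genes = len(genes)
    kw_stat = np.empty(n_genes)
    p_raw = np.empty(n_genes)
    means = np.empty((n_genes, len(stages)))
    for i in range(n_genes):
        row = V[i]
        kw_stat[i], p_raw[i] = kruskal_wallis(
            row if test_idx is None else row[test_idx], test_design
        )
        means[i] = [row[g].mean() for g in groups]

    p_adj = adjust_pvalues(p_raw, adjust)
    direction = np.array(
        [
            monotonic_direction(means[i]) if p_adj[i] <= alpha else "none"
            for i in range(n_genes)
        ],
        dtype=object,
    )

    out = pd.DataFrame({"gene": genes, "kw_statistic": kw_stat, "p_raw": p_raw,
                        "p_adjusted": p_adj})
    for j, k in enumerate(stages):
        out[f"mean_stage{k}"] = means[:, j]
    out["direction"] = direction
    return out


def meg_counts(table: pd.DataFrame) -> dict[str, int]:
    """MI/MD tallies of an :func:`identify_megs` result table."""
    d = table["direction"]
    return {"MI": int((d == "MI").sum()), "MD": int((d == "MD").sum())}
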