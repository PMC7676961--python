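"""MFSelector-style monotone feature scoring via discriminating lines.

For each gene and each of the K-1 cumulative stage splits (stages <= k vs
stages > k), a single expression threshold — the "discriminating line" — is
placed to minimise the number of misclassified samples.  Under the
increasing hypothesis the lower stages should fall at or below the line and
the higher stages above it.  The DEtotal score is the sum of the K-1
minimal misclassification counts; smaller scores mean a cleaner staged
separation.  Significance comes from a stage-label permutation null with
the add-one estimator, followed by the same multiple-testing adjustment
used by the Kruskal-Wallis screen.

Conventions fixed here (the score is only defined up to them):

* candidate thresholds are the observed expression values of the gene
  (a superset of per-stage candidate sets, so the minimum can only tie or
  improve);
* a sample exactly on the line counts as below it (``value <= t``) under
  the increasing hypothesis; the decreasing hypothesis is scored as the
  increasing score of the negated values, so its boundary rule is the
  mirror image;
* on tied misclassification counts the smallest threshold wins
  (largest, by mirror symmetry, for decreasing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .megdetect import StageDesign, adjust_pvalues

__all__ = ["split_error", "detotal", "permutation_test", "mfselect", "MFScore"]


@dataclass
class MFScore:
    """DEtotal decomposition for one gene."""

    detotal: int
    split_errors: list[int]
    lines: list[float]
    perfect_monotone: bool


def _validate_direction(direction: str) -> str:
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"direction must be 'increasing' or 'decreasing', got {direction!r}")
    return direction


def split_error(
    values: np.ndarray,
    stages: np.ndarray,
    k: int,
    direction: str = "increasing",
) -> tuple[int, float]:
    """Minimal misclassification for the split (stages <= k) vs (stages > k).

    For the increasing direction a lower-group sample is misclassified when
    its value exceeds the line and an upper-group sample when its value is
    at or below it; the decreasing direction is the exact mirror image
    (the score of the negated values), so the sign-flip duality
    ``split_error(v, inc) == split_error(-v, dec)`` holds identically.
    Returns ``(min_misclassified, line)``; ties take the smallest
    minimising threshold for increasing and, by mirror symmetry, the
    largest for decreasing.
    """
    _validate_direction(direction)
    v = np.asarray(values, dtype=float).ravel()
    s = np.asarray(stages, dtype=np.int64).ravel()
    if v.shape != s.shape:
        raise ValueError("values and stages must have equal length")
    if direction == "decreasing":
        err, line = split_error(-v, s, k, "increasing")
        return err, -line
    lower = s <= k
    upper = ~lower
    if not lower.any() or not upper.any():
        raise ValueError(f"split at k={k} leaves an empty side")

    # sort candidates ascending; for each t count errors in O(n) via cumsums
    order = np.argsort(v, kind="mergesort")
    vs = v[order]
    low_s = lower[order].astype(np.int64)
    up_s = upper[order].astype(np.int64)
    # candidates: distinct observed values; threshold t classifies "<= t" low
    # errors(t) = #lower with value > t + #upper with value <= t
    distinct_end = np.flatnonzero(np.r_[vs[1:] != vs[:-1], True])
    n_low = low_s.sum()
    cum_low = np.cumsum(low_s)
    cum_up = np.cumsum(up_s)
    errs = (n_low - cum_low[distinct_end]) + cum_up[distinct_end]
    best = int(np.argmin(errs))  # argmin takes first minimum = smallest t
    return int(errs[best]), float(vs[distinct_end[best]])


def detotal(
    values: np.ndarray,
    stages: np.ndarray,
    direction: str = "increasing",
) -> MFScore:
    """Total discriminating error over all K-1 cumulative stage splits.

    ``perfect_monotone`` is True when every split separates cleanly
    (DEtotal = 0) and the K-1 minimising lines are strictly ordered in the
    tested direction (later-stage lines above earlier ones for increasing).
    """
    _validate_direction(direction)
    s = np.asarray(stages, dtype=np.int64).ravel()
    levels = np.unique(s)
    if len(levels) < 2:
        raise ValueError("need at least 2 stages")
    split_errs: list[int] = []
    lines: list[float] = []
    for k in levels[:-1]:
        err, line = split_error(values, s, int(k), direction)
        split_errs.append(err)
        lines.append(line)
    total = int(sum(split_errs))
    if direction == "increasing":
        ordered = all(b > a for a, b in zip(lines, lines[1:]))
    else:
        ordered = all(b < a for a, b in zip(lines, lines[1:]))
    return MFScore(total, split_errs, lines, total == 0 and ordered)


def permutation_test(
    values: np.ndarray,
    stages: np.ndarray,
    direction: str = "increasing",
    n_perm: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> float:
    """Permutation p-value for one gene's DEtotal.

    Stage labels are permuted ``n_perm`` times and DEtotal recomputed;
    the add-one estimator ``(1 + #{perm <= observed}) / (n_perm + 1)``
    avoids zero p-values.  Pass ``rng`` to share one generator across genes
    (labels permuted once per permutation for all genes); otherwise a fresh
    generator is seeded from ``seed``.

    With ``exhaustive`` (feasible only for small n) every label arrangement
    is enumerated once and the exact null probability
    ``#{detotal(perm) <= observed} / n!`` is returned, with no add-one
    correction; ``n_perm`` and the generator are ignored.
    """
    observed = detotal(values, stages, direction).detotal
    s = np.asarray(stages, dtype=np.int64).ravel()
    if exhaustive:
        from itertools import permutations

        if len(s) > 9:
            raise ValueError("exhaustive enumeration limited to n <= 9 samples")
        hits = total = 0
        for perm in permutations(s):
            total += 1
            if detotal(values, np.array(perm), direction).detotal <= observed:
                hits += 1
        return hits / total
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(s)
        if detotal(values, perm, direction).detotal <= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def mfselect(
    expr,
    design: StageDesign,
    direction: str = "increasing",
    alpha: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
    adjust: str = "BH",
    shared_permutations: bool = True,
) -> pd.DataFrame:
    """Score every gene of a matrix with DEtotal plus a permutation null.

    With ``shared_permutations`` (default) each of the ``n_perm`` label
    shuffles is applied to all genes at once, preserving between-gene
    correlation under the null; otherwise each gene draws its own
    permutation stream from ``seed``.

    Returns one row per gene: ``gene``, ``detotal``, ``split_errors``
    (semicolon-joined), ``perfect_monotone``, ``p_perm``, ``p_adjusted``,
    ``direction``, ``significant``.
    """
    _validate_direction(direction)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if list(expr.samples) != list(design.samples):
        raise ValueError("sample axes of matrix and stage design do not match")
    V = np.asarray(expr.values, dtype=float)
    genes = list(expr.genes)
    s = design.stage

    scores = [detotal(V[i], s, direction) for i in range(len(genes))]
    observed = np.array([sc.detotal for sc in scores])

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(genes), dtype=np.int64)
    if shared_permutations:
        for _ in range(n_perm):
            perm = rng.permutation(s)
            for i in range(len(genes)):
                if detotal(V[i], perm, direction).detotal <= observed[i]:
                    hits[i] += 1
        p_perm = (1 + hits) / (n_perm + 1)
    else:
        p_perm = np.array(
            [
                permutation_test(V[i], s, direction, n_perm=n_perm, rng=rng)
                for i in range(len(genes))
            ]
        )
    p_adj = adjust_pvalues(p_perm, adjust)

    return pd.DataFrame(
        {
            "gene": genes,
            "detotal": observed,
            "split_errors": [";".join(map(str, sc.split_errors)) for sc in scores],
            "perfect_monotone": [sc.perfect_monotone for sc in scores],
            "p_perm": p_perm,
            "p_adjusted": p_adj,
            "direction": direction,
            "significant": p_adj <= alpha,
        }
    )
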