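"""Kruskal-Wallis screen, BH adjustment, and monotone classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from monoseq.io import ExpressionMatrix
from monoseq.megdetect import (
    StageDesign,
    adjust_pvalues,
    identify_megs,
    kruskal_wallis,
    meg_counts,
    monotonic_direction,
)
from monoseq.simdata import SimTruth, simulate_expression


def brute_force_bh(p):
    """Step-up BH computed literally: sort, scale by m/i, running min, cap."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(scaled, 1.0)
    return out


class TestKruskalWallis:
    def test_three_group_oracle(self, three_stage_design):
        # ranks 1..6, group rank sums 3, 7, 11: H = 192/42
        h, p = kruskal_wallis(np.array([1, 2, 3, 4, 5, 6.0]), three_stage_design)
        assert h == pytest.approx(192 / 42, abs=1e-12)
        assert 0 < p < 1

    def test_all_tied_returns_zero_one(self, three_stage_design):
        h, p = kruskal_wallis(np.full(6, 3.7), three_stage_design)
        assert (h, p) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda v: v**3, lambda v: 2 * v + 10]
    )
    def test_rank_invariance_under_monotone_transform(
        self, three_stage_design, transform
    ):
        rng = np.random.default_rng(5)
        v = rng.normal(size=6)
        h1, p1 = kruskal_wallis(v, three_stage_design)
        h2, p2 = kruskal_wallis(transform(v), three_stage_design)
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_fewer_than_two_stages_rejected(self):
        with pytest.raises(ValueError, match="2 distinct stages"):
            StageDesign(["a", "b"], [1, 1])


class TestAdjustPvalues:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH"),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_single_p_unchanged(self):
        for method in ("BH", "bonferroni", "none"):
            assert adjust_pvalues([0.03], method) == pytest.approx([0.03])

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(adjust_pvalues(np.ones(7), "BH"), np.ones(7))

    def test_bh_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            m = rng.integers(1, 51)
            p = rng.uniform(size=m)
            np.testing.assert_allclose(
                adjust_pvalues(p, "BH"), brute_force_bh(p), atol=1e-12
            )

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=40)
        assert np.all(adjust_pvalues(p, "BH") >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])


def brute_force_direction(means):
    d = np.diff(means)
    if np.all(d >= 0) and not np.all(d == 0):
        return "MI"
    if np.all(d <= 0) and not np.all(d == 0):
        return "MD"
    return "none"


class TestMonotonicDirection:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ([1, 2, 3, 4], "MI"),
            ([4, 3, 2, 1], "MD"),
            ([1, 3, 2, 4], "none"),
            ([1, 1, 2, 2], "MI"),
            ([2, 2, 2, 2], "none"),
        ],
    )
    def test_examples(self, means, expected):
        assert monotonic_direction(means) == expected

    def test_exhaustive_sign_patterns_k4(self):
        # all 27 sign patterns of the 3 step differences
        for steps in itertools.product([-1, 0, 1], repeat=3):
            means = np.concatenate([[0.0], np.cumsum(steps)])
            assert monotonic_direction(means) == brute_force_direction(means)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            monotonic_direction([1.0, np.inf])


def planted_fixture(n_mi=50, n_md=0, p=500, effect=1.0, seed=7):
    mi = frozenset(f"G{k:04d}" for k in range(n_mi))
    md = frozenset(f"G{k:04d}" for k in range(n_mi, n_mi + n_md))
    truth = SimTruth(mi, md, {1: 15, 2: 15, 3: 15, 4: 15},
                     effect_step=effect, noise_sd=1.0, seed=seed)
    expr, design = simulate_expression(truth, p)
    return truth, expr, design


class TestIdentifyMegs:
    def test_null_noise_yields_few_calls(self):
        truth, expr, design = planted_fixture(n_mi=0, p=500, effect=0.0, seed=11)
        tab = identify_megs(expr, design, alpha=0.05)
        counts = meg_counts(tab)
        assert counts["MI"] + counts["MD"] <= 0.10 * 500

    def test_planted_mi_recovered(self):
        truth, expr, design = planted_fixture(n_mi=50, p=500, effect=1.0, seed=7)
        tab = identify_megs(expr, design, alpha=0.1)
        called_mi = set(tab.loc[tab.direction == "MI", "gene"])
        assert len(called_mi & truth.mi_genes) >= 45

    def test_labels_only_below_threshold(self):
        _, expr, design = planted_fixture(n_mi=20, p=200, effect=1.5, seed=3)
        tab = identify_megs(expr, design, alpha=0.1)
        labeled = tab.direction != "none"
        assert (tab.loc[labeled, "p_adjusted"] <= 0.1).all()

    def test_stored_means_recheck_direction(self):
        _, expr, design = planted_fixture(n_mi=20, n_md=20, p=200, seed=3)
        tab = identify_megs(expr, design, alpha=0.2)
        mean_cols = [c for c in tab.columns if c.startswith("mean_stage")]
        for _, row in tab[tab.direction != "none"].iterrows():
            assert (
                brute_force_direction(row[mean_cols].to_numpy(float))
                == row["direction"]
            )

    def test_sample_shuffle_invariance(self):
        _, expr, design = planted_fixture(n_mi=10, p=100, seed=9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(design.samples))
        expr2 = ExpressionMatrix(
            expr.genes, [expr.samples[i] for i in perm], expr.values[:, perm]
        )
        design2 = design.subset(perm)
        t1 = identify_megs(expr, design, alpha=0.1)
        t2 = identify_megs(expr2, design2, alpha=0.1)
        pd.testing.assert_frame_equal(t1, t2)

    def test_alpha_monotonicity(self):
        _, expr, design = planted_fixture(n_mi=30, n_md=30, p=300, seed=13)
        counts = [
            meg_counts(identify_megs(expr, design, alpha=a))
            for a in (0.05, 0.1, 0.15, 0.2)
        ]
        for a, b in zip(counts, counts[1:]):
            assert b["MI"] >= a["MI"] and b["MD"] >= a["MD"]

    def test_control_group_leads_the_chain(self):
        # control (stage 0) mean must occupy the first slot of the profile
        truth = SimTruth(frozenset(["G0000"]), frozenset(),
                         {0: 10, 1: 10, 2: 10, 3: 10},
                         effect_step=3.0, noise_sd=0.5, seed=21)
        expr, design = simulate_expression(truth, 50)
        assert design.has_control
        tab = identify_megs(expr, design, alpha=0.1)
        cols = [c for c in tab.columns if c.startswith("mean_stage")]
        assert cols[0] == "mean_stage0"
        row = tab[tab.gene == "G0000"].iloc[0]
        assert row["direction"] == "MI"

    def test_control_exclusion_changes_test_not_chain(self):
        truth = SimTruth(frozenset(["G0000"]), frozenset(),
                         {0: 10, 1: 10, 2: 10, 3: 10},
                         effect_step=2.0, noise_sd=0.5, seed=22)
        expr, design = simulate_expression(truth, 30)
        with_ctrl = identify_megs(expr, design, alpha=0.1,
                                  include_control_in_test=True)
        without = identify_megs(expr, design, alpha=0.1,
                                include_control_in_test=False)
        # statistics differ, but stage-mean profiles are identical
        assert not np.allclose(with_ctrl.kw_statistic, without.kw_statistic)
        cols = [c for c in with_ctrl.columns if c.startswith("mean_stage")]
        pd.testing.assert_frame_equal(with_ctrl[cols], without[cols])

    def test_zero_variance_gene_kept_with_p_one(self):
        _, expr, design = planted_fixture(n_mi=0, p=20, seed=2)
        expr.values[0] = 5.0
        tab = identify_megs(expr, design, alpha=0.1)
        assert tab.loc[0, "kw_statistic"] == 0.0
        assert tab.loc[0, "p_raw"] == 1.0
        assert len(tab) == 20
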