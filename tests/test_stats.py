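"""Cohort statistics against enumeration and simulation oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from myoshape.datasets import load_donor_cohort
from myoshape.stats import (
    chi_square,
    demographics_summary,
    descriptor_fusion_screen,
    mann_whitney,
    product_moment_correlation,
    rank_correlation,
    wilcoxon_paired,
)
from myoshape.synthetic import CohortSpec, attach_shape_summaries, make_cohort


def _rho(x, y):
    """Plain Spearman rho via ranks (test-side reference)."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


class TestRankCorrelation:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert rank_correlation(x, np.exp(x)).r == pytest.approx(1.0)
        assert rank_correlation(x, -(x**3)).r == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = rank_correlation(x, y).r
        assert rank_correlation(np.exp(x), y).r == pytest.approx(base)
        assert rank_correlation(x, 3 * y + 7).r == pytest.approx(base)

    def test_exact_path_matches_enumeration_oracle(self):
        # brute force over all n! permutations as the p-value oracle
        rng = np.random.default_rng(2)
        for n in (6, 7):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            obs = abs(_rho(x, y))
            count = sum(
                abs(_rho(x, np.array(perm))) >= obs - 1e-12
                for perm in itertools.permutations(y)
            )
            exact_p = count / math.factorial(n)
            assert rank_correlation(x, y, exact=True).p == pytest.approx(
                exact_p, abs=0.02
            )
            # the default t-approximation should sit near the exact value
            assert rank_correlation(x, y).p == pytest.approx(exact_p, abs=0.06)

    def test_internal_exact_path_matches_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        obs = abs(_rho(x, y))
        count = sum(
            abs(_rho(x, np.array(perm))) >= obs - 1e-12
            for perm in itertools.permutations(y)
        )
        assert rank_correlation(x, y, exact=True).p == pytest.approx(
            count / math.factorial(6)
        )

    def test_constant_input_flagged(self):
        rep = rank_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rep.r) and not rep.correlated

    def test_correlated_flag_rule(self):
        x = np.arange(8.0)
        assert rank_correlation(x, x).correlated
        rng = np.random.default_rng(4)
        weak = rank_correlation(x, rng.permutation(x)).r
        if abs(weak) <= 0.5:
            assert not rank_correlation(x, rng.permutation(x)).correlated


class TestProductMomentCorrelation:
    def test_affine_relation(self):
        x = np.arange(10.0)
        assert product_moment_correlation(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_orthogonal_deviations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to the linear trend
        assert product_moment_correlation(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_cohort_age_fusion_index(self):
        coh = load_donor_cohort()
        rep = product_moment_correlation(coh["Age"], coh["FusionIndex"])
        assert rep.r == pytest.approx(-0.578, abs=0.01)
        assert rep.p < 0.05
        assert rep.n == 14


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p == pytest.approx(1.0)
        assert res.method == "mann-whitney-exact"

    def test_full_separation_u_zero(self):
        res = mann_whitney([10, 11, 12], [1, 2, 3])
        assert min(res.statistic, 9 - res.statistic) == 0.0

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(0.5, 1.0, size=6)
            exact = mann_whitney(a, b).p
            approx = mann_whitney(a, b, exact_max_n=0).p
            assert approx == pytest.approx(exact, abs=0.05)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestWilcoxonPaired:
    def test_uniform_shift_gives_zero_statistic(self):
        a = np.arange(10.0)
        res = wilcoxon_paired(a + 1.0, a)
        assert res.statistic == 0.0
        assert res.p < 0.01

    def test_antisymmetric_differences_at_midpoint(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])  # differences -1, 1, -1, 1
        res = wilcoxon_paired(a, b)
        assert res.statistic == pytest.approx(4 * 5 / 4)  # midpoint n(n+1)/4 = 5
        assert res.p == pytest.approx(1.0)

    def test_exact_enumeration_matches_implementation(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.4, 1.0, 8)
        b = rng.normal(0.0, 1.0, 8)
        res = wilcoxon_paired(a, b)
        from scipy.stats import rankdata

        d = a - b
        ranks = rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        mu = len(d) * (len(d) + 1) / 4
        count = sum(
            abs(sum(r for r, s in zip(ranks, signs) if s) - mu) >= abs(w_plus - mu) - 1e-12
            for signs in itertools.product((0, 1), repeat=len(d))
        )
        assert res.p == pytest.approx(count / 2 ** len(d))

    def test_all_zero_differences_flagged(self):
        res = wilcoxon_paired([1.0, 2.0], [1.0, 2.0])
        assert math.isnan(res.p)


class TestChiSquare:
    def test_identical_rows(self):
        res = chi_square([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        res = chi_square([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)

    def test_against_permutation_oracle(self):
        # Monte-Carlo permutation of group labels; large enough margins for
        # the 1-df asymptotic reference to apply
        rng = np.random.default_rng(7)
        table = np.array([[60, 40], [45, 55]])
        res = chi_square(table)
        n1 = int(table[0].sum())
        values = np.concatenate(
            [np.ones(int(table[:, 0].sum())), np.zeros(int(table[:, 1].sum()))]
        )
        reps = 4000
        count = 0
        for _ in range(reps):
            perm = rng.permutation(values)
            a = int(perm[:n1].sum())
            c = int(perm[n1:].sum())
            t = [[a, n1 - a], [c, len(values) - n1 - c]]
            try:
                stat = chi_square(t).statistic
            except ValueError:
                continue
            if stat >= res.statistic - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / reps, abs=0.02)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            chi_square([[1, -2], [3, 4]])


class TestDemographicsSummary:
    def test_single_sex_cohort_flagged(self):
        coh = load_donor_cohort()
        males_only = coh[coh["Sex"] == "M"]
        out = demographics_summary(males_only)
        assert out["groups"]["F"]["n"] == 0
        assert math.isnan(out["tests"]["age"]["p"])

    def test_single_donor_sd_flagged(self):
        coh = load_donor_cohort().iloc[:1]
        out = demographics_summary(coh)
        assert math.isnan(out["overall"]["age_sd"])

    def test_swap_symmetry_of_tests(self):
        coh = load_donor_cohort()
        flipped = coh.assign(Sex=coh["Sex"].map({"M": "F", "F": "M"}))
        a = demographics_summary(coh)
        b = demographics_summary(flipped)
        for key in ("age", "bmi", "fusion_index", "tobacco"):
            assert a["tests"][key]["p"] == pytest.approx(b["tests"][key]["p"])


class TestDescriptorFusionScreen:
    def test_constant_fusion_index_flags_nothing(self):
        coh = make_cohort(CohortSpec(n_donors=10, fi_age_slope=0.0, noise_sd=0.0, seed=8))
        coh = attach_shape_summaries(coh, seed=8)
        screen, missing = descriptor_fusion_screen(coh)
        assert not screen["significant"].any()
        assert missing == []

    def test_strong_negative_coupling_recovered(self):
        coh = make_cohort(CohortSpec(n_donors=14, seed=9))
        coh = attach_shape_summaries(
            coh,
            coupling={"area_shape": -3.0, "total_area_occupied": -3.0},
            noise_sd=0.5,
            seed=9,
        )
        screen, _ = descriptor_fusion_screen(coh)
        area = screen[screen["descriptor"] == "area_shape"]
        assert (area["r"] < -0.5).all()
        assert area["significant"].all()

    def test_missing_columns_listed_and_skipped(self):
        coh = make_cohort(CohortSpec(n_donors=8, seed=10))
        coh = attach_shape_summaries(coh, seed=10)
        coh = coh.drop(columns=["perimeter_P2_12h"])
        screen, missing = descriptor_fusion_screen(coh)
        assert missing == ["perimeter_P2_12h"]
        assert len(screen) == 19 * 4 - 1

    def test_pvalues_in_unit_interval(self):
        coh = attach_shape_summaries(make_cohort(CohortSpec(n_donors=9, seed=11)), seed=11)
        screen, _ = descriptor_fusion_screen(coh)
        assert screen["p"].between(0, 1).all()
        assert screen["r"].between(-1, 1).all()
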