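"""Tissue profiling and group comparisons: oracles at small n, planted recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ibdgba import io as cio
from ibdgba.expression import (
    ExpressionError,
    compare_gene_set_vs_background,
    compare_git_vs_brain,
    mean_tpm_profile,
    region_heterogeneity,
)
from ibdgba.io import BRAIN, GIT, TpmMatrix
from ibdgba.simulate import TpmSimConfig, generate_tpm_matrix


def make_matrix(values, tissues, groups, genes=None):
    genes = genes or [f"G{i}" for i in range(len(values))]
    df = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=tissues)
    return TpmMatrix(values=df, gene_symbols={g: g for g in genes},
                     tissue_groups=dict(zip(tissues, groups)))


class TestMeanTpmProfile:
    def test_single_gene_single_tissue_identity(self):
        m = make_matrix([[7.5]], ["T"], [GIT])
        (p,) = mean_tpm_profile(m, {"G0"})
        assert p.mean_tpm == 7.5 and p.rank_in_group == 1

    def test_arithmetic_mean_over_genes(self):
        m = make_matrix([[2.0], [4.0]], ["T"], [GIT])
        (p,) = mean_tpm_profile(m, {"G0", "G1"})
        assert p.mean_tpm == 3.0

    def test_ranks_are_group_permutations_and_ties_break_by_name(self):
        m = make_matrix([[5.0, 5.0, 1.0, 9.0]], ["Tb", "Ta", "Tc", "B1"],
                        [GIT, GIT, GIT, BRAIN])
        profiles = {p.tissue: p for p in mean_tpm_profile(m, {"G0"})}
        assert [profiles[t].rank_in_group for t in ("Ta", "Tb", "Tc")] == [1, 2, 3]
        assert profiles["B1"].rank_in_group == 1

    def test_gene_and_tissue_order_invariance(self):
        m1 = make_matrix([[1, 2], [3, 4]], ["A", "B"], [GIT, BRAIN])
        m2 = make_matrix([[4, 3], [2, 1]], ["B", "A"], [BRAIN, GIT], genes=["G1", "G0"])
        p1 = {p.tissue: p.mean_tpm for p in mean_tpm_profile(m1, {"G0", "G1"})}
        p2 = {p.tissue: p.mean_tpm for p in mean_tpm_profile(m2, {"G1", "G0"})}
        assert p1 == p2

    def test_no_matching_genes_is_an_error(self):
        m = make_matrix([[1.0]], ["T"], [GIT])
        with pytest.raises(ExpressionError):
            mean_tpm_profile(m, {"NOPE"})


def _two_group_matrix(x, y, n_git=1, n_brain=0):
    """Gene-set rows x and background rows y over n_git GIT tissues."""
    tissues = [f"T{i}" for i in range(n_git)] + [f"B{i}" for i in range(n_brain)]
    groups = [GIT] * n_git + [BRAIN] * n_brain
    values = np.concatenate([np.tile(np.asarray(x)[:, None], (1, len(tissues))),
                             np.tile(np.asarray(y)[:, None], (1, len(tissues)))])
    genes = [f"S{i}" for i in range(len(x))] + [f"N{i}" for i in range(len(y))]
    return make_matrix(values, tissues, groups, genes), {f"S{i}" for i in range(len(x))}


class TestSetVsBackground:
    def test_identical_distributions_give_large_p(self):
        vals = np.linspace(1, 10, 30)
        m, genes = _two_group_matrix(vals, vals)
        res = compare_gene_set_vs_background(m, genes, GIT)
        assert res.p_value > 0.9

    def test_u_statistic_matches_exact_enumeration_at_small_n(self):
        x = [1.0, 3.0, 5.0, 7.0, 9.0, 11.0]
        y = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
        m, genes = _two_group_matrix(x, y)
        res = compare_gene_set_vs_background(m, genes, GIT)
        # brute U: count pairwise wins (+0.5 per tie)
        u_brute = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        assert res.statistic == u_brute
        exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        # asymptotic p with continuity correction stays close to the exact null
        assert res.p_value == pytest.approx(exact.pvalue, abs=0.06)

    def test_planted_twofold_shift_is_detected(self):
        cfg = TpmSimConfig(
            n_genes_set=200, n_genes_background=2000,
            git_mean=20.0, brain_mean=20.0, other_mean=20.0, background_mean=10.0,
            noise_sd_log=0.472, gene_sd_log=0.0,  # CV ~= 0.5
            region_effect_sd={GIT: 0.0, BRAIN: 0.0}, seed=11,
        )
        matrix, truth = generate_tpm_matrix(cfg)
        res = compare_gene_set_vs_background(matrix, set(truth["set_gene_ids"]), GIT)
        assert res.p_value < 1e-6

    def test_too_few_genes_is_an_error(self):
        m, genes = _two_group_matrix([1.0], [2.0, 3.0])
        with pytest.raises(ExpressionError):
            compare_gene_set_vs_background(m, genes, GIT)


class TestGitVsBrain:
    def test_identical_values_everywhere_give_large_p(self):
        m, genes = _two_group_matrix(np.linspace(1, 5, 10), [], n_git=2, n_brain=2)
        res = compare_git_vs_brain(m, genes)
        assert res.p_value > 0.9

    def test_u_statistics_sum_to_product_of_sample_sizes(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(2, 1, size=(10, 4))
        m = make_matrix(vals, ["G1", "G2", "B1", "B2"], [GIT, GIT, BRAIN, BRAIN])
        res = compare_git_vs_brain(m, set(m.gene_ids))
        x = vals[:, :2].mean(axis=1)
        y = vals[:, 2:].mean(axis=1)
        u_x = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        u_y = sum((yi > xi) + 0.5 * (yi == xi) for xi in x for yi in y)
        assert u_x + u_y == len(x) * len(y)
        assert res.statistic == pytest.approx(u_x)

    def test_planted_git_brain_difference_is_significant(self):
        matrix, truth = generate_tpm_matrix(TpmSimConfig(seed=3))
        res = compare_git_vs_brain(matrix, set(truth["set_gene_ids"]))
        assert res.p_value < 0.01

    def test_missing_group_is_an_error(self):
        m, genes = _two_group_matrix([1.0, 2.0], [], n_git=2, n_brain=0)
        with pytest.raises(ExpressionError):
            compare_git_vs_brain(m, genes)


class TestRegionHeterogeneity:
    def test_identical_tissue_vectors_give_f_zero_p_one(self):
        col = np.linspace(1, 9, 12)
        m = make_matrix(np.tile(col[:, None], (1, 3)), ["B1", "B2", "B3"], [BRAIN] * 3)
        res = region_heterogeneity(m, set(m.gene_ids), BRAIN)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_tissues_f_equals_squared_t(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(10, 2, size=(15, 2))
        m = make_matrix(vals, ["B1", "B2"], [BRAIN, BRAIN])
        res = region_heterogeneity(m, set(m.gene_ids), BRAIN)
        t = stats.ttest_ind(vals[:, 0], vals[:, 1], equal_var=True)
        assert res.statistic == pytest.approx(t.statistic**2)
        assert res.p_value == pytest.approx(t.pvalue)

    def test_five_tissue_fixture_matches_hand_computed_sums_of_squares(self):
        vals = np.array(
            [[1.0, 2.0, 3.0, 4.0, 10.0],
             [2.0, 3.0, 4.0, 5.0, 11.0],
             [3.0, 4.0, 5.0, 6.0, 12.0]]
        )
        m = make_matrix(vals, [f"B{i}" for i in range(5)], [BRAIN] * 5)
        res = region_heterogeneity(m, set(m.gene_ids), BRAIN)
        grand = vals.mean()
        ss_between = sum(3 * (vals[:, j].mean() - grand) ** 2 for j in range(5))
        ss_within = sum(((vals[:, j] - vals[:, j].mean()) ** 2).sum() for j in range(5))
        f_hand = (ss_between / 4) / (ss_within / 10)
        assert res.statistic == pytest.approx(f_hand)

    def test_f_invariant_under_shift_and_scale(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(1, 0.5, size=(20, 4))
        tissues = [f"B{i}" for i in range(4)]
        f0 = region_heterogeneity(make_matrix(vals, tissues, [BRAIN] * 4),
                                  {f"G{i}" for i in range(20)}, BRAIN).statistic
        f_shift = region_heterogeneity(make_matrix(vals + 100, tissues, [BRAIN] * 4),
                                       {f"G{i}" for i in range(20)}, BRAIN).statistic
        f_scale = region_heterogeneity(make_matrix(vals * 7, tissues, [BRAIN] * 4),
                                       {f"G{i}" for i in range(20)}, BRAIN).statistic
        assert f_shift == pytest.approx(f0)
        assert f_scale == pytest.approx(f0)

    def test_single_tissue_group_is_an_error(self):
        m = make_matrix([[1.0], [2.0]], ["B1"], [BRAIN])
        with pytest.raises(ExpressionError):
            region_heterogeneity(m, set(m.gene_ids), BRAIN)
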