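import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from osteomir import (
    GeneTargetMap,
    SurvivalData,
    bh_fdr,
    ease_enrichment,
    geneset_survival_analysis,
    ks_stat,
    ls_stat,
    per_gene_pvalues,
    permutation_pvalue,
    random_set_control,
)
from osteomir.genesets import GeneSetError

from conftest import make_matrix


class TestStatistics:
    def test_null_boundary_all_p_one(self):
        assert ls_stat([1.0, 1.0, 1.0]) == 0.0
        assert ks_stat([1.0, 1.0, 1.0]) == 0.0

    def test_ls_closed_form(self):
        assert ls_stat([0.1, 0.01]) == pytest.approx((-math.log(0.1) - math.log(0.01)) / 2)

    def test_ks_by_direct_enumeration(self):
        # oracle: max over i of (i/k - p_(i)) for p = (0.1, 0.2)
        expected = max(1 / 2 - 0.1, 2 / 2 - 0.2)
        assert ks_stat([0.1, 0.2]) == pytest.approx(expected)
        assert ks_stat([0.2, 0.1]) == pytest.approx(expected)  # order invariant

    def test_ks_never_negative(self, rng):
        assert ks_stat([1.0]) == 0.0
        for _ in range(20):
            assert ks_stat(rng.uniform(size=10)) >= 0.0

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_permutation_of_pvalues(self, pvals):
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(pvals))
        assert ls_stat(pvals) == pytest.approx(ls_stat(shuffled))
        assert ks_stat(pvals) == pytest.approx(ks_stat(shuffled))

    def test_zero_pvalue_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            value = ls_stat([0.0, 0.5])
        assert np.isfinite(value)


class TestPerGenePvalues:
    @staticmethod
    def _survival(rng, n, beta=0.0, x=None):
        if x is None:
            x = np.zeros(n)
        time = rng.exponential(np.exp(-beta * x)) + 1e-9
        censor = rng.uniform(0, 3.0, n)
        return np.minimum(time, censor), (time <= censor).astype(int)

    def test_null_pvalues_are_uniform(self, rng):
        from scipy import stats

        n = 80
        pvals = []
        for _ in range(500):
            x = rng.normal(size=n)
            time, event = self._survival(rng, n)
            matrix = make_matrix(x[None, :], feature_ids=["g"])
            p = per_gene_pvalues(matrix, SurvivalData(time, event)).loc["g", "p"]
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_effect_detected(self, rng):
        n = 300
        hits = 0
        reps = 30
        for _ in range(reps):
            x = rng.normal(size=n)
            time, event = self._survival(rng, n, beta=1.0, x=x)
            matrix = make_matrix(x[None, :], feature_ids=["g"])
            p = per_gene_pvalues(matrix, SurvivalData(time, event)).loc["g", "p"]
            hits += p < 0.05
        assert hits / reps >= 0.9

    def test_constant_gene_flagged_with_p_one(self, rng):
        matrix = make_matrix(np.vstack([np.ones(20), rng.normal(size=20)]))
        data = SurvivalData(rng.exponential(5, 20) + 0.01, np.ones(20, dtype=int))
        result = per_gene_pvalues(matrix, data)
        assert result.loc["f1", "constant"] and result.loc["f1", "p"] == 1.0
        assert not result.loc["f2", "constant"]


class TestPermutationPvalue:
    def test_never_returns_zero_and_is_deterministic(self, rng):
        pvals = pd.Series(rng.uniform(size=100), index=[f"g{i}" for i in range(100)])
        geneset = [f"g{i}" for i in range(10)]
        a = permutation_pvalue(geneset, pvals, n_perm=200, seed=5)
        b = permutation_pvalue(geneset, pvals, n_perm=200, seed=5)
        assert a.p_ls == b.p_ls and a.p_ks == b.p_ks
        assert a.p_ls > 0 and a.p_ks > 0

    def test_degenerate_shared_pvalue_gives_p_one(self):
        pvals = pd.Series(0.3, index=[f"g{i}" for i in range(30)])
        res = permutation_pvalue([f"g{i}" for i in range(8)], pvals, n_perm=100, seed=1)
        assert res.p_ls == 1.0

    def test_small_sets_reported_too_small(self, rng):
        pvals = pd.Series(rng.uniform(size=30), index=[f"g{i}" for i in range(30)])
        res = permutation_pvalue(["g0", "g1"], pvals, n_perm=100, seed=1)
        assert res.too_small and math.isnan(res.ls)

    def test_set_exceeding_universe_rejected(self, rng):
        pvals = pd.Series(rng.uniform(size=5), index=[f"g{i}" for i in range(5)])
        with pytest.raises(GeneSetError):
            permutation_pvalue([f"g{i}" for i in range(6)], pvals, n_perm=100, seed=1)

    def test_random_sets_self_calibrate(self, rng):
        # a randomly drawn candidate set should reject at roughly alpha
        pvals = pd.Series(rng.uniform(size=300), index=[f"g{i}" for i in range(300)])
        rejections = 0
        reps = 200
        genes = pvals.index.to_numpy()
        for i in range(reps):
            members = rng.choice(genes, size=20, replace=False)
            res = permutation_pvalue(list(members), pvals, n_perm=200, seed=1000 + i)
            rejections += res.p_ls < 0.05
        assert 0.02 <= rejections / reps <= 0.09


class TestRandomSetControl:
    def test_fixed_seed_gives_identical_controls(self, rng):
        pvals = pd.Series(rng.uniform(size=120), index=[f"g{i}" for i in range(120)])
        cand = permutation_pvalue([f"g{i}" for i in range(44)], pvals, n_perm=100, seed=2)
        a = random_set_control(pvals, cand, n_sets=5, set_size=44, n_perm=100, seed=9)
        b = random_set_control(pvals, cand, n_sets=5, set_size=44, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_candidate_beats_controls(self, rng):
        # candidate genes carry tiny p-values; random controls do not
        pvals = pd.Series(
            np.concatenate([rng.uniform(1e-6, 1e-3, 44), rng.uniform(size=400)]),
            index=[f"g{i}" for i in range(444)],
        )
        cand = permutation_pvalue([f"g{i}" for i in range(44)], pvals, n_perm=500, seed=2)
        control = random_set_control(pvals, cand, n_sets=10, set_size=44, n_perm=500, seed=3)
        assert (control["p_ls"] > cand.p_ls).sum() >= 9


class TestPipelineWiring:
    def test_expansive_tier_variance_filters_and_restrictive_does_not(self, cohort):
        data = SurvivalData.from_clinical(cohort.clinical)
        expansive = geneset_survival_analysis(
            cohort.mrna, data, cohort.target_map, tier="expansive", n_perm=100, seed=0
        )
        restrictive = geneset_survival_analysis(
            cohort.mrna, data, cohort.target_map, tier="restrictive", n_perm=100, seed=0
        )
        assert set(expansive["mirna"]) == set(cohort.profile_features)
        # restrictive sets hold 3 genes -> all reported too small, not scored
        assert restrictive["too_small"].all()
        assert not expansive["too_small"].any()

    def test_planted_target_sets_score_better_than_random_sets(self, cohort, rng):
        data = SurvivalData.from_clinical(cohort.clinical)
        result = geneset_survival_analysis(
            cohort.mrna, data, cohort.target_map, tier="expansive", n_perm=200, seed=0
        )
        pvals = per_gene_pvalues(cohort.mrna, data)["p"]
        background = [g for g in pvals.index if g.startswith("bg-")]
        random_ls = [
            ls_stat(pvals.loc[rng.choice(background, size=10, replace=False)])
            for _ in range(20)
        ]
        assert result["ls"].mean() > np.mean(random_ls)

    def test_coherent_planted_set_reaches_small_permutation_p(self, rng):
        # every set gene carries a strong direct hazard effect; background is null
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 300
            latent = rng.normal(size=n)
            time = rng.exponential(np.exp(-0.8 * latent)) + 1e-9
            censor = rng.uniform(0, 3.0, n)
            data = SurvivalData(np.minimum(time, censor), (time <= censor).astype(int))
            set_genes = 0.8 * latent[None, :] + rng.normal(size=(44, n)) * 0.6
            null_genes = rng.normal(size=(200, n))
            matrix = make_matrix(
                np.vstack([set_genes, null_genes]),
                feature_ids=[f"hit{i}" for i in range(44)] + [f"bg{i}" for i in range(200)],
            )
            pvals = per_gene_pvalues(matrix, data)["p"]
            res = permutation_pvalue(
                [f"hit{i}" for i in range(44)], pvals, n_perm=1000, seed=7
            )
            hits += res.p_ls <= 0.01
        assert hits / reps >= 0.8


class TestEaseEnrichment:
    def test_overlap_of_one_gives_p_one(self):
        bg = {f"g{i}" for i in range(50)}
        res = ease_enrichment({"g0", "g1"}, bg, {"pw": {"g0", "g40"}})
        assert res.loc[0, "ease_p"] == 1.0

    def test_list_equals_background_gives_p_one(self):
        bg = {f"g{i}" for i in range(20)}
        res = ease_enrichment(bg, bg, {"pw": bg})
        assert res.loc[0, "ease_p"] == pytest.approx(1.0)

    def test_hand_computed_hypergeometric_tail(self):
        # oracle: direct summation of the decremented-overlap tail
        from math import comb

        n_bg, n_path, n_list, overlap = 100, 20, 10, 8
        tail = sum(
            comb(n_path, x) * comb(n_bg - n_path, n_list - x) for x in range(overlap - 1, n_list + 1)
        ) / comb(n_bg, n_list)
        bg = {f"g{i}" for i in range(n_bg)}
        pathway = {f"g{i}" for i in range(n_path)}
        gene_list = {f"g{i}" for i in range(overlap)} | {f"g{i}" for i in range(90, 92)}
        res = ease_enrichment(gene_list, bg, {"pw": pathway})
        assert res.loc[0, "ease_p"] == pytest.approx(tail, rel=1e-10)

    def test_list_outside_background_rejected(self):
        with pytest.raises(GeneSetError):
            ease_enrichment({"alien"}, {"g1"}, {})

    def test_empty_background_rejected(self):
        with pytest.raises(GeneSetError):
            ease_enrichment(set(), set(), {})


class TestBHFdr:
    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_q_dominates_p_and_is_monotone(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestGeneTargetMap:
    def test_restrictive_must_be_subset_of_expansive(self):
        with pytest.raises(GeneSetError, match="subset"):
            GeneTargetMap(expansive={"m": {"a"}}, restrictive={"m": {"a", "b"}})

    def test_tsv_round_trip(self, tmp_path, cohort):
        path = tmp_path / "targets.tsv"
        cohort.target_map.write_tsv(path)
        back = GeneTargetMap.read_tsv(path)
        assert back.expansive == cohort.target_map.expansive
        assert back.restrictive == cohort.target_map.restrictive
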