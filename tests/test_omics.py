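"""Paired differential abundance, FDR, normalization, ORA, concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from invadomics import omics


def _paired(core_vals, inv_vals, features=None):
    features = features or [f"f{i}" for i in range(len(core_vals))]
    units = [f"U{j}" for j in range(len(core_vals[0]))]
    core = pd.DataFrame(core_vals, index=features, columns=units, dtype=float)
    inv = pd.DataFrame(inv_vals, index=features, columns=units, dtype=float)
    return core, inv


class TestPairedDifferential:
    def test_no_change_gives_unit_fold_change(self):
        core, inv = _paired([[10, 20, 30]], [[10, 20, 30]])
        out = omics.paired_differential(core, inv, pseudo=0.0)
        assert out.loc[0, "fold_change"] == pytest.approx(1.0)
        assert out.loc[0, "log2_fc"] == pytest.approx(0.0)
        assert out.loc[0, "p_value"] == 1.0  # zero variance in the log-ratios

    def test_exact_doubling(self):
        core, inv = _paired([[10, 20, 30]], [[20, 40, 60]])
        out = omics.paired_differential(core, inv, pseudo=0.0)
        assert out.loc[0, "fold_change"] == pytest.approx(2.0)
        assert out.loc[0, "direction"] == "up"

    def test_p_matches_closed_form_paired_t(self):
        rng = np.random.default_rng(3)
        c = rng.lognormal(3, 0.3, 7)
        i = rng.lognormal(3.5, 0.3, 7)
        core, inv = _paired([c], [i])
        out = omics.paired_differential(core, inv, pseudo=0.0)
        d = np.log(i) - np.log(c)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(7))
        expected = 2 * stats.t.sf(abs(t), df=6)
        assert out.loc[0, "p_value"] == pytest.approx(expected)

    def test_fc_mode_ratio_mean(self):
        core, inv = _paired([[10, 100]], [[20, 400]])
        mean_ratio = omics.paired_differential(core, inv, pseudo=0.0)
        ratio_mean = omics.paired_differential(core, inv, pseudo=0.0,
                                               fc_mode="ratio_mean")
        assert mean_ratio.loc[0, "fold_change"] == pytest.approx(420 / 110)
        assert ratio_mean.loc[0, "fold_change"] == pytest.approx((2 + 4) / 2)

    def test_single_pair_errors(self):
        core, inv = _paired([[10]], [[20]])
        with pytest.raises(ValueError):
            omics.paired_differential(core, inv)


class TestRankTop:
    def test_max_fold_change_wins(self):
        diff = pd.DataFrame({"feature": ["cysta", "ab", "nico"],
                             "fold_change": [9.6, 5.0, 1.9],
                             "p_value": [0.01, 0.003, 0.002]})
        assert omics.rank_top(diff, k=1).loc[0, "feature"] == "cysta"

    def test_tie_break_lexical(self):
        diff = pd.DataFrame({"feature": ["b", "a", "c"],
                             "fold_change": [2.0, 2.0, 2.0],
                             "p_value": [0.5, 0.5, 0.5]})
        assert list(omics.rank_top(diff, k=3)["feature"]) == ["a", "b", "c"]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            omics.rank_top(pd.DataFrame({"feature": [], "fold_change": [],
                                         "p_value": []}), k=0)


class TestBHAdjust:
    def test_hand_applied_step_up(self):
        assert np.allclose(omics.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert omics.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_ones(self):
        assert np.allclose(omics.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            omics.bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_dominates_raw_p_and_capped(self, ps):
        adj = omics.bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)


class TestGeomeanNormalize:
    def test_identical_samples_unit_factors(self):
        m = pd.DataFrame({"A": [5.0, 10, 20], "B": [5.0, 10, 20]})
        _, f = omics.geomean_normalize(m)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference(self):
        m = pd.DataFrame({"A": [10.0, 20, 30, 40, 5], "B": [20.0, 40, 60, 80, 10]})
        norm, f = omics.geomean_normalize(m)
        assert f["B"] / f["A"] == pytest.approx(2.0)
        assert np.allclose(norm["A"], norm["B"])

    def test_median_of_ratios_hand_computed(self):
        m = pd.DataFrame({"A": [2.0, 8, 4, 16, 10], "B": [8.0, 2, 4, 4, 10]})
        ref = stats.gmean(m, axis=1)
        expected = np.median(m.to_numpy() / ref[:, None], axis=0)
        _, f = omics.geomean_normalize(m)
        assert np.allclose(f, expected)

    def test_zero_features_excluded_from_reference(self):
        m = pd.DataFrame({"A": [0.0, 10, 20], "B": [5.0, 10, 20]})
        _, f = omics.geomean_normalize(m)  # row 0 has a zero -> dropped
        assert np.allclose(f, 1.0)

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.lognormal(3, 1, (30, 4)) + 1)
        norm, _ = omics.geomean_normalize(m)
        _, f2 = omics.geomean_normalize(norm)
        assert np.allclose(f2, 1.0, atol=1e-9)

    def test_all_rows_contain_zero_errors(self):
        m = pd.DataFrame({"A": [0.0, 1.0], "B": [1.0, 0.0]})
        with pytest.raises(ValueError):
            omics.geomean_normalize(m)


def _brute_force_hypergeom_p(M, n, N, k):
    """P[X >= k] by exhaustive enumeration over all N-subsets of the universe."""
    universe = list(range(M))
    members = set(range(n))
    total = hits_ge = 0
    for combo in itertools.combinations(universe, N):
        total += 1
        if len(members & set(combo)) >= k:
            hits_ge += 1
    return hits_ge / total


class TestORA:
    def test_matches_hypergeometric_point_masses(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"S": universe[:5]}
        hits = universe[:4] + [universe[10]]
        out = omics.ora_enrichment(hits, sets, universe)
        expected = stats.hypergeom.pmf([4, 5], 20, 5, 5).sum()
        assert out.loc[0, "p_value"] == pytest.approx(expected)
        assert out.loc[0, "overlap"] == 4

    def test_complete_overlap_minimal_case(self):
        universe = ["a", "b", "c"]
        out = omics.ora_enrichment(universe, {"S": universe}, universe)
        assert out.loc[0, "overlap"] == 3
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("M,n,N", [(8, 3, 4), (10, 5, 3), (12, 6, 6)])
    def test_exhaustive_enumeration_small_universes(self, M, n, N):
        universe = [f"g{i}" for i in range(M)]
        sets = {"S": universe[:n]}
        rng = np.random.default_rng(M * 100 + n * 10 + N)
        hits = list(rng.choice(universe, size=N, replace=False))
        out = omics.ora_enrichment(hits, sets, universe)
        k = out.loc[0, "overlap"]
        assert out.loc[0, "p_value"] == pytest.approx(
            _brute_force_hypergeom_p(M, n, N, k))

    def test_q_dominates_p(self):
        universe = [f"g{i}" for i in range(30)]
        sets = {f"S{j}": universe[j:j + 6] for j in range(0, 24, 3)}
        rng = np.random.default_rng(1)
        hits = list(rng.choice(universe, size=8, replace=False))
        out = omics.ora_enrichment(hits, sets, universe)
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            omics.ora_enrichment([], {"S": ["a"]}, [])


class TestConcordance:
    def test_identity(self):
        a = pd.Series([1.0, -2.0, 0.5], index=list("abc"))
        res = omics.concordance(a, a)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["pct_discordant"] == 0.0

    def test_printed_worked_example(self):
        """20 sign-discordant genes of 322 -> 6.2%."""
        rng = np.random.default_rng(0)
        idx = [f"x{i}" for i in range(322)]
        a = pd.Series(rng.normal(1, 0.2, 322), index=idx)  # all positive
        b = a.copy()
        b.iloc[:20] = -b.iloc[:20]
        res = omics.concordance(a, b)
        assert res["n_discordant"] == 20 and res["n_total"] == 322
        assert res["pct_discordant"] == 6.2

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a = pd.Series(rng.normal(0, 1, 50) + 3, index=[f"x{i}" for i in range(50)])
        res = omics.concordance(a, -a)
        assert res["pearson_r"] == pytest.approx(-1.0)
        assert res["pct_discordant"] == 100.0

    def test_invariance_to_order_and_positive_rescaling(self):
        rng = np.random.default_rng(4)
        idx = [f"x{i}" for i in range(40)]
        a = pd.Series(rng.normal(0, 1, 40), index=idx)
        b = pd.Series(rng.normal(0, 1, 40), index=idx)
        base = omics.concordance(a, b)
        shuffled = omics.concordance(a.sample(frac=1, random_state=1), b * 3.7)
        assert shuffled["pct_discordant"] == base["pct_discordant"]
        assert shuffled["n_total"] == base["n_total"]

    def test_too_few_shared_features(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            omics.concordance(a, a)


class TestSubsetMetabolic:
    def test_printed_worked_example(self):
        """344 metabolic genes among 2,172 DEGs -> 16%."""
        degs = [f"g{i}" for i in range(2172)]
        catalog = {f"g{i}" for i in range(344)}
        res = omics.subset_metabolic(degs, catalog)
        assert res["n_metabolic"] == 344 and res["pct"] == 16

    def test_catalog_superset_and_disjoint(self):
        degs = ["a", "b", "c"]
        assert omics.subset_metabolic(degs, set(degs) | {"z"})["pct"] == 100
        assert omics.subset_metabolic(degs, {"z"})["pct"] == 0

    def test_empty_deg_list_errors(self):
        with pytest.raises(ValueError):
            omics.subset_metabolic([], {"a"})


class TestPCAScores:
    def test_replicated_samples_zero_variance(self):
        m = pd.DataFrame({"s1": [1.0, 2, 3], "s2": [1.0, 2, 3], "s3": [1.0, 2, 3]})
        scores, _ = omics.pca_scores(m)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-9)

    def test_separated_groups_split_on_pc1(self):
        from invadomics.simulate import AbundanceSimConfig, simulate_paired_abundance
        mat, pairing, _ = simulate_paired_abundance(
            AbundanceSimConfig(n_features=300, n_pairs=6, frac_changed=0.3,
                               effect_log2=4.0, noise_sd_log=0.2, seed=9))
        scores, evr = omics.pca_scores(mat)
        pc1 = scores["PC1"]
        core = pc1[[s for s in pc1.index if s.endswith("_core")]]
        inv = pc1[[s for s in pc1.index if s.endswith("_invasive")]]
        assert core.max() < inv.min() or inv.max() < core.min()
        assert evr.sum() <= 1.0 + 1e-9

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            omics.pca_scores(pd.DataFrame({"a": [1.0], "b": [2.0]}))


def test_null_fdr_controlled_over_seeds():
    """BH keeps the false-discovery proportion at or under nominal on null data."""
    from invadomics.simulate import AbundanceSimConfig, simulate_paired_abundance
    false_hits = 0
    for seed in range(3):
        mat, pairing, _ = simulate_paired_abundance(
            AbundanceSimConfig(n_features=300, n_pairs=7, frac_changed=0.0, seed=seed))
        core, inv = omics.split_pairs(mat, pairing)
        diff = omics.paired_differential(core, inv)
        false_hits += int((diff["p_adjusted"] <= 0.05).sum())
    assert false_hits <= 3  # ~0 expected; tolerate rare stragglers
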