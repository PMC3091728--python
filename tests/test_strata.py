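"""Gene strata: plasticity, 5'UTR tertiles, stratified profiles, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from promoterscape import (
    Frame,
    GeneAnnotation,
    InputError,
    SiteRecord,
    build_strata,
    plasticity,
    stratified_profiles,
    tata_by_utr_test,
    utr_length_ttest,
    utr_tertiles,
)


def _gene(gene_id, utr, tata="unknown", tss0=2001):
    plen = 200 + utr
    return GeneAnnotation(gene_id, "chr1", "+", cds_start=tss0 + utr,
                          upstream_boundary=tss0 + utr - plen - 1, tss=tss0,
                          tata=tata)


class TestPlasticity:
    @pytest.mark.parametrize("row,expected", [
        ([1, -1, 1, -1], 1.0),
        ([0, 0, 0], 0.0),
        ([2, 0], 2.0),
    ])
    def test_mean_squared_log_ratio(self, row, expected):
        out = plasticity(pd.DataFrame({"g": row}).T)
        assert out["g"] == pytest.approx(expected)

    def test_all_missing_gene_excluded(self):
        df = pd.DataFrame([[1.0, 1.0], [np.nan, np.nan]], index=["a", "b"])
        out = plasticity(df)
        assert list(out.index) == ["a"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-4, 4), min_size=2, max_size=8))
    def test_invariant_to_condition_order_and_missing_padding(self, row):
        base = pd.DataFrame({"g": row}).T
        permuted = base[base.columns[::-1]]
        padded = base.copy()
        padded["extra"] = np.nan
        v = plasticity(base)["g"]
        assert plasticity(permuted)["g"] == pytest.approx(v)
        assert plasticity(padded)["g"] == pytest.approx(v)


class TestUtrTertiles:
    def test_lengths_one_to_nine_split_evenly(self):
        genes = [_gene(f"g{i}", i) for i in range(1, 10)]
        thresholds, labels = utr_tertiles(genes)
        assert thresholds == (4, 7)
        assert labels.value_counts().to_dict() == {"short": 3, "medium": 3, "long": 3}
        assert labels["g3"] == "short" and labels["g4"] == "medium" and labels["g7"] == "long"

    def test_equal_lengths_degenerate(self):
        genes = [_gene(f"g{i}", 50) for i in range(6)]
        with pytest.raises(InputError):
            utr_tertiles(genes)

    def test_four_quantile_variant(self):
        genes = [_gene(f"g{i}", i) for i in range(1, 13)]
        _, labels = utr_tertiles(genes, quantiles=4)
        assert sorted(labels.value_counts().to_dict().values()) == [3, 3, 3, 3]

    def test_synthetic_tertiles_bracket_configured_mean(self, small_pkg):
        thresholds, _ = utr_tertiles(small_pkg.genes)
        assert thresholds[0] < small_pkg.config.utr_mean < thresholds[1] + 40


class TestStratifiedProfiles:
    def test_identical_strata_give_identical_profiles(self, small_pkg):
        ids = [g.gene_id for g in small_pkg.genes]
        labels_a = {g: "x" for g in ids}
        labels_b = {g: "y" for g in ids}
        pa = stratified_profiles(small_pkg.sites, small_pkg.genes, labels_a, Frame.TSS)
        pb = stratified_profiles(small_pkg.sites, small_pkg.genes, labels_b, Frame.TSS)
        assert np.array_equal(pa["x"].n, pb["y"].n)
        assert np.array_equal(pa["x"].r, pb["y"].r)

    def test_single_gene_stratum_is_delta_profile(self):
        g = _gene("g1", 0)
        s = SiteRecord("tf", "chr1", g.tss - 115, g.tss - 115, "g1")
        profs = stratified_profiles([s], [g], {"g1": "solo"}, Frame.TSS, window=1)
        prof = profs["solo"]
        at = dict(zip(prof.positions, prof.d))
        assert at[-115] == 1.0 and prof.n.sum() == 1

    def test_higher_site_rate_stratum_has_higher_density(self):
        from promoterscape import SyntheticConfig, simulate

        pkg = simulate(SyntheticConfig(n_genes=400, seed=19,
                                       site_rate_high_plasticity=9.0,
                                       plasticity_top_n=120))
        strata = build_strata(pkg.genes, expr=pkg.expr, top_n=120)
        labels = strata["plasticity_group"][strata["plasticity_group"] != "middle"]
        profs = stratified_profiles(pkg.sites, pkg.genes, labels, Frame.TSS)
        hi, lo = profs["top120"], profs["bottom120"]
        ok = ~np.isnan(hi.d_smooth) & ~np.isnan(lo.d_smooth)
        assert np.nanmean(hi.d_smooth[ok]) > 1.5 * np.nanmean(lo.d_smooth[ok])


class TestTataByUtr:
    def _strata(self, counts):
        rows = []
        i = 0
        for (tata, grp), n in counts.items():
            for _ in range(n):
                rows.append({"gene_id": f"g{i}", "tata": tata, "utr_group": grp,
                             "utr5_len": 10, "expr_level": "high"})
                i += 1
        return pd.DataFrame(rows).set_index("gene_id")

    def test_matches_closed_form_chi_square(self):
        counts = {("containing", "short"): 10, ("containing", "medium"): 20,
                  ("containing", "long"): 30, ("less", "short"): 40,
                  ("less", "medium"): 30, ("less", "long"): 20}
        res = tata_by_utr_test(self._strata(counts))
        obs = np.array([[10, 20, 30], [40, 30, 20]], float)
        exp = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        # scipy applies no continuity correction for dof > 1
        assert res.chi2 == pytest.approx(chi2)
        assert res.dof == 2
        assert res.p == pytest.approx(stats.chi2.sf(chi2, 2))

    def test_perfect_association_rejects(self):
        counts = {("containing", "short"): 0, ("containing", "medium"): 0,
                  ("containing", "long"): 10, ("less", "short"): 10,
                  ("less", "medium"): 10, ("less", "long"): 0}
        res = tata_by_utr_test(self._strata(counts))
        assert res.p < 0.01
        cell = res.cell_tests
        enr = cell[(cell.tata == "containing") & (cell.utr_group == "long")]
        assert float(enr["enrichment"].iloc[0]) > 1.0

    def test_independent_labels_accept_at_scale(self):
        rng = np.random.default_rng(23)
        n = 3000
        df = pd.DataFrame({
            "tata": rng.choice(["containing", "less"], n, p=[0.2, 0.8]),
            "utr_group": rng.choice(["short", "medium", "long"], n),
            "utr5_len": rng.integers(1, 200, n),
            "expr_level": "high",
        }, index=[f"g{i}" for i in range(n)])
        assert tata_by_utr_test(df).p > 0.001


class TestUtrLengthTtest:
    def test_identical_groups_p_one(self):
        v = pd.Series([10.0, 10.0, 10.0, 10.0], index=list("abcd"))
        g = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        out = utr_length_ttest(v, g, "x", "y")
        assert out.t == 0.0 and out.p == 1.0

    def test_shifted_groups_reject(self):
        rng = np.random.default_rng(29)
        v = pd.Series(np.concatenate([rng.normal(60, 30, 500),
                                      rng.normal(100, 30, 500)]),
                      index=[f"g{i}" for i in range(1000)])
        g = pd.Series(["a"] * 500 + ["b"] * 500, index=v.index)
        out = utr_length_ttest(v, g, "b", "a")
        assert out.p < 1e-10 and out.mean_a > out.mean_b

    def test_matches_textbook_welch(self):
        v = pd.Series([1.0, 2, 3, 4, 2, 4, 6], index=list("abcdefg"))
        g = pd.Series(["x"] * 4 + ["y"] * 3, index=v.index)
        out = utr_length_ttest(v, g, "x", "y")
        t, p = stats.ttest_ind([1, 2, 3, 4], [2, 4, 6], equal_var=False)
        assert out.t == pytest.approx(t) and out.p == pytest.approx(p)

    def test_single_group_errors(self):
        v = pd.Series([1.0, 2.0], index=list("ab"))
        g = pd.Series(["x", "x"], index=v.index)
        with pytest.raises(InputError):
            utr_length_ttest(v, g, "x", "y")


class TestBuildStrata:
    def test_partition_and_top_bottom_sizes(self, small_pkg):
        strata = build_strata(small_pkg.genes, expr=small_pkg.expr, top_n=50)
        counts = strata["plasticity_group"].value_counts()
        assert counts["top50"] == 50 and counts["bottom50"] == 50
        # every labelled gene appears in exactly one utr group
        labelled = strata["utr_group"].dropna()
        assert labelled.isin(["short", "medium", "long"]).all()

    def test_plasticity_extremes_separated(self, small_pkg):
        strata = build_strata(small_pkg.genes, expr=small_pkg.expr, top_n=50)
        top = strata.loc[strata["plasticity_group"] == "top50", "plasticity"]
        bot = strata.loc[strata["plasticity_group"] == "bottom50", "plasticity"]
        assert top.min() >= bot.max()
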