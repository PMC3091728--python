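"""Coverage-normalized density, randomization envelope, bootstrap bias."""

import numpy as np
import pytest
from scipy import stats

from promoterscape import (
    Frame,
    GeneAnnotation,
    InputError,
    SiteRecord,
    bootstrap_bias,
    compare_bias,
    density_profile,
    localization_bias,
    randomization_envelope,
    randomize_sites,
    site_positions,
)
from promoterscape.density import BiasResult, PositionalProfile, _smooth


def _gene(gene_id="g1", strand="+", plen=300, utr=0, tss0=1001, chrom="chr1"):
    """Gene whose TSS-frame promoter covers [-(plen-utr), -1]."""
    if strand == "+":
        cds = tss0 + utr
        ub = cds - plen - 1
    else:
        cds = tss0 - utr
        ub = cds + plen + 1
    return GeneAnnotation(gene_id, chrom, strand, cds_start=cds,
                          upstream_boundary=ub, tss=tss0)


class TestSitePositions:
    def test_midpoint_and_span_of_ten_bp_site(self):
        g = _gene(tss0=1000)
        s = SiteRecord("tf", "chr1", 881, 890, "g1")
        mids = site_positions([s], [g], Frame.TSS, mode="midpoint")
        assert [c.position for c in mids] == [-115]
        span = site_positions([s], [g], Frame.TSS, mode="span")
        assert sorted(c.position for c in span) == list(range(-119, -109))

    def test_single_base_site_modes_agree(self):
        g = _gene(tss0=1000)
        s = SiteRecord("tf", "chr1", 900, 900, "g1")
        for mode in ("midpoint", "span"):
            (c,) = site_positions([s], [g], Frame.TSS, mode=mode)
            assert c.position == -100


class TestDensityProfile:
    def test_single_promoter_single_site_unsmoothed(self):
        g = _gene(plen=200, tss0=1001)
        s = SiteRecord("tf", "chr1", 886, 886, "g1")  # frame -115
        prof = density_profile([s], [g], Frame.TSS, window=1, frame_range=(-200, -1))
        at = dict(zip(prof.positions, prof.d))
        assert at[-115] == 1.0
        assert sum(v for k, v in at.items() if k != -115) == 0.0

    def test_two_promoter_normalization(self):
        g1 = _gene("g1", plen=300, tss0=1001)
        g2 = _gene("g2", plen=150, tss0=5001)
        both = [SiteRecord("tf", "chr1", 886, 886, "g1"),
                SiteRecord("tf", "chr1", 4886, 4886, "g2")]
        prof = density_profile(both, [g1, g2], Frame.TSS, window=1)
        assert dict(zip(prof.positions, prof.d))[-115] == 1.0
        prof1 = density_profile(both[:1], [g1, g2], Frame.TSS, window=1)
        assert dict(zip(prof1.positions, prof1.d))[-115] == 0.5  # r(-115) = 2

    def test_constant_density_is_smoothing_fixed_point(self):
        c = 0.37
        out = _smooth(np.full(100, c), np.ones(100, bool), 41)
        assert np.allclose(out, c)

    def test_even_window_rejected(self):
        g = _gene()
        with pytest.raises(InputError):
            density_profile([], [g], Frame.TSS, window=40)

    def test_midpoint_counts_conserve_mapped_sites(self, small_pkg):
        prof = density_profile(small_pkg.sites, small_pkg.genes, Frame.TSS,
                               frame_range=(-10_000, 10_000))
        mapped = sum(1 for s in small_pkg.sites
                     if next(g for g in small_pkg.genes
                             if g.gene_id == s.gene_id).has_tss)
        assert int(prof.n.sum()) == mapped

    def test_equal_length_promoters_match_brute_force(self):
        rng = np.random.default_rng(3)
        genes = [_gene(f"g{i}", plen=200, tss0=1001 + 10_000 * i) for i in range(20)]
        sites = []
        for i, g in enumerate(genes):
            for _ in range(rng.poisson(3)):
                pos = int(rng.integers(g.promoter_interval[0], g.promoter_interval[1] + 1))
                sites.append(SiteRecord("tf", "chr1", pos, pos, g.gene_id))
        prof = density_profile(sites, genes, Frame.TSS, window=1, frame_range=(-200, -1))
        brute = np.zeros(200)
        for s in sites:
            g = next(g for g in genes if g.gene_id == s.gene_id)
            brute[s.start - g.tss + 200] += 1
        assert np.allclose(prof.d, brute / len(genes))


class TestRandomizeSites:
    def test_site_filling_promoter_is_pinned(self):
        g = _gene(plen=10)
        s = SiteRecord("tf", "chr1", *g.promoter_interval, "g1")
        for seed in range(5):
            (r,) = randomize_sites([s], [g], seed)
            assert (r.start, r.end) == g.promoter_interval

    def test_uniform_placement_of_point_site(self):
        g = _gene(plen=100)
        s = SiteRecord("tf", "chr1", g.promoter_interval[0], g.promoter_interval[0], "g1")
        rng = np.random.default_rng(12)
        draws = np.array([randomize_sites([s], [g], rng)[0].start
                          for _ in range(10_000)])
        counts = np.bincount(draws - g.promoter_interval[0], minlength=100)
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_two_sites_randomized_independently(self):
        g = _gene(plen=200)
        a = SiteRecord("a", "chr1", g.promoter_interval[0], g.promoter_interval[0], "g1")
        b = SiteRecord("b", "chr1", g.promoter_interval[0] + 5,
                       g.promoter_interval[0] + 5, "g1")
        rng = np.random.default_rng(13)
        pairs = np.array([[x.start for x in randomize_sites([a, b], [g], rng)]
                          for _ in range(5000)])
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_lengths_and_counts_preserved_within_promoter(self, small_pkg):
        rand = randomize_sites(small_pkg.sites, small_pkg.genes, 4)
        assert len(rand) == len(small_pkg.sites)
        by_id = {g.gene_id: g for g in small_pkg.genes}
        for orig, new in zip(small_pkg.sites, rand):
            assert new.length == orig.length and new.gene_id == orig.gene_id
            lo, hi = by_id[new.gene_id].promoter_interval
            assert lo <= new.start and new.end <= hi


class TestEnvelope:
    def test_two_replicates_give_min_max_band(self):
        g = _gene(plen=100)
        s = SiteRecord("tf", "chr1", g.promoter_interval[0] + 3,
                       g.promoter_interval[0] + 3, "g1")
        env = randomization_envelope([s], [g], Frame.TSS, R=2, seed=5,
                                     window=1, frame_range=(-100, -1))
        assert (env.lo95 <= env.mean + 1e-12).all()
        assert (env.mean <= env.hi95 + 1e-12).all()
        # with R=2 the percentile band is exactly the min/max of the two reps
        assert set(np.unique(env.lo95)) <= {0.0, 1.0}
        assert env.hi95.max() == 1.0

    def test_deterministic_given_seed(self, small_pkg):
        kw = dict(R=5, seed=21, frame_range=(-300, -1))
        e1 = randomization_envelope(small_pkg.sites, small_pkg.genes, Frame.TSS, **kw)
        e2 = randomization_envelope(small_pkg.sites, small_pkg.genes, Frame.TSS, **kw)
        assert (e1.mean == e2.mean).all() and (e1.hi95 == e2.hi95).all()


class TestLocalizationBias:
    def _profile(self, d_smooth, r=None):
        n_pos = len(d_smooth)
        pos = np.arange(-n_pos, 0)
        r = np.full(n_pos, 100.0) if r is None else r
        return PositionalProfile(Frame.TSS, pos, np.zeros(n_pos), r,
                                 np.array(d_smooth, float),
                                 np.array(d_smooth, float), 1, 100, 10)

    def test_constant_profile_has_unit_ratio(self):
        assert localization_bias(self._profile([0.3] * 5), (-5, -1), 1) == pytest.approx(1.0)

    def test_single_spike_ratio(self):
        prof = self._profile([0, 0, 2, 0, 0])
        assert localization_bias(prof, (-5, -1), 1) == pytest.approx(5.0)

    def test_zero_mean_errors(self):
        with pytest.raises(InputError):
            localization_bias(self._profile([0, 0, 0]), (-3, -1), 1)


class TestBootstrapBias:
    def test_degenerate_identical_genes_give_zero_spread(self):
        genes = [_gene(f"g{i}", plen=100, tss0=1001 + 10_000 * i) for i in range(8)]
        sites = [SiteRecord("tf", "chr1", g.tss - 50, g.tss - 50, g.gene_id)
                 for g in genes]
        res = bootstrap_bias(sites, genes, Frame.TSS, B=20, seed=2,
                             window=1, eval_range=(-100, -1), min_coverage=1)
        assert res.sd_ratio == 0.0
        assert res.mean_ratio == pytest.approx(100.0)  # one hot position of 100

    def test_bit_identical_given_seed(self, small_pkg):
        kw = dict(B=10, seed=31, min_coverage=5)
        r1 = bootstrap_bias(small_pkg.sites, small_pkg.genes, Frame.TSS, **kw)
        r2 = bootstrap_bias(small_pkg.sites, small_pkg.genes, Frame.TSS, **kw)
        assert (r1.ratios == r2.ratios).all()

    def test_ratios_at_least_one(self, small_pkg):
        res = bootstrap_bias(small_pkg.sites, small_pkg.genes, Frame.TSS,
                             B=20, seed=8, min_coverage=5)
        assert (res.ratios >= 1.0).all()
        assert min(res.ratios) <= res.mean_ratio <= max(res.ratios)


class TestCompareBias:
    @staticmethod
    def _result(values):
        arr = np.array(values, float)
        return BiasResult(Frame.TSS, arr, np.arange(len(arr)), len(arr), 0)

    def test_identical_vectors(self):
        r = self._result([1.5, 1.5, 1.5])
        out = compare_bias(r, self._result([1.5, 1.5, 1.5]))
        assert out.t == 0.0 and out.p == 1.0

    def test_clear_separation(self):
        a = self._result([1.0, 1.001, 0.999, 1.0])
        b = self._result([2.0, 2.001, 1.999, 2.0])
        assert compare_bias(a, b).p < 1e-6

    def test_matches_textbook_welch(self):
        xa, xb = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0]
        out = compare_bias(self._result(xa), self._result(xb))
        ma, mb = np.mean(xa), np.mean(xb)
        va, vb = np.var(xa, ddof=1) / len(xa), np.var(xb, ddof=1) / len(xb)
        t = (ma - mb) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert out.t == pytest.approx(t)
        assert out.p == pytest.approx(p)
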