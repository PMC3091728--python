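"""Synthetic genome package generator.

Produces a fully synthetic stand-in for the study inputs — gene
annotations with TSSs and variable-length intergenic promoters, binding
sites placed with a TSS-anchored positional preference, per-base
nucleosome occupancy drawn from four promoter archetypes, deletion/SNP
catalogues with a distance-dependent deletion rate, and a log2 expression
ratio matrix — so that every pipeline stage can be exercised and its
parameter recovery checked without any external download.

Defaults encode the statistical structure the analyses assume: a 0.6/0.4
mixture of a Normal(-115, 40) TSS-anchored component and a uniform
component for site placement, lognormal intergenic lengths (median ~450
bp), gamma 5'UTR lengths (mean 70, shape 2, whose tertiles fall near
39/81 bp), four equal-weight occupancy archetypes ordered from deep NFR
to fully occupied, TATA propensity increasing with 5'UTR length, and a
deletion rate rising linearly with distance from the TSS.  A truth table
records every planted label for recovery tests.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_frames import (
    Frame,
    GeneAnnotation,
    PolymorphismEvent,
    SiteRecord,
    from_frame,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Infeasible or inconsistent synthetic configuration."""


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    seed: int = 0
    # geometry
    intergenic_len_median: float = 450.0
    intergenic_len_sigma: float = 0.6       # lognormal sigma (log-scale)
    min_promoter_len: int = 60
    utr_mean: float = 70.0
    utr_shape: float = 2.0                  # gamma shape; scale = mean/shape
    gene_body_len: int = 1000
    gene_gap: int = 200
    genes_per_chrom: int = 500
    frac_minus_strand: float = 0.4
    frac_bidirectional: float = 0.2
    frac_no_tss: float = 0.02
    # binding sites
    peak_offset: int = -115
    peak_sd: float = 40.0
    peak_weight: float = 0.6
    sites_per_promoter: float = 3.0
    site_rate_high_plasticity: float | None = None
    plasticity_top_n: int = 500
    site_len_min: int = 8
    site_len_max: int = 12
    n_tfs: int = 100
    # nucleosome occupancy
    type_mix: tuple = (0.25, 0.25, 0.25, 0.25)
    occupancy_noise: float = 0.3
    occupancy_missing: float = 0.03
    frac_low_coverage: float = 0.05
    # polymorphisms
    deletion_rate: float = 4e-4             # per bp at the TSS-adjacent base
    deletion_rate_slope: float = 0.003      # relative increase per bp of distance
    deletion_len_mean: float = 8.0
    snp_rate: float = 0.005                 # per bp, position-independent
    # expression
    n_conditions: int = 100
    plasticity_sd_low: float = 0.4
    plasticity_sd_high: float = 1.2
    expr_missing: float = 0.01

    def validate(self) -> None:
        for name in ("frac_minus_strand", "frac_bidirectional", "frac_no_tss",
                     "peak_weight", "occupancy_missing", "frac_low_coverage",
                     "expr_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if len(self.type_mix) != 4 or abs(sum(self.type_mix) - 1.0) > 1e-9 or min(self.type_mix) < 0:
            raise ConfigError("type_mix must be 4 non-negative proportions summing to 1")
        if self.n_genes < 4:
            raise ConfigError("n_genes must be at least 4")
        if not (1 <= self.site_len_min <= self.site_len_max):
            raise ConfigError("require 1 <= site_len_min <= site_len_max")
        if self.site_len_max > self.min_promoter_len - 10:
            raise ConfigError(
                f"site_len_max={self.site_len_max} too large for the minimum "
                f"promoter length {self.min_promoter_len}"
            )
        for name in ("sites_per_promoter", "deletion_rate", "snp_rate",
                     "peak_sd", "occupancy_noise", "deletion_rate_slope"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.peak_offset >= 0:
            raise ConfigError("peak_offset must be upstream of the TSS (negative)")
        if self.n_conditions < 1:
            raise ConfigError("n_conditions must be >= 1")


@dataclass
class SyntheticPackage:
    config: SyntheticConfig
    genes: list
    sites: list
    occupancy: pd.DataFrame      # bedGraph rows: chrom, start(0-based), end, value
    snps: list
    deletions: list
    expr: pd.DataFrame           # genes x conditions log2 ratios
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# occupancy archetype templates over frame positions -1000..+201
# ---------------------------------------------------------------------------

def _gauss(x, mu, sd):
    return np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def occupancy_template(occ_type: int, x: np.ndarray) -> np.ndarray:
    """Mean log2 occupancy for archetype 0..3 (deep NFR .. fully occupied)."""
    # archetypes share a 0.4 far-upstream background (distal window bases
    # belong to neighbouring genes' territory) and differ in the
    # promoter-proximal architecture
    if occ_type == 0:   # sharp ~200bp NFR flanked by positioned -1/+1 nucleosomes
        return 0.4 - 1.8 * _gauss(x, -100, 55) + 0.6 * _gauss(x, -230, 45) + 0.6 * _gauss(x, 30, 45)
    if occ_type == 1:   # deep NFR, downstream nucleosome only (no -1 nucleosome)
        return 0.4 - 1.2 * _gauss(x, -120, 70) + 0.7 * _gauss(x, 40, 50)
    if occ_type == 2:   # broad shallow depletion, no positioned -1 nucleosome
        return 0.4 - 0.8 * _gauss(x, -150, 160) + 0.3 * _gauss(x, 80, 60)
    if occ_type == 3:   # fully occupied promoter
        return 0.4 + 0.5 * _gauss(x, -100, 250)
    raise ValueError(f"unknown occupancy archetype {occ_type}")


# ---------------------------------------------------------------------------
# gene geometry
# ---------------------------------------------------------------------------

def _draw_promoter_len(cfg: SyntheticConfig, rng) -> int:
    while True:
        p = int(round(rng.lognormal(np.log(cfg.intergenic_len_median),
                                    cfg.intergenic_len_sigma)))
        if p >= cfg.min_promoter_len:
            return p


def _draw_utr(cfg: SyntheticConfig, rng, prom_len: int) -> int:
    cap = prom_len - 40  # keep a usable upstream stretch
    for _ in range(200):
        u = int(round(rng.gamma(cfg.utr_shape, cfg.utr_mean / cfg.utr_shape)))
        if 0 <= u <= cap:
            return u
    return max(cap // 2, 0)


def simulate_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> list[GeneAnnotation]:
    """Lay out genes on chromosomes; a fraction form divergent (shared-
    promoter) pairs and a fraction lack a mapped TSS."""
    cfg.validate()
    n_pairs = int(round(cfg.frac_bidirectional * cfg.n_genes / 2))
    n_single = cfg.n_genes - 2 * n_pairs
    plan: list[str] = ["pair"] * n_pairs + ["single"] * n_single
    rng.shuffle(plan)

    genes: list[GeneAnnotation] = []
    gid = 0
    chrom_no, cursor, on_chrom = 1, 1000, 0

    def next_chrom_maybe():
        nonlocal chrom_no, cursor, on_chrom
        if on_chrom >= cfg.genes_per_chrom:
            chrom_no += 1
            cursor = 1000
            on_chrom = 0

    def has_tss() -> bool:
        return rng.random() >= cfg.frac_no_tss

    for item in plan:
        next_chrom_maybe()
        chrom = f"chr{chrom_no:02d}"
        if item == "single":
            strand = "-" if rng.random() < cfg.frac_minus_strand else "+"
            P = _draw_promoter_len(cfg, rng)
            if strand == "+":
                ub = cursor
                cds = cursor + P + 1
                utr = _draw_utr(cfg, rng, P)
                tss = cds - utr if has_tss() else None
                cursor = cds + cfg.gene_body_len + cfg.gene_gap
            else:
                cds = cursor + cfg.gene_body_len
                ub = cds + P + 1
                utr = _draw_utr(cfg, rng, P)
                tss = cds + utr if has_tss() else None
                cursor = ub + cfg.gene_gap
            genes.append(GeneAnnotation(
                gene_id=f"g{gid:05d}", chrom=chrom, strand=strand,
                cds_start=cds, upstream_boundary=ub, tss=tss,
            ))
            gid += 1
            on_chrom += 1
        else:
            # divergent pair: minus-strand gene A, shared intergenic, plus-strand B
            P = _draw_promoter_len(cfg, rng)
            cds_a = cursor + cfg.gene_body_len
            cds_b = cds_a + P + 1
            utr_a = _draw_utr(cfg, rng, P)
            utr_b = _draw_utr(cfg, rng, P)
            tss_a = cds_a + utr_a if has_tss() else None
            tss_b = cds_b - utr_b if has_tss() else None
            genes.append(GeneAnnotation(
                gene_id=f"g{gid:05d}", chrom=chrom, strand="-",
                cds_start=cds_a, upstream_boundary=cds_b, tss=tss_a,
                bidirectional=True,
            ))
            genes.append(GeneAnnotation(
                gene_id=f"g{gid + 1:05d}", chrom=chrom, strand="+",
                cds_start=cds_b, upstream_boundary=cds_a, tss=tss_b,
                bidirectional=True,
            ))
            gid += 2
            on_chrom += 2
            cursor = cds_b + cfg.gene_body_len + cfg.gene_gap
    return genes


# ---------------------------------------------------------------------------
# binding sites
# ---------------------------------------------------------------------------

def simulate_sites(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    genes: list[GeneAnnotation],
    rates: np.ndarray | None = None,
) -> list[SiteRecord]:
    """Plant sites: a TSS-anchored truncated-normal component (out-of-range
    draws are redrawn, not clipped) mixed with a uniform component."""
    sites: list[SiteRecord] = []
    for gi, g in enumerate(genes):
        lam = cfg.sites_per_promoter if rates is None else float(rates[gi])
        n = rng.poisson(lam)
        pstart, pend = g.promoter_interval
        plen = pend - pstart + 1
        for _ in range(n):
            L = int(rng.integers(cfg.site_len_min, cfg.site_len_max + 1))
            placed = False
            if g.has_tss and rng.random() < cfg.peak_weight and g.upstream_len >= 1:
                for _try in range(100):
                    x = int(round(rng.normal(cfg.peak_offset, cfg.peak_sd)))
                    if not (-g.upstream_len <= x <= -1):
                        continue
                    mid = from_frame(x, g, Frame.TSS)
                    h = (L - 1) // 2
                    if g.strand == "+":
                        s, e = mid - h, mid - h + L - 1
                    else:
                        s, e = mid + h - L + 1, mid + h
                    if pstart <= s and e <= pend:
                        placed = True
                        break
            if not placed:
                s = pstart + int(rng.integers(0, plen - L + 1))
                e = s + L - 1
            tf = f"TF{int(rng.integers(0, cfg.n_tfs)):03d}"
            sites.append(SiteRecord(tf=tf, chrom=g.chrom, start=int(s), end=int(e),
                                    gene_id=g.gene_id))
    return sites


# ---------------------------------------------------------------------------
# occupancy, polymorphisms, expression
# ---------------------------------------------------------------------------

_OCC_X = None


def _occ_frame_offsets():
    global _OCC_X
    if _OCC_X is None:
        u = np.arange(-1000, 201)          # linearized offsets from the TSS base
        _OCC_X = (u, u + (u >= 0))         # (offset, frame coordinate)
    return _OCC_X


def _simulate_occupancy(cfg, rng, genes, occ_type):
    """Stamp per-base occupancy; where two windows overlap (shared
    promoters) the base takes the value of the nearer TSS."""
    offs, x = _occ_frame_offsets()
    vals: dict[str, np.ndarray] = {}
    dist: dict[str, np.ndarray] = {}
    spans: dict[str, int] = {}
    for g in genes:
        if g.has_tss:
            spans[g.chrom] = max(spans.get(g.chrom, 0), g.tss + 1500)
    for chrom, hi in spans.items():
        vals[chrom] = np.full(hi + 1, np.nan)
        dist[chrom] = np.full(hi + 1, np.inf)

    lowcov = rng.random(len(genes)) < cfg.frac_low_coverage
    gaps: list[tuple[str, int, int]] = []
    for gi, g in enumerate(genes):
        if not g.has_tss:
            continue
        tpl = occupancy_template(occ_type[gi], x.astype(float))
        row = tpl + rng.normal(0.0, cfg.occupancy_noise, len(x))
        gpos = (g.tss + offs) if g.strand == "+" else (g.tss - offs)
        ok = gpos >= 1
        d = np.abs(gpos - g.tss)
        v, dd = vals[g.chrom], dist[g.chrom]
        closer = ok & (d < dd[np.clip(gpos, 0, len(dd) - 1)])
        v[gpos[closer]] = row[closer]
        dd[gpos[closer]] = d[closer]
        if lowcov[gi]:
            gap_len = int(len(x) * rng.uniform(0.25, 0.5))
            gap_at = int(rng.integers(0, len(x) - gap_len))
            sel = gpos[gap_at:gap_at + gap_len]
            gaps.append((g.chrom, int(sel.min()), int(sel.max())))

    for chrom, lo, hi in gaps:
        vals[chrom][lo:hi + 1] = np.nan
    rows = []
    for chrom in sorted(vals):
        v = vals[chrom]
        pos = np.nonzero(~np.isnan(v))[0]
        keep = rng.random(len(pos)) >= cfg.occupancy_missing
        pos = pos[keep]
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": pos - 1, "end": pos, "value": v[pos],
        }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "value"])


def _simulate_polymorphisms(cfg, rng, genes):
    snps: list[PolymorphismEvent] = []
    dels: list[PolymorphismEvent] = []
    for g in genes:
        if not g.has_tss or g.upstream_len < 1:
            continue
        D = min(g.upstream_len, 800)
        d_axis = np.arange(1, D + 1)
        w = 1.0 + cfg.deletion_rate_slope * d_axis
        n_del = rng.poisson(cfg.deletion_rate * w.sum())
        if n_del:
            cw = np.cumsum(w)
            dists = np.searchsorted(cw, rng.random(n_del) * cw[-1]) + 1
            lens = 1 + rng.poisson(max(cfg.deletion_len_mean - 1, 0), n_del)
            for dist_i, L in zip(dists, lens):
                # event extends upstream from the sampled distance, clipped
                far = min(dist_i + int(L) - 1, D)
                if g.strand == "+":
                    s, e = g.tss - far, g.tss - dist_i
                else:
                    s, e = g.tss + dist_i, g.tss + far
                dels.append(PolymorphismEvent("deletion", g.chrom, int(s), int(e)))
        n_snp = rng.poisson(cfg.snp_rate * D)
        if n_snp:
            dists = rng.integers(1, D + 1, n_snp)
            for dist_i in dists:
                p = g.tss - dist_i if g.strand == "+" else g.tss + dist_i
                snps.append(PolymorphismEvent("SNP", g.chrom, int(p), int(p)))
    return snps, dels


def _simulate_expression(cfg, rng, genes):
    ids = [g.gene_id for g in genes]
    sd = rng.uniform(cfg.plasticity_sd_low, cfg.plasticity_sd_high, len(genes))
    vals = rng.normal(0.0, 1.0, (len(genes), cfg.n_conditions)) * sd[:, None]
    if cfg.expr_missing > 0:
        vals[rng.random(vals.shape) < cfg.expr_missing] = np.nan
    cols = [f"cond{j:04d}" for j in range(cfg.n_conditions)]
    return pd.DataFrame(vals, index=pd.Index(ids, name="gene_id"), columns=cols), sd


# ---------------------------------------------------------------------------
# top-level
# ---------------------------------------------------------------------------

def simulate(cfg: SyntheticConfig) -> SyntheticPackage:
    """Generate the full in-memory synthetic package (deterministic in seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = simulate_genes(cfg, rng)
    n = len(genes)

    # occupancy archetypes; divergent pairs share one (their windows overlap)
    occ_type = rng.choice(4, size=n, p=np.asarray(cfg.type_mix, float))
    by_cds = {(g.chrom, g.cds_start): i for i, g in enumerate(genes)}
    for i, g in enumerate(genes):
        if not g.bidirectional:
            continue
        j = by_cds.get((g.chrom, g.upstream_boundary))
        if j is not None and genes[j].upstream_boundary == g.cds_start and i < j:
            occ_type[j] = occ_type[i]

    # TATA propensity increases with 5'UTR length around the configured marginal
    utr = np.array([g.utr5_len if g.has_tss else np.nan for g in genes], float)
    utr_c = np.where(np.isnan(utr), 0.0, utr - np.nanmean(utr))
    tata_marginal = 0.2
    logit = np.log(tata_marginal / (1 - tata_marginal)) + 0.01 * utr_c
    p_tata = 1.0 / (1.0 + np.exp(-logit))
    tata = np.where(rng.random(n) < p_tata, "containing", "less")

    expr, sd = _simulate_expression(cfg, rng, genes)
    abundance = rng.normal(0.0, 1.0, n)
    level = np.select(
        [abundance >= np.quantile(abundance, 2 / 3), abundance >= np.quantile(abundance, 1 / 3)],
        ["high", "medium"], default="low",
    )

    genes = [
        dataclasses.replace(g, tata=str(tata[i]), expr_level=str(level[i]))
        for i, g in enumerate(genes)
    ]

    rates = np.full(n, cfg.sites_per_promoter)
    if cfg.site_rate_high_plasticity is not None:
        order = np.lexsort(([g.gene_id for g in genes], -sd))
        rates[order[: cfg.plasticity_top_n]] = cfg.site_rate_high_plasticity
    sites = simulate_sites(cfg, rng, genes, rates)

    occupancy = _simulate_occupancy(cfg, rng, genes, occ_type)
    snps, dels = _simulate_polymorphisms(cfg, rng, genes)

    n_sites = pd.Series([s.gene_id for s in sites]).value_counts()
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "occ_type": ["I II III IV".split()[t] for t in occ_type],
        "expr_sd": sd,
        "tata": tata,
        "expr_level": level,
        "utr5_len": [g.utr5_len if g.has_tss else -1 for g in genes],
        "n_sites": [int(n_sites.get(g.gene_id, 0)) for g in genes],
        "site_rate": rates,
    }).set_index("gene_id")
    return SyntheticPackage(config=cfg, genes=genes, sites=sites,
                            occupancy=occupancy, snps=snps, deletions=dels,
                            expr=expr, truth=truth)


def generate(cfg: SyntheticConfig, out_dir) -> dict[str, Path]:
    """Write the synthetic package to disk; byte-identical for equal config+seed."""
    pkg = simulate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "genes": "genes.tsv", "sites": "sites.bed", "occupancy": "occ.bedGraph",
        "snps": "snps.bed", "deletions": "dels.bed", "expr": "expr.tsv",
        "truth": "truth.tsv", "config": "config.yaml",
    }.items()}

    gdf = pd.DataFrame({
        "gene_id": [g.gene_id for g in pkg.genes],
        "chrom": [g.chrom for g in pkg.genes],
        "strand": [g.strand for g in pkg.genes],
        "tss": ["" if g.tss is None else g.tss for g in pkg.genes],
        "cds_start": [g.cds_start for g in pkg.genes],
        "upstream_boundary": [g.upstream_boundary for g in pkg.genes],
        "utr5_len": ["" if g.utr5_len is None else g.utr5_len for g in pkg.genes],
        "tata": [g.tata for g in pkg.genes],
        "expr_level": [g.expr_level for g in pkg.genes],
    })
    gdf.to_csv(paths["genes"], sep="\t", index=False)

    strand_of = {g.gene_id: g.strand for g in pkg.genes}
    with open(paths["sites"], "w") as fh:
        for s in pkg.sites:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.tf}\t.\t{strand_of[s.gene_id]}\n")

    pkg.occupancy.to_csv(paths["occupancy"], sep="\t", index=False, header=False,
                         float_format="%.4f")
    for key, events in (("snps", pkg.snps), ("deletions", pkg.deletions)):
        with open(paths[key], "w") as fh:
            for ev in events:
                fh.write(f"{ev.chrom}\t{ev.start - 1}\t{ev.end}\t{ev.kind}\n")
    pkg.expr.to_csv(paths["expr"], sep="\t", float_format="%.4f")
    pkg.truth.to_csv(paths["truth"], sep="\t", float_format="%.4f")

    import yaml

    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
    return paths
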