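# promoterscape

Positional analysis of *cis*-regulatory elements in yeast promoters:
where transcription-factor binding sites (TFBSs) sit relative to the
transcription start site (TSS) versus the translation start codon, and
how that distribution relates to nucleosome architecture, TATA boxes,
5'UTR length, polymorphism pressure and transcriptional output.

It is written for regulatory-genomics analyses where promoter lengths
vary widely, so raw positional counts are misleading: a position close to
the anchor is contained in nearly every promoter, a position 400 bp
upstream in only a fraction of them.

## Core statistic

For a gene set, a reference frame (TSS or start codon; positions are
signed, `-1` abuts `+1`, no 0) and `n(x)` sites at frame position `x`
contained in `r(x)` promoters,

```
d(x) = n(x) / r(x)
```

smoothed with a centered 41-bp moving average. Inference:

- **randomization envelope** — sites re-placed uniformly within their own
  promoters, 95% pointwise band over replicates;
- **bootstrap localization bias** — genes resampled with replacement and
  the peak-to-average ratio `max(d_smooth)/mean(d_smooth)` recorded per
  pseudoreplicate; the two frames' ratio distributions are compared with
  a Welch t-test;
- **polymorphism profiles** — deletion/SNP frequency `F(x) = N(x)/seqs(x)`
  in the 800 bp upstream of the TSS against a shuffle null;
- **promoter typing** — TSS-aligned nucleosome occupancy over a 1201-bp
  window, k-means (k = 4, 20 restarts) into Types I–IV ordered by
  nucleosome-free-region depth;
- **strata** — TATA status, 5'UTR-length tertiles, transcriptional
  plasticity (mean squared log2 ratio) extremes, expression level, each
  with per-stratum profiles and chi-square / Welch contrasts.

A synthetic genome-package generator (`promoterscape simulate`) produces
annotations, sites, occupancy tracks, polymorphism catalogues and an
expression matrix with the statistical structure the analyses assume,
plus a truth table for recovery checks.

## Worked example

```python
import numpy as np
from promoterscape import (SyntheticConfig, simulate, Frame, density_profile,
                           bootstrap_bias, compare_bias)

pkg = simulate(SyntheticConfig(n_genes=2000, seed=1))
prof = density_profile(pkg.sites, pkg.genes, Frame.TSS)
ok = ~np.isnan(prof.d_smooth) & (prof.positions < 0)
print(prof.positions[ok][np.argmax(prof.d_smooth[ok])])

tss = bootstrap_bias(pkg.sites, pkg.genes, Frame.TSS, B=200, seed=101)
sc  = bootstrap_bias(pkg.sites, pkg.genes, Frame.START_CODON, B=200, seed=102)
res = compare_bias(tss, sc)
print(f"{tss.mean_ratio:.2f} +/- {tss.sd_ratio:.2f} vs "
      f"{sc.mean_ratio:.2f} +/- {sc.sd_ratio:.2f}  (t={res.t:.1f}, p={res.p:.3g})")
```

prints

```
-116
5.07 +/- 0.10 vs 3.45 +/- 0.08  (t=180.3, p=0)
```

The planted site preference (Normal at -115 bp upstream of the TSS, sd
40, weight 0.6) is recovered at -116 bp by the smoothed density, and the
TSS-frame profile is far more localized than the start-codon-frame
profile of the same sites — the contrast that motivates anchoring
positional analyses on the TSS.

The same analyses run from the shell:

```
promoterscape simulate --n-genes 2000 --seed 1 --out-dir pkg/
promoterscape run-all --genes pkg/genes.tsv --sites pkg/sites.bed \
    --occupancy pkg/occ.bedGraph --snps pkg/snps.bed --deletions pkg/dels.bed \
    --expr pkg/expr.tsv --randomize 200 --bootstrap 200 --out-dir report/
```

which writes one TSV per figure-analogue (`fig1a` … `fig4b`) and a
`manifest.json` with seeds, statistics and output hashes; reruns with the
same configuration are bit-identical.

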