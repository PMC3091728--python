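"""Gene strata and between-stratum tests.

Strata compared throughout the analysis: TATA-box presence, 5'UTR length
groups (tertiles by default), transcriptional plasticity extremes
(top/bottom 500 by the mean squared log2 expression ratio across many
conditions) and categorical expression level.  Positional site profiles
are recomputed per stratum — coverage normalization included — and the
association and location tests (chi-square, Welch t) are the ones used
for promoter architecture contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_frames import Frame, GeneAnnotation, InputError, SiteRecord
from .density import PositionalProfile, density_profile

log = logging.getLogger(__name__)

UTR_GROUPS_3 = ("short", "medium", "long")


def plasticity(expr: pd.DataFrame) -> pd.Series:
    """Per-gene transcriptional plasticity: mean squared log2 ratio.

    ``expr`` is genes x conditions of log2 expression ratios; missing
    values are ignored.  Genes with no non-missing value are excluded
    (logged).
    """
    vals = (expr.astype(float) ** 2).mean(axis=1, skipna=True)
    dropped = vals.index[vals.isna()]
    if len(dropped):
        log.info("%d genes with no expression data excluded from plasticity",
                 len(dropped))
    return vals.dropna().rename("plasticity")


def utr_tertiles(
    genes: Sequence[GeneAnnotation],
    quantiles: int = 3,
) -> tuple[tuple[int, ...], pd.Series]:
    """Split TSS-known genes into 5'UTR-length quantile groups.

    Returns the thresholds (the smallest 5'UTR length in each group above
    the first — e.g. a gene is "medium" when t1 <= len < t2) and a label
    per gene.  Ties at a boundary go to the lower group.
    """
    usable = [g for g in genes if g.has_tss]
    if len(usable) < quantiles:
        raise InputError(f"need at least {quantiles} TSS-known genes")
    lens = pd.Series({g.gene_id: g.utr5_len for g in usable})
    if lens.nunique() == 1:
        raise InputError("all 5'UTR lengths identical; quantile groups degenerate")
    qs = np.quantile(lens.to_numpy(), np.arange(1, quantiles) / quantiles)
    names = UTR_GROUPS_3 if quantiles == 3 else tuple(
        f"q{i + 1}" for i in range(quantiles)
    )
    codes = np.digitize(lens.to_numpy(), qs, right=True)  # boundary ties stay low
    labels = pd.Series([names[c] for c in codes], index=lens.index, name="utr_group")
    thresholds = tuple(
        int(lens[labels == names[i]].min()) for i in range(1, quantiles)
    )
    return thresholds, labels


def build_strata(
    genes: Sequence[GeneAnnotation],
    expr: pd.DataFrame | None = None,
    top_n: int = 500,
    quantiles: int = 3,
) -> pd.DataFrame:
    """Assemble the per-gene stratum table.

    Columns: ``tata``, ``utr5_len``, ``utr_group``, ``expr_level`` and —
    when an expression matrix is given — ``plasticity`` and
    ``plasticity_group`` ('top500'/'bottom500'/'middle', boundary ties
    broken by gene-id order for determinism).
    """
    df = pd.DataFrame(
        {
            "tata": {g.gene_id: g.tata for g in genes},
            "expr_level": {g.gene_id: g.expr_level for g in genes},
            "utr5_len": {g.gene_id: g.utr5_len if g.has_tss else np.nan for g in genes},
        }
    )
    _, utr_labels = utr_tertiles(genes, quantiles)
    df["utr_group"] = utr_labels
    if expr is not None:
        pl = plasticity(expr)
        df["plasticity"] = pl
        ranked = pl.reset_index()
        ranked.columns = ["gene_id", "plasticity"]
        top = ranked.sort_values(["plasticity", "gene_id"],
                                 ascending=[False, True]).head(top_n)["gene_id"]
        bottom = ranked.sort_values(["plasticity", "gene_id"],
                                    ascending=[True, True]).head(top_n)["gene_id"]
        grp = pd.Series("middle", index=pl.index, name="plasticity_group")
        grp[top] = f"top{top_n}"
        grp[bottom] = f"bottom{top_n}"
        df["plasticity_group"] = grp
    return df


def stratified_profiles(
    sites: Sequence[SiteRecord],
    genes: Sequence[GeneAnnotation],
    labels: Mapping[str, str] | pd.Series,
    frame: Frame,
    **profile_kwargs,
) -> dict[str, PositionalProfile]:
    """One coverage-normalized profile per stratum (r computed in-stratum)."""
    if isinstance(labels, pd.Series):
        labels = labels.dropna().to_dict()
    out: dict[str, PositionalProfile] = {}
    for label in sorted(set(labels.values()), key=str):
        members = {g for g, l in labels.items() if l == label}
        sub_genes = [g for g in genes if g.gene_id in members]
        sub_sites = [s for s in sites if s.gene_id in members]
        if not any(g.usable(frame) for g in sub_genes):
            log.info("stratum '%s' empty in frame %s; skipped", label, frame.value)
            continue
        out[label] = density_profile(sub_sites, sub_genes, frame, **profile_kwargs)
    return out


@dataclass
class ChiSquareResult:
    table: pd.DataFrame
    chi2: float
    p: float
    dof: int
    cell_tests: pd.DataFrame  # per-cell 2x2 vs rest: chi2, p, enrichment


def tata_by_utr_test(strata: pd.DataFrame) -> ChiSquareResult:
    """Chi-square association between TATA presence and 5'UTR group.

    The overall test uses the 2x3 (TATA containing/less x short/medium/
    long) table; each cell additionally gets a 2x2 test of that cell
    against the rest, with an enrichment ratio (observed/expected).
    """
    sub = strata[strata["tata"].isin(["containing", "less"]) & strata["utr_group"].notna()]
    table = pd.crosstab(sub["tata"], sub["utr_group"])
    order = [g for g in UTR_GROUPS_3 if g in table.columns] or list(table.columns)
    table = table.loc[["containing", "less"], order]
    expected = stats.contingency.expected_freq(table.to_numpy())
    if (expected == 0).any():
        raise InputError("a contingency cell has expected count 0; use an exact test")
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy())
    rows = []
    total = table.to_numpy().sum()
    for i, tata in enumerate(table.index):
        for j, grp in enumerate(table.columns):
            a = table.iat[i, j]
            row_rest = table.iloc[i].sum() - a
            col_rest = table.iloc[:, j].sum() - a
            rest = total - a - row_rest - col_rest
            c2, cp, _, _ = stats.chi2_contingency([[a, row_rest], [col_rest, rest]])
            rows.append({
                "tata": tata, "utr_group": grp, "observed": int(a),
                "expected": expected[i, j], "enrichment": a / expected[i, j],
                "chi2": c2, "p": cp,
            })
    return ChiSquareResult(table=table, chi2=float(chi2), p=float(p), dof=int(dof),
                           cell_tests=pd.DataFrame(rows))


@dataclass
class TTestResult:
    t: float
    p: float
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    n_a: int
    n_b: int


def utr_length_ttest(
    values: pd.Series,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> TTestResult:
    """Welch two-sample t-test of a per-gene quantity between two strata.

    Typically 5'UTR length between TATA-containing and TATA-less genes or
    between promoter architecture types.
    """
    common = values.index.intersection(groups.index)
    v, g = values[common].astype(float), groups[common]
    xa = v[g == group_a].dropna().to_numpy()
    xb = v[g == group_b].dropna().to_numpy()
    if len(xa) < 2 or len(xb) < 2:
        raise InputError("both groups need at least 2 observations")
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0 and xa.mean() == xb.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return TTestResult(
        t=float(t), p=float(p), mean_a=float(xa.mean()), mean_b=float(xb.mean()),
        se_a=float(xa.std(ddof=1) / np.sqrt(len(xa))),
        se_b=float(xb.std(ddof=1) / np.sqrt(len(xb))),
        n_a=len(xa), n_b=len(xb),
    )
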