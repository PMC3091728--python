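"""End-to-end orchestration: from an on-disk genome package to report tables.

``run_all`` executes the analysis stages in the order the results are
read: positional site density in both reference frames with randomization
envelopes, bootstrap localization-bias comparison, polymorphism profiles,
nucleosome promoter typing, and the per-type / per-stratum profiles and
tests.  One TSV is written per figure-analogue plus a JSON manifest
recording seeds, parameters, stage status, headline statistics and output
hashes; a rerun with the same configuration reproduces outputs
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome_frames import (
    Frame, InputError, read_annotations, read_events, read_sites,
)
from .density import (
    bootstrap_bias, compare_bias, density_profile, randomization_envelope,
)
from .polymorphism import polymorphism_frequency, positional_trend_test
from .nucleosomes import filter_coverage, group_occupancy, kmeans_types, load_occupancy
from .strata import (
    build_strata, stratified_profiles, tata_by_utr_test, utr_length_ttest,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    genes: Path
    sites: Path
    out_dir: Path
    occupancy: Path | None = None
    snps: Path | None = None
    deletions: Path | None = None
    expr: Path | None = None
    window: int = 41
    mode: str = "midpoint"
    randomize_reps: int = 1000
    bootstrap_reps: int = 1000
    rand_seed: int = 11
    boot_seed: int = 12
    cluster_seed: int = 13
    eval_range: tuple[int, int] = (-800, -1)
    top_n: int = 500
    min_coverage_occ: float = 0.80
    exclude_bidirectional: bool = False
    plot: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _profile_table(profile, envelope=None) -> pd.DataFrame:
    df = profile.to_frame_df()
    if envelope is not None:
        df["rand_mean"] = envelope.mean
        df["rand_lo95"] = envelope.lo95
        df["rand_hi95"] = envelope.hi95
    return df


def _wide_profiles(profiles: dict) -> pd.DataFrame:
    out = None
    for label, p in profiles.items():
        df = p.to_frame_df()[["position", "d_smooth"]].rename(
            columns={"d_smooth": f"d_smooth_{label}"}
        )
        out = df if out is None else out.merge(df, on="position", how="outer")
    return out


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(config: RunConfig) -> Path:
    """Run every stage; returns the report directory.

    Stages with missing optional inputs are skipped with a notice in the
    manifest; any hard failure aborts with the stage name (outputs written
    so far are preserved).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": {},
        "stats": {},
    }
    written: list[Path] = []

    def stage(name):
        def deco(fn):
            try:
                fn()
                manifest["stages"].setdefault(name, "ok")
            except (StageError,):
                raise
            except Exception as exc:
                manifest["stages"][name] = f"failed: {exc}"
                _finish(out, manifest, written)
                raise StageError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("load")
    def _load():
        state["genes"] = read_annotations(config.genes)
        state["sites"], rejected = read_sites(config.sites, state["genes"])
        manifest["stats"]["sites_rejected"] = rejected
        manifest["stats"]["n_genes"] = len(state["genes"])
        manifest["stats"]["n_sites"] = len(state["sites"])

    @stage("density")
    def _density():
        kw = dict(window=config.window, mode=config.mode,
                  exclude_bidirectional=config.exclude_bidirectional)
        for frame, fname in ((Frame.TSS, "fig1a.tsv"), (Frame.START_CODON, "fig1b.tsv")):
            prof = density_profile(state["sites"], state["genes"], frame, **kw)
            env = randomization_envelope(
                state["sites"], state["genes"], frame, R=config.randomize_reps,
                seed=config.rand_seed, window=config.window, mode=config.mode)
            _write(_profile_table(prof, env), out / fname)
            written.append(out / fname)
            state[f"profile_{frame.value}"] = prof
        peak = state["profile_tss"]
        ok = ~np.isnan(peak.d_smooth) & (peak.positions < 0)
        manifest["stats"]["tss_peak_position"] = int(
            peak.positions[ok][np.argmax(peak.d_smooth[ok])])

    @stage("bias")
    def _bias():
        results = {}
        for frame in (Frame.TSS, Frame.START_CODON):
            results[frame.value] = bootstrap_bias(
                state["sites"], state["genes"], frame, B=config.bootstrap_reps,
                seed=config.boot_seed, window=config.window, mode=config.mode,
                eval_range=config.eval_range)
        cmp_res = compare_bias(results["tss"], results["startcodon"])
        manifest["stats"]["bias"] = {
            "mean_ratio_tss": results["tss"].mean_ratio,
            "sd_ratio_tss": results["tss"].sd_ratio,
            "mean_ratio_startcodon": results["startcodon"].mean_ratio,
            "sd_ratio_startcodon": results["startcodon"].sd_ratio,
            "t": cmp_res.t, "p": cmp_res.p,
        }

    @stage("polymorphism")
    def _poly():
        if config.deletions is None and config.snps is None:
            manifest["stages"]["polymorphism"] = "skipped: no polymorphism input"
            return
        if config.deletions is not None:
            dels = read_events(config.deletions, "deletion")
            prof = polymorphism_frequency(dels, state["genes"], "deletion",
                                          seed=config.rand_seed,
                                          reps=config.randomize_reps,
                                          window=config.window)
            _write(prof.to_frame_df(), out / "fig1c.tsv")
            written.append(out / "fig1c.tsv")
        if config.snps is not None:
            snps = read_events(config.snps, "SNP")
            prof = polymorphism_frequency(snps, state["genes"], "SNP",
                                          seed=config.rand_seed,
                                          reps=config.randomize_reps,
                                          window=config.window)
            _write(prof.to_frame_df(), out / "snp_profile.tsv")
            written.append(out / "snp_profile.tsv")
            _, p = positional_trend_test(prof)
            manifest["stats"]["snp_trend_p"] = p

    @stage("cluster")
    def _cluster():
        if config.occupancy is None:
            manifest["stages"]["cluster"] = "skipped: no occupancy input"
            return
        occ = load_occupancy(config.occupancy, state["genes"])
        occ = filter_coverage(occ, config.min_coverage_occ)
        assign = kmeans_types(occ, seed=config.cluster_seed)
        state["occ"], state["types"] = occ, assign
        pd.DataFrame({"gene_id": assign.assignments.index,
                      "type": assign.assignments.values}).to_csv(
            out / "fig2b.tsv", sep="\t", index=False)
        written.append(out / "fig2b.tsv")
        manifest["stats"]["cluster_sizes"] = {
            k: int(v) for k, v in sorted(assign.sizes.items())}
        # genome-average occupancy vs overall site density
        avg = group_occupancy(occ, {"all": occ.gene_ids})
        prof = state["profile_tss"].to_frame_df()[["position", "d_smooth"]]
        fig2a = avg.reset_index().merge(prof, on="position", how="left")
        _write(fig2a, out / "fig2a.tsv")
        written.append(out / "fig2a.tsv")
        # per-type site density
        profs = stratified_profiles(state["sites"], state["genes"],
                                    assign.assignments, Frame.TSS,
                                    window=config.window, mode=config.mode)
        _write(_wide_profiles(profs), out / "fig2c.tsv")
        written.append(out / "fig2c.tsv")

    @stage("strata")
    def _strata():
        expr = None
        if config.expr is not None:
            expr = pd.read_csv(config.expr, sep="\t", index_col=0)
        strata = build_strata(state["genes"], expr=expr, top_n=config.top_n)
        state["strata"] = strata
        kw = dict(window=config.window, mode=config.mode)
        tata_profiles = stratified_profiles(
            state["sites"], state["genes"],
            strata["tata"][strata["tata"].isin(["containing", "less"])],
            Frame.TSS, **kw)
        _write(_wide_profiles(tata_profiles), out / "fig2d.tsv")
        written.append(out / "fig2d.tsv")
        utr_profiles = stratified_profiles(state["sites"], state["genes"],
                                           strata["utr_group"], Frame.TSS, **kw)
        _write(_wide_profiles(utr_profiles), out / "fig2e.tsv")
        written.append(out / "fig2e.tsv")
        # TATA x 5'UTR association
        chi = tata_by_utr_test(strata)
        _write(chi.cell_tests.assign(overall_chi2=chi.chi2, overall_p=chi.p),
               out / "fig3c.tsv")
        written.append(out / "fig3c.tsv")
        manifest["stats"]["tata_utr_chi2_p"] = chi.p
        tt = utr_length_ttest(strata["utr5_len"], strata["tata"], "containing", "less")
        _write(pd.DataFrame([dataclasses.asdict(tt)]), out / "fig3d.tsv")
        written.append(out / "fig3d.tsv")
        manifest["stats"]["utr_by_tata_p"] = tt.p
        if "types" in state:
            types = state["types"].assignments
            rows = []
            for t in sorted(types.unique()):
                members = types.index[types == t]
                vals = strata.loc[strata.index.intersection(members), "utr5_len"].dropna()
                rows.append({"type": t, "mean_utr5_len": vals.mean(),
                             "se": vals.std(ddof=1) / np.sqrt(len(vals)), "n": len(vals)})
            _write(pd.DataFrame(rows), out / "fig3a.tsv")
            written.append(out / "fig3a.tsv")
            tt41 = utr_length_ttest(strata["utr5_len"], types, "IV", "I")
            manifest["stats"]["utr_typeIV_vs_I"] = dataclasses.asdict(tt41)
            occ_by_utr = group_occupancy(
                state["occ"],
                {g: strata.index[strata["utr_group"] == g].tolist()
                 for g in strata["utr_group"].dropna().unique()})
            _write(occ_by_utr.reset_index(), out / "fig3b.tsv")
            written.append(out / "fig3b.tsv")
        if "plasticity_group" in strata.columns:
            pl_profiles = stratified_profiles(
                state["sites"], state["genes"],
                strata["plasticity_group"][strata["plasticity_group"] != "middle"],
                Frame.TSS, **kw)
            _write(_wide_profiles(pl_profiles), out / "fig4a.tsv")
            written.append(out / "fig4a.tsv")
        expr_profiles = stratified_profiles(
            state["sites"], state["genes"],
            strata["expr_level"][strata["expr_level"].isin(["high", "medium", "low"])],
            Frame.TSS, **kw)
        if expr_profiles:
            _write(_wide_profiles(expr_profiles), out / "fig4b.tsv")
            written.append(out / "fig4b.tsv")

    if config.plot:
        _plots(out)
    _finish(out, manifest, written)
    return out


def _plots(out: Path):
    """Decorative quick-look plots for any profile tables present."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is optional
        log.warning("matplotlib unavailable; skipping plots")
        return
    for tsv in sorted(out.glob("fig*.tsv")):
        df = pd.read_csv(tsv, sep="\t")
        if "position" not in df.columns:
            continue
        fig, ax = plt.subplots(figsize=(7, 3.5))
        for col in df.columns:
            if col.startswith(("d_smooth", "F_smooth", "rand_", "all")):
                ax.plot(df["position"], df[col], label=col, lw=1)
        ax.set_xlabel("position")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(tsv.with_suffix(".png"), dpi=100)
        plt.close(fig)


def _finish(out: Path, manifest: dict, written: list[Path]):
    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    # hash covers the reproducibility contract (results), not I/O paths
    payload = json.dumps({k: manifest[k] for k in ("stages", "stats", "outputs")},
                         sort_keys=True, default=str)
    manifest["manifest_hash"] = hashlib.sha256(payload.encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
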