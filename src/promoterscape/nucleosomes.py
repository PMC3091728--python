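"""TSS-aligned nucleosome occupancy and k-means promoter typing.

Per-base log2 nucleosome occupancy is aligned on each gene's TSS over a
1201-bp window (frame positions -1000..-1, +1..+201: one kilobase
upstream, the TSS base, 200 bp downstream).  Genes with at least 80% of
the window covered by data are clustered with k-means (Euclidean
distance, best of 20 random restarts) into four promoter architecture
types, relabelled I-IV by ascending mean occupancy over the
nucleosome-free-region window [-150, -50]: Type I promoters have the
deepest NFR, Type IV are essentially fully occupied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome_frames import Frame, FrameGrid, GeneAnnotation, InputError

log = logging.getLogger(__name__)

OCC_RANGE = (-1000, 201)      # 1201 frame coordinates
NFR_WINDOW = (-150, -50)
TYPE_LABELS = ("I", "II", "III", "IV")


@dataclass
class OccupancyMatrix:
    gene_ids: list[str]
    positions: np.ndarray      # frame coordinates, length 1201
    values: np.ndarray         # genes x positions, NaN = missing

    @property
    def coverage(self) -> np.ndarray:
        return 1.0 - np.isnan(self.values).mean(axis=1)

    def subset(self, gene_ids: Sequence[str]) -> "OccupancyMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids if g in idx]
        return OccupancyMatrix(
            gene_ids=[self.gene_ids[i] for i in rows],
            positions=self.positions,
            values=self.values[rows],
        )


@dataclass
class ClusterAssignment:
    assignments: pd.Series     # gene_id -> "I".."IV"
    inertia: float
    reps_used: int
    seed: int
    nfr_means: dict            # type label -> mean occupancy in NFR window

    @property
    def sizes(self) -> dict:
        return self.assignments.value_counts().to_dict()


def _read_bedgraph(track) -> pd.DataFrame:
    if isinstance(track, pd.DataFrame):
        df = track.iloc[:, :4].copy()
    else:
        df = pd.read_csv(track, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3])
    df.columns = ["chrom", "start", "end", "value"]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return df


def load_occupancy(
    track,
    genes: Sequence[GeneAnnotation],
    frame_range: tuple[int, int] = OCC_RANGE,
) -> OccupancyMatrix:
    """Align a bedGraph occupancy track on each gene's TSS, strand-aware.

    ``track`` is a bedGraph path or an equivalent 4-column DataFrame
    (0-based half-open intervals).  Window bases absent from the track are
    NaN; genes with no covered base at all are dropped (logged).
    """
    df = _read_bedgraph(track)
    grid = FrameGrid(*frame_range)
    # dense per-chromosome arrays (yeast-scale genomes)
    dense: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        size = int(sub["end"].max())
        arr = np.full(size, np.nan)
        lens = (sub["end"] - sub["start"]).to_numpy()
        idx = np.repeat(sub["start"].to_numpy(), lens) + _within_run_offsets(lens)
        arr[idx] = np.repeat(sub["value"].to_numpy(), lens)
        dense[chrom] = arr

    gene_ids, rows = [], []
    dropped = 0
    offs = grid.positions - (grid.positions > 0)  # signed bp offsets from TSS
    for g in genes:
        if not g.has_tss:
            continue
        arr = dense.get(g.chrom)
        if arr is None:
            dropped += 1
            continue
        # genomic positions of the window bases, 1-based -> 0-based index
        gpos = (g.tss + offs) if g.strand == "+" else (g.tss - offs)
        gidx = gpos - 1
        row = np.full(grid.size, np.nan)
        ok = (gidx >= 0) & (gidx < len(arr))
        row[ok] = arr[gidx[ok]]
        if np.isnan(row).all():
            dropped += 1
            continue
        gene_ids.append(g.gene_id)
        rows.append(row)
    if dropped:
        log.info("%d genes without occupancy data dropped", dropped)
    if not rows:
        raise InputError("no genes with occupancy data")
    return OccupancyMatrix(gene_ids=gene_ids, positions=grid.positions,
                           values=np.vstack(rows))


def _within_run_offsets(lens: np.ndarray) -> np.ndarray:
    total = int(lens.sum())
    out = np.arange(total)
    out -= np.repeat(np.cumsum(lens) - lens, lens)
    return out


def filter_coverage(matrix: OccupancyMatrix, min_cov: float = 0.80) -> OccupancyMatrix:
    """Drop genes with less than ``min_cov`` of the window covered (inclusive)."""
    keep = matrix.coverage >= min_cov
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("%d genes below %.0f%% occupancy coverage removed",
                 n_removed, 100 * min_cov)
    if not keep.any():
        raise InputError("coverage filter removed every gene")
    return OccupancyMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        positions=matrix.positions,
        values=matrix.values[keep],
    )


def kmeans_types(
    matrix: OccupancyMatrix,
    k: int = 4,
    reps: int = 20,
    seed: int = 0,
    impute: str = "row_mean",
) -> ClusterAssignment:
    """Cluster promoters into k nucleosome-architecture types.

    Missing cells are imputed (per-row mean by default, per-position mean
    with ``impute='position_mean'``) before Euclidean k-means with
    ``reps`` random restarts (best inertia kept).  Raw cluster indices are
    mapped to Type I..IV by ascending mean occupancy over the NFR window.
    """
    X = matrix.values.copy()
    if X.shape[0] < k:
        raise InputError(f"need at least {k} genes to form {k} clusters")
    if impute == "row_mean":
        fill = np.nanmean(X, axis=1, keepdims=True)
    elif impute == "position_mean":
        fill = np.broadcast_to(np.nanmean(X, axis=0, keepdims=True), X.shape)
    else:
        raise InputError("impute must be 'row_mean' or 'position_mean'")
    X = np.where(np.isnan(X), fill, X)
    if len(np.unique(X, axis=0)) < k:
        raise InputError(
            "fewer distinct occupancy profiles than clusters; the data are "
            "degenerate — reduce k or check the input track"
        )
    km = KMeans(n_clusters=k, n_init=reps, random_state=seed)
    raw = km.fit_predict(X)

    nfr = (matrix.positions >= NFR_WINDOW[0]) & (matrix.positions <= NFR_WINDOW[1])
    cluster_nfr = np.array([
        np.nanmean(matrix.values[raw == c][:, nfr]) for c in range(k)
    ])
    order = np.argsort(cluster_nfr)
    labels = TYPE_LABELS[:k] if k <= 4 else tuple(str(i + 1) for i in range(k))
    mapping = {int(c): labels[rank] for rank, c in enumerate(order)}
    assignments = pd.Series(
        [mapping[int(c)] for c in raw], index=matrix.gene_ids, name="type"
    )
    nfr_means = {mapping[int(c)]: float(cluster_nfr[c]) for c in range(k)}
    return ClusterAssignment(assignments=assignments, inertia=float(km.inertia_),
                             reps_used=reps, seed=seed, nfr_means=nfr_means)


def group_occupancy(
    matrix: OccupancyMatrix,
    groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-position mean occupancy (over non-missing cells) for each group."""
    idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    out = {}
    for label, members in groups.items():
        rows = [idx[g] for g in members if g in idx]
        if not rows:
            raise InputError(f"group '{label}' has no genes with occupancy data")
        out[label] = np.nanmean(matrix.values[rows], axis=0)
    return pd.DataFrame(out, index=pd.Index(matrix.positions, name="position"))
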