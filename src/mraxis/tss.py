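"""Strand-oriented metagene coverage profiles around transcription start sites.

Computes the mean ChIP coverage (e.g. H3K27me3) in fixed-width bins across
±15 kb windows centred on the TSSs of a gene set. Windows are oriented
5'→3' of each gene: the TSS of a minus-strand gene is its annotation end,
and its per-gene bin vector is reversed before averaging, so bin offsets
always read upstream → downstream. Coordinates are BED/bedGraph 0-based
half-open; bedGraph gaps count as zero coverage; windows overhanging the
chromosome start are clipped and the lost positions masked out of the
means rather than the gene being dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TSSWindow", "TSSProfile", "tss_windows", "profile_density"]


@dataclass(frozen=True)
class TSSWindow:
    gene_id: str
    chrom: str
    start: int  # genomic, clipped at 0
    end: int
    reverse: bool  # True for minus-strand genes
    clipped_left: int  # positions lost to the chromosome start


@dataclass
class TSSProfile:
    gene_set_name: str
    bin_edges: np.ndarray  # offsets in bp relative to the TSS, oriented
    mean_density: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_bp": self.bin_edges[:-1],
                "mean_density": self.mean_density,
                "n_genes": self.n_genes,
            }
        )


def tss_windows(
    annotations: pd.DataFrame,
    gene_set,
    flank: int = 15_000,
) -> list[TSSWindow]:
    """Oriented ±flank windows around each gene's TSS.

    ``annotations`` is a BED6-like frame (chrom, start, end, name, score,
    strand). The TSS is ``start`` for + genes and ``end`` for − genes.
    Genes missing from the annotation are skipped with a warning.
    """
    by_name = annotations.set_index("name")
    windows = []
    missing = []
    for gene in sorted(gene_set):
        if gene not in by_name.index:
            missing.append(gene)
            continue
        row = by_name.loc[gene]
        tss = int(row["start"]) if row["strand"] == "+" else int(row["end"])
        lo, hi = tss - flank, tss + flank
        clipped = max(0, -lo)
        windows.append(
            TSSWindow(
                gene_id=gene,
                chrom=str(row["chrom"]),
                start=max(lo, 0),
                end=hi,
                reverse=row["strand"] == "-",
                clipped_left=clipped,
            )
        )
    if missing:
        warnings.warn(f"{len(missing)} genes missing from annotation: {missing[:5]}")
    return windows


def _window_bins(
    intervals: np.ndarray, window: TSSWindow, full_lo: int, n_bins: int, bin_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Coverage-weighted sums and valid-position counts per bin for one window.

    ``intervals`` is an (n, 3) float array of (start, end, value) on the
    window's chromosome. Bin b covers genomic [full_lo + b*bin_size,
    full_lo + (b+1)*bin_size); positions below window.start (clipped) are
    masked. Gaps between bedGraph intervals contribute 0 coverage but
    still count as valid positions.
    """
    sums = np.zeros(n_bins)
    valid = np.zeros(n_bins)
    edges = full_lo + np.arange(n_bins + 1) * bin_size
    # valid positions per bin: inside [window.start, window.end)
    lo = np.maximum(edges[:-1], window.start)
    hi = np.minimum(edges[1:], window.end)
    valid = np.maximum(hi - lo, 0).astype(float)
    if intervals.size:
        starts = np.maximum(intervals[:, 0], window.start)
        ends = np.minimum(intervals[:, 1], window.end)
        keep = starts < ends
        for s, e, v in zip(starts[keep], ends[keep], intervals[keep, 2]):
            b0 = int((s - full_lo) // bin_size)
            b1 = int((e - 1 - full_lo) // bin_size)
            for b in range(max(b0, 0), min(b1, n_bins - 1) + 1):
                ov = min(e, edges[b + 1]) - max(s, edges[b])
                if ov > 0:
                    sums[b] += v * ov
    return sums, valid


def profile_density(
    coverage: pd.DataFrame,
    windows: list[TSSWindow],
    bin_size: int = 300,
    flank: int = 15_000,
    gene_set_name: str = "",
    return_matrix: bool = False,
):
    """Binned mean coverage profile across a set of TSS windows.

    Parameters
    ----------
    coverage : bedGraph frame (chrom, start, end, value), sorted and
        non-overlapping per chromosome (see :func:`mraxis.io.read_bedgraph`).
    windows : output of :func:`tss_windows`.
    bin_size : bp per bin; must divide ``2 * flank``.
    return_matrix : also return the per-gene bin matrix (genes x bins,
        NaN where a bin is fully masked).

    Per window, each bin's value is the interval-overlap-weighted mean
    coverage over its valid (unclipped) positions; minus-strand vectors
    are reversed; the profile is the per-bin mean across genes, ignoring
    masked positions.
    """
    if (2 * flank) % bin_size != 0:
        raise ValueError("bin_size must divide the full window width (2*flank)")
    n_bins = (2 * flank) // bin_size
    by_chrom = {
        chrom: sub[["start", "end", "value"]].to_numpy(dtype=float)
        for chrom, sub in coverage.groupby("chrom", sort=False)
    }
    matrix = np.full((len(windows), n_bins), np.nan)
    names = []
    for i, w in enumerate(windows):
        names.append(w.gene_id)
        intervals = by_chrom.get(w.chrom, np.empty((0, 3)))
        full_lo = w.start - w.clipped_left  # unclipped window origin
        sums, valid = _window_bins(intervals, w, full_lo, n_bins, bin_size)
        vec = np.divide(sums, valid, out=np.full(n_bins, np.nan), where=valid > 0)
        if w.reverse:
            vec = vec[::-1]
        matrix[i] = vec
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(matrix, axis=0) if len(windows) else np.full(n_bins, np.nan)
    edges = np.arange(-flank, flank + 1, bin_size)
    profile = TSSProfile(gene_set_name, edges, mean, len(windows))
    if return_matrix:
        return profile, pd.DataFrame(matrix, index=names, columns=edges[:-1])
    return profile
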