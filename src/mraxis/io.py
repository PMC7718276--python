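"""Readers and writers for the plain-text formats the pipeline exchanges.

GMT gene sets, expression matrices (genes x samples TSV), BED6 gene
annotations, bedGraph coverage tracks, and the 4-column strain-variant
blacklist. Genomic interval formats are 0-based half-open throughout.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_bed6",
    "write_bed6",
    "read_bedgraph",
    "write_bedgraph",
    "read_blacklist",
    "write_blacklist",
]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_expression(path) -> pd.DataFrame:
    """Expression matrix TSV: first column gene identifiers, header = samples."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index.name = "gene"
    return mat


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 6:
        raise ValueError(f"{path}: BED6 requires 6 columns, found {bed.shape[1]}")
    bed = bed.iloc[:, :6]
    bed.columns = BED6_COLUMNS
    bad = ~bed["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: undefined strand at rows {list(bed.index[bad])[:5]}")
    if (bed["start"] >= bed["end"]).any():
        raise ValueError(f"{path}: intervals must satisfy start < end")
    return bed


def write_bed6(bed: pd.DataFrame, path) -> None:
    bed[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph; require per-chromosome sorted, non-overlapping."""
    track = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
    )
    for chrom, sub in track.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts >= ends).any():
            raise ValueError(f"{path}: empty/inverted interval on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{path}: unsorted or overlapping intervals on {chrom}")
    return track


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


BLACKLIST_COLUMNS = ["chrom", "pos", "ref", "alt"]


def read_blacklist(path) -> set[tuple[str, int, str, str]]:
    """Strain-variant blacklist TSV with header chrom, pos, ref, alt (1-based)."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(BLACKLIST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: blacklist lacks columns {sorted(missing)}")
    return {
        (str(r.chrom), int(r.pos), r.ref, r.alt) for r in table.itertuples(index=False)
    }


def write_blacklist(keys, path) -> None:
    rows = sorted(keys)
    pd.DataFrame(rows, columns=BLACKLIST_COLUMNS).to_csv(path, sep="\t", index=False)
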