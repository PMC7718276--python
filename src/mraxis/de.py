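"""Differential-expression gene scoring.

Turns an (externally produced) differential-expression table — gene,
log2 fold-change, p-value, BH-adjusted p-value — into

* significance-called up/down gene sets (``|log2FC| > 1`` and
  ``adj_p < 0.05`` by default, strict inequalities), and
* signed gene scores ``S = sign(log2FC) * -log10(adj_p)`` used both for
  pre-ranked GSEA and as the per-gene weight in the regulator network score.

The table is consumed, not fitted: no count modelling happens here.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DERecord",
    "GeneScore",
    "benjamini_hochberg",
    "gene_score",
    "score_table",
    "call_differential",
    "rank_genes",
    "map_homologs",
    "read_de_table",
    "write_scores",
]

#: -log10 of the smallest positive normal double; caps scores when adj_p == 0.
SCORE_CAP = -np.log10(sys.float_info.min)


@dataclass(frozen=True)
class DERecord:
    """One row of a differential-expression table."""

    gene_id: str
    log2_fc: float
    p_value: float
    adj_p_value: float

    def __post_init__(self) -> None:
        for field in ("p_value", "adj_p_value"):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{field} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class GeneScore:
    """Signed significance score for one gene: sign(log2FC) * -log10(adj p)."""

    gene_id: str
    score: float


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Implements the classic step-up procedure: sort the m p-values
    ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank down, and cap at 1.

    Parameters
    ----------
    p_values : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray
        Adjusted p-values aligned with the input positions.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("all p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce the step-up monotonicity: adj_(i) = min over j >= i
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m, dtype=float)
    adj[order] = adj_sorted
    return adj


def gene_score(record: DERecord) -> GeneScore:
    """Signed significance score for one DE record.

    ``score = sign(log2_fc) * -log10(adj_p_value)``; an adjusted p of 0 is
    capped at the smallest positive normal double before the log, giving a
    finite score of about 307.65.
    """
    adj = max(record.adj_p_value, sys.float_info.min)
    magnitude = -np.log10(adj)
    return GeneScore(record.gene_id, float(np.sign(record.log2_fc) * magnitude))


def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`gene_score` over a DE table.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``gene``, ``log2_fc``, ``adj_p_value`` (extra columns kept).

    Returns
    -------
    pandas.DataFrame with columns ``gene`` and ``score``.
    """
    _check_unique_genes(table)
    adj = np.maximum(table["adj_p_value"].to_numpy(dtype=float), sys.float_info.min)
    score = np.sign(table["log2_fc"].to_numpy(dtype=float)) * (-np.log10(adj))
    return pd.DataFrame({"gene": table["gene"].to_numpy(), "score": score})


def call_differential(
    table: pd.DataFrame,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> dict[str, set[str]]:
    """Partition genes into ``up``, ``down`` and ``unchanged`` sets.

    ``up``: ``log2_fc > fc_threshold`` and ``adj_p_value < q_threshold``;
    ``down`` symmetric. Both inequalities are strict, matching the
    published thresholds (fold-change > 1, adjusted p < 0.05) as printed.
    """
    if fc_threshold <= 0 or q_threshold <= 0:
        raise ValueError("thresholds must be positive")
    _check_unique_genes(table)
    fc = table["log2_fc"].to_numpy(dtype=float)
    q = table["adj_p_value"].to_numpy(dtype=float)
    genes = table["gene"].to_numpy()
    sig = q < q_threshold
    up = set(genes[(fc > fc_threshold) & sig])
    down = set(genes[(fc < -fc_threshold) & sig])
    unchanged = set(genes) - up - down
    return {"up": up, "down": down, "unchanged": unchanged}


def rank_genes(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by descending score; ties broken lexicographically by gene.

    Accepts and returns a DataFrame with columns ``gene`` and ``score``.
    The output is independent of input order.
    """
    _check_unique_genes(scores)
    out = scores.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out[["gene", "score"]]


def map_homologs(
    scores: pd.DataFrame, mapping: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Translate gene identifiers (e.g. mouse to human) through a 2-column map.

    Genes absent from the mapping are dropped and counted. A source gene
    mapping to several targets emits one row per target (flagged in the
    report). When several source genes collapse onto one target, the entry
    with the largest absolute score wins.

    Parameters
    ----------
    scores : DataFrame with columns ``gene``, ``score``.
    mapping : DataFrame with columns ``source``, ``target``.

    Returns
    -------
    (translated scores DataFrame, report dict with keys ``n_input``,
    ``n_dropped``, ``n_one_to_many``, ``n_collisions``)
    """
    if mapping.columns.size < 2:
        raise ValueError("mapping must have two columns: source, target")
    mapping = mapping.rename(
        columns={mapping.columns[0]: "source", mapping.columns[1]: "target"}
    )
    _check_unique_genes(scores)
    merged = scores.merge(mapping, left_on="gene", right_on="source", how="left")
    dropped = merged["target"].isna()
    kept = merged.loc[~dropped]
    multi = int((kept.groupby("source")["target"].transform("size") > 1).sum())
    # many-to-one: keep the row with the largest |score| per target
    kept = kept.assign(_abs=kept["score"].abs())
    kept = kept.sort_values(["target", "_abs"], ascending=[True, False], kind="stable")
    n_before = len(kept)
    kept = kept.drop_duplicates("target", keep="first")
    report = {
        "n_input": len(scores),
        "n_dropped": int(dropped.sum()),
        "n_one_to_many": multi,
        "n_collisions": n_before - len(kept),
    }
    out = kept[["target", "score"]].rename(columns={"target": "gene"})
    return out.reset_index(drop=True), report


def read_de_table(path) -> pd.DataFrame:
    """Read a TSV DE table with header gene, log2_fc, p_value, adj_p_value."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene", "log2_fc", "p_value", "adj_p_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table {path} lacks columns: {sorted(missing)}")
    _check_unique_genes(table)
    return table


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)


def _check_unique_genes(table: pd.DataFrame) -> None:
    col = "gene" if "gene" in table.columns else table.columns[0]
    dup = table[col][table[col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene identifiers: {sorted(set(dup))[:5]}")
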