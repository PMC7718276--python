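"""Gene-set enrichment statistics: pre-ranked GSEA, ssGSEA, overlaps.

Pre-ranked GSEA is the classic weighted Kolmogorov-Smirnov running sum:
walking down the ranked list, set members add ``|score|^weight``
(normalised by the in-set total) and non-members subtract ``1/(N - Nh)``;
the enrichment score (ES) is the signed maximum deviation. The null is a
gene-label permutation (the ranked lists here come from full-cohort
statistics, so phenotype permutation does not apply); the NES divides the
ES by the mean magnitude of same-sign null scores.

ssGSEA computes per-sample scores as the integrated difference between a
rank-weighted (``rank^alpha``, alpha = 0.25) in-set ECDF and the
unweighted out-of-set ECDF, optionally min-max normalised across the
whole result matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "preranked_gsea",
    "preranked_gsea_collection",
    "ssgsea",
    "prep_expression",
    "hypergeometric_overlap",
    "pearson_correlation",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    n_hits: int


def _running_sum_es(abs_scores: np.ndarray, hit: np.ndarray, weight: float) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    ``abs_scores``: |score| per ranked position (descending ranking);
    ``hit``: boolean membership per position.
    """
    n = abs_scores.size
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit a non-empty strict subset of the ranking")
    w = abs_scores**weight if weight != 0 else np.ones(n)
    hit_weight = np.where(hit, w, 0.0)
    total = hit_weight.sum()
    if total == 0:  # all in-set scores are exactly zero: fall back to flat weights
        hit_weight = hit.astype(float)
        total = float(nh)
    steps = hit_weight / total - (~hit) / (n - nh)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _null_es(
    abs_scores: np.ndarray, nh: int, weight: float, n_perm: int, rng
) -> np.ndarray:
    """Gene-label permutation null: ES for n_perm random hit placements."""
    n = abs_scores.size
    w = abs_scores**weight if weight != 0 else np.ones(n)
    # random Nh hit positions per permutation, vectorised across permutations
    u = rng.random((n_perm, n))
    hit_idx = np.argpartition(u, nh - 1, axis=1)[:, :nh]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, hit_idx, True, axis=1)
    hit_w = np.where(hits, w, 0.0)
    totals = hit_w.sum(axis=1, keepdims=True)
    flat = totals[:, 0] == 0
    if flat.any():
        hit_w[flat] = hits[flat].astype(float)
        totals[flat] = nh
    steps = hit_w / totals - (~hits) / (n - nh)
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def _p_and_nes(es: float, null: np.ndarray) -> tuple[float, float]:
    same_sign = null[null >= 0] if es >= 0 else null[null < 0]
    if same_sign.size == 0:
        warnings.warn("no same-sign null ES; NES and p reported as NaN")
        return float("nan"), float("nan")
    p = float(np.mean(np.abs(same_sign) >= abs(es)))
    nes = float(es / np.mean(np.abs(same_sign)))
    return p, nes


def preranked_gsea(
    ranked: pd.DataFrame,
    gene_set: GeneSet,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
) -> EnrichmentResult:
    """Pre-ranked GSEA of one gene set against a ranked score table.

    Parameters
    ----------
    ranked : DataFrame with columns ``gene``, ``score``, already sorted
        descending (see :func:`mraxis.de.rank_genes`).
    gene_set : the set to test; must overlap the ranking and not cover it.
    n_perm : gene-label permutations for the null.
    weight : running-sum exponent on |score| (1 = classic weighted KS).
    seed : permutation RNG seed.

    For a single set the FDR q equals the nominal permutation p; use
    :func:`preranked_gsea_collection` for the cross-set NES-based FDR.
    """
    genes = ranked["gene"].to_numpy()
    abs_scores = np.abs(ranked["score"].to_numpy(dtype=float))
    hit = np.isin(genes, list(gene_set.genes))
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the ranking")
    if nh == genes.size:
        raise ValueError(f"gene set {gene_set.name!r} covers the whole ranking")
    es = _running_sum_es(abs_scores, hit, weight)
    rng = np.random.default_rng(seed)
    null = _null_es(abs_scores, nh, weight, n_perm, rng)
    p, nes = _p_and_nes(es, null)
    return EnrichmentResult(gene_set.name, es, nes, p, p, nh)


def preranked_gsea_collection(
    ranked: pd.DataFrame,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
    fdr_method: str = "nes",
) -> pd.DataFrame:
    """Pre-ranked GSEA over a collection, with cross-set FDR.

    ``fdr_method='nes'`` uses the standard GSEA procedure comparing each
    observed NES against the pooled same-sign null NES distribution;
    ``'bh'`` applies Benjamini-Hochberg to the nominal p-values. Sets with
    no overlap or full coverage are skipped with a warning.
    """
    genes = ranked["gene"].to_numpy()
    abs_scores = np.abs(ranked["score"].to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    rows, null_nes_pool = [], []
    for gs in gene_sets:
        hit = np.isin(genes, list(gs.genes))
        nh = int(hit.sum())
        if nh == 0 or nh == genes.size:
            warnings.warn(f"skipping degenerate gene set {gs.name!r}")
            continue
        es = _running_sum_es(abs_scores, hit, weight)
        null = _null_es(abs_scores, nh, weight, n_perm, rng)
        p, nes = _p_and_nes(es, null)
        pos, neg = null[null >= 0], null[null < 0]
        if pos.size:
            null_nes_pool.append(pos / np.mean(pos))
        if neg.size:
            null_nes_pool.append(neg / np.mean(np.abs(neg)))
        rows.append({"set": gs.name, "es": es, "nes": nes, "p": p, "n_hits": nh})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(fdr=[])
    if fdr_method == "bh":
        from .de import benjamini_hochberg

        out["fdr"] = benjamini_hochberg(out["p"].fillna(1.0).to_numpy())
    elif fdr_method == "nes":
        pool = np.concatenate(null_nes_pool)
        obs = out["nes"].to_numpy()
        fdr = np.full(obs.size, np.nan)
        for i, v in enumerate(obs):
            if np.isnan(v):
                continue
            if v >= 0:
                num = np.mean(pool[pool >= 0] >= v) if (pool >= 0).any() else 1.0
                den = np.mean(obs[~np.isnan(obs) & (obs >= 0)] >= v)
            else:
                num = np.mean(pool[pool < 0] <= v) if (pool < 0).any() else 1.0
                den = np.mean(obs[~np.isnan(obs) & (obs < 0)] <= v)
            fdr[i] = min(1.0, num / den) if den > 0 else 1.0
        out["fdr"] = fdr
    else:
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    return out[["set", "es", "nes", "p", "fdr", "n_hits"]]


def ssgsea(
    expr: pd.DataFrame,
    sets: dict[str, set[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample GSEA scores for every (sample, gene set) pair.

    Per sample, genes are ranked by expression (rank N = most expressed;
    ties broken deterministically by row order) and the score is the sum
    over list positions of the difference between the ``rank^alpha``-
    weighted in-set ECDF and the unweighted out-of-set ECDF. Sets with
    fewer than 2 matrix genes are skipped with a warning. With
    ``normalize=True`` all scores are divided by the overall max-min
    range, putting them on a comparable cross-sample scale.

    Returns a tidy DataFrame ``sample  set  es``.
    """
    n_genes = expr.shape[0]
    gene_index = {g: i for i, g in enumerate(expr.index)}
    rows = []
    memberships = {}
    for name, genes in sets.items():
        idx = np.array(sorted(gene_index[g] for g in genes if g in gene_index))
        if idx.size < 2:
            warnings.warn(f"gene set {name!r} has < 2 genes in the matrix; skipped")
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        memberships[name] = mask
    for sample in expr.columns:
        values = expr[sample].to_numpy(dtype=float)
        order = np.argsort(-values, kind="stable")  # descending
        rank_value = n_genes - np.arange(n_genes)  # N at the top, 1 at the bottom
        weights = rank_value.astype(float) ** alpha
        for name, mask in memberships.items():
            hit = mask[order]
            in_w = np.where(hit, weights, 0.0)
            p_in = np.cumsum(in_w) / in_w.sum()
            p_out = np.cumsum(~hit) / (n_genes - hit.sum())
            rows.append({"sample": sample, "set": name, "es": float(np.sum(p_in - p_out))})
    out = pd.DataFrame(rows)
    if normalize and not out.empty:
        span = out["es"].max() - out["es"].min()
        if span > 0:
            out["es"] = out["es"] / span
    return out


def prep_expression(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Filter an FPKM-like matrix for ssGSEA.

    Drops genes with row mean < 1; among rows sharing a gene name keeps
    the one with the largest total expression. Values must be
    non-negative.
    """
    if (fpkm.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    keep = fpkm[fpkm.mean(axis=1) >= 1.0]
    totals = keep.sum(axis=1)
    best = (
        pd.DataFrame({"gene": keep.index, "total": totals.to_numpy()})
        .reset_index(drop=True)
        .sort_values("total", ascending=False, kind="stable")
        .drop_duplicates("gene", keep="first")
        .index
    )
    out = keep.iloc[sorted(best)]
    return out


def hypergeometric_overlap(set_a: set, set_b: set, universe: set) -> float:
    """Upper-tail hypergeometric p-value of the overlap of two gene sets.

    ``P(X >= |A ∩ B|)`` drawing ``|B|`` genes from ``|universe|`` with
    ``|A|`` successes; symmetric in A and B.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b))
    return float(min(p, 1.0))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must share a length of at least 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
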