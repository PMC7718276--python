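"""Synthetic inputs with the statistical structure the analyses assume.

Every downstream stage — gene scoring, master-regulator inference, GSEA,
variant filtering, TSS profiling — can be exercised end-to-end without
external downloads by generating:

* a random TF-DNA / protein-interaction network and a differential-
  expression table with one *planted* active TF whose depth-≤3
  subnetwork genes carry shifted scores (geometrically attenuated with
  depth),
* multi-sample FPKM-like expression matrices with one gene set shifted
  in the second group,
* paired-caller, multi-normal somatic call sets containing shared true
  somatic variants, caller-specific false positives and blacklisted
  strain polymorphisms (emulating the unmatched outbred-normal design),
* coverage tracks with promoter-localised depletion over a chosen gene
  set, plus the matching gene annotation.

All generators are pure functions of their configuration: a single
global seed expands into independent per-component substreams through
``numpy.random.SeedSequence`` spawn keys, so adding one generator never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import benjamini_hochberg
from .network import RegulatoryEdge, build_subnetwork
from .variants import VariantRecord

__all__ = [
    "NetworkSimConfig",
    "PlantConfig",
    "VariantSimConfig",
    "simulate_network",
    "plant_regulator",
    "simulate_expression_matrix",
    "simulate_variant_calls",
    "random_gene_annotation",
    "simulate_coverage",
]

# stable substream ids; appending new components keeps existing streams intact
_COMPONENTS = {
    "network": 1,
    "plant": 2,
    "expression": 3,
    "variants": 4,
    "coverage": 5,
    "genes": 6,
}

CALLERS = ("varscan", "mutect2")
_BASES = np.array(list("ACGT"))


def substream(seed: int, component: str) -> np.random.Generator:
    """Independent RNG substream for one generator component."""
    key = _COMPONENTS[component]
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid configuration field {name!r}: {msg}")


@dataclass(frozen=True)
class NetworkSimConfig:
    """Shape of the simulated regulatory network.

    Out-degrees are Poisson; TF-DNA targets are drawn from all other
    nodes (so TF→TF edges create depth-2/3 structure), PPI partners from
    the other TFs. Edge confidences are uniform in ``confidence_range``.
    """

    n_tfs: int = 50
    n_target_genes: int = 1000
    tf_dna_out_degree_mean: float = 20.0
    ppi_degree_mean: float = 5.0
    confidence_range: tuple[float, float] = (0.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_tfs >= 1, "n_tfs", "must be >= 1")
        _require(
            self.n_target_genes >= self.n_tfs,
            "n_target_genes",
            "must be >= n_tfs",
        )
        _require(
            self.tf_dna_out_degree_mean > 0,
            "tf_dna_out_degree_mean",
            "must be positive",
        )
        _require(self.ppi_degree_mean > 0, "ppi_degree_mean", "must be positive")
        lo, hi = self.confidence_range
        _require(
            0 < lo <= hi <= 1, "confidence_range", "needs 0 < low <= high <= 1"
        )

    def tf_names(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tfs + 1)]

    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_target_genes + 1)]


@dataclass(frozen=True)
class PlantConfig:
    """The planted active regulator.

    ``effect_mean`` shifts the score-generating normal for genes in the
    planted TF's depth-≤3 subnetwork, attenuated by ``depth_decay**(D-1)``.
    """

    planted_tf: str
    effect_mean: float = 2.0
    noise_sd: float = 1.0
    depth_decay: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.noise_sd > 0, "noise_sd", "must be positive")
        _require(0 < self.depth_decay <= 1, "depth_decay", "must lie in (0, 1]")


@dataclass(frozen=True)
class VariantSimConfig:
    """Paired-caller, multi-normal somatic call-set simulation."""

    n_true_somatic: int = 50
    n_fp_per_caller: int = 30
    n_strain_variants: int = 20
    n_normals: int = 3
    vaf_true: float = 0.35
    coverage_mean: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_true_somatic", "n_fp_per_caller", "n_strain_variants"):
            _require(getattr(self, f) >= 0, f, "must be >= 0")
        _require(self.n_normals >= 1, "n_normals", "must be >= 1")
        _require(0 < self.vaf_true < 1, "vaf_true", "must lie in (0, 1)")
        _require(self.coverage_mean > 0, "coverage_mean", "must be positive")


def simulate_network(config: NetworkSimConfig) -> list[RegulatoryEdge]:
    """Random TF-DNA + PPI edge list; deterministic given the config seed."""
    rng = substream(config.seed, "network")
    tfs = config.tf_names()
    genes = config.gene_names()
    nodes = np.array(tfs + genes)
    lo, hi = config.confidence_range
    edges: list[RegulatoryEdge] = []
    for tf in tfs:
        pool = nodes[nodes != tf]
        k = min(int(rng.poisson(config.tf_dna_out_degree_mean)), pool.size)
        targets = rng.choice(pool, size=k, replace=False)
        confs = rng.uniform(lo, hi, size=k)
        for t, c in zip(targets, confs):
            edges.append(RegulatoryEdge(tf, str(t), "tf_dna", float(c)))
    # undirected PPI among TFs: each TF proposes ~half the target degree
    if len(tfs) > 1:
        seen = set()
        tf_arr = np.array(tfs)
        for tf in tfs:
            pool = tf_arr[tf_arr != tf]
            k = min(int(rng.poisson(config.ppi_degree_mean / 2.0)), pool.size)
            partners = rng.choice(pool, size=k, replace=False)
            confs = rng.uniform(lo, hi, size=k)
            for p, c in zip(partners, confs):
                pair = tuple(sorted((tf, str(p))))
                if pair in seen:
                    continue
                seen.add(pair)
                edges.append(RegulatoryEdge(pair[0], pair[1], "ppi", float(c)))
                edges.append(RegulatoryEdge(pair[1], pair[0], "ppi", float(c)))
    return edges


def plant_regulator(
    edges: list[RegulatoryEdge], plant: PlantConfig
) -> tuple[pd.DataFrame, dict]:
    """Differential-expression table with the planted TF's subnetwork shifted.

    Every network node g receives ``z ~ Normal(mu_g, noise_sd)`` with
    ``mu_g = effect_mean * depth_decay**(D-1)`` for members of the
    planted TF's depth-≤3 *regulatory* (tf_dna) subnetwork and 0
    otherwise; ``log2_fc = z``, ``p`` is the two-sided normal tail of
    ``z / noise_sd`` and ``adj_p`` the BH adjustment.

    The effect deliberately propagates through directed TF→target edges
    only: a transcription factor's activity shifts its transcriptional
    targets and targets-of-target-TFs. Propagating through PPI edges
    would shift the direct-target programs of the planted TF's protein
    partners, i.e. activate those partners as regulators in their own
    right and invalidate the single-TF truth record. PPI edges still
    participate on the detection side (the combined-network sub-score).

    Returns the DE table and a truth record with the planted TF and its
    member depths.
    """
    sources = {e.source for e in edges if e.kind == "tf_dna"}
    if plant.planted_tf not in sources:
        raise KeyError(f"planted TF {plant.planted_tf!r} sources no tf_dna edge")
    sub = build_subnetwork(plant.planted_tf, edges, max_depth=3, kinds=("tf_dna",))
    depth = {n.gene_id: n.distance for n in sub.nodes}
    universe = sorted({e.source for e in edges} | {e.target for e in edges})
    rng = substream(plant.seed, "plant")
    mu = np.array(
        [
            plant.effect_mean * plant.depth_decay ** (depth[g] - 1)
            if g in depth
            else 0.0
            for g in universe
        ]
    )
    z = rng.normal(mu, plant.noise_sd)
    p = 2.0 * stats.norm.sf(np.abs(z) / plant.noise_sd)
    adj = benjamini_hochberg(p)
    table = pd.DataFrame(
        {"gene": universe, "log2_fc": z, "p_value": p, "adj_p_value": adj}
    )
    truth = {"planted_tf": plant.planted_tf, "member_depths": depth}
    return table, truth


def simulate_expression_matrix(
    n_samples_per_group: int,
    gene_sets: dict[str, set[str]],
    shifted_set: str,
    shift: float,
    seed: int = 0,
    n_background_genes: int = 500,
    sample_noise_sd: float = 0.25,
) -> pd.DataFrame:
    """FPKM-like matrix with one gene set up-shifted in the second group.

    Per-gene baselines are log-normal (meanlog 1, sdlog 1); per-sample
    values multiply the baseline by log-normal noise; genes of
    ``shifted_set`` are multiplied by ``2**shift`` in group 2. Columns
    are ``grp1_i`` / ``grp2_i``.
    """
    if shifted_set not in gene_sets:
        raise KeyError(f"unknown gene set {shifted_set!r}")
    rng = substream(seed, "expression")
    set_genes = sorted(set().union(*gene_sets.values()))
    background = [f"BG{i:05d}" for i in range(1, n_background_genes + 1)]
    genes = set_genes + background
    baseline = rng.lognormal(mean=1.0, sigma=1.0, size=len(genes))
    cols = [f"grp1_{i}" for i in range(1, n_samples_per_group + 1)] + [
        f"grp2_{i}" for i in range(1, n_samples_per_group + 1)
    ]
    noise = rng.lognormal(0.0, sample_noise_sd, size=(len(genes), len(cols)))
    mat = baseline[:, None] * noise
    shifted = np.isin(genes, sorted(gene_sets[shifted_set]))
    mat[np.ix_(shifted, np.arange(n_samples_per_group, 2 * n_samples_per_group))] *= (
        2.0**shift
    )
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=cols)


def _random_sites(rng, n: int, occupied: set[int]) -> list[tuple[int, str, str]]:
    """n unique SNV sites (pos, ref, alt) on one contig, avoiding occupied."""
    sites = []
    while len(sites) < n:
        pos = int(rng.integers(1, 10_000_000))
        if pos in occupied:
            continue
        occupied.add(pos)
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append((pos, str(_BASES[ref]), str(_BASES[alt])))
    return sites


def simulate_variant_calls(
    config: VariantSimConfig,
) -> tuple[dict, set, set]:
    """Per-(caller, normal) call sets, strain blacklist and somatic truth.

    True somatics appear in both callers against every normal (tumour
    VAF binomially sampled around ``vaf_true``, normal VAF 0);
    caller-specific false positives appear in exactly one caller; strain
    polymorphisms appear everywhere but are listed in the blacklist.
    Depths are Poisson around ``coverage_mean``.

    Returns ``(calls, blacklist_keys, truth_keys)`` where ``calls`` maps
    ``(caller, normal_id)`` to a list of VariantRecords.
    """
    rng = substream(config.seed, "variants")
    occupied: set[int] = set()
    true_sites = _random_sites(rng, config.n_true_somatic, occupied)
    strain_sites = _random_sites(rng, config.n_strain_variants, occupied)
    fp_sites = {
        caller: _random_sites(rng, config.n_fp_per_caller, occupied)
        for caller in CALLERS
    }
    normals = [f"normal{i}" for i in range(1, config.n_normals + 1)]
    effects = np.array(["missense", "nonsense", "frameshift", "splice_site", "other"])

    def record(pos, ref, alt, t_vaf_target, n_vaf, caller, gene):
        t_dp = max(int(rng.poisson(config.coverage_mean)), 1)
        n_dp = max(int(rng.poisson(config.coverage_mean)), 1)
        t_vaf = rng.binomial(t_dp, t_vaf_target) / t_dp if t_vaf_target > 0 else 0.0
        return VariantRecord(
            chrom="chr1",
            pos=pos,
            ref=ref,
            alt=alt,
            tumour_depth=t_dp,
            tumour_vaf=float(t_vaf),
            normal_depth=n_dp,
            normal_vaf=float(n_vaf),
            effect=str(rng.choice(effects)),
            gene=f"GV{pos % 997:03d}",
            caller=caller,
        )

    calls: dict[tuple[str, str], list[VariantRecord]] = {}
    for caller in CALLERS:
        for normal in normals:
            recs = []
            for pos, ref, alt in true_sites:
                recs.append(record(pos, ref, alt, config.vaf_true, 0.0, caller, ""))
            for pos, ref, alt in strain_sites:
                recs.append(record(pos, ref, alt, 0.5, 0.0, caller, ""))
            for pos, ref, alt in fp_sites[caller]:
                recs.append(record(pos, ref, alt, 0.1, 0.0, caller, ""))
            calls[(caller, normal)] = recs
    blacklist = {("chr1", pos, ref, alt) for pos, ref, alt in strain_sites}
    truth = {("chr1", pos, ref, alt) for pos, ref, alt in true_sites}
    return calls, blacklist, truth


def random_gene_annotation(
    n_genes: int = 40,
    gene_length: int = 5000,
    spacing: int = 40_000,
    chrom: str = "chr1",
    seed: int = 0,
) -> pd.DataFrame:
    """Evenly spaced non-overlapping BED6 genes with random strands."""
    rng = substream(seed, "genes")
    starts = 20_000 + spacing * np.arange(n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + gene_length,
            "name": [f"G{i:05d}" for i in range(1, n_genes + 1)],
            "score": 0,
            "strand": strands,
        }
    )


def simulate_coverage(
    genes: pd.DataFrame,
    depleted_set,
    depletion_factor: float,
    flank: int = 1000,
    baseline: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """bedGraph track with promoter-localised depletion over ``depleted_set``.

    Coverage is ``baseline`` everywhere except the strand-aware promoter
    windows [TSS - flank, TSS + flank) of the depleted genes, where it is
    multiplied by ``depletion_factor`` (in [0, 1); 0 silences the
    promoter completely — the synthetic analogue of losing a repressive
    mark would invert the factor).
    """
    if not 0 <= depletion_factor < 1:
        raise ValueError("depletion_factor must lie in [0, 1)")
    names = set(genes["name"])
    unknown = set(depleted_set) - names
    if unknown:
        raise KeyError(f"depleted genes absent from annotation: {sorted(unknown)[:5]}")
    rows = []
    for chrom, sub in genes.groupby("chrom", sort=False):
        span_end = int(sub["end"].max()) + 2 * flank + 20_000
        dep = sub[sub["name"].isin(set(depleted_set))]
        promoters = []
        for r in dep.itertuples(index=False):
            tss = r.start if r.strand == "+" else r.end
            promoters.append((max(tss - flank, 0), min(tss + flank, span_end)))
        promoters.sort()
        merged: list[list[int]] = []
        for lo, hi in promoters:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        cursor = 0
        for lo, hi in merged:
            if lo > cursor:
                rows.append((chrom, cursor, lo, baseline))
            rows.append((chrom, lo, hi, baseline * depletion_factor))
            cursor = hi
        if cursor < span_end:
            rows.append((chrom, cursor, span_end, baseline))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
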