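"""Somatic-variant consensus filtering and pathway mutant classification.

Post-caller filtering for tumour/normal exome designs:

* two-caller consensus (a variant must be reported by both callers),
* the unmatched-tumour rule — a variant is retained only when both
  callers report it against *every* available normal and it is absent
  from a strain-polymorphism blacklist (used when no matched normal
  exists, e.g. outbred-strain tumours),
* depth/VAF gates (tumour and normal depth > 10x, tumour VAF >= 0.05,
  normal VAF <= 0.01), and
* three-state pathway classification (mutant / wild_type /
  indeterminate) combining protein-altering SNVs/indels (VAF > 0.2,
  depth > 20) with copy-number amplifications (>= 5 copies) and
  homozygous deletions.

Variant identity is the normalised (chrom, pos, ref, alt) key: shared
suffix then prefix bases are trimmed so equivalent indel representations
intersect correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "VariantRecord",
    "CNASegment",
    "FilterConfig",
    "PathwayCall",
    "normalize_variant",
    "consensus_variants",
    "unmatched_consensus",
    "somatic_filter",
    "classify_pathway_status",
    "read_vcf",
    "write_vcf",
]

DAMAGING_EFFECTS = frozenset({"missense", "frameshift", "nonsense", "splice_site"})
EFFECTS = DAMAGING_EFFECTS | {"synonymous", "other"}


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumour_depth: int = 0
    tumour_vaf: float = 0.0
    normal_depth: int = 0
    normal_vaf: float = 0.0
    effect: str = "other"
    gene: str = ""
    caller: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        for f in ("tumour_vaf", "normal_vaf"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1], got {v}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CNASegment:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    copy_number: int
    gene_overlaps: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment must satisfy start < end")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass(frozen=True)
class FilterConfig:
    """Published filtering thresholds (strict inequalities where noted)."""

    min_coverage: int = 10  # strict >, tumour and normal
    min_tumour_vaf: float = 0.05  # inclusive >=
    max_normal_vaf: float = 0.01  # inclusive <=
    pathway_min_vaf: float = 0.2  # strict >
    pathway_min_coverage: int = 20  # strict >
    amplification_copies: int = 5  # >= counts as amplified
    deletion_copies: int = 0  # == counts as homozygous deletion
    neutral_copies: int = 2

    def __post_init__(self) -> None:
        if self.min_tumour_vaf <= self.max_normal_vaf:
            raise ValueError("min_tumour_vaf must exceed max_normal_vaf")
        for f in ("min_coverage", "pathway_min_coverage", "amplification_copies"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass(frozen=True)
class PathwayCall:
    sample_id: str
    pathway: str
    status: str  # mutant | wild_type | indeterminate
    evidence: tuple = ()


def normalize_variant(v: VariantRecord) -> VariantRecord:
    """Minimal left-aligned representation: trim shared suffix, then prefix."""
    ref, alt, pos = v.ref, v.alt, v.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (v.ref, v.alt, v.pos):
        return v
    return replace(v, ref=ref, alt=alt, pos=pos)


def consensus_variants(calls_a, calls_b) -> list[VariantRecord]:
    """Variants reported by both callers, keyed on normalised chrom/pos/ref/alt.

    Record fields (depths, VAFs, annotations) are taken from caller A; the
    caller field is set to ``consensus``.
    """
    a = {normalize_variant(v).key: normalize_variant(v) for v in calls_a}
    b_keys = {normalize_variant(v).key for v in calls_b}
    return [
        replace(v, caller="consensus")
        for key, v in sorted(a.items())
        if key in b_keys
    ]


def unmatched_consensus(calls, blacklist) -> list[VariantRecord]:
    """Consensus filter for tumours without a matched normal.

    Parameters
    ----------
    calls : mapping (caller, normal) -> iterable of VariantRecord.
        Every caller must have been run against every normal; a missing
        combination raises with the missing pairs listed.
    blacklist : set of (chrom, pos, ref, alt) strain-polymorphism keys.

    Keeps variants present in *every* (caller, normal) call set and
    absent from the blacklist. Returned records carry caller
    ``consensus`` with fields from the first (caller, normal) pairing.
    """
    if not calls:
        raise ValueError("no call sets supplied")
    callers = sorted({c for c, _ in calls})
    normals = sorted({n for _, n in calls})
    if len(callers) < 2:
        raise ValueError(f"unmatched consensus requires >= 2 callers, got {callers}")
    missing = [(c, n) for c in callers for n in normals if (c, n) not in calls]
    if missing:
        raise ValueError(f"missing caller/normal call sets: {missing}")
    normalized = {
        pair: {normalize_variant(v).key: normalize_variant(v) for v in vs}
        for pair, vs in calls.items()
    }
    first = normalized[(callers[0], normals[0])]
    shared = set(first)
    for pair in normalized:
        shared &= set(normalized[pair])
    shared -= set(blacklist)
    return [replace(first[k], caller="consensus") for k in sorted(shared)]


def somatic_filter(variants, config: FilterConfig = FilterConfig()) -> list[VariantRecord]:
    """Depth and allele-frequency gates on annotated variants.

    Keeps variants with tumour and normal depth strictly above
    ``min_coverage``, tumour VAF >= ``min_tumour_vaf`` and normal VAF <=
    ``max_normal_vaf``.
    """
    kept = []
    for v in variants:
        if v.tumour_depth is None or v.normal_depth is None:
            raise ValueError(f"variant {v.chrom}:{v.pos} lacks depth annotation")
        if (
            v.tumour_depth > config.min_coverage
            and v.normal_depth > config.min_coverage
            and v.tumour_vaf >= config.min_tumour_vaf
            and v.normal_vaf <= config.max_normal_vaf
        ):
            kept.append(v)
    return kept


def classify_pathway_status(
    variants,
    cna_segments,
    pathway_genes: set[str],
    config: FilterConfig = FilterConfig(),
    sample_id: str = "",
    pathway: str = "",
    annotated_genes: set[str] | None = None,
) -> PathwayCall:
    """Three-state pathway mutant classification for one sample.

    mutant: any pathway gene carries a protein-altering SNV/indel
    (missense, frameshift, nonsense or splice_site) with tumour VAF >
    ``pathway_min_vaf`` and depth > ``pathway_min_coverage``, OR overlaps
    a copy-number segment with >= ``amplification_copies`` copies or a
    homozygous deletion. wild_type: every pathway gene is free of
    SNVs/indels of any effect and of copy-number change. Anything in
    between (e.g. a sub-threshold or synonymous variant only) is
    indeterminate.
    """
    if not pathway_genes:
        raise ValueError("pathway_genes must be non-empty")
    if annotated_genes is not None:
        unknown = pathway_genes - annotated_genes
        if unknown:
            warnings.warn(
                f"pathway genes absent from annotation, treated as no-evidence: "
                f"{sorted(unknown)[:5]}"
            )
            pathway_genes = pathway_genes & annotated_genes
    evidence = []
    any_variant = False
    for v in variants:
        if v.gene not in pathway_genes:
            continue
        any_variant = True
        if (
            v.effect in DAMAGING_EFFECTS
            and v.tumour_vaf > config.pathway_min_vaf
            and v.tumour_depth > config.pathway_min_coverage
        ):
            evidence.append(v)
    any_cna = False
    for seg in cna_segments:
        overlap = set(seg.gene_overlaps) & pathway_genes
        if not overlap:
            continue
        if seg.copy_number != config.neutral_copies:
            any_cna = True
        if (
            seg.copy_number >= config.amplification_copies
            or seg.copy_number == config.deletion_copies
        ):
            evidence.append(seg)
    if evidence:
        status = "mutant"
    elif not any_variant and not any_cna:
        status = "wild_type"
    else:
        status = "indeterminate"
    return PathwayCall(sample_id, pathway, status, tuple(evidence))


# ---------------------------------------------------------------------------
# VCF v4.2 I/O (two samples TUMOR / NORMAL, FORMAT fields DP and AF)

_EFFECT_INFO = "EFF"
_GENE_INFO = "GENE"


def write_vcf(variants, path) -> None:
    """Write VariantRecords as an uncompressed two-sample VCF v4.2."""
    import pysam

    header = pysam.VariantHeader()
    contigs = sorted({v.chrom for v in variants})
    for c in contigs:
        header.contigs.add(c)
    header.info.add(_GENE_INFO, 1, "String", "Annotated gene symbol")
    header.info.add(_EFFECT_INFO, 1, "String", "Coding effect class")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AF", 1, "Float", "Variant allele frequency")
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: x.key):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
            )
            rec.info[_GENE_INFO] = v.gene or "."
            rec.info[_EFFECT_INFO] = v.effect
            rec.samples["TUMOR"]["DP"] = v.tumour_depth
            rec.samples["TUMOR"]["AF"] = v.tumour_vaf
            rec.samples["NORMAL"]["DP"] = v.normal_depth
            rec.samples["NORMAL"]["AF"] = v.normal_vaf
            out.write(rec)


def _sample_dp_af(sample) -> tuple[int, float]:
    dp = sample.get("DP")
    af = sample.get("AF")
    if af is None:
        ad = sample.get("AD")
        if ad is None or dp in (None, 0):
            raise ValueError("sample lacks AF and cannot derive it from AD/DP")
        af = ad[1] / dp
    if isinstance(af, tuple):
        af = af[0]
    return int(dp or 0), float(af)


def read_vcf(path, caller: str = "") -> list[VariantRecord]:
    """Read a two-sample (TUMOR/NORMAL) VCF into VariantRecords.

    AF is taken from the per-sample FORMAT field, or derived from AD when
    only allele depths are present.
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if "TUMOR" not in samples:
            raise ValueError(f"{path}: expected a TUMOR sample, found {samples}")
        has_normal = "NORMAL" in samples
        for rec in vcf:
            t_dp, t_af = _sample_dp_af(rec.samples["TUMOR"])
            n_dp, n_af = _sample_dp_af(rec.samples["NORMAL"]) if has_normal else (0, 0.0)
            gene = rec.info.get(_GENE_INFO, ".")
            effect = rec.info.get(_EFFECT_INFO, "other")
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    tumour_depth=t_dp,
                    tumour_vaf=t_af,
                    normal_depth=n_dp,
                    normal_vaf=n_af,
                    effect=effect if effect in EFFECTS else "other",
                    gene="" if gene == "." else gene,
                    caller=caller,
                )
            )
    return records
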