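# Methods

This note records the exact computational definitions implemented in
`mraxis`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and known limitations. It makes no
empirical claims beyond what the test suite and
`scripts/acceptance.py` compute.

## 1. Differential-expression scoring

Each gene *g* with log2 fold-change `fc_g` and raw p-value `p_g` is
assigned the signed score

```
S_g = sign(fc_g) · (−log10 q_g)
```

where `q_g` is the Benjamini–Hochberg (BH) adjusted p-value. BH is the
classical step-up procedure, implemented directly (sorted `p·n/rank`
with a reverse cumulative minimum, clipped at 1); the test suite
cross-checks it element-wise against statsmodels' `fdr_bh` on random
vectors at 10⁻¹² tolerance. Reported `q = 0` (an underflowed
p-value) is capped at the smallest positive double, so the maximum
attainable score magnitude is `−log10(2.2e−308) ≈ 307.65` rather than
infinity.

A gene is called differential when **both** `|fc_g| > 1` **and**
`q_g < 0.05`, with strict inequalities: a gene sitting exactly on
either threshold is not called. Ranking of scored genes is by
descending `|S|` with ties broken by gene identifier, so output order
is deterministic.

Cross-species homolog mapping drops unmapped genes (counted in the
report), expands one-to-many mappings to all targets, and resolves
many-to-one collisions by keeping the source gene with the largest
absolute score.

## 2. Regulator network score

Edges are directed, typed (`tf_dna` regulatory binding or `ppi`
protein interaction) and carry a confidence in (0, 1]. For a root TF
*t*, a breadth-first traversal over the selected edge kinds assigns
each reachable gene (depth ≤ 3) a distance `D`, a single parent, and
that parent edge's confidence `S_n`. When several parents reach a gene
at the same minimal depth, the parent with the highest edge confidence
wins; remaining ties resolve to the lexicographically smallest parent
identifier, so the subnetwork is unique. Parallel edges keep the
maximum confidence. `L` is the parent's out-degree counted on the
**full** network (over the selected kinds), not on the extracted
subnetwork. The score is

```
N_t = Σ_{g ∈ subnetwork}  S_g · S_n(g) / ( D(g) · L(parent(g)) )
```

with `S_g = 0` for genes absent from the DE table. An `absolute` mode
substitutes `|S_g|`. The implementation is validated against an
independently coded brute-force oracle on hundreds of random graphs at
10⁻¹² tolerance.

Three sub-scores per TF:

* `m1` — `N_t` on the `tf_dna`-only network;
* `m2` — `N_t` on the combined `tf_dna` + `ppi` network;
* `m3` — `−log10` of the upper-tail hypergeometric p-value of the
  overlap between the TF's depth-1 `tf_dna` targets and the DE gene
  set, in the universe of all network genes.

Each sub-score is ranked descending (rank 1 = largest; average ranks
on ties); the aggregate statistic is the **sum of the three ranks**,
sorted ascending with ties broken by TF identifier. Rank aggregation
is deliberately scale-free: the three sub-scores live on incomparable
scales, and summing ranks avoids any weighting choice.

## 3. Enrichment analyses

**Pre-ranked GSEA.** For a ranked score table and a gene set of size
`N_h` in a list of `N` genes, the running sum increases by
`|S|^w / Σ_hits |S|^w` at each hit and decreases by `1/(N − N_h)` at
each miss (`w = 1` by default); the enrichment statistic ES is the
signed maximum deviation from zero. The null is **gene-label
permutation**: set membership is re-drawn uniformly `n_perm` times
(default 1000), implemented by ranking a random matrix so all
permutations are generated vectorised from one seeded generator.
`NES = ES / mean(|null ES of the same sign|)`, and the p-value is the
plain empirical fraction of same-sign null ES at least as extreme.
Across a collection, the false-discovery estimate follows the standard
NES-based procedure (pooled same-sign null NES), with plain BH across
sets available as an alternative. The running sum is validated against
a plain-loop oracle; calibration is validated by the measured type-I
error on null rankings (≈ 0.05).

Note that when a small permutation count yields no same-sign null ES,
NES and p are reported as NaN with a warning, rather than silently
substituting a value.

**Single-sample GSEA.** Genes are ranked per sample by descending
expression (rank `N` = most expressed), weighted `rank^α` with
`α = 0.25`; the score is the integrated difference between the
weighted in-set and unweighted out-of-set empirical distribution
functions, Σ(P_in − P_out). Optional normalisation divides all scores
by the overall max−min score range, making scores comparable across
sets. Expression preprocessing discards genes with mean abundance
< 1 and resolves duplicate gene rows by keeping the most-expressed
one.

**Set overlap.** Upper-tail hypergeometric probability
`P(X ≥ |A∩B|)` for two sets in a finite universe, computed with
scipy's hypergeometric survival function and validated by exhaustive
binomial-coefficient enumeration for every configuration with universe
≤ 12. Pearson correlation (scipy) is provided for signature-score
comparisons, requiring n ≥ 3 and non-degenerate variance.

## 4. Somatic-variant consensus and pathway status

Variants are first reduced to a minimal representation (trim shared
ref/alt suffix, then shared prefix, keeping at least one base and
advancing the 1-based position), so equivalent indel encodings from
different callers intersect correctly.

* **Two-caller consensus** keeps variants present in both call sets by
  `(chrom, pos, ref, alt)` key.
* **Unmatched-normal consensus** (for tumours without a matched
  normal): a variant is kept only if every (caller × normal) call set
  contains it, minus a strain-polymorphism blacklist. At least two
  callers are required, and a missing caller/normal combination is an
  error (listing the missing pairs), not a silent skip.
* **Somatic gates**: tumour and normal depth strictly > 10×, tumour
  VAF ≥ 0.05, normal VAF ≤ 0.01 (both inclusive).
* **Pathway status** is three-state. *Mutant*: a protein-altering
  variant (missense, nonsense, frameshift, splice site) in a pathway
  gene with VAF > 0.2 and depth > 20 (strict), or a copy-number
  segment overlapping a pathway gene with ≥ 5 copies or 0 copies.
  *Wild type*: no variant of any effect class and no non-neutral
  copy-number segment touching the pathway. Anything in between —
  e.g. a sub-threshold damaging variant, a synonymous variant, a
  3–4-copy gain — is *indeterminate* rather than being forced into
  either class.

VCF I/O uses pysam (VCFv4.2, two samples TUMOR/NORMAL with `DP` and
`AF` FORMAT fields, `GENE`/`EFF` INFO fields).

## 5. TSS metagene profiles

Coordinates are 0-based half-open throughout. The transcription start
site is `start` for plus-strand genes and `end` for minus-strand
genes. Each gene gets the window `[TSS − flank, TSS + flank)`
(default flank 15 000 bp, bin 300 bp; the bin size must divide the
window). Bin values are interval-overlap-weighted means of the
bedGraph track, with bases not covered by any interval counted as
zero coverage. Minus-strand vectors are reversed so bin 0 is always
the most upstream position. Windows clipped at the chromosome start
have their missing positions **masked** (NaN), not zero-filled, and
per-bin means across genes are NaN-aware — so a clipped gene neither
drags the profile down nor is discarded. The binning is validated
against a per-base oracle (exact per-base expansion, reshape, mean).

## 6. Synthetic data generator

The generator is a first-class module: every analysis can be exercised
end to end with known ground truth. All randomness flows through
`numpy.random.SeedSequence(entropy=seed, spawn_key=(component,))`, so
each component (network, planting, expression, variants, coverage,
genes) has an independent, reproducible stream and results are
byte-identical across runs of the same seed.

**Regulatory network** (defaults: 50 TFs, 1000 target genes): each TF
draws a Poisson(20) number of `tf_dna` targets uniformly from all
other nodes, and proposes Poisson(5/2) `ppi` partners among TFs
(stored as symmetric directed pairs); edge confidences are uniform on
[0.5, 1.0]. Out-degree 20 and confidence ≥ 0.5 reflect
medium-confidence curated regulatory networks; 5 PPI partners gives a
connected but sparse TF–TF layer.

**Planted regulator** (defaults: effect 2.0, noise SD 1.0, depth decay
0.5): members of the planted TF's depth-≤ 3 **`tf_dna`** subnetwork
receive mean log2 fold-change `effect · decay^(depth−1)`; every
network gene then draws `fc ~ Normal(mean, SD)` and a two-sided
Gaussian p-value. The effect deliberately propagates through directed
regulatory edges only: a protein–protein edge does not transmit a
transcriptional program, and planting through PPI edges would shift
the direct target programs of the planted TF's interaction partners —
i.e. would genuinely activate several regulators while the ground
truth named one. Detection, by contrast, still uses both edge kinds
(`m2`), so the scorer is not given any information the generator
withholds. The default effect/noise/decay values make recovery hard
but achievable (≥ 90% top-rank recovery across 100 simulations, as
measured by `mraxis.evaluation.planted_recovery_rate`).

**Expression matrix**: log-normal baselines, multiplicative log-normal
noise, one gene set shifted by a known log2 factor in the second
group, plus low-expressed background genes that the `prep` filter
should remove.

**Variant calls** (defaults: 50 true somatic variants, 30
caller-specific false positives per caller, 20 blacklisted strain
polymorphisms, 3 normals, true VAF 0.35, 100× coverage): true
variants appear in every (caller × normal) call set, false positives
in exactly one caller, strain polymorphisms everywhere but on the
blacklist; depths are Poisson, observed VAFs binomial. 100× depth and
VAF 0.35 are typical of exome tumour sequencing.

**Coverage tracks**: constant baseline (10.0) with promoter windows of
chosen genes multiplied by a depletion factor — a caricature of
promoter-localised signal loss, designed so the expected profile is
known in closed form.

**What the generator does not emulate**: read-level artefacts
(mapping bias, strand bias, GC effects), overdispersed count noise
(expression noise is Gaussian/log-normal, not negative binomial),
linked or multi-allelic variants, clonal heterogeneity of VAFs,
correlated edge structure (hubs beyond Poisson degree, motifs), or
chromatin-domain-scale coverage structure. It is a correctness and
calibration harness, not a biological simulator.

## 7. Pipeline and reproducibility

`mraxis run` executes simulate → score → regulators → gsea → ssgsea →
variants → tssprofile from a single YAML configuration merged over
shipped defaults. Configuration problems are reported with field names
and fail with exit code 1 before any stage runs; stage failures are
tagged with the stage name and exit 2. Every output file's SHA-256
checksum is recorded in `manifest.json`; identical configuration and
seed reproduce identical checksums (asserted by the test suite).

## 8. Numerical choices

* BH adjustment, GSEA running sums, the network score, consensus
  logic and TSS binning are implemented directly (they are the
  substance of the method); scipy provides the hypergeometric and
  normal distributions and Pearson correlation; statsmodels is used
  only as an independent cross-check in tests.
* Empirical p-values are plain fractions `(#null ≥ observed)/n_perm`;
  with finite permutations the smallest attainable p is `1/n_perm`.
* Score caps: `−log10 q` is capped at ≈ 307.65 (smallest positive
  double) instead of propagating infinities.
* When the GSEA running sum's maximum positive and minimum negative
  deviations are equal to within float epsilon, the sign of ES is
  decided by summation-order noise; the acceptance script therefore
  compares magnitudes in that (rare, degenerate) case.
* All ordering is made deterministic by explicit tie-breaks
  (identifier order), so outputs are stable across runs and platforms.

## 9. Limitations

* The network score treats the BFS tree as the causal path; genes
  reachable by several routes are counted once via a single chosen
  parent, which under-counts convergent regulation.
* `m3` degenerates to 0 when the DE set is empty (the hypergeometric
  p is 1); with weak effects the aggregate ranking is then carried by
  `m1`/`m2` alone.
* Gene-permutation GSEA ignores inter-gene correlation; on correlated
  real data its p-values are anti-conservative relative to
  phenotype permutation.
* The somatic filter assumes caller-reported depths and VAFs are
  comparable across callers; no re-genotyping is performed.
* The pathway classifier is evidence-threshold-based; it does not
  integrate multiple sub-threshold observations into a combined
  likelihood.
* Recall/precision and recovery figures quoted anywhere in this
  repository are measured on the synthetic generator under its stated
  defaults, and say nothing about performance on real cohorts.
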