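# Methods

## Scope and data model

`breaksig` analyzes *called* variants: alignment, variant calling and
breakpoint discovery happen upstream, and the package consumes their
products (VCF, FASTA, BED). Internally everything is 0-based half-open;
VCF's 1-based convention is converted at the I/O boundary. Multi-allelic
records are split per ALT, each split inheriting the site-level MQ and DP,
because signatures are substitution-specific. Equal-length multi-base
substitutions (MNVs) are excluded with a tally rather than decomposed —
the analysis is defined over SNSs and 1-bp-anchored indels. Symbolic and
N-containing alleles are rejected at parse time; every rejection class is
counted and `records_in = records_kept + records_rejected` is asserted by
the test suite. Soft-masked (lowercase) reference bases are treated as
their uppercase nucleotide.

## Case-specific derivation

The escaped-cell-specific call set is derived in a fixed order:

1. MQ ≥ `mq_min` (default 30, inclusive) on **both** call sets;
2. subtraction of control from case on exact (chrom, pos, ref, alt) keys —
   a different ALT at the same site is a different mutation;
3. AF ≥ `af_min` (default 0.5, inclusive; AF falls back to the genotype via
   0/1 → 0.5, 1/1 → 1.0) and the depth rule on the remainder.

Filtering the control only on MQ before subtracting, then depth/AF
filtering the difference, avoids low-coverage control sites masquerading as
case-specific calls while not discarding case calls merely because the
control call was marginal.

**Depth rule.** Matching a call's depth *exactly* to the mean coverage
would discard nearly every record, so the depth policy is explicit:
`GE_MEAN` (default; DP ≥ mean coverage), `BAND` (|DP − mean| ≤ 25 % of the
mean), or `NONE`. The choice is recorded in the filter report. Mean
coverage is a user-supplied number — the package does not parse alignments.

**SNS load** is the filtered SNS count divided by mean coverage. Because it
is ambiguous whether a load should be quoted for the total filtered call
set or the case-specific subset, the pipeline reports both.

## Signature computation

Channels follow the field convention: 6 pyrimidine-strand substitution
classes (C>A…T>G) × 4 × 4 flanking bases, substitution-major with flanks
lexicographic, labels `A[C>T]G`. Purine-centered calls are
reverse-complemented together with their flanks (an involution the test
suite checks). Sites at contig edges or with N flanks are excluded and
counted; conservation (counts + exclusions = inputs) is asserted.

Correction divides each channel count by the genome-wide occurrence of its
pyrimidine-collapsed triplet, then renormalizes to sum 1 — the minimal
reading of "corrected for triplet frequency". Triplet counts are always
computed from the supplied FASTA (windows with N skipped), so toy genomes
and full references use one code path. A channel observed in a context the
genome lacks is an inconsistency and raises.

Similarity to a catalog is plain cosine on the corrected vector — the
standard metric for 96-channel comparison — reported as a ranking, not
thresholded. A catalog is a TSV (`context`, one column per signature); a
small built-in catalog of four deliberately distinct process-like
signatures (APOBEC-like TpC spikes, CpG-deamination C>T, a flat
HR-deficiency-like profile, and an ApT-biased T>C profile) serves as the
default and as the simulation basis.

## Breakpoint association

Each junction side is one point coordinate (a BED3 record). Windows
`[pos−w, pos+w)` (default w = 50 kb) are clipped to chromosome bounds and
merged; base-pair accounting uses effective (non-N) positions, and
`window_bp + outside_bp = total effective size` is an asserted invariant.

Genome-wide **enrichment** counts each variant once against the merged
windows and reports per-class densities per effective Mb, their ratio, and
a one-sided permutation p-value. Under the null, n variants placed
uniformly over the effective genome yield an in-window count distributed
Binomial(n, p_in) with p_in the effective in-window fraction; the test
samples that binomial directly (n_perm = 1000 by default) — exactly the
distribution materialized placements would give, at negligible cost — and
applies the +1/(n_perm+1) correction. With the denominators fixed,
ratio ≥ observed is equivalent to count ≥ observed, which is what is
compared. The ratio is ∞-sentineled when nothing falls outside, and
flagged NaN for empty classes.

**Per-breakpoint counts** are deliberately window-local: a variant within
w of k breakpoints contributes to all k rows (the enrichment uses merged
windows instead; both conventions are stated in the output headers).

**Kataegis** detection is the field-standard run rule: maximal runs of at
least `min_cluster_size` (default 6) consecutive substitutions with
successive distances ≤ `imd_max` (default 1 kb). Both are config knobs.
Clusters are annotated with APOBEC-type content (pyrimidine-collapsed
C>T/C>G) and distance to the nearest supplied breakpoint. Detection is
order-independent (positions are sorted internally).

*Density caveat.* An IMD rule is only informative when the background
inter-mutation spacing is much larger than `imd_max`. Real somatic genomes
carry ~1 mutation/Mb; the desk-scale default simulation carries ~2/kb,
where runs of six arise by chance everywhere. Cluster-recovery claims are
therefore evaluated on a sparser simulated background (500 case-specific +
2 000 shared mutations on 5 Mb ≈ 100/Mb — still ~100× real density), where
the detector achieves precision/recall ≥ 0.9 against planted truth.

## Synthetic data

The generator emulates the statistical structure of the paired-call-set
design at desk scale. Defaults: 5 Mb over 2 chromosomes at GC 0.41 with
N runs; 20 breakpoints; 20 000 shared mutations (uniform over non-N
positions, one germline genotype reused across both files); 10 000
case-specific substitutions from the mixture {APOBEC 0.55, FLAT 0.30,
CPG 0.15}; 10 kataegis clusters of 8 mutations over 2 kb within 50 kb of a
breakpoint; 2 000 shared and 1 000 case-specific small indels (1–3 bp) so
the INS/DEL paths are exercised; MQ < 30 on 5 % of records, 60 %
heterozygous calls, DP negative-binomial (mean 30, dispersion 10) so the
depth filter has realistic tails. MQ/DP noise is drawn per file; genotype
is a per-variant property.

Case-specific channels are sampled proportional to *implanted profile ×
genome triplet availability* and then assigned a uniformly chosen matching
triplet site, so the triplet-corrected recovered profile converges to the
implanted mixture in expectation (tested at n = 300 vs 3 000). Kataegis
clusters pick one strand each and keep all substitutions C>T/C>G on that
strand, mimicking APOBEC processivity on ssDNA. All placement is
collision-free; case-specific keys are asserted absent from the OFF file.
Outputs are byte-identical under a fixed seed.

What the generator does **not** model: sequencing reads (no FASTQ/BAM),
mapping artifacts correlated along the genome, indel left-alignment
ambiguity (inputs are assumed normalized), copy-number or LOH structure,
replication timing, and real chromatin-dependent mutation-rate variation.
Passing recovery tests therefore demonstrates the correctness of the
computational pipeline under its stated model, not calling accuracy on
real sequencing data.

## Kinetics

Background is the mean intensity of a region outside the cell, averaged by
default over all frames (a pre-damage-only flag exists, since either
reading of "an area outside the cell" is defensible). After subtraction,

    I(t) = [ mean_pre(ROI2′) / ROI2′(t) ] · [ ROI1′(t) / mean_pre(ROI1′) ]

with `mean_pre` over the first `n_pre` frames. Non-positive pre-damage
corrected intensities or a zero corrected whole-cell intensity are data
errors. I(t) is invariant under joint rescaling of ROI1′ and ROI2′ (the
expression-level normalization, tested as a property), and its pre-damage
mean is exactly 1 when ROI2′ is constant over those frames. No smoothing
is applied; cross-cell averaging is a separate frame-aligned mean.

## Problem sizes and numerics

The shipped tests and the acceptance script use the default 5 Mb genome
for signature recovery and determinism, 5 000 placed variants and
n_perm = 1000 for enrichment (50 replicates at n = 500 for p-value
uniformity), and the sparse background above for cluster recovery —
sizes chosen so the full suite replays in well under a minute per study
while keeping Monte-Carlo error far from the decision boundaries.
Corrected profiles are renormalized to sum 1 within 1e-9; cosine ties in
catalog ranking keep catalog order; all randomness derives from a single
seed (numpy `default_rng`), and pipeline reruns are byte-stable.
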