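# breaksig

Reverse-engineer the repair history of genomically unstable cells from
paired variant call sets.

Cells that escape a prolonged arrest carry a mutational record of how their
double-strand breaks were repaired. `breaksig` takes a case ("ESC", escaped
/ induced) and a control ("OFF", non-induced) whole-genome VCF from the
same clone, derives the case-specific mutations, and asks three questions
of them:

1. **What process made them?** The case-specific single-nucleotide
   substitutions (SNS) are tallied into the standard 96 trinucleotide
   channels (6 pyrimidine-strand substitution classes × 16 flanking-base
   pairs), corrected for the genome-wide abundance of each triplet, and
   ranked against a reference signature catalog by cosine similarity.
2. **Are they tied to rearrangements?** SNS/INS/DEL densities within
   ±50 kb of supplied chromosomal breakpoints are compared with the
   remaining (non-N) genome, with a one-sided permutation test, plus
   per-breakpoint counts.
3. **Are they clustered?** Kataegis-like hypermutation — runs of ≥ 6
   substitutions with inter-mutation distance ≤ 1 kb — is detected and
   annotated with its APOBEC-type content (C·G→T·A transitions and
   C·G→G·C transversions) and distance to the nearest breakpoint.

Because studies of this kind rarely release raw sequencing data, the
package ships a synthetic-data generator that emulates the full statistical
structure (shared germline background, signature-mixture case-specific
mutations, breakpoint-proximal kataegis clusters, MQ/DP/GT noise) with
per-variant ground truth, so every stage is testable end to end. A side
module implements the double-normalization used for laser-ablation
recruitment-kinetics traces.

## Model summary

* **Case-specific derivation.** Both call sets are filtered on mapping
  quality (MQ ≥ 30); the control is subtracted from the case on exact
  (chrom, pos, ref, alt) keys; the remainder is filtered on allele fraction
  (AF ≥ 0.5, with 0/1 → 0.5 and 1/1 → 1.0 when no AF tag is present) and
  read depth relative to the sample's mean coverage.
* **Triplet correction.** With raw channel counts `m_c` and genome triplet
  counts `t_c`, the corrected signature is
  `s_c = (m_c / t_c) / Σ_k (m_k / t_k)`.
* **Enrichment.** Windows `[b−w, b+w)` around breakpoints are merged;
  `ratio = density_near / density_far` on effective (non-N) bp; the null
  re-places the same number of variants uniformly over the effective
  genome (`perm_p` with the +1/(n+1) correction).
* **Kinetics.** `I(t) = [mean_pre(ROI2′)/ROI2′(t)] · [ROI1′(t)/mean_pre(ROI1′)]`
  after background subtraction, normalizing away expression level and
  acquisition photobleaching.

## Worked example

Simulate a default data set (5 Mb genome, 20 breakpoints, 20 000 shared +
10 000 case-specific mutations from a 0.55/0.30/0.15 APOBEC/FLAT/CPG
mixture, 10 kataegis clusters), run the pipeline, and score recovery:

```sh
breaksig simulate --outdir sim --seed 7
breaksig run --off sim/off.vcf --esc sim/esc.vcf --ref sim/genome.fa \
             --breakpoints sim/breakpoints.bed --outdir run \
             --mean-coverage 30 --seed 7
breaksig compare-truth --run run --truth sim/truth.json
```

prints

```json
{
  "dominant_recovered_first": true,
  "enrichment_ratio": 0.981194,
  "kataegis_precision": 0.03571428571428571,
  "kataegis_recall": 0.7,
  "signature_cosine": 0.9959736745769197,
  "top_signature": "APOBEC"
}
```

The pipeline recovered 5 043 case-specific substitutions (of 33 080 ESC
calls) whose corrected profile matches the implanted mixture at cosine
0.996, and the dominant mixture component ranks first in the catalog
(`run/similarity.tsv`: APOBEC 0.925, FLAT 0.463, CPG 0.351). The
background here is uniform, so the breakpoint enrichment ratio is ~1
(0.98, perm_p 0.75) — an enriched placement drives it above 1. Kataegis
precision is poor *at this density* by design: 10 000 substitutions on
5 Mb is ~2/kb, which saturates an inter-mutation-distance rule; at a
sparser, more genome-like background the detector recovers planted
clusters at precision/recall ≥ 0.9 (see `docs/methods.md`).

Per-stage outputs land in `run/`: filter tallies, the 96-channel signature
(raw + corrected), similarity ranks, enrichment and per-breakpoint TSVs,
kataegis clusters, and a rainfall table for plotting.

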