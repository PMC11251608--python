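# Methods

## The problem

Population-scale statistical phasers (SHAPEIT5, Beagle) estimate
haplotypes by borrowing information across samples. This works extremely
well at common variants but degrades sharply at rare ones: a singleton
carries no linkage-disequilibrium information at all, so roughly a third
of singleton heterozygous genotypes end up on the wrong haplotype, almost
always as *flip errors* — a single het assigned to the wrong parental
copy on an otherwise correctly phased background. Common variants instead
fail (rarely) through *switch errors*, where the assignment of an entire
downstream segment inverts.

This package corrects flip errors after the fact using the sample's own
sequencing reads. A read pair that covers a suspect heterozygous genotype
*and* a nearby confidently phased heterozygous genotype reveals which
alleles co-occur on one chromosome; counting such phase-informative pairs
either validates the reported phase or proves it wrong, in which case the
genotype is flipped.

## Pipeline

1. **Extraction.** A single coordinate-order pass over the phased VCF/BCF
   selects, per sample, every phased heterozygous SNV whose phasing
   confidence (FORMAT/PP) is below 0.99 — or, for phasers that emit no
   score, whose MAF is below a threshold (default 0.001, the MAF-proxy
   mode) — together with its nearest *eligible* het neighbors, up to two
   on each side. Eligible anchors are common hets (MAF at or above the
   threshold) or rare hets with confidence at or above 0.99; a
   low-confidence het never anchors another target, because anchoring on
   uncertain phase would propagate errors. The pass keeps only a bounded
   per-sample buffer, so memory is O(samples). Targets are stored in a
   compact per-sample binary file plus a sample-free site-only BCF
   (documented in `variant_io`), giving O(1) random access to any
   sample's records.

2. **Phase calling.** For each target, the sample's reads over the target
   and anchors are fetched from the indexed BAM/CRAM. A read is used only
   if it is a mapped, primary, non-duplicate member of a proper
   forward–reverse pair with both mates mapped and MAPQ ≥ 50; base calls
   below quality 20 are masked. A read pair contributes at most one
   observation per (target, anchor): mate calls at a site must agree or
   the fragment is discarded for that target; bases matching neither
   allele count as nothing. An observation *confirms* the stored phase if
   its two alleles lie on one haplotype under the stored orientation, and
   *contradicts* it otherwise. Under the default **strict** rule a target
   is switched only when at least one pair contradicts and none confirms,
   and validated only in the mirror case; everything else — no evidence,
   or mixed evidence — is left unresolved. The opt-in **majority** rule
   resolves mixed evidence toward the larger count (ties unresolved),
   which is the sensible behavior when one of several anchors is itself
   mis-phased.

3. **Update.** Switched targets get their haplotype alleles swapped
   (`1|0` ↔ `0|1`); switched and validated targets get the composite
   confidence annotation

       PP_new = PP_old + supporting_reads + 1

   so any PP > 1.0 marks a read-checked genotype, the fractional part
   recovers the original statistical confidence, and `floor(PP) − 1` the
   supporting read count. Unresolved targets and all other genotypes pass
   through untouched. A verification pass then proves per genotype that
   the allele content is unchanged (no het became hom), that nothing with
   original confidence ≥ 0.99 moved, and that the number of changed
   genotypes equals the number of switch decisions.

### Numerical and edge-case choices

- The writer rounds the fractional confidence to six decimals so the
  composite value decodes stably; BCF FORMAT floats are IEEE float32, so
  a value re-read from a BCF carries ≈1e-5 absolute error for read counts
  up to ~50. Pure in-memory encode/decode is exact to 1e-6 over the whole
  valid grid (pp ∈ [0.5, 0.99), reads ≥ 1).
- A genotype with confidence exactly 1.0 (or ≥ 0.99) is never rephased;
  the encoder refuses such inputs outright.
- MAF→MAC conversion floors `2·N·maf`. In a 147,754-sample cohort a MAF
  of 0.001 corresponds to MAC 295 and 0.0002 to MAC 59.
- Targets with no eligible anchor on either side are kept and come out
  unresolved; anchors never cross contig boundaries.
- In MAF-proxy mode targets have no original score; the composite
  annotation uses 0.5 (complete uncertainty) as the fractional part.
- Re-polishing an already-annotated file is supported: composite values
  are decoded back to the original confidence before re-encoding, which
  also makes the genotype update an involution (re-applying a switch plan
  restores the original file).
- Region-chunked extraction scans a ±2 kb padding (configurable) so
  anchor lists at chunk edges match a whole-file pass whenever the
  anchors fall inside the padding.

## Synthetic cohorts

The simulator generates, from one seed, a complete test cohort: random
reference, biallelic SNV truth haplotypes, an error-injected "statistically
phased" VCF with confidence scores, and per-sample paired-end reads.

- **Frequency spectrum**: per-site allele frequency
  `f = 1/2N + (0.5 − 1/2N)·Beta(a, b)` with a = 0.35, b = 2.5 by default —
  heavily rare-skewed, as in sequencing cohorts; haplotype alleles are
  i.i.d. Bernoulli(f) and monomorphic draws are dropped. The analytic MAC
  distribution under the law is available for spectrum checks
  (`expected_mac_probability`).
- **Phasing errors**: rare hets (MAF below `rare_maf`) flip independently
  with a MAC-binned probability, 34% at singletons decaying to 0.5% above
  MAC 200 by default; at each common-het interval a switch starts with
  probability 0.001, inverting the remainder of the sample's labels. The
  registry of injected errors exactly reconstructs the truth/emitted
  discordance matrix.
- **Confidence scores**: emitted for rare hets only (common hets carry no
  score, mirroring phasers that score rare variants). Scores are drawn
  conditionally on local correctness from a *miscalibrated* model: the
  marginal places 25% of its mass above 0.99 and the rest uniformly over
  [0.5, 0.99), and the conditional error falls linearly from 33.7% at 0.5
  to 12.5% near 0.99 — informative but overconfident, so the realized
  error rate within score bins decreases with the score by construction.
  A *separated* model (0.98 if wrong, 0.995 if right) isolates every
  injected error below the extraction threshold for exact-recovery
  experiments.
- **Reads**: fragments drawn uniformly from the two true haplotypes at
  the configured coverage (default 30×, 2×150 bp, 450 ± 100 bp inserts),
  written pre-aligned at their generative coordinates — haplotypes differ
  from the reference only by SNVs, so placements are exact and no
  aligner is involved. Uniform substitution errors (default 0.1%), a
  low-MAPQ read fraction, a low-base-quality fraction and a duplicate-flag
  fraction exercise every read filter.
- `rare_maf` (default 0.05) plays the role at desk scale that the 0.001
  MAF cutoff plays at biobank scale; extraction fixtures set
  `maf_threshold = rare_maf` so "rare/common" means the same thing on
  both sides.

What the simulator does **not** model: mapping ambiguity and alignment
artifacts (reads are placed exactly), indels and structural variants,
context-dependent sequencing error profiles, GC/coverage bias, and
reference bias. Tests passing on these cohorts therefore demonstrate the
correctness of the bookkeeping — filters, pairing, orientation logic,
encodings, accounting — and the behavior of the decision rule under
idealized noise, not robustness to real-world alignment pathology.

## Evaluation

- **Switch error rate (SER)**: per sample, successive het pairs whose
  relative orientation disagrees with truth, over all such pairs —
  invariant under whole-sample relabeling of either input. Pairs are
  binned by the MAC of the rarer variant (default edges 1, 2–5, 6–10,
  11–20, 21–50, 51–100, 101–200, 201+), so flip errors at rare hets land
  in rare bins.
- **Rephased-subset SER**: restricted to pairs whose attributed (rarer)
  variant carries a validated/switched decision, excluding pairs that
  touch an *unchecked* target (extracted but unresolved) — such a pair
  measures the unchecked suspect, not the polished call. On a MAC tie the
  pair is attributed to the left variant.
- **Linkage accounting**: per MAC bin, the fraction of targets linked to
  an anchor by at least one accepted read pair (decision ≠ unresolved)
  and the switched fraction among linked.
- **Calibration**: decided targets binned by original confidence; the
  switched fraction per bin is the read-measured error rate of the
  statistical phaser at that confidence. Default bins are four
  equal-width bins over [0.5, 0.99): desk-scale cohorts yield a few
  thousand decided calls, i.e. ~10³ per quartile bin, enough to resolve
  the miscalibration slope; finer binning is under-powered at this scale
  and the edges are configurable.

## Benchmark scenario sizes

The canned scenarios (`phasepolish.benchmarks`, driven by
`scripts/acceptance.py` and the end-to-end tests) use cohort sizes chosen
to give stable statistics at interactive runtimes: 100 randomized
mini-cohorts of 3–6 samples / 20 kb / ~6–10× for the oracle-agreement
checks; 10 samples / 60 kb / 30× for the error-free and safety cohorts;
the full defaults (30 samples / 200 kb / 1300 sites / 30×) for the noisy
improvement run; and a dense 300-sample / 100 kb / 12× cohort for
calibration, sized so each confidence bin holds >10³ decided calls.

## Known limitations

- Short-read pairs only: no long reads, no single-end mode, no
  phase-set (PS) block construction across more than target+anchors.
- SNVs only; indel/SV re-phasing would need a realignment model.
- Anchors are trusted at their stored phase within a single pass; a
  mis-phased anchor converts a flip correction into a local flip error
  (the strict rule leaves most such cases unresolved instead, and the
  majority rule arbitrates between disagreeing anchors).
- The strict rule's "no contradiction" requirement means one noisy read
  can demote a correctable target to unresolved; this is the intended
  conservative trade-off (polishing must not create errors).
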