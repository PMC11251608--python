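# phasepolish

Read-backed polishing of statistically phased haplotypes.

Statistical phasers (SHAPEIT5, Beagle, ...) resolve common variants almost
perfectly but mis-assign a large fraction of *rare* heterozygous genotypes —
up to a third of singletons — almost always as **flip errors**: one het
placed on the wrong haplotype of an otherwise correct background.
`phasepolish` fixes these after the fact using the sample's own sequencing
reads. For every low-confidence phased het it finds the nearest confidently
phased het neighbors ("anchors"), counts the read pairs that cover both
sites, and:

- **validates** the phase if ≥ 1 pair supports it and none contradicts,
- **switches** it (`1|0` ↔ `0|1`) if ≥ 1 pair contradicts it and none
  supports, or
- leaves it **unresolved** otherwise (no informative pair, or mixed
  evidence under the default strict rule).

The polished VCF/BCF records the outcome in the PP FORMAT field as a
composite score `PP_new = PP_old + supporting_reads + 1`: any value > 1.0
marks a read-checked genotype, its fractional part is the original
statistical confidence, and `floor(PP) − 1` the supporting read count. A
verification pass proves no genotype was damaged (allele content
preserved, no het became hom, nothing with confidence ≥ 0.99 touched).

Evidence is deliberately strict: mapped primary FR read pairs only, both
mates mapped, no duplicates, MAPQ ≥ 50, base quality ≥ 20, mates must
agree. Polishing is designed so it can only remove phase errors, never
introduce them.

The package is fully testable without external data: a seeded simulator
generates diploid cohorts (reference, true haplotypes, an error-injected
phased VCF with confidence scores, and per-sample BAMs), and an evaluator
computes switch error rates stratified by minor allele count, linkage
accounting, and confidence-calibration tables against the simulated truth.

## Worked example

Simulate an 8-sample cohort, polish it, and measure the improvement:

```bash
cat > sim.yaml <<EOF
n_samples: 8
region_length: 60000
n_sites: 400
rare_maf: 0.13
EOF

phasepolish simulate --config sim.yaml --out cohort --seed 42
# wrote cohort with 8 samples, 305 sites, 77 injected errors to cohort

phasepolish extract --vcf cohort/phased.bcf --output targets --maf-threshold 0.13
# 204 targets across 8 samples

phasepolish polish --store targets --alignments cohort/S002.bam \
    --sample S002 --output S002.tsv
# 28 targets: 10 validated, 3 switched, 15 unresolved
# (repeat per sample; each sample only needs its own BAM)

phasepolish update --vcf cohort/phased.bcf --decisions S000.tsv ... \
    --output polished.bcf
# annotated 103 genotypes (29 switched)
# verification passed (2440 genotypes)

phasepolish evaluate ser --truth cohort --estimate polished.bcf \
    --decisions S000.tsv ...
```

```
mac_bin          evaluated_pairs  discordant_pairs  ser
1                196              47                0.239796
2-5              373              29                0.077748
...
overall          575              76                0.132174
rephased_subset  156              3                 0.0192308
```

Before polishing the same cohort measured `ser = 0.377551` in the
singleton bin and `0.222609` overall: polishing removed roughly a third
of all phase errors, and the subset of genotypes it could actually check
against reads is an order of magnitude cleaner (1.9% vs 37.8% singleton
errors). The per-sample decision files list each target with its outcome,
read counts and original confidence; in the polished file a PP of 4.87
decodes as "original confidence 0.87, 3 supporting reads, read-checked":

```python
>>> from phasepolish import decode_confidence
>>> decode_confidence(4.87)
(0.87, 3, True)
```

The library mirrors the CLI one-to-one (`extract_targets`,
`polish_sample`, `apply_decisions` / `verify_update`, `write_fixture`,
`switch_error_rate`, `calibration_table`, ...) for use from Python.

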