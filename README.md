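# hlameth

Analysis toolkit for DNA-methylation studies of the highly polymorphic HLA
region on chromosome 6:

1. **Probe reliability auditing** — classifies population SNPs that fall
   inside the influential 3' window of Infinium methylation-array probes
   (`ONSITE` / `5nt` / `10nt` categories over the four strand × design-type
   layouts) against a population allele-frequency VCF, and derives per-probe
   reliability verdicts at configurable MAF thresholds (default 0.05 and
   0.01, compared with `>=`).
2. **DMP association** — region-restricted case–control testing on
   beta-value matrices: detection-P filtering (probes failing in strictly
   more than 10% of samples are dropped), optional blocklist removal,
   per-probe two-sample t-tests, OLS regression adjusting for HLA-DQB1\*06:02
   carrier status, and Bonferroni correction with `n_tests` recomputed from
   the probes actually tested.
3. **Allele-level expression** — per-allele RNA read counts are
   length-normalized and scaled so each sample's abundances sum to one
   million; each allele is compared to the reference allele
   (DQB1\*06:02) by Wilcoxon rank-sum, and per-sample aggregates
   (non-reference sum, DQB1 \*03/\*04 and \*05/\*06 sublineage sums) are
   compared case vs control by t-test.
4. **Synthetic data** — a seeded generator for every pipeline input
   (manifest, AF-panel VCF, beta/detection-P matrices, sample sheet, allele
   counts) with planted SNPs, planted direct / carrier-mediated methylation
   effects, and a machine-readable ground-truth ledger.

All coordinates are 1-based inclusive; `chr6` and `6` are unified before
any join.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), a brute-force oracle for the
probe-influence window tables, Monte-Carlo power/calibration checks, and
`tests/test_acceptance.py` with one test per acceptance criterion.

## CLI

```sh
hlameth simulate   --seed 1 --out sim/            # synthetic inputs + truth.json
hlameth audit      --manifest sim/manifest.tsv --af-vcf sim/panel.vcf \
                   --region hla_flanking --maf 0.05 --maf 0.01 --out audit_
hlameth dmp        --beta sim/beta.tsv --detp sim/detp.tsv \
                   --manifest sim/manifest.tsv --samples sim/samples.tsv \
                   --region hla_flanking --out dmp_
hlameth expression --counts sim/allele_counts.tsv --samples sim/samples.tsv \
                   --reference-allele "DQB1*06:02" --out expr_
hlameth run-all    --config cfg.yaml --seed 1 --out run/
```

Regions can be a known name (`hla_flanking`, `hla_class_i`, `hla_class_ii`)
or a literal `chrom:start-end`. Exit codes: 0 success, 2 configuration
error, 3 data error. `run-all` writes `run_metadata.json` with the config
snapshot, seed, per-stage probe counts and the analysis decisions (t-test
flavor, MAF operator, alpha threshold); identical configs yield
byte-identical outputs.

Example config (`cfg.yaml`):

```yaml
simulate:
  n_probes: 400
  n_background_snps: 300
  region: "6:26000000-35000000"
audit:
  maf_thresholds: [0.05, 0.01]
dmp:
  alpha: 0.05
```

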