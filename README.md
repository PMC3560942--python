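# pssmap

Genetic mapping of an incompletely penetrant binary trait segregating in
inbred mouse crosses — built around the closure of the presphenoidal
synchondrosis (PSS), a midline cranial-base growth plate that fuses shortly
after birth in the DBA/2J strain but stays open in other common inbred
strains.

The package is aimed at mouse geneticists analysing crosses between inbred
strains where the phenotype is a binary call (affected / unaffected), the
penetrance depends on genotype and scoring age, and genotyping or sequencing
is concentrated on affected animals.  It provides three connected layers:

1. **A synthetic-data generator** (`pssmap.sim`) that stands in for the
   colony and the sequencer: fully homozygous parental strains, meiosis
   under the Haldane model (Poisson crossovers, no interference), F1 / F2 /
   backcross cohorts, a single-trait-locus penetrance model
   `P(affected | g) = 1 − (1 − p_g)(1 − b)`, and pooled low-coverage
   sequencing with Poisson depth and a per-read base-error rate.
2. **Cross statistics** (`pssmap.segscan`):
   - Mendelian goodness of fit: Pearson χ² = Σ (O − E)²/E with no
     continuity correction (1 df for affected/unaffected counts, 2 df for
     F2 genotype classes against 1:2:1);
   - the affected-only segregation-distortion genome scan with a Bonferroni
     threshold α / n_tests;
   - χ² independence tests between closed- and open-phenotype genotype
     tables;
   - a single-locus feasibility diagnostic: the expected affected
     proportion of each design is linear in the penetrance triple
     (p₀, p₁, p₂) — F1: p₁; F2: ¼p₀ + ½p₁ + ¼p₂; backcross to the carrier
     strain: ½p₁ + ½p₂ — so "can one locus explain all crosses?" is a
     linear program over [0, 1]³, with a binomial-deviance best fit.
3. **Pooled-WGS analysis** (`pssmap.poolscan`): support classification of
   reported strain-distinguishing SNPs (covered in both pools, pools
   internally homozygous, consensus alleles differ), the six-filter
   novel-SNP hard cascade (≥2 alternate reads; quality > 30; mapping
   quality > 40; combined depth > 4 and < 80; repeat exclusion; > 3 SNPs
   per 10-bp window), 10-Mb sliding-window strain-allele-fraction scans and
   200-kb SNP-density profiles.

File formats (`pssmap.formats`): CSV/TSV for maps, genotypes, phenotypes
and pileups; VCF 4.x for variant sites and filter verdicts; BED for repeat
masks.  A `pssmap` CLI exposes every stage plus a YAML-driven `run`
command that emits a reproducibility manifest.

## Worked example

Is the trait compatible with a single recessive locus?  Affected counts per
cross design go straight in:

```bash
$ pssmap gof --affected 86 --unaffected 395 --expected-fraction 0.25
{"chi2": 13.0069, "df": 1, "p": 0.0003103, ...}

$ pssmap gof --affected 45 --unaffected 40 --expected-fraction 0.5
{"chi2": 0.2941, "df": 1, "p": 0.5876, ...}
```

The backcross fits a recessive 1:1 expectation (p ≈ 0.59) but the F2 does
not (p ≈ 0.0003).  The feasibility diagnostic shows no penetrance triple
can reconcile the three designs:

```bash
$ pssmap feasibility --obs F1=0/67 --obs F2=86/481 --obs BC=45/85
{
  "feasible": false,
  "best_fit": [0.0, 0.0, 0.8263],
  "deviance": 6.9992,
  "certificate": "F1 proportion 0 forces p1 = 0; then BC expected proportion
                  is confined to [0.000, 0.500] but 0.529 was observed"
}
```

An affected F1 proportion of zero pins the heterozygote penetrance to 0,
which caps the backcross expectation at ½ — below the observed 0.529 — so
inheritance must involve more than one locus.

Simulating a cross and scanning affected offspring recovers a planted
trait locus:

```bash
$ pssmap simulate-cross --design F2 --n 481 --n-markers 874 \
      --penetrance pen.yaml --seed 1 --out-dir demo
wrote 481 F2 offspring x 874 markers to demo
$ pssmap scan --genotypes demo/genotypes.csv --phenotypes demo/phenotypes.csv \
      --map demo/markers.tsv --out demo/scan.tsv --n-tests 874
tested 874 markers; threshold 5.72e-05; peak m11_0006 (chr11:14347556) p=1.75e-69
```

with `pen.yaml` declaring a nearly recessive chromosome-11 locus:

```yaml
trait_locus: m11_0006
background_rate: 0.0
penetrance:
  P21: [0.02, 0.02, 0.9]
```

The peak marker is the planted locus itself, far beyond the Bonferroni
threshold 0.05/874 ≈ 5.72 × 10⁻⁵.

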