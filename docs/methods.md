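# Methods

## The mapping problem

A binary skeletal trait — closure of the presphenoidal synchondrosis (PSS),
a cranial-base growth plate — segregates when a closing strain (here called
strain B, DBA/2J-like) is crossed to a non-closing strain (strain A).  The
trait is incompletely penetrant and its penetrance depends on the age at
which animals are scored, so observed affected proportions in F1, F2 and
backcross cohorts do not follow clean Mendelian ratios.  The package
implements the two mapping strategies appropriate to this setting:

* **selective genotyping**: genotype only affected offspring and scan each
  marker for segregation distortion — enrichment of the causal strain's
  alleles — against the neutral expectation (1:2:1 in an F2, 1:1 in a
  backcross);
* **bulk-segregant pooled sequencing**: sequence a DNA pool of selected
  offspring at low coverage and scan for genomic windows whose pooled
  strain-allele fraction departs from ½.

## Simulator

**Genome and markers.**  The default genome has 19 autosomes with
approximate mouse physical (61–197 Mb) and genetic (56–103 cM) lengths.
bp↔cM conversion is piecewise-linear interpolation between per-chromosome
anchor points (the default two anchors give a uniform recombination rate).
Marker panels are spread evenly in genetic distance, proportional to
chromosome cM length, mimicking a genotyping array designed for uniform
genetic coverage.

**Meiosis.**  Crossover counts per chromosome are Poisson with mean
(length in cM)/100, positions uniform in cM, no interference — the Haldane
model.  The recombination fraction between two markers d cM apart is then
r = (1 − e^(−2d/100))/2, which the test suite verifies by Monte Carlo at
five distances.  Haldane was chosen over interference models (e.g.
chi-square / gamma renewal) because it is the simplest defensible default
and closed-form testable; crossover interference mainly affects
double-crossover patterns, not the marker-wise allele frequencies these
analyses consume.

**Crosses.**  Parents are fully homozygous and informative at every marker,
so an F1 carries one pure-A and one pure-B haplotype and only F1 meiosis
needs simulating: F2 = two F1 gametes, backcross = one F1 gamete plus a
constant gamete from the recurrent inbred.  Genotypes are coded 0/1/2 (B
allele dosage) with −9 for missing.

**Penetrance.**  One designated trait locus; for each scoring age a triple
(p₀, p₁, p₂) gives P(affected | genotype), combined independently with a
genotype-free background rate b:
P(affected) = 1 − (1 − p_g)(1 − b).  Ages are separate triples rather than
a parametric hazard because the underlying observations are per-age
proportions (e.g. 59% affected at P21 vs 90% at P35 in one cross); a
hazard model would add parameters the data cannot pin down.  Scoring age
is an explicit input — the generator does not decide when a cohort is
scored.

**Pooled sequencing.**  At each variant site the read depth of a pool is
Poisson(mean depth); each read picks a uniformly random pool member, one of
its two alleles uniformly, and is miscalled to the other allele with the
base-error rate.  Because reads are independent, the alternate-read count
at depth d is exactly Binomial(d, f(1−e) + (1−f)e) with f the pool's
alternate-allele frequency (mean dosage / 2), and the implementation draws
from that binomial directly.  The reference genome is taken to be
strain-B-like, so ref = strain-B allele and alt = strain-A allele at every
informative site.  Site and mapping qualities are drawn from normal
distributions truncated at zero (defaults: mean 60 sd 15, mean 55 sd 8),
centred above the hard-filter thresholds so that the filter cascade sees a
realistic mix of passing and failing annotations; real caller quality
distributions are not modelled.

**Seeding.**  Every stage draws from a named substream of one master seed
(`substream(seed, name)`, a CRC32-keyed `SeedSequence` spawn), so stages
are independently reproducible and insensitive to each other's draw counts.

### What the generator does not emulate

Coverage clumping (real low-coverage sequencing has strongly autocorrelated
depth, GC bias and mapping dropouts — simulated Poisson coverage is more
even, so simulated "fraction of sites covered" runs higher than a real
experiment's at the same mean depth); alignment artifacts (soft clips,
strand bias, reference bias); genotyping error in array data; sex
chromosomes; mutation during the cross; crossover interference.  Passing
tests therefore demonstrate correctness of the statistics and of signal
recovery under the stated sampling models, not robustness to these
artifacts.

## Cross statistics

All χ² statistics are Pearson Σ(O − E)²/E with **no continuity
correction**.  The two published goodness-of-fit values pin this choice
down: 45 affected / 40 unaffected against ½ gives p = 0.588 (printed 0.59)
without correction but ≈ 0.66 with Yates, and 86/395 against ¼ gives
χ² = 13.01, p = 0.00031 only without correction.

Expected-count policy: a zero expected count is an error; an expected count
below 5 warns but does not error, because the affected-only scan is
legitimately run on small cohorts (37 affected F2 gives expected cells
9.25/18.5/9.25).

**Affected-only scan.**  Per marker, genotype counts among non-missing
affected individuals are tested against the design ratio; markers with no
genotyped individual are reported as untested rather than dropped.  The
family-wise threshold is α/n_tests with n_tests defaulting to the number of
markers actually tested; a `threshold_override` reproduces a literal
published cut such as 5 × 10⁻⁵ (the rounded form of 0.05/874 =
5.72 × 10⁻⁵).  Peak tie-breaking: smallest p, then largest χ², then lowest
genomic coordinate.

**Single-locus feasibility.**  Expected affected proportions are linear in
(p₀, p₁, p₂): F1 → p₁, F2 → ¼p₀ + ½p₁ + ¼p₂, backcross to B → ½p₁ + ½p₂.
Exact matchability of the observed point estimates inside [0, 1]³ is a
linear program (solved by HiGHS); the best fit under sampling noise
minimises the binomial deviance (21³ grid multistart + Nelder–Mead polish,
proportions clipped to [10⁻¹², 1 − 10⁻¹²]).  When infeasible, a
pin-and-propagate argument is attempted for a human-readable certificate —
a design with proportion 0 (or 1) pins every parameter it weights, after
which another design's observation may fall outside its attainable
interval — falling back to the least-squares residual when interval
propagation alone cannot prove it.

## Pooled-WGS analysis

**Support classification.**  A reported strain-distinguishing SNP is
evaluated only when both pools have ≥1 read (otherwise `not_covered`).  A
pool with a single read uses that read as its consensus; a pool with ≥2
reads must be unanimous, otherwise the site is `ambiguous` (non-homozygous,
excluded).  Covered, unambiguous sites are `supported` when the two pools'
consensus alleles differ.  The confirmation rate is supported /
(supported + not_supported) among covered unambiguous sites.

**Hard-filter cascade.**  Six filters, all evaluated for every site (no
short-circuit), verdicts list every failure in cascade order:
alternate reads (both pools combined) ≥ 2; site quality > 30; mapping
quality > 40; combined depth > 4 and < 80 (strict bounds: 5–79 pass);
repeat-mask exclusion (a 1-based site position p is masked when p − 1 lies
in a 0-based half-open mask interval); and the cluster filter.  The cluster
window slides over base pairs: any run of four candidates spanning ≤ 9 bp
(i.e. > 3 SNPs inside some 10-bp window) removes **all** sites in the
offending span — the conservative all-removed semantics usual in hard
filtering, since the cluster signals a local alignment artifact rather
than identifying which member is wrong.

**Window scans.**  10-Mb windows tile each chromosome from 0 with a 1-Mb
default step (step = window gives a non-overlapping tiling); the last
window truncates at the chromosome end.  A window's strain-A fraction is
the read-weighted fraction over contained informative sites, reported as
missing — never 0 — when the window has no informative reads, to avoid
fabricating depletion signals.  Windows with ≤ 4 sites are flagged
low-density.  No enrichment threshold is imposed; Wilson binomial
confidence intervals are available (`window_fraction_ci`) and significance
judgements are left to the user.  The 200-kb density profile is a
non-overlapping tiling with per-window counts and presence flags, plus the
genome fraction of 10-Mb tiles holding ≤ 4 SNPs.

**Coordinates.**  Variant sites are 1-based (VCF convention); windows and
masks 0-based half-open (BED convention); conversion happens only at the
I/O boundary.

## Numerical and testing choices

* Test problem sizes: Monte-Carlo map-function and penetrance checks use
  10,000 gametes/offspring with 3σ binomial bands; scan calibration uses
  1,000 replicates of 500 affected at 200 unlinked markers; planted-locus
  recovery uses 200 replicates of 37 affected at 874 markers; pooled-scan
  recovery uses 100 replicates of 50,000 sites at mean depth 2.5.  These
  sizes make the binomial acceptance bands decisive while keeping the whole
  suite fast on one CPU.
* The null-calibration uniformity invariant (KS test on 10,000 markers,
  rejection in ≤ 5% of runs at α = 0.01) is checked at a cohort size of
  2,000, where the χ² approximation is accurate.  At small cohort sizes the
  discreteness of the Pearson statistic is itself detectable by a
  10,000-sample KS test, so uniformity in that strict sense holds only
  asymptotically; the separate α = 0.05 type-I-error calibration is checked
  at 500 affected and passes.
* Unlinked-marker nulls are generated directly from the 1:2:1 law (two
  Bernoulli gametes per genotype) rather than by whole-genome meiosis —
  distributionally identical for mutually unlinked markers and much
  cheaper.
* Floating-point output: p-values are printed with 4 significant digits;
  window fractions with 4.  CSV/TSV dialects are pinned (UTF-8, mandatory
  headers, '.' decimal).
* Degenerate inputs: empty cohorts, all-zero count vectors, empty pools,
  unsorted candidate lists and out-of-map markers raise errors naming the
  offender; genotype classes empty in both comparison groups are dropped
  with a warning.

## Known limitations

Single-trait-locus penetrance only (no epistasis or polygenic background
beyond the uniform background rate); marker-wise χ² scans only (no interval
mapping or permutation thresholds); biallelic SNPs only (microsatellites
are treated as biallelic informative markers, indels are out of scope); the
pooled model ignores depth autocorrelation and alignment artifacts, so its
coverage and confirmation figures are optimistic relative to real
low-coverage data.
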