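# Methods

## Model and tests

### The proxy-ratio test

For one gene region, the rare minor-allele counts of functional variants
(x₁f in cases, x₀f in controls) and proxy (non-functional) variants
(x₁p, x₀p) are modelled as four independent Poisson observations with
means λ₁f, λ₁p, λ₀f, λ₀p. The null hypothesis is equality of the
functional:proxy rate ratios, λ₁f/λ₁p = λ₀f/λ₀p. The rationale: the
proxy class measures how well the region is sequenced, called and
annotated in each dataset, and technology or pipeline artifacts scale
both variant classes together, whereas disease association acts on the
functional class only.

The constrained MLEs (Lagrange multipliers) are closed-form quadratic
forms in the counts over the total count; they satisfy the ratio
constraint exactly and conserve the observed total. Because the
unconstrained MLEs are the observed counts and the totals are conserved,
the likelihood-ratio statistic reduces to the Poisson deviance

G = 2 Σ [ x ln(x/λ̂) − (x − λ̂) ],  with 0·ln 0 := 0,

referred to χ² with 1 degree of freedom (one constraint). All factorial
terms cancel between numerator and denominator, which is what makes
non-integer, coverage-weighted counts legitimate inputs.

**Degenerate genes.** A gene with all four counts zero, or with an entire
classification margin empty (no functional alleles anywhere, or no proxy
alleles anywhere), carries no information about the ratio null; such
genes return a flagged invalid result (NaN p-value) rather than raising,
so genome-wide scans continue.

### Coverage weighting

High-coverage sequencing recovers relatively more functional than
synonymous variation than low-coverage sequencing does. The weighted test
divides the functional counts by each group's genome-wide median of the
per-gene functional:proxy allele ratio (m₁ in cases, m₀ in controls)
before applying the same test. Genes with zero proxy alleles in a group
are excluded from that group's median (their ratio is undefined); the
median of an even-length set is the midpoint of the central pair. The
medians must be estimated genome-wide — computing them from a handful of
genes is unstable and the code raises when no eligible genes exist.

### Negative-binomial extension

With over-dispersed counts, each cell is modelled NB(mean λ, size η),
variance λ(1 + λ/η), Poisson in the η → ∞ limit. η is taken as *known*
(user-supplied); the test is the analogous 1-df LRT. For the constrained
fit the null is parameterized as (λ₁p, λ₀p, ρ) with λ₁f = ρλ₁p and
λ₀f = ρλ₀p. At fixed ρ the stationarity condition for each group's λ is
a quadratic with a single positive root, so both λ's are profiled out in
closed form and the likelihood is maximized by a golden-section search on
log ρ (bracket ±15 around the Poisson closed-form ratio, 120 iterations,
final bracket ≪ 1e-10). This profile construction replaces a generic
3-parameter optimizer: it is vectorizable across a 20,000-gene genome
(the whole NB type-I experiment runs in under a second) and cannot step
outside the feasible region. It agrees with a dense 3-parameter grid
search and with Nelder-Mead on the full likelihood to ~1e-7 in the
p-value.

**Calibration caveat.** With known η the NB test removes the gross
inflation the Poisson test suffers on over-dispersed data (≈0.36
empirical rate at nominal 0.05 for η = 5, mean 20), but a residual
anti-conservativeness of the χ²₁ approximation remains: the long-run
rejection rate is ≈0.056 at the 0.045 threshold (≈0.061 at 0.05).
Over-dispersion at η = 5 inflates each cell's variance five-fold, so the
effective information per gene resembles a Poisson problem with mean ≈4,
where the one-observation-per-cell asymptotics are known to be rough.
The acceptance test asserting strict interval containment of the nominal
rate therefore fails by this small margin, by design left as-is.

### Comparator tests

*Case-control LRT*: two-sample Poisson comparison of functional counts
with person-count offsets — pooled rate r̂ = (x₁+x₀)/(n₁+n₀), deviance of
the observed counts from n₁r̂ and n₀r̂, χ²₁. Powerful, but biased whenever
cases and controls were sequenced or processed differently.

*Case-only LRT*: one-sample Poisson deviance of a gene's functional count
in cases against e = rate × length_kb × n_cases, where the per-kb
per-case rate is either supplied (simulation truth) or estimated
genome-wide as Σ functional alleles / (Σ kb × n_cases). Robust to
genome-wide case-control differences (they enter the genome-wide rate)
but confounded by any gene-specific deviation from the length-expected
count.

### Significance threshold and inflation factor

The Poisson proxy-ratio test carries a slight, consistent
anti-conservativeness; multiplying the significance level by 0.9
(0.05 → 0.045, 0.01 → 0.009) restores the nominal rate. This adjustment
is an explicit option — reported p-values are never silently rescaled, so
they remain comparable across tests. Genome-wide calibration is
summarized by the inflation factor λ = median(observed χ²₁ statistics) /
0.454936 (the exact χ²₁ median, not a simulated reference); p-values are
converted through the χ²₁ quantile function.

## Variant-to-gene aggregation

Inputs are biallelic per-variant records (gene, Sequence Ontology
consequence terms, AC/AN per dataset, optional external reference
frequencies). Processing order: orient to the minor allele → MAF filters
→ classification → per-gene summation → gene thresholds. Choices:

* **Minor-allele orientation**: alternate alleles with frequency > 0.5
  are flipped (count = AN − AC) and flagged; rare-variant filters make
  flips rare, but silent reference/alternate mismatches would otherwise
  corrupt counts.
* **MAF filters**: a variant must pass the internal threshold in *both*
  datasets (failing either removes it from both, keeping the two count
  columns comparable) and, when configured, every external reference
  frequency must pass the external threshold. MAF is only evaluated
  where AN is available. Typical regimes: internal ≤ 1% plus external
  ≤ 1%, or a stricter internal ≤ 0.1% with no external panel.
* **Classification**: functional = the protein-altering Sequence
  Ontology set (missense, nonsense, frameshift, canonical splice,
  in-frame indels, protein-altering, initiator/stop loss); proxy is one
  of three nested definitions — synonymous only (SYN), Ensembl
  low-impact (LOW), or everything non-functional (NOT_FUNC). Functional
  terms win when a variant carries both.
* **Gene thresholds**: a gene is kept only if its functional total
  (x₁f + x₀f) *and* its proxy total (x₁p + x₀p) each reach `min_alleles`
  (default 5; 10 and 20 supported).
* The external-frequency filter is applied before aggregation; filter
  input/output record counts are logged.

## Simulation engine

Each gene contributes four independent Poisson (or NB) draws with means
baseline_rate × gene_length_kb × N_group × multipliers. Defaults are the
baseline study conditions: 0.001 minor alleles per subject per kb, 20 kb
genes, 1,000 cases and 1,000 controls, 20,000 genes. Multiplier
placement encodes the confounding taxonomy:

* association (effect 1.2–3): case functional mean only, associated
  genes only;
* case-control confounding (1.1–1.5): both case classes, genome-wide —
  a technology difference is agnostic to predicted function;
* gene confounding (1.2–2): both classes of a confounded gene, in both
  groups or in cases only.

Genes are allocated across the four association × gene-confounding
states; by default the allocation splits equally over the states a
scenario's multipliers actually activate (configurable). Type-I error is
the rejection fraction among non-associated genes and power among
associated genes, both with exact Clopper-Pearson 95% intervals, at the
raw or 0.9-adjusted threshold. All draws come from a single seeded
generator filling whole arrays, so results are reproducible cell-by-cell
from one seed; control-size sweeps offset the seed per grid point.

This generator reproduces the mechanism the tests assume (independent
per-class count noise with multiplicative technology effects). It does
not emulate linkage between variants, shared samples across genes,
ancestry mismatch, or annotation error correlated with the functional
split — so calibrated behaviour here shows robustness to count-level
confounding, not to population-structure artifacts, which real analyses
must still control by ancestry matching.

Problem sizes used by the default experiments and tests (20,000 genes
per scenario, 10,000 replicates per binomial model) keep every
experiment in the seconds range while giving Monte-Carlo standard errors
of ~0.0015 on a 0.05 rejection rate.

## Poisson-fit diagnostics

Per-gene totals are sums over k variants of binomial minor-allele counts
on 2n chromosomes. Under Hardy-Weinberg equilibrium, genotype-level
sampling (multinomial over the three genotype classes, counting
2×hom + het) is distributionally identical to the allele-level
Binomial(2n, MAF) draw, so the cheaper allele-level path is the default
and the genotype-level path is kept behind a flag as a fidelity check.
Across the diagnostic grid (MAF 1e-4–5e-3, n 1e3/1e4, k 5–20) the
variance/mean ratio stays at 1 − MAF ≈ 1: binomial-per-variant totals
are never over-dispersed relative to Poisson, supporting the Poisson
count model for rare variation.

Distribution fit is quantified by total-variation distance between the
empirical mass function and the matched Poisson (support truncated where
Poisson mass < 1e-12, tail mass folded in). Note that at a fixed
replicate count the empirical TV carries a sampling-noise floor that
*grows* with the width of the support, i.e. with the expected total;
comparisons of TV across scenarios with very different means mostly
reflect that floor, which is why the moment (variance/mean) check, not
TV, is the headline no-overdispersion assertion. QQ summaries use
−log₁₀ expected quantiles i/(n+1), a pointwise 95% band from the
Beta(i, n+1−i) law of uniform order statistics, and the inflation factor
λ; the band is pointwise, so the covered fraction of one genome scan is
itself random — on average 95%.

## Numerical conventions

* 0·ln 0 := 0 throughout; deviances are clamped at 0 against float
  round-off; G = 0 exactly when the observed ratios satisfy the null.
* Constraint residual tolerance for accepting externally supplied null
  estimates: 1e-6 relative; identities of the closed form hold to 1e-10.
* NB golden-section: fixed 120 iterations (no data-dependent stopping),
  bracket log ρ̂ ± 15.
* P-values are written in scientific notation with 6 significant digits;
  other floats with 12 digits (lossless round trip at that precision).
* Clopper-Pearson intervals via Beta quantiles, with exact endpoints at
  0 and n successes.

## Known limitations

* No covariate adjustment (sex, ancestry principal components): cases
  and external controls must be ancestry-matched upstream.
* External and internal controls cannot be combined in a single test.
* Gene-region only; no single-variant testing.
* η for the over-dispersed test must be supplied, and its χ²₁
  calibration is only approximate at small effective counts (see the
  calibration caveat above).
* The aggregation layer consumes consequence annotations as given;
  annotation versioning, region intersection and sample-level QC are out
  of scope.
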