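# Methods

## Setting

`targetmr` estimates the genetically mimicked effect of pharmacologically
modulating a drug target from GWAS summary statistics alone.  Variants in or
near the gene encoding the target that robustly associate with the drug's
biomarker (e.g. LDL-cholesterol for lipid-lowering targets) serve as
instrumental variables; their associations with downstream outcomes, scaled
by their associations with the biomarker, estimate what a drug acting on
that target would do.  The package implements the four analysis stages such
studies use — a mortality/lifespan estimate, a panel of a-priori outcomes,
a phenome-wide scan, and colocalization of each finding — plus a synthetic
summary-statistics generator so that every stage has a recovery test with
known truth.

## Instrument selection

Candidates are restricted to the gene body ± a cis flank (default 1 Mb),
minor-allele frequency strictly above 1% (always derived from the
effect-allele frequency, never trusted from a separate column), and
two-sided p strictly below 5×10⁻⁸.  Greedy clumping walks candidates in
ascending p (ties: larger |β|/se, then variant ID — needed because
simulated p-values can tie) and keeps a variant iff its LD r² with every
kept variant is below 0.001.  The output is therefore pairwise independent
at the ceiling and invariant to input row order.  Named published SNP lists
are accepted as an alternative, with LD-proxy lookup (r² > 0.8) for
missing variants.  Instrument strength is screened by the single-SNP
approximation F = (β/se)²; F ≤ 10 flags potential weak-instrument bias but
does not drop the variant.

## Harmonization

Variants are matched by rsID only (coordinates are carried as opaque
1-based metadata; no liftover).  Outcome records with the swapped allele
pair have β negated and EAF reflected; strand flips are resolved by
complementing alleles before the swap test; indels match by exact string
only.  Palindromic (A/T, C/G) variants cannot be strand-resolved from
labels, so the default policy drops them when MAF > 0.42 in either dataset
and otherwise aligns by frequency side; a `drop`-all policy is available
because upstream conventions vary.  Every rejected row and dropped variant
is counted and logged.

When an instrument is missing from the outcome GWAS and an LD matrix is
supplied, the best proxy with r² > 0.8 substitutes for it.  If the proxy is
present in the exposure GWAS too, both sides are substituted — the Wald
ratio then remains unbiased, because numerator and denominator attenuate by
the same factor r — otherwise only the outcome side is substituted (β
negated when r < 0), which attenuates the ratio by at most r.  Ties in r²
break by genomic distance, then ID.

## Causal estimation

* **Wald ratio** β̂ = β_out/β_exp with the first-order delta-method SE
  se_out/|β_exp| (exposure-side noise neglected; appropriate for the strong
  instruments the F screen enforces).
* **IVW**: weights 1/se²; fixed effects for ≤3 instruments, multiplicative
  random effects for ≥4 (SE inflated by max(1, √(Q/(k−1))) with Cochran's
  Q), matching the common convention for small correlated-instrument sets;
  the switch is overridable and Q is always reported.  An additive
  (DerSimonian–Laird) variant was deliberately not implemented; the
  multiplicative form is the one matching the fixed/random switch rule used
  here.
* **Correlated instruments**: generalized least squares through the origin
  with Ω_ij = se_i·se_j·ρ_ij.  With ρ = I this reproduces fixed-effects IVW
  exactly (tested to 10 significant digits).  A singular Ω (e.g. duplicated
  variants) is ridged by escalating diagonal jitter (ε up to 10⁻⁶ of the
  mean diagonal) before raising.
* **Scaling**: estimates are reported per SD *decrease* of the biomarker via
  an explicit sign convention (never an implicit negation); lifespan effects
  on the log-protection-ratio scale are multiplied by 10 to approximate life
  years.  Binary outcomes analysed by linear regression are mapped to log
  odds by dividing β and SE by μ(1−μ), μ being the case fraction; the
  divisor is isolated in one function should a frequency-dependent
  refinement ever be wanted.  Confidence intervals use the exact normal
  0.975 quantile.
* **Contrasts** (between drugs, between sexes) use the two-sided z-test
  z = (β₁−β₂)/√(se₁²+se₂²), whose value is invariant to common rescaling.

## Colocalization

Per-variant evidence is Wakefield's log approximate Bayes factor
lABF = ½(log(1−r) + rZ²) with r = w/(se²+w); prior effect variances default
to (0.2·sd_Y)² for quantitative traits and 0.15² on the log-odds scale for
binary traits (linear-scale binary inputs are converted first; the
conversion is logged).  Assuming at most one causal variant per trait,
enumeration over configurations gives hypotheses H0–H4; all sums use
log-sum-exp, and the H3 term log(exp(L1+L2) − exp(L12)) is evaluated with
log1p, clamping negative round-off to −∞ (exactly −∞ for single-variant
regions, where H3 is impossible).  Default priors are p1 = p2 = 1e-4 and
p12 = 1e-5 per variant, with a sensitivity grid (default adds 1e-6) that
reuses the lABFs.  Two summaries accompany PP0–PP4: the conditional
probability PP4/(PP3+PP4) — shared variant given the outcome has a causal
variant in the region, useful when outcome power is low — and the
per-variant shared-signal posterior softmax(lABF1+lABF2), whose argmax is
the reported top shared variant.  The phrase "conditional on a variant
associated with the outcome" could also be read as conditioning on
{H2,H3,H4}; the PP4/(PP3+PP4) convention is used, and either number can be
recomputed from the emitted PP table.  The analysis window is the gene body
± 100 kb, inclusive.

## Phenome-wide scan

The catalog filter applies rules in a fixed order — duplicates, excluded
categories, availability, then thresholds (binary: ≥100 cases; continuous/
ordinal: ≥10,000 samples; thresholds strict, boundaries included) — and
each phenotype is charged to the first rule it violates, so per-rule counts
add up flowchart-style.  Each surviving phenotype gets a Wald/IVW estimate
per SD decrease of the exposure, binary phenotypes pass through the OR
transformation, and BH-FDR (step-up; q-values are the standard running
minima) is applied across each scan separately — one family per sex
stratum, pooling binary and continuous phenotypes, which follows from
correcting each reported scan as a unit.  Results plus skip logs conserve
the filtered catalog count.

## Synthetic data generator

The generator works at the summary-statistics level.  For a region of m
variants with LD correlation R (AR(1), r_ij = ρ^|i−j|, positive definite
for ρ < 1) and joint causal effects b on standardized genotypes, the
marginal truth is R·b and one GWAS's observed betas are a single draw from
MVN(R·b, σ²R/n) with SE σ/√n — σ² = 1 for standardized quantitative traits,
μ(1−μ) for binary traits on the linear scale (binary causal effects are
specified as log odds ratios and planted as α·μ(1−μ)).  An
allele-frequency-scaled SE mode (σ/√(2nf(1−f))) exists for I/O realism.
Scaffolds (IDs, positions, alleles, EAF) can be pinned by a separate
`scaffold_seed` so multiple traits share one region.  Default conditions
follow the regimes the estimators are meant for: GWAS n of 5×10⁴–10⁵,
AR(1) ρ = 0.9 in cis regions, causal effects of 0.05 SD for regional
signals, two-sample MR with five instruments of 0.08–0.15 SD, phenomes of
2,000 phenotypes with 90% exact nulls and alternative effects N(0, 0.02²)
on the marginal scale at n = 10⁵ (half binary with μ = 0.1).

What the generator does *not* emulate: individual-level genotypes,
population structure, sample overlap between exposure and outcome GWAS,
non-normal phenotype distributions, and realistic UK-Biobank-style
phenotype correlation across the phenome.  Passing tests therefore
demonstrate estimator correctness and calibration under the stated
two-sample summary-statistics model, not robustness to those real-data
complications.

## Numerical choices and degenerate inputs

p-values are floored at 10⁻³²⁰ to stay in (0,1] under underflow; read-time
validation checks p against |β/se| within one order of magnitude (source
GWAS may use t references or rounded values).  LD matrices are validated
for symmetry, unit diagonal, |r| ≤ 1 and PSD to 10⁻⁶.  A Wald ratio with
β_exp = 0 raises; empty harmonized overlap raises; BH on an empty vector
returns empty; conditional coloc probability is flagged missing (None) when
PP3+PP4 = 0.  The full pipeline contains no randomness of its own, so a
rerun with identical inputs and seed is byte-identical; the config
fingerprint hashes the scientific configuration but not the output
location.

## Problem sizes used in validation

The test suite runs the statistical checks at: 1,000 random instances for
the GLS/IVW equivalence; 500 random regions (m ≤ 12) against the
enumeration oracle; 1,000 replicates for 95% CI coverage at θ = 0.3, k = 5,
n = 10⁵; 200 + 200 replicates for colocalization calibration (m = 50,
ρ = 0.9, n = 5×10⁴, effect 0.05 SD); 200 seeds × 2,000 phenotypes for FDR
control.  The acceptance script repeats the FDR experiment from scratch.

## Known limitations

Single-causal-variant colocalization only (no SuSiE-style multi-causal
decomposition); no MR-Egger or weighted-median estimators (their
assumptions fail for the correlated cis instrument sets this package
targets); no LD computation from genotypes and no remote proxy services;
the OR transformation is the μ(1−μ) first-order approximation and degrades
for rare variants with large effects.
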