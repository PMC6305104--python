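# Methods

## Design and models

`mirpair` analyzes paired carcinoma / normal-mucosa expression: every subject
contributes one sample of each tissue, and all inference is within-subject.
Three statistical components do the work.

### Paired negative-binomial differential expression

For gene *g* and subject *i* with tissue *t* ∈ {normal, carcinoma}, counts are
modeled as

    y_it ~ NB(μ_it, θ),   log μ_it = β₀ + β_t·[t = carcinoma] + u_i + log N_it

with a per-subject random intercept u_i ~ N(0, σ_u²), a per-gene NB size θ
(variance μ + μ²/θ, no shrinkage across genes), and the sample's total count
over the protein-coding gene universe N_it as exposure offset. The marginal
likelihood integrates u_i by Gauss–Hermite quadrature (default 25 nodes) and
is maximized by L-BFGS-B over (β₀, β_t, log θ, log σ_u), with a Nelder–Mead
restart when the line search degenerates (this happens in the Poisson limit,
where θ runs to its bound on a nearly flat likelihood). The test of β_t = 0 is
a likelihood-ratio test by default; a Wald test (numerical Hessian) is
available — at low counts the LRT is the more stable of the two, which is why
it is the default. A fixed-effects fallback (`method="fixed"`, one intercept
per subject via statsmodels NB regression) is provided for very small data
where σ_u is weakly identified; the two methods are compared on simulated data
in the test suite, and the quadrature fit is cross-checked against R's
glmmTMB, which agrees on β_t to ~1e-6 on a shared dataset.

Note that because the offset is the *realized* protein-coding total, the model
measures relative abundance: an effect shared by every gene in the denominator
is absorbed into the offset and is by construction undetectable. Simulated
power or recovery studies must therefore plant effects in a small fraction of
the gene universe, as real pathway effects are against a ~17k-gene background.

Reported fold changes are ratios of arithmetic mean RPMPCG values
(carcinoma / normal), not exp(β_t): that is the convention of the reference
tables the package reproduces, verified row-by-row in the acceptance suite.
The reporting gate keeps genes with adjusted p ≤ 0.05 (Benjamini–Hochberg
within one analysis) and FC > 1.50 or FC < 0.67, both FC inequalities strict.
The FDR threshold is inclusive because the reference analysis admits adjusted
p printed exactly at 0.050. MSS/MSI strata rerun the identical analysis on
subject subsets; stratum-unique genes are the set difference against the
overall pass list.

### Normalization

* **RPMPCG** (reads per million protein-coding genes):
  value = 1e6 · count / (sample total over the protein-coding universe). The
  denominator always uses the full universe even when only a pathway subset is
  reported.
* **Q75 scaling** for array signals: each sample is multiplied by
  median(P75 of all samples) / (its own P75). Idempotent, and exactly undoes a
  single sample's multiplicative distortion. The percentile interpolation
  convention is configurable (default: linear, over all probes) because the
  array vendor's exact convention is not published.
* **Prevalence filters**: "expressed" means strictly > 0 (counts and signals
  are non-negative and no floor is given); retention requires expression in
  strictly more than `min_fraction` of the reference samples. Defaults: miRNAs
  20% of normal-mucosa samples; mRNAs 50% of all samples ("majority", the
  exact number being unstated, is exposed as configuration).

### Bootstrap-calibrated association

Per-subject differentials d = (carcinoma − normal) for each feature feed the
per-pair model d_mrna ~ 1 + d_mirna + age + sex, compared with the null model
without d_mirna by the extra-sum-of-squares F (1 numerator df). The p-value is
a residual bootstrap under the null: y\* = null fitted values + resampled null
residuals, both models refit B times (default B = 10,000), and
p = (1 + #{F\* ≥ F_obs}) / (B + 1) — never zero, ties counted conservatively.
Covariates stay in the bootstrap's null model ("no association" means no
miRNA term, not no covariates). Refits reuse the QR decompositions of the
fixed design matrices; the test suite verifies this is numerically identical
to naive per-resample refitting, and that p agrees with the parametric F
p-value within ±0.02 under Gaussian errors. Degenerate perfect fits
(residual SS ≈ 0 relative to ‖y‖²) are assigned F = ∞ and p = 1/(B+1).

The primary reported slope `beta_std` is the slope after z-scoring both
differentials (a correlation-scale quantity, matching the magnitude range of
the reference table's coefficients); the raw-scale slope is retained. BH
adjustment is applied within each gene's family of miRNA tests. Admission to
the interaction table requires gene-level q ≤ 0.05; the miRNA fold-change
reporting filter (> 1.50 or < 0.67) applies at reporting, not testing, so FDR
families are unaffected by it.

### Seed matching

Sites are exact Watson–Crick reverse complements of the miRNA 5' seed on the
UTR sense strand; no wobble, mismatches, or context scoring. Two conventions
ship because "the first six to eight nucleotides" is ambiguous relative to the
field-standard position-2 seed: `literal` (positions 1–6/1–7/1–8; default) and
`canonical` (6mer, 7mer-m8, 7mer-A1, 8mer with the A1 adenine anchor). Within
a convention, site types are tiered longest-first and a lower-tier call at the
same anchor (the UTR position of the 6-nt core) is suppressed, so one planted
8-nt site yields exactly one call. The gene-level flag ORs over all isoforms
and assemblies. Scanning is checked against a naive all-offsets oracle.

## Synthetic data

The generator emulates the targeted study: 217 subjects by default, ages
N(64.8, 10.1), 54.4% male, 13.4% MSI; NB counts with subject random intercept
and uniform library sizes (0.8–1.2M); array signals with log-normal baselines
and per-sample multiplicative distortions in [0.5, 2]. Dispersion (θ = 5) and
library-size spread are not reported by any cohort and are stated defaults,
not cohort estimates. For a planted pair (g, m, β) the miRNA's subject-level
differential is scale·(β·z_g + noise_sd·ε) with z_g the z-scored RPMPCG
differential of the gene, so with noise_sd = √(1−β²) the population
standardized slope equals β exactly. Signals stay non-negative by lifting the
normal-tissue baseline by max(0, −d) instead of clipping: clipping would
attenuate planted slopes and distort null calibration.

Planted miRNAs additionally receive a tumor-level mean shift
(`mirna_tumor_shift`, default 1.5 in units of the differential scale) so that,
like every reported associated miRNA, they are themselves differentially
expressed and survive the fold-change reporting filter. A consequence worth
knowing: global-scaling normalizations such as Q75 assume most features are
not differential. If a large fraction of the catalog carries the tumor shift,
the scaling absorbs real biology and attenuates planted slopes — so
simulation studies here keep planted miRNAs a small fraction of the catalog
(the regime real cohorts are in, e.g. tens of differential miRNAs among
hundreds tested).

Planted UTR sites are written as exact site patterns at recorded positions.
"Clean" backgrounds (no site for any catalog miRNA anywhere but the planted
windows) cannot be produced by whole-sequence rejection sampling — a 2 kb
sequence avoids ~150 six-nt patterns with probability ≈ e⁻²⁴ — so the
generator instead repairs the background: each spurious hit gets one random
base inside it (outside planted windows) mutated, re-scanning until clean.
The companion "clean-compatible" catalog draw rejects miRNA sequences whose
site patterns embed another catalog miRNA's pattern, since such a planted
site would legitimately contain a second site and zero-extra-call ground
truth would be unattainable.

What the generator does **not** emulate: probe-level array noise, FFPE
degradation, realistic UTR composition or conservation, per-gene correlation
structure, or library-preparation batch effects. Passing tests demonstrate
that the pipeline's algorithms are correct and calibrated under the stated
model, not that the model captures every property of real cohort data.

## Numerical and reproducibility choices

* One root seed per simulation; four fixed substreams (counts, signals, UTRs,
  metadata) via `SeedSequence` spawn keys, so any stage regenerates
  identically in isolation.
* Per-pair bootstrap streams are derived from the pair's rank in the sorted
  pair list: association results are independent of input ordering.
* Censored printed p-values ("<0.001") parse to their printed bound; this
  only ever matters for threshold comparisons far from 0.05.
* All-zero genes return p = 1 (flagged); non-convergent fits are flagged and
  excluded from the BH family with a warning.
* Site tables sort by (gene, miRNA, position); network exports sort nodes and
  edges, so re-export is byte-identical.

## Problem sizes used in checks

Stochastic checks state their study conditions up front: bootstrap null
calibration uses 1,000 tests at n = 200 subjects and B = 999 (binomial 95%
band 0.037–0.064 around α = 0.05); NB recovery plants log(3.70) in 5 of 400
genes at n = 200 pairs (±10%); association sign recovery plants 40 pairs at
|β| = 0.3, n = 200 (≥ 95%); the DE type-I property uses 400 null genes at 40
pairs; the seed-scan exactness study uses 50 miRNAs × 100 clean 2 kb UTRs
with 100 planted sites (recall 1.0, zero extra calls, exact agreement with
the all-offsets oracle).

## Known limitations

* No moderated dispersion estimation; low-count genes rely on per-gene ML.
* The NB GLMM uses non-adaptive quadrature; extreme σ_u with very low counts
  may need more nodes (`n_quad`).
* Cohort-level p-values of the original study are not reproducible from the
  packaged summaries — raw data were never deposited — so cohort claims are
  validated through the printed tables plus the property/calibration suite.
* The miRNA fold-change reporting filter assumes normalized signals; applying
  it to raw signals would mix in the array distortions.
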