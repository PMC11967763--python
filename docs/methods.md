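# Methods

## Copy-number similarity

For a matched tumor–organoid pair the per-gene allele-specific copy states
(cnA ≥ cnB ≥ 0, major/minor allele) are compared by Euclidean distance
d = ‖(cnAₜ, cnBₜ) − (cnAₒ, cnBₒ)‖.  Distances are min–max normalized *within
the pair, across its genes* — normalizing across a cohort would make one
pair's score depend on unrelated samples — and similarity is s = 1 − d′.
The pair-level summary is the arithmetic mean of per-gene s (median available
via `summary="median"`).

Degenerate case: when max(d) = min(d) (identical profiles, or a perfectly
uniform offset) the normalization is undefined.  The package sets s = 1 for
every gene and flags the result (`SimilarityResult.degenerate`).  Rationale:
under a within-pair normalization such a pair carries no internal
dissimilarity signal, and the identical-profile case must score 1; users
comparing degenerate and non-degenerate pairs should heed the flag.  A
consequence worth knowing: the score is relative within a pair, so any
non-degenerate pair has at least one gene at s = 0 and one at s = 1.

## Variant concordance

Variant identity is (chrom, pos, ref, alt), 1-based, matching VCF.  The
confident-variant filter keeps VAF strictly greater than 0.05; upstream
panel-of-normals or population-database filtering is assumed already applied
to the input tables.  The shared / tumor-private / organoid-private partition
is plain set arithmetic over keys, with proportions over the union.

Corrected allelic fraction is min(1, VAF/purity), a pure
dilution-by-normal-cells correction under which a clonal heterozygous variant
in a diploid region reads ≈ 0.5.  A fuller correction would also use local
copy number; purity-only is a stated convention of this package, and
downstream comparisons inherit it.

Shared vs private corrected AFs are compared with a two-sided Mann–Whitney
rank-sum test: exact null distribution when the combined n ≤ 12 and there are
no ties, normal approximation with tie correction otherwise.

## Single-dose screen

Replicate z-scores use the matched vehicle's sample mean and SD (ddof = 1
everywhere): z = (Xₛ − X̄ᵥ)/SDᵥ.  Drugs dissolved in water (cisplatin,
carboplatin, 5-FU) are normalized against H₂O wells, everything else against
DMSO.  Fold-change is computed on raw signals, FC = mean(drug)/mean(vehicle).

Z-factor: Z′ = 1 − 3(SD_pos + SD_neg)/|mean_pos − mean_neg| with
staurosporine as positive control.  The absolute mean difference keeps the
standard Z′ semantics (≤ 1, larger is better) regardless of which control
reads higher; a signed denominator would produce Z′ > 1 nonsense when the
positive control is the lower signal.  With two vehicle labels on a plate the
negative control defaults to all vehicle wells pooled; a per-label Z′ is
available through the `vehicle` argument.

Dunnett many-to-one comparisons run on raw signals, one family per vehicle
label (z-scaling is a per-specimen affine transform of the same comparison,
so the test is identical either way; raw is the default and the alternative
is a caller-side choice of inputs).  Adjusted p-values come from
`scipy.stats.dunnett` with a fixed internal seed for its multivariate-t
integration, giving reproducible values with ≤ 1e-3 jitter relative to exact
quadrature.  A single-drug family is special-cased to the pooled-variance
two-sample t-test, the exact k = 1 limit of Dunnett's procedure.

Sensitivity call: z̄ ≤ −1.5 AND p_adj < 0.05 AND 1 − FC > 0.5, with the
*mean* replicate z-score compared to the cutoff.  The conjunction is stricter
than any single criterion; on null plates the empirical call rate is ≈ 0.

## Dose-response

The curve family is the fixed-slope normalized-response log-logistic
Y = 100/(1 + 10^(X − logIC50)), X in log₁₀ molar: top 100, bottom 0, unit
Hill slope, one free parameter.  Fitting is least squares via a 241-point
grid over the tested X range ± 2 logs followed by bounded scalar minimization
(xatol 1e-10); this is immune to the saddle/plateau failures multi-parameter
starts suffer and recovers noiseless logIC50 to < 1e-6.  A variable-slope
variant (free Hill coefficient, started from the fixed-slope optimum) sits
behind `variable_slope=True`.

Normalized AUC is the mean normalized viability over the tested
log-concentration window: trapezoidal area of viability clipped to [0, 100]
over [Xmin, Xmax], divided by 100·(Xmax − Xmin).  This makes 0.5 the
"half-maximal average viability" boundary used for the sensitive (< 0.5) /
resistant (≥ 0.5) split, with the boundary itself classed resistant.  By
default the integrand is the observed points with replicates averaged per
concentration; integrating the fitted curve instead is supported
(`normalized_auc(fit=..., x_range=...)`) and agrees closely on well-sampled
series.  Fixed-ratio combinations are validated for a constant ratio and fit
as a single agent on the first component's concentration axis; no
synergy scoring is attempted.

## Mixed-model association

The mutation–drug model is z_ij = β₀ + β₁x_i + u_i + ε_ij with a per-sample
random intercept u_i ~ N(0, τ²), fit by **maximum likelihood** (not REML) so
the full and null (β₁ dropped) log-likelihoods are comparable; p-values come
from the LRT statistic 2(ℓ_full − ℓ_null) on χ²₁.  β₁ is in z-score units
per mutated status.

Numerical care: quasi-Newton optimizers occasionally stall on the τ² = 0
boundary below the interior maximum, which would inflate the LRT.  `fit_lmm`
therefore maximizes over two optimizers (BFGS, then Powell) and additionally
guards each model with the exact boundary solution (OLS with the ML variance
estimate), taking whichever likelihood is highest.  With this scheme the
p-values reproduce R lme4's ML likelihood-ratio test to < 2e-8 across
hundreds of simulated designs.

Known limitation: with ~10 samples the χ²₁ reference is anticonservative —
the empirical null rejection rate at α = 0.05 is ≈ 0.08 for 10 samples × 3
replicates (τ = 0.5, σ = 1), for this package and for lme4 alike.  This is a
property of the asymptotic LRT at small sample counts, not of the
implementation; interpret borderline p-values accordingly.  No
multiple-testing correction is applied across the (gene, drug) matrix by
default (Benjamini–Hochberg behind `bh_adjust=True`); pairs with fewer than
two samples per mutation class are reported as not-testable rather than
dropped.  The balanced-design identity β̂₁ = mean(z|x=1) − mean(z|x=0) is
exercised by tests.

The pathway–drug model is OLS of a per-sample pathway activity score (e.g.
ssGSEA, consumed as input) on the sample's normalized AUC; the slope is
reported under the conventional heatmap label "OR" with its t-test p-value.

## Synthetic data: what it emulates and what it does not

Defaults are the study conditions: 74.7 % shared deleterious SNVs, ≥ 3 drug
replicates at Cmax with ~10 % assay CV, 12-sample × 3-replicate association
designs, 80 % copy-event inheritance with a 5 % private-event rate.

* **Copy profiles**: tumors start diploid and receive gain/loss events on
  contiguous gene blocks (geometric lengths, mean 5 genes), mirroring
  segmental CNVs; organoids inherit each event independently with probability
  `shared_event_fraction` and gain Poisson-distributed private events.
* **Variants**: shared loci are clonal with allelic fractions
  Beta-distributed around purity/2 (heterozygous-diploid approximation,
  concentration 50); private loci are subclonal around purity/6.  No
  published AF model exists for this design; these centers are conventions
  chosen so shared AFs stochastically dominate private ones, which real
  tumor/organoid pairs show.  Private loci split evenly between tumor-private
  and organoid-private; deleterious flags are Bernoulli(0.7).
* **Plates**: vehicle wells fluctuate around a 1000-AU baseline with
  multiplicative Gaussian noise, drug wells around baseline × (1 − effect),
  staurosporine at 2 % of baseline; signals truncate at 0.  No spatial/edge
  effects, no plate drift.
* **Dose-response**: the generating curve is exactly the fitted family plus
  multiplicative noise, so noiseless recovery is exact by construction and
  noisy recovery measures optimizer robustness, not model misspecification.
* **Association**: exactly the random-intercept generating process.

Because generators and models share their functional families, passing tests
demonstrate correct implementation and statistical calibration — not
robustness to the model misspecification, batch effects, or caller error
profiles of real data.

All randomness flows from one `numpy.random.default_rng(seed)` per generator
call; fixed configs give byte-identical outputs and no global state is
touched.

## Pipeline and formats

TSV/CSV interchange: UTF-8, mandatory header, '.' decimal, no index column;
'#'-prefixed comment lines stamp every output with the analytic config hash
(seed, thresholds, vehicle map, simulation parameters — file paths excluded
so relocated runs hash equal) and the seed.  VCF is read-only via cyvcf2,
taking AF from INFO or FORMAT under a configurable key.  The CLI
(`pdoconcord simulate|concordance|screen|dose|associate|run`) is a thin layer
over `run_pipeline`, which validates stage dependencies before doing any work
and writes a JSON manifest per invocation.

## Validation problem sizes

The release gates in `tests/test_acceptance.py` and `scripts/acceptance.py`
use: 100 random 50-gene pairs for similarity-oracle agreement (1e-12); 200
cohorts for the concordance mirror; 1000 loci × 100 cohorts for variant
recovery; 1000 null plates + 500 effect plates for screen calibration and
power; 200 noisy fits for logIC50 recovery; 1000 null + 500 effect cohorts
for the mixed model.  These sizes put Monte-Carlo error well inside each
asserted band while keeping the full suite to a few minutes on one CPU.
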