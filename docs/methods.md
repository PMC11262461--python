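# Methods

## Model

For one ligand–receptor (LR) pair, the response is the pairwise
communication score C_ij = L_i · R_j over all ordered unit pairs (i, j) with
Euclidean distance D_ij ≤ dmax, self pairs included (autocrine signaling,
D = 0, decay weight 1). L and R are the ligand/receptor expression values at
the sender and receiver unit; multi-subunit complexes are combined by the
elementwise minimum over subunits by default (a conservative
all-subunits-required rule; a geometric-mean option exists). The mean model
is

    log E(C_ij) = β₀ + exp(−ρ D_ij) Σ_{g₁,g₂} β_{g₁g₂} M_{i,g₁} M_{j,g₂}
                  + ν_L(grid(i)) + ν_R(grid(j)),

with M the units × types composition matrix (rows sum to 1; one-hot at
single-cell resolution) and G² directed interaction coefficients per pair.
The design matrix orders interaction columns sender-major; with one-hot
composition each row has exactly one nonzero interaction entry equal to the
decay weight, and with mixed composition the interaction block of a row sums
to the decay weight.

C_ij is sparse with continuous positive values, so the emission law is the
compound Poisson–Gamma (Tweedie) family with power index p ∈ (1, 2):
variance φ μ^p, exact point mass exp(−λ) at zero with
λ = μ^{2−p}/(φ(2−p)). The two random-intercept blocks are bucketed on a
rectangular spatial grid rather than per unit, cutting the random-effect
dimension from 2N to 2·Ngrid; the default grid targets ≈25 units per
rectangle (n_x = n_y = max(2, round(√(N/25)))), user-overridable.

## Fitting

Estimation maximizes the penalized log-quasi-likelihood

    −½ Σ d(y, μ; p) − ½ λ_L ‖ν_L‖² − ½ λ_R ‖ν_R‖²,

where d is the Tweedie unit deviance; the penalty matrices are identities
and the fixed effects (intercept + interactions) are unpenalized. The solver
is penalized IRLS with log link: weights μ^{2−p}, working response
η + (y−μ)/μ, normal equations (CᵀWC + S_λ)θ = CᵀWz, with step-halving on
the penalized deviance. Starting values μ⁰ = y + mean(y)/10 guard exact
zeros. Convergence requires both a relative deviance change < 1e-8 and a
relative coefficient move < 1e-7 (flat penalized directions keep moving long
after the deviance stabilizes; the second criterion is what makes the solver
agree with a generic optimizer to 1e-4 sup-norm), capped at 200 iterations;
non-converged fits return the best iterate flagged `converged=False`.

A note on the penalty convention: writing the ridge penalty as λνᵀSν versus
½λνᵀSν only rescales λ by 2, which the GCV selection absorbs; the package
uses the ½-convention so that S_λ in the normal equations carries λ itself.

Exact collinearity in the fixed block is detected by sequential QR (a
near-zero diagonal of R flags a column dependent on its predecessors) and
dependent columns are dropped, reported as NaN coefficients. This matters at
ρ = 0, where the interaction columns sum exactly to the intercept.

- **Smoothing (λ_L, λ_R):** GCV = n·D/(n − edf)², minimized over a 7×7
  log-spaced grid on [1e−3, 1e3] with warm-started fits, then a local
  Nelder–Mead refinement in log10 space (≤40 evaluations). edf is the trace
  of the influence matrix of the final weighted penalized least-squares
  step.
- **Power index p:** profiled over {1.1, …, 1.9} at the selected smoothing;
  each candidate is refit and scored by the exact series log-likelihood at
  the fitted means and Pearson dispersion. Near-ties resolve toward 1.5; a
  flat profile (e.g. a perfectly fitted constant response, where the Pearson
  dispersion collapses to 0) returns 1.5. Grid profiling rather than
  continuous optimization keeps the selection cheap and reproducible; the
  grid resolution (0.1) is far below the precision at which p influences the
  fixed-effect estimates.
- **Dispersion φ:** Pearson estimator Σ(y−μ̂)²/μ̂^p / (n − edf) at
  convergence — stable and conventional, rather than joint maximum
  likelihood.
- **Decay rate ρ:** fixed during fitting; selected by AIC = −2·loglik +
  2·edf over a user-supplied candidate list (ties toward the smallest ρ).
  The series log-likelihood, not the quasi-likelihood, feeds the AIC. When
  no candidates are given, a scale-adaptive default is used: 0 plus the
  rates that reduce the decay weight to {0.75, 0.5, 0.25, 0.1} at the median
  positive pairwise distance.
- **Tweedie density:** for y > 0 the series is summed in log space around
  its dominant index n* = y^{2−p}/(φ(2−p)), extending the range until the
  tail term is below 1e−12 of the dominant term (cap 10⁴ terms, then a
  diagnostic failure). For y = 0 the point mass is closed-form.

## Inference

Wald z-tests per interaction coefficient use the penalized ("Bayesian")
covariance φ̂ (CᵀWC + S_λ)⁻¹ restricted to the fixed block (default); a
sandwich form φ̂ A⁻¹(CᵀWC)A⁻¹ is available via `FitConfig.cov_type`. The
intercept is reported but never tested. Benjamini–Hochberg adjustment is
applied across the entire emitted table (all LR pairs × all type pairs, one
family) by default; per-pair adjustment is a config option. Non-converged
pairs stay in the table flagged rather than silently dropped.

Pathway-level inference pools responses over the pathway's LR pairs on the
identical spatial pair set (C_ij = Σ_k C_ijk) and sends the pooled
pseudo-pair through the same fit path, re-selecting ρ for the pooled
response (self-contained, rather than reusing per-pair selections).

## Synthetic data

The generator draws coordinates (uniform square or lattice, default 10×10
field), composition (one-hot with uniform type frequencies, or Dirichlet
with concentration 1 for spots), grid-level normal random intercepts
(sd 0.2 each side by default; optionally unit-level to stress the grid
approximation), and then pairwise scores directly from the mean model above
with compound Poisson–Gamma emission (Poisson count of Gamma jumps — exact,
no approximation). Defaults plant a single positive channel
β(type1→type2) = 1.5 with β₀ = −1, ρ = 0.5, p = 1.5, φ = 0.5, N = 300 and
dmax = 1.4 (≈5000 ordered pairs) — sizes at which a desk machine fits the
full pipeline in seconds while the planted effect is comfortably
identifiable.

A structural caveat: a score that is a deterministic product L_i·R_j of
unit-level expression cannot simultaneously carry the non-separable pairwise
mean exp(−ρD)·MᵀBM. The drawn pairwise score table is therefore the exact
ground truth, and the expression matrix is an approximate rank-1 embedding
(ligand value = √(mean score as sender), receptor value = mean score as
receiver / √(overall mean)), so L_i·R_j reproduces the drawn score structure
in expectation but smears the distance decay. Consequences for what tests
show: recovery/calibration studies that fit the drawn scores test the
estimator under a correctly specified model; the end-to-end
expression-level run tests the full pipeline including score construction,
and is asserted only on sign/ranking behavior. Pure-noise genes (constant
mean, Tweedie noise) provide null LR pairs. Real SRT features the generator
does not emulate: spatially structured cell-type domains, library-size
variation, gene–gene correlation, segmentation errors — passing tests say
nothing about robustness to those.

## Simulation studies (shipped harnesses)

`studies.recovery_study` (30 replicates by default) simulates at the default
conditions, runs the full inference path with ρ candidates {0, 0.5, 2}, and
records the planted coefficient's estimate, sign and relative bias plus the
AIC-selected ρ. `studies.null_calibration_study` sets all β = 0 (random
effects retained, N = 200) and pools the G² = 9 Wald p-values per replicate.
Observed behavior at these scales: sign recovery ≈ 100%, median |relative
bias| ≈ 5%, ρ selected correctly in ≥ 90% of replicates, null rejection at
nominal 5% within the exact binomial band, and < 10-point degradation when
the generator uses unit-level instead of grid-level random effects — these
are exactly the quantities `scripts/acceptance.py` recomputes.

## Numerical choices and edge cases

- η is clipped to ±30 inside PIRLS to guard exp overflow in early
  iterations.
- An identically zero response is rejected per pair ("no signal") and the
  pair skipped with a log entry; unmatched genes likewise skip the pair.
- Degenerate bounding-box axes (all x or all y equal) collapse to one grid
  bin with a warning.
- Distance boundary is inclusive (D = dmax kept); pair enumeration uses a
  k-d tree but is contract-equivalent to the O(N²) double loop.
- Duplicate gene symbols are summed on read (preserves signal from
  multi-probe genes); "expressed" in the QC filters means strictly positive.
- The cell filter runs before the gene filter; the gene-prevalence threshold
  is a fraction of the *surviving* cells.

## Known limitations

- Wald inference conditions on the selected ρ, λ and p; selection
  uncertainty is not propagated (the calibration study shows the practical
  effect is small at the shipped scales).
- Isotropic exponential decay only; no anisotropic kernels or ligand
  diffusion modeling.
- Between-condition differential communication is out of scope — fit groups
  separately and contrast downstream.
- The KNN-style evenly-divided-communication variant and spline smooths on
  fixed effects are deliberately not implemented.
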