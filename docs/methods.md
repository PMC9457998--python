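# Methods

## Design construction and coding

`make_bbd` emits the three-factor Box–Behnken design in a fixed canonical
order — factor pairs (1,2), (1,3), (2,3), each pair visiting (−,−), (+,−),
(−,+), (+,+) with the third factor at its centre, followed by the centre
replicates. OLS fits are invariant to run order, so designs recorded in a
different order (such as the bundled case-study table) analyse identically.
Coding is the standard symmetric map x = (X − centre)/half-range with the
centre at the arithmetic midpoint of the low/high levels; with three
symmetric levels this is the only coding consistent with −1/0/+1 labels.
`validate_design` reports (never raises on) column balance, interaction and
linear–quadratic orthogonality, coding consistency and the BBD edge-run
pattern. Only the 3-factor design is supported; other factor counts are
rejected rather than silently generalized.

## Response-surface fitting

Models are ordinary least squares on coded term columns (intercept, linear,
two-factor interaction, pure quadratic), computed through `statsmodels`;
standard errors are the usual √(MSE·(XᵀX)⁻¹) diagonal. A rank-deficient
model matrix raises an error naming the collinear terms (identified by
QR with column pivoting). Coded fits are converted to actual-unit equations
by exact polynomial expansion of the coding substitution, so both forms
predict identically to machine precision — this is tested at 1000 random
points per response.

On a three-factor BBD the linear and interaction estimates have closed
forms: β̂ᵢ = (Σy|xᵢ=+1 − Σy|xᵢ=−1)/8 and β̂ᵢⱼ = (y₊₊+y₋₋−y₊₋−y₋₊)/4, and
they do not change when quadratic terms enter or leave the model. The test
suite uses these contrasts as an independent oracle against the matrix
least-squares path.

**ANOVA.** Per-term sums of squares are Type III (partial): the increase in
residual SS when the term alone is dropped, F-tested against the residual
MS. Sequential (Type I) SS is available as an option. Pure error comes from
replicated design points (the three centre runs in the case study, giving
2 df); lack of fit is the remainder of the residual, F-tested against pure
error. Without replicates the lack-of-fit rows are marked unavailable
rather than raising.

**Fit statistics.** R² = 1 − SSres/SStot; adjusted R² penalises by
parameter count; PRESS uses the leave-one-out leverage identity
Σ(eᵢ/(1−hᵢᵢ))², verified in tests against explicit n-fold refitting;
predicted R² = 1 − PRESS/SStot; CV% = 100·√MSE/ȳ; adequate precision is the
signal-to-noise form (max ŷ − min ŷ)/√(p·MSE/n) over the design points,
which reproduces the case study's published values (17.80 for CIP, 13.81
for COD) and should exceed ~4 for a usable model.

**Model reduction.** Backward elimination refits each round and drops the
hierarchy-respecting term with the largest coefficient p-value above α
(default 0.05, configurable), ties broken toward the higher-order term.
Because null terms survive at roughly the test level, reduction on
near-noiseless synthetic data collapses to the generating model only most
of the time; the tests assert the true effect is never dropped and the
exact collapse happens at the expected rate rather than pinning one seed.

## Case-study term sets

The bundled 15-run study uses the full 10-term quadratic for CIP and COD.
For ENRO two nested models matter: the 9-term set (no C²) under which its
published coefficient table was produced, and the further-reduced
linear + interaction model that generated the published per-run predictions
and the reported optimum. Both are bundled (`DEFAULT_TERM_SETS` versus
`PREDICTION_TERM_SETS`); because of the BBD contrast invariance the linear
and interaction coefficients agree exactly between the two. With the
prediction sets, all 45 published per-run predictions are reproduced within
±1 percentage point. The published CIP coefficient column below its A row
duplicates the COD column (a typographic artefact in the source table and
inconsistent with the raw data); only the independently consistent cells
are pinned in tests. Likewise the published ENRO/COD R²/StdDev/CV triplets
are not mutually consistent with any single fit of the raw table; CIP's
statistics (R² 0.9834, CV 1.63%, mean 76.13, adequate precision 17.80) are
pinned, the others are reported but not asserted.

## Desirability optimization

Each response's prediction maps to d ∈ [0,1] by the Derringer–Suich ramps
(maximize/minimize one-sided, target two-sided, in-range indicator), with
weight exponents shaping the ramp and importance exponents weighting the
geometric mean D. Default bounds are the observed response min/max and all
weights/importances are 1 — the common software defaults for this analysis.
D is maximized by Nelder–Mead from `n_starts` Latin-hypercube seeds
(default 32) inside the cube; candidates are clipped to the cube inside the
objective, so the returned optimum is always feasible, and the whole search
is deterministic given a seed. A 101³ grid search serves as the oracle in
tests on random quadratic surfaces.

On the case study the free search lands at pH 6, OLR 2 and ~75% antibiotic
dose — the reported optimum — with predicted removals 80/83/73% (nearest
integer). The overall desirability there is ≈0.61 under the default goal
settings; the case study's published scalar desirability (0.85) depends on
goal settings that are not recoverable from the printed data, so it is
reported but not asserted anywhere.

## Kinetics

First-order decay C(t) = plateau + (C₀ − plateau)e^{−kt} is fitted by
Levenberg–Marquardt nonlinear least squares (scipy `curve_fit`),
initialized deterministically from a log-linear regression of ln(C −
plateau guess) on t, with the plateau guess min(C) when the plateau is
free and 0 otherwise; values at or below the guess are floored before the
log so initialization never fails, and no random restarts are used. A
constant series or a non-positive fitted rate raises (no decay signal).
Half-life is ln2/k; parameter standard errors come from the covariance of
the fit. The modified-Gompertz option models the remaining concentration
as C(t) = C₀(1 − exp(−exp((k·e/C₀)(λ−t)+1))) — the degraded amount follows
the classic Gompertz sigmoid with amplitude C₀, maximum rate k
(concentration/day) and lag λ (days) — and reports the time at which the
curve crosses C₀/2 as its half-life. Both models report RSS, R² and
adjusted R² so they can be compared on equal data; neither is guaranteed
to dominate the other.

## Synthetic data

`simulate_bbd_responses` adds i.i.d. homoscedastic Gaussian noise to a
known coded polynomial on a BBD — exactly the error structure the
quadratic response model assumes, so zero-noise refits recover coefficients
to 1e−9 (tested). Responses are clipped to [0,100] only on request, to
keep that exactness testable. `simulate_decay` generates plateaued
first-order series with additive Gaussian noise scaled to C₀ (default
daily sampling over a 28-day batch, matching the case-study incubation);
negative draws are floored at 0 and flagged. Default kinetic presets are
the case study's fitted values (C₀ 2270/2242 mg/L, k 0.0958/0.148 day⁻¹,
residual 10/8 mg/L for ENRO/CIP; the source table prints the amplitude and
residual labels swapped, and the presets use the physically consistent
assignment). What the generator does **not** emulate: heteroscedastic or
autocorrelated errors, adsorption/biodegradation partitioning, or any
mechanistic digestion dynamics — so passing recovery tests demonstrate
correctness of the estimators under the assumed error model, not robustness
to real-data violations of it.

Simulation sizes in the test suite (200 replicates for recovery medians,
500 for coverage and SE-band checks, a 101³ grid for the optimizer oracle)
were chosen to make the Monte-Carlo error small relative to the asserted
margins while the whole suite runs in well under a minute.

## Known limitations

* Three factors only; no blocking, no other design families.
* No Box–Cox response transformation (the case-study responses need none)
  and no robust or mixed-model alternatives to OLS.
* Desirability optimization offers no confidence region on the optimum;
  the D landscape is flat in OLR near the case-study optimum at pH −1, so
  the exact OLR coordinate is weakly identified.
* The published ENRO half-life (14 d) is inconsistent with every published
  ENRO rate constant (ln2/0.0958 ≈ 7.2 d); the package computes half-lives
  from fitted rate constants and makes no attempt to reconcile the printed
  value.
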