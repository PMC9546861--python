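# Methods

## Scope and model

`multikin` analyses 1:1 pseudo-first-order binding of multivalent peptide
analytes to a surface-tethered target protein, plus the two orthogonal
solution assays used to cross-check such screens (competitive displacement
and microarray neutralization), and a regression study of how architecture
determines the fitted rates. Avidity is treated *phenomenologically*: each
compound, whatever its valency, is described by one apparent (k_on, k_off)
pair. No configurational-network or multi-site mechanistic model is
attempted; the apparent constants are exactly what a single-exponential
analysis of the real instruments reports.

Concentrations are molar everywhere in memory. CSV files carry nanomolar
columns (`*_nM`) because the assays span mM to pM and a single on-disk unit
with an explicit suffix prevents silent thousand-fold errors.

## Kinetic forward model and fit

Association at analyte concentration C:

    S(t) = A · C/(C + K_D) · (1 − exp(−k_obs·t)),   k_obs = k_on·C + k_off

Dissociation continues from the association end level with exp(−k_off·t).
The equilibrium-occupancy factor C/(C+K_D) makes association levels depend
on affinity, which is what lets the plateau serve as a (weak) affinity
proxy. Phase intervals are half-open; phase-local time restarts at zero at
each boundary.

Double referencing is `(measurement − reference) − (blank_measurement −
blank_reference)` on a shared time grid; mismatched grids are an error (no
interpolation), since silent resampling is a classic source of rate bias.

The global fit shares (k_on, k_off) across concentrations with one free
amplitude per curve, optimized in log-rate space by Levenberg–Marquardt.
Exponential fits are initialization-sensitive, so starts are deterministic:
per-curve k_obs estimates (best-of-13 log-spaced starts over 1e-4..10 s⁻¹,
ties to the smaller rate), a pooled log-linear dissociation estimate of
k_off, and three fallback k_on decades. Standard errors come from the
Jacobian at the optimum (unweighted least squares — no variance model is
assumed). A fit is *not determinable* when the largest amplitude is below
3× the residual SD or the rate uncertainties exceed the estimates; when
only k_off is unresolved (se > estimate) the K_D is flagged as an upper
bound rather than suppressed. The association level is reported both as the
mean of the final 10 % of association samples (primary, model-free) and as
the fitted amplitude.

## Competition chain

The three-species equilibrium (target T, tracer C, competitor L, constants
K_D and K_i) is reduced by mass balance to one strictly increasing equation
in free target and solved by Brent bracketing on [0, T_t] at ~1e-15
relative tolerance. This solver is the package's internal oracle: the γ
closed form and the EC50→K_i conversion are validated against it rather
than against each other. γ itself is evaluated through the conjugate form
2T/(s+√(s²−4TC)) to avoid cancellation at small bound fractions.

The Hill fit is a four-parameter logistic in log10 concentration with the
slope bounded to [0.3, 5] and, for displacement-oriented data, the bottom
plateau bounded to [0, 1.5·min(signal)] — both stabilize 16-point plates.
Orientation lives in top/bottom, so activation-shaped curves give the same
EC50. Fits whose EC50 leaves the concentration grid, or whose dynamic range
is indistinguishable from zero (< max(3·residual SD, 0.1 % of signal
scale)), are flagged and should be read as bounds.

K_i conversion is exact given the true midpoint EC50. Because the simulated
displacement curve is the exact equilibrium response (not a logistic), the
Hill-fitted EC50 carries a small model-mismatch bias; on a 28-point 1:1
series from 1 mM the full round trip recovers K_i within 0.5 % across
10 nM–10 µM at 20 nM target / 10 nM tracer. A 16-point series from 1 mM
bottoms out at 30.5 nM and truncates the transition of a 10 nM competitor,
biasing its K_i by tens of percent — an assay-design limit, not a fitting
one; the round-trip validation therefore uses the longer series. The
conversion refuses (assay-window error) whenever the EC50 is at or below
the zero-affinity floor γ·(T_t/γ − K_D/(2−γ) − C_t/2), where no positive
K_i exists.

The direct tracer K_D fit uses the tight-binding quadratic isotherm (the
same γ with the titrated protein as T), not the hyperbolic approximation,
because the reference assay runs at 1 nM tracer where K_D ≈ tracer
concentration and the hyperbola is >10 % biased.

## Microarray quantification

Background is subtracted per spot and floored at zero (clip count logged).
The duplicate deviation pools each left/right pair's deviations from its
own pair mean — √(Σ(x−x̄_pair)²/n) with n the total number of points — so
identical duplicate sides give exactly 0 irrespective of spot-to-spot
brightness variation. Relative binding is the summed background-subtracted
intensity per condition divided by the no-competitor sum; the control is
therefore exactly 1, the operation is idempotent, and it commutes with any
global intensity rescaling. Neutralization IC50s reuse the Hill machinery
on the positive-concentration conditions.

## Architecture encoding and prediction

Responses with missing K_D, k_on or k_off are dropped; replicates of the
same compound (valency, epitope, linker string) collapse to medians. K_D
(molar) and k_off are transformed as y = ln(x)²; since every realistic K_D
is far below 1 M the logarithm is negative and the inverse is
x = exp(−√y) — the molar unit is pinned because it selects this branch.
k_on is regressed untransformed.

Features are the 20 amino-acid-composition fractions plus a 14-bit
positional linker one-hot (capacity 7 build tokens; J→[1,0], O→[0,1],
gap→[0,0]): 34 columns before zero-variance removal. Constancy is tested
with ptp (exact), and removal operates on the full matrix before
cross-validation — faithful to the stated workflow, at the cost of a mild
selection leak that cannot change predictions here because removed columns
are constant. LOOCV trains one fresh `RandomForestRegressor` per fold
(scikit-learn defaults, `random_state` pinned to the run seed); rows are
sorted by id first so predictions are invariant to input order. Evaluation
uses R² = 1 − SS_res/SS_tot (with the convention that zero-variance
observed values score 1 for perfect and −∞ for imperfect predictions — the
guard that keeps degenerate bootstrap resamples well-defined), Pearson
product-moment correlations, and a 1000-resample paired percentile
bootstrap of R² (2.5–97.5 %).

## Synthetic-data generator

The generator *is* the study conditions. The default library crosses
valencies (2, 4, 8) × epitope lengths (5–8, an FSIVG core centred in
synthetic flanking residues so composition varies with length) × a 3×3 grid
of per-tier PEG-spacer counts (o1, o2 ∈ {0, 1, 2}) — 108 compounds, which
deduplicate to 84 distinct ones because dimers have no second tier. The
linker build string carries one J per branching tier beyond the first, so
valency is implicit in the token encoding, as it is in the real compounds.

Planted rates are rule-based: base k_on 2×10³ M⁻¹s⁻¹ and k_off 2×10⁻³ s⁻¹,
valency multipliers (k_on ×1/×8/×60, k_off ×1.8/×1.0/×0.55 for 2/4/8),
epitope power laws (e/5)² on k_on and (e/5)^−0.3 on k_off, small per-token
linker effects on k_on (×1.06 per O, ×0.97 per J), and bounded log-uniform
jitter (±0.15 on ln k_on, ±0.08 on ln k_off, deterministic per compound id
and seed). These values were chosen once so that, across the default
library, on-rates span ≥100-fold while off-rates stay within 5-fold, K_D
falls monotonically (in expectation) with valency and epitope length, and
absolute affinities run from low-µM dimers to low-nM octamers — the
qualitative structure of avidity-engineered binder panels.

Trace simulation samples at 1 Hz with a 30 s baseline, 300 s association
and 600 s dissociation by default (instrument-realistic values; the
durations are configuration, not measured fact). Noise is additive i.i.d.
Gaussian per point and drift is linear — the simplest model consistent with
double-referenced biosensor data; the correction removes common-mode drift
exactly by construction. An optional concentration-dependent apparent
on-rate k_on,app = k_on·(C/C_ref)^β is available for robustness studies of
the anomaly sometimes seen with multivalent analytes (β = 0 by default: the
clean 1:1 model). Displacement plates map the exact ternary bound-tracer
fraction affinely to an F_norm scale (850–900 ‰); microarray spots draw a
per-spot lognormal brightness (σ = 0.2) and decay logistically in log
competitor concentration.

What the simulators deliberately omit: mass-transport limitation, rebinding
and surface heterogeneity in traces; thermophoretic trace shapes (only the
F_norm-vs-concentration layer is modelled); image-level microarray
artefacts (segmentation starts from intensity tables); and any mechanistic
valency model. Passing tests therefore demonstrate the correctness of the
analysis chain on its stated model class — not that real instruments
satisfy that model.

## Numerical and design choices

* Rates optimized in log space; exponent arguments clipped (≤700) so
  wayward optimizer steps cannot overflow.
* Multi-start order is deterministic everywhere; RSS ties break to the
  smaller rate constant.
* Global-fit problem sizes: 3 concentrations × 930 samples; the noisy
  recovery study uses 100 simulated replicates at 1 % relative noise.
* `fit_global` with a single concentration requires a dissociation phase
  (k_on and k_off are otherwise inseparable) and errors accordingly.
* Resource arithmetic reports each method's per-peptide protein mass as a
  fold ratio to a reference method, rounded to one decimal, from a
  configurable mass table (defaults: FPS 0.64 µg, BLI 18.25 µg,
  ITC 182.4 µg, TRIC 0.29 µg).

## Known limitations

* One apparent exponential per compound: biphasic or heterogeneous binding
  is out of scope and will be flagged not-determinable or mis-fit.
* The EC50→K_i conversion assumes pure competition at equilibrium;
  allosteric or incomplete displacement violates it silently.
* LOOCV on a library with near-duplicate compounds optimistically biases
  R²; replicate collapsing mitigates but cannot remove relatedness between
  folds.
* The AAC encoding is composition-only — positional epitope information is
  invisible to the model by design.
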