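# Methods

This note documents the model, the estimation procedure, the synthetic-data
generator, and the numerical and design choices behind `vestfit`, in the
spirit of a package's statistical reference documentation.

## Stimulus and temporal basis

The protocol translates the subject along 26 directions sampled evenly on a
sphere: azimuths {0, 45, …, 315}° crossed with elevations {−45, 0, 45}°,
plus the two poles. Azimuth is measured in the horizontal plane (forward =
90°, leftward = 0°); elevation +90° is the downward pole under this
convention, and azimuth is canonicalized to 0 at the poles so each pole is
a unique grid point. Angles between directions are 3D great-circle angles
(arccos of the unit-vector dot product, clipped to [−1, 1] before arccos).

Each 2-s trial follows a Gaussian velocity profile with σ = 0.2 s centered
at t = 1 s and total displacement 0.13 m. Displacement and σ are
independent settings: the corresponding ideal-Gaussian peak velocity is
d/(σ√(2π)) ≈ 0.26 m/s and peak acceleration ≈ 0.08 g; no fixed
peak-acceleration value is imposed. The four temporal basis profiles are
the Gaussian (velocity), its first derivative (biphasic acceleration), its
second derivative (triphasic jerk), and its cumulative integral (position,
a smooth step). Each is evaluated on the PSTH's own bin centers
(25-ms steps by default) after shifting by the fitted delay τ0, then
normalized so that max − min = 1 *over the realized trial window* — the
normalization applies to the profile the model actually uses, not to the
infinite-support ideal. If the window covers less than ±2σ around the
shifted center the profiles degrade gracefully and a warning is emitted.

## Response model

See the README for the model equation. Three conventions matter:

- **Rectification.** The summed prediction (components + baseline) is
  clipped at zero before being compared to data, so the model can be
  silent during inhibitory epochs. Rectification applies to the total, not
  to individual components.
- **Non-negative weights.** A cosine component satisfies
  (W, pd) ≡ (−W, antipodal pd); constraining W ≥ 0 and expressing reversals
  through the preferred direction removes this degeneracy.
- **Shared delay.** One τ0 is shared by all components of a model,
  bounded to [−0.1, 0.3] s — fitted delays in this preparation fall in
  0.04–0.14 s, and the bound brackets them with margin.

Parameter counts: 2 + 4k for k free-tuning components (6/10/14/18 for
1/2/3/4), and 8 for the separable VAJ (three weights, one shared tuning,
delay, baseline).

## PSTH construction and screening

Spikes are binned at 25 ms per trial, averaged across repetitions per
direction, and smoothed with a Gaussian kernel (σ = 100 ms, reflected-edge
handling via nearest-mode filtering). Raw per-trial binned rates are
retained. Two inclusion criteria gate analysis:

**Temporal response modulation.** For each direction, per-trial firing at
the PSTH peak (trough) must exceed (fall below) baseline firing by a
one-sided Wilcoxon rank-sum test at α = 0.01, and the cell passes only if
two directions 45° apart (in 3D) are both significant — for the peak or
for the trough. Two implementation details are deliberate:

- *Leave-one-out peak selection.* Each trial's peak bin is located on the
  smoothed average of the other trials. Selecting the bin on the full
  average biases the selected values upward under the null (the argmax
  chases shared noise); with leave-one-out selection the measured null
  pass rate on constant-rate Poisson cells is below α, and the
  45°-neighbor conjunction keeps the overall criterion conservative.
- *Rank-sum rather than signed-rank.* A paired exact signed-rank test on
  five (peak, baseline) pairs cannot reach p < 0.01 (its smallest
  two-sided p is 1/16), so at the protocol's minimum of 5 repetitions that
  test can never fire. The package instead compares the five per-trial
  peak-bin rates against the five per-trial mean rates in the baseline
  window (the first 250 ms of the trial, before appreciable stimulus
  motion) with the exact rank-sum test, whose smallest one-sided p
  (1/126) resolves α = 0.01.

**Space-time structure.** A balanced two-way ANOVA (direction × time bin,
with interaction) on the single-trial binned rates; the cell passes when
both main effects and the interaction are significant at α = 0.001. The
sums of squares are computed in closed form for the balanced design (the
equivalent dummy-coded OLS would materialize a 2080-column design matrix)
and are verified against `statsmodels.anova_lm` in the tests. Raw
(unsmoothed) bins are the default — smoothing correlates residuals and
inflates the time factor — with `use_smoothed=True` available as an
explicit anticonservative knob. Note two consequences of the model's
structure: a purely cosine-tuned cell (offset 0) has a near-zero *time*
main effect (positive and negative direction responses cancel in the time
marginal), and a pure acceleration/jerk cell has a near-zero *space* main
effect (the biphasic profile integrates to ≈ 0 over the trial), so the
criterion is genuinely selective, not a formality.

## Fitting and model selection

Each model is fitted to the 26 × 80 smoothed PSTH by bounded nonlinear
least squares (scipy trust-region reflective), minimizing the sum of
squared residuals of the rectified prediction with equal bin weighting.
Bounds: weights [0, 500] spikes/s, baseline [0, 300] spikes/s, offsets
[−1, 1], delay [−0.1, 0.3] s, elevation [−90, 90]°, azimuth unconstrained
modulo wrap-around.

The objective is multimodal in the preferred directions, so fits are
multi-started. The workhorse initializer exploits a reparameterization:
for fixed τ0 and ignoring rectification, the model is *linear* in the
per-component vector `w⃗_c = W_c (1 − |o_c|) · r(pd_c)` and scalar
`b_c = W_c o_c`, plus FR0 — so a single least-squares solve profiles every
spatial parameter at once. Inverting the map (W = |w⃗| + |b|, o = b/W, pd
from w⃗) gives a near-optimal start, evaluated on a small delay grid
{0, 0.05, 0.1} s. Additional starts come from embeddings of fitted
submodels (extra components at zero weight) and one seeded random draw;
the best candidates by initial cost are polished and the returned solution
is the best over polished and unpolished candidates. Because a warm start
can never be degraded, R² is monotone non-decreasing along nested chains
(V → VA → VAJ, …, SepVAJ → VAJ), which keeps partial R² and the
separability index well-defined up to optimizer tolerance.

Goodness of fit is R² = 1 − RSS/TSS with TSS about the grand mean of the
PSTH. Models are compared with BIC = n log(RSS/n) + p log(n) (natural
log; RSS = 0 maps to −∞), where the effective n counts 10 independent time
points per direction profile — round(duration / 2σ_kernel) — hence
n = 260 for the default protocol. The best model minimizes BIC among the
seven canonical specs, ties broken toward fewer parameters. Partial R² of
each component is (R²_VAJ − R²_reduced)/(1 − R²_reduced), clipped at zero
when optimizer noise makes the numerator marginally negative, and
undefined (an error) when the reduced model already fits perfectly.
The separability index is R²_SepVAJ / R²_VAJ. The four-component PVAJ
model is fitted only on request: the protocol's 2-s window barely samples
the post-movement epoch where position responses would be distinguished,
so position estimates are intrinsically fragile.

## Synthetic-neuron generator

The generator defines the study conditions for all validation: 26
directions × 5 repetitions of 2-s trials, inhomogeneous-Poisson spiking
following the rectified model rate at 1-ms resolution (counts drawn per
bin, spike times placed uniformly within the bin), and additive Gaussian
per-trial rate offsets (SD 5 spikes/s, rectified) emulating slow
excitability fluctuations. Ground-truth parameters are drawn with
preferred directions area-uniform on the sphere (azimuth uniform,
elevation arcsine-transformed), weights uniform in [20, 100] spikes/s,
baselines in [10, 80] spikes/s, delays in [0, 0.15] s and offsets in
[−0.8, 0.8] — ranges bracketing the medians reported across vestibular
areas (component weights of tens of spikes/s for central neurons,
baselines from ~10 to ~75 spikes/s, delays 0.04–0.14 s, velocity offsets
around 0.3–0.6 and acceleration offsets near 0). Populations are split
equally across the seven canonical specs (remainder round-robin). A
2000-spikes/s rate cap guards against pathological parameter draws.

What the generator does *not* emulate: non-Poisson firing regularity
(real otolith afferents range from very regular to very irregular),
gravity/tilt sensitivity, canal convergence, and any eye-movement or
visual covariates. Passing recovery tests therefore demonstrates that the
estimation machinery is correct and well-conditioned under Poisson
variability at realistic rates — not that every property of recorded
neurons is captured.

## Validation results computed by the tests and acceptance script

- **Parameter recovery** (the study's own validation design, scaled to
  desk size): 70 Poisson neurons, 10 per spec, 5 repetitions. The
  BIC-best model contains every generating component whose weight exceeds
  20% of the weight sum in ≳90% of neurons; the median PD error of the
  dominant component is ~6°; fitted normalized weights correlate with
  generating weights at r ≈ 0.93.
- **Separability**: noiseless shared-tuning generators give SepI = 1.00;
  a generator with opposite velocity/acceleration PDs, equal weights, and
  population-typical offsets (velocity 0.5, acceleration 0) gives
  SepI ≈ 0.78. (With *zero* offsets an opposite-PD two-component response
  is nearly rank-1 in space-time and the separable model recovers most of
  its variance via the delay freedom — offsets are what make real central
  neurons inseparable.)
- **Null calibration**: the chance PD-angle distribution matches its
  closed-form CDF (1 − cos θ)/2 to sup-deviation < 0.01 at n = 10⁵;
  the temporal screening criterion passes ~1–3% of constant-rate Poisson
  cells at α = 0.01; Rayleigh-test p-values are uniform under uniform PDs.
- **Oracle agreement**: the direction-maximized peak-to-trough modulation
  and the position ratio (searched on a 3° grid with local simplex
  refinement) agree with a 1° dense-grid brute force within 0.2%.

Problem sizes (70 neurons, 500 null cells, 10⁵ angle samples, 200 Rayleigh
replicates, 20 oracle parameter sets) were chosen as the smallest
populations at which the recovery and calibration statistics are stable
across seeds.

## Known limitations

- Weight estimates inherit a small systematic shrinkage because the model
  is fitted to kernel-smoothed PSTHs with unsmoothed basis profiles;
  sharp components (jerk) are affected most. The model-comparison
  statistics (BIC ordering, partials, SepI) are insensitive to this.
- With strong offsets (|o| → 1) a component's preferred direction is
  weakly identified — the cosine part carries little variance — so PD
  errors concentrate in high-offset components. Population PD summaries
  should be restricted to components present in the BIC-best model, as
  the angle-distribution utilities do.
- The percentile bootstrap for medians is approximately, not exactly,
  calibrated at small n.
- R² uses variance about the PSTH grand mean; a completely flat PSTH has
  no defined R² and is rejected on model construction.
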