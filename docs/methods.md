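# Methods

This note records the modelling choices, defaults and limitations behind
`ctmaug`. It documents *how* quantities are computed; every empirical number
mentioned is one the test suite or `scripts/acceptance.py` computes itself.

## Corticothalamic model and analytic spectrum

The linearized corticothalamic model is parameterized by the gain vector
(G_ee, G_ei, G_ese, G_esre, G_srs), the synaptic decay/rise rates α ≤ β
(s⁻¹), the loop delay t₀ (s), the cortical damping γ_e (s⁻¹), the excitatory
axonal range r_e (m) and one overall amplitude. Individual connection gains
G_ab are not identifiable from a power spectrum — only these loop products
enter the transfer function — so the package fits and stores exactly this
vector. The sensory drive spectrum is taken as flat (unit), with all scale
absorbed into the amplitude parameter.

The spectrum sums spatial modes k = 2π(m, n)/(L_x, L_y) over
m, n ∈ [−m_max, m_max] with the volume-conduction filter exp(−k²/k₀²).
Defaults: L_x = L_y = 0.5 m, k₀ = 10 m⁻¹, r_e = 0.086 m, γ_e = 116 s⁻¹,
m_max = 8 — values typical of the neural-field literature; the mode sum is
converged at m_max = 8 (band-power change to m_max = 16 below 0.1 %, an
acceptance check). Frequencies are handled in Hz at the API surface and
converted to ω = 2πf internally.

Default wake-like operating point (used by tests, examples and the synthetic
cohort): G_ee = 5.89, G_ei = −8.28, G_ese = 6.34, G_esre = −6.05,
G_srs = −0.74, α = 83 s⁻¹, β = 380 s⁻¹, t₀ = 85 ms. This places an alpha
resonance near 9.8 Hz and a beta resonance near 18 Hz and is stable with a
comfortable margin.

Steady state and physiology: the full sigmoid fixed point is solved by a
bracketing scan over the cortical potential with a nested inner solve for the
relay potential (the reticular feedback makes the inner problem monotone).
Inverting gains to connection strengths uses the extra freedom in splitting
loop products: the symmetric split G_es = G_se = √G_ese is tried first and,
if the sigmoid template cannot support it, the split is rebalanced along a
deterministic 1-D family — every split reproduces the same loop gains and
hence the same spectrum. Inversion is supported in the generic regime
(G_ese > 0, G_srs < 0) and for the fully decoupled zero-loop-gain case;
other degenerate sign combinations raise `InfeasibleGains`.

## Simulators

Two generators produce source signals from a gain vector:

- **time_domain** integrates the linearized population equations per spatial
  mode with semi-implicit Euler: two second-order dendritic filters for the
  relay and reticular populations, one for the cortical input, the damped
  wave operator for the excitatory field, and circular delay buffers of
  length t₀/2 on the corticothalamic links. The step (default 10⁻⁴ s) is
  snapped down so t₀/2 is an integer step count. White noise drives the
  relay dendrite, scaled by amplitude/G_es and by 1/√(2·dt) so the output's
  one-sided Welch density matches the analytic spectrum absolutely. Output
  is anti-alias filtered and resampled to 250 Hz.
- **spectral_synthesis** draws independent complex Gaussian Fourier
  coefficients with expected power equal to the analytic spectrum and
  inverse-transforms. For the linearized model driven by Gaussian noise the
  two generators are distributionally equivalent; their long-run band shapes
  agree within the Welch estimator noise (an acceptance check at 300 s).

The stability screen used during fitting and jittering tests the analytic
spectrum on a dense 0.5–45 Hz grid (finite, positive, peak-to-median ratio
below 10⁴). This probes the real frequency axis only; a parameter set can
pass it yet carry a growing mode in time. Where that happens during
augmentation the time-domain run is replaced by spectral synthesis, which
cannot diverge and has the same target spectrum. Note the ratio proxy is not
monotone along rays toward zero gain — a shrinking gain vector can pass
through a resonance — so "smaller gains" must not be assumed safer.

## Spectral fitting

`fit_ctm_mcmc` is single-parameter-at-a-time random-walk Metropolis on the
eight-parameter box: G_ee ∈ (0, 25), G_ei ∈ (−25, 0), G_ese ∈ (0, 40),
G_esre ∈ (−40, 0), G_srs ∈ (−10, 0), α ∈ (20, 200) s⁻¹, β ∈ (α, 800) s⁻¹,
t₀ ∈ (60, 140) ms. The objective is the sum of squared log₁₀-power residuals
on the 8–30 Hz band with the multiplicative scale profiled out in closed
form, so the fit is invariant to absolute calibration; the acceptance
likelihood treats the residuals as Gaussian with sd 0.05 in log₁₀ units
(a cold chain that actually localizes). Proposals start at 5 % of the box
width and adapt toward 20–40 % acceptance during warm-up. Because the
objective surface is multimodal, chains start from the best of 256
stability-screened prior draws, and a bounded Nelder–Mead simplex refines
each chain's best sample (and the two best prior points) before the best
overall becomes `map_gains`; the amplitude is then profiled back in so the
fitted band level matches the target. A split-chain R-hat on t₀ and α below
1.1 sets the advisory `converged` flag. With 20 000 steps this recovers a
noise-free target's t₀ to well under 1 ms and its band shape to under 2 %;
against a 72-epoch simulated average the residual shape error is dominated
by the sampling noise of the target itself (≈ 8 %).

## Augmentation

Model-based augmentation operates per condition and per CSP source on
training-fold epochs only: epoch-averaged periodogram → MCMC fit → optional
jitter → simulation → calibration → segmentation into epochs of the training
epoch length. Jitter adds N(0, (1.5·σ_typical)²) to a subset of {α, γ_e, t₀}
with σ_typical = 14 s⁻¹, 25 s⁻¹, 3 ms respectively, draws 10·factor
parameter sets, and redraws any that fail the stability screen; loop gains
are never jittered. Draws are cycled round-robin over the required epochs,
one continuous simulation per draw.

Generated signals are band-passed with the same 8–30 Hz zero-phase filter as
the real data (TP features must be compared on band-limited signals) and
scaled so their Welch band power equals the experimental target's, times the
analytic band-power ratio between the jittered and the fitted parameter set —
calibration fixes the scale the fit cannot pin down while preserving
jitter-induced power changes. The γ jitter targets γ_e, the only population
with a propagation-scale axonal range.

The noise baseline draws factor·n rows per condition from
N(μ_feat, 1.5·S_feat) in feature space. The 1.5 multiplies the *covariance*
here but the *standard deviation* in parameter jitter, mirroring how the two
procedures are specified.

## Evaluation protocol

`inverse_cv` partitions epochs into k = 3 stratified folds, trains the whole
pipeline (CSP fit, optional augmentation, LDA) on one fold and validates on
the union of the others; `full_cv` is regular stratified 7-fold. Within
`run_benchmark` the baseline and every strategy share the same partition
seed per subject, so the treated/untreated comparison is paired at the fold
level and a factor-0 strategy reproduces the baseline bit-exactly. Subjects
are excluded when full-set Ac ≤ 0.5, small-set Ac ≤ 0.5, or small-set Ac >
full-set Ac; improvements are tested with a two-sided paired t-test across
the retained subjects. By default one seeded partition is drawn per subject;
`n_repeats` re-randomizes the partition and averages the accuracies per
subject, which the cohort benchmark uses (two repeats) because the
per-subject delta of a single 3-fold partition carries enough partition
noise to swamp a 2–5 % effect. The
proficiency grid search keeps subjects with baseline Ac above a threshold
and returns the threshold maximizing the number of strategies with a
significant positive improvement (ties to the lowest threshold).

## Synthetic cohorts

`make_subject` builds epochs from three model sources: a contralateral pair
whose parameters swap between conditions — t₀ = 80 vs 90 ms and drive
amplitude 1.6 vs 0.8, i.e. a resonance shift plus a ~2× band-power
asymmetry, the phenomenology of lateralized sensorimotor desynchronization —
plus a condition-independent background source, mixed into 22 channels
through fixed Gaussian-bump topographies with white sensor noise. Subjects
receive small random physiology offsets (t₀ sd 1.5 ms, amplitude sd 8 %),
and the sensor-noise multiplier sweeps 1–25× geometrically across a cohort
so baseline accuracies span roughly chance to 0.95, giving the subject
filter and proficiency search something to act on.

Each epoch's source amplitude is additionally scaled by a lognormal factor
(sd 0.30): real MI EEG shows strong slow fluctuations of band power across
epochs, and this nonstationarity is precisely what makes 24-epoch training
sets unstable — with purely stationary sources a small training set already
estimates the LDA well and augmentation has nothing to repair. What the
fixtures do *not* emulate: artifacts (ocular, muscular), channel
correlations beyond the three planted topographies, session drift, and any
nonlinearity of the underlying dynamics. Passing tests therefore demonstrate
the machinery end to end under a model-matched, nonstationary-power cohort,
not performance on real recordings; the '2a' GDF adapter exists for the
latter but ships untested. An AR(2)-oscillator surrogate mode
(`CohortSpec(mode="ar2")`) provides a model-mismatched fixture for
robustness probes.

## Numerical conventions and edge cases

- Total power follows the unitary DFT convention, under which the time- and
  frequency-domain expressions agree to machine precision (Parseval).
- The Higuchi estimator uses strides n = 1..10 and returns *minus* the slope
  of log₂L(n) on log₂n, so a linear ramp gives exactly 1 and white noise ≈ 2;
  the raw slope is negative for fractal signals. A constant signal returns
  1.0 with a warning.
- Periodograms are rectangular-window, density-normalized; Welch
  comparisons against analytic spectra use 2 s segments (0.5 Hz resolution,
  ~150 averages at 300 s) so estimator noise sits well inside the tolerance.
- CSP uses trace-normalized per-epoch covariances averaged per class and a
  generalized eigendecomposition with a 10⁻¹⁰·trace ridge; patterns are the
  filter pseudo-inverse. LDA is pooled-covariance with 10⁻⁶ shrinkage.
- The steady-state solver warns and takes the lowest-potential root when
  multiple fixed points are bracketed.
- All randomness flows through explicit integer seeds (numpy `SeedSequence`
  spawning for nested procedures; the numba kernels seed the legacy
  generator per call), making every simulation, fit and benchmark
  bit-reproducible.

## Known limitations

- The fit holds γ_e and r_e fixed (not identifiable from a single band
  shape); fitting them would require multi-band or multi-sensor data.
- `physio_from_gains` cannot represent every point of the prior box (a
  net-excitatory cortex has no sigmoid-consistent steady state) — by design
  it reports infeasibility rather than silently clipping.
- Benchmark problem sizes (12 subjects, 72 epochs/condition, 5 000 MCMC
  steps inside augmentation, 20 000 for the recovery checks) were chosen so
  a full desk-scale run completes in minutes while leaving the statistical
  conclusions stable; they are package defaults, not protocol constants.
- Multi-class CSP, channel-level augmentation and deep-learning baselines
  are out of scope.
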