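# Methods

This note documents the models, numerical choices and known limitations of
tempoevo. It states no empirical result that the test suite does not itself
compute.

## Tempo traits from activity series

Each recording is processed in a fixed order: rescale to [0, 1] →
15-point Gaussian-weighted moving average → continuous wavelet transform.
Rescaling first makes the coherence factor exactly amplitude-invariant;
smoothing suppresses high-frequency noise that would otherwise distort the
wavelet peak (the pipeline's property tests verify the dominant period of
a noisy 40-min sinusoid moves by less than one grid step under smoothing).
The smoothing kernel uses the common signal-processing convention for a
Gaussian window of length L, standard deviation (L−1)/5, truncated and
renormalized at the record edges so a constant series is unchanged.

The transform is an analytic continuous wavelet transform evaluated by
FFT, L1-normalized so a unit-amplitude sinusoid contributes equal
magnitude at every scale. The default mother wavelet is the analytic
Morlet with center frequency ω₀ = 6; a generalized Morse wavelet
(γ = 3, β = 20, the common default of other CWT tools) is available, and
the two families agree on the synthetic suite because both output metrics
are ratio- or argmax-based. The period grid is logarithmic with 12 voices
per octave spanning [2 × sample interval, record length / 2]. The signal
is mirror-padded on both sides to mitigate edge effects; no
cone-of-influence exclusion is applied, since the periodogram sums *all*
coefficient magnitudes over time. Raw (not squared) magnitudes are summed.

Dominant period is the grid period at the global periodogram maximum (ties
break deterministically toward the shorter period). Rhythmicity is
β = max(power)/mean(power); β ≥ 1 by construction with equality only on a
flat periodogram. When colony recordings are longer than individual ones,
comparative analyses truncate colony series to the individual length
first; the head of the series is kept (recordings start each morning, so
the head is the comparable segment — the generator is stationary and the
choice is immaterial for synthetic data, which a 50-seed paired test
confirms).

## Activity extraction from images

*Frame differencing*: each ROI frame is binarized by a local-mean adaptive
threshold (window ≈ 1/8 of the shorter ROI side). A pixel is foreground
when darker than its local mean by (1 − sensitivity)/2 times the frame's
intensity range; the range-relative offset makes the mask — and hence the
activity values — invariant to global affine intensity changes. The
activity value per transition is the fraction of ROI pixels whose binary
value changed. Constant frames binarize to background with a warning.

*Optical flow*: classic Horn–Schunck (brightness constancy plus global
smoothness, α = 1.0, 100 Jacobi iterations), implemented in-package; the
library variational flows available here (TV-L1, iterative Lucas–Kanade)
spread flow far beyond a moving object and fail a displaced-mass oracle by
factors of 4–20, whereas Horn–Schunck with these settings stays within
30%. Frame pairs are jointly rescaled to [0, 1] before flow estimation,
which makes the output exactly invariant to affine intensity changes. The
activity value is the mean flow magnitude over the frame.

*Centroid tracking* (isolated ants): Otsu threshold, largest dark
connected component, ties toward the lowest (row, col) centroid. A frame
with nothing detected, or with a second component at least half the size
of the largest (ambiguous detection), is flagged and the last valid
centroid carried forward; more than 20% flagged frames is an error.

*Open-field speed*: instantaneous speed is per-transition displacement ×
fps / body length (body-lengths/s). The mean moving speed averages only
frames above the 0.5 BL/s threshold; a track that never exceeds it raises
a distinct "never moving" error, because the mean over zero moving frames
is undefined rather than zero.

## Species tip values

Per trait, a linear mixed model with species cell-means fixed effects and
a colony-of-origin random intercept is fit by REML. The implementation
profiles the criterion down to a one-dimensional search over the
variance ratio λ = σ²_colony/σ²_residual (bounded log-scale search with a
λ = 0 boundary check), which makes per-replicate refits inside the
bootstrap cheap; it is verified against statsmodels MixedLM to 1e-4.
With one observation per group, or no residual degrees of freedom, the
criterion is flat in λ and the estimate reduces gracefully to the species
mean. Cell-means coding makes the species coefficient directly the
species-level expected value. A descriptive likelihood-ratio test of the
species factor is available but feeds no downstream decision.

## Evolutionary inference

*Brownian rate.* Tip values are standardized by dividing each trait by its
cross-species mean (restandardized inside every bootstrap replicate). The
rate is the maximum-likelihood estimate under x ~ N(z₀·1, σ²C):
z₀ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1), σ² = rᵀC⁻¹r/n, computed via a Cholesky factor of
C that is reused across replicates. ML (not REML) matches the default of
the standard comparative fitting tools; its (n−1)/n bias is verified by
simulation. Exact invariants hold: σ̂² scales as 1/c when all branches are
scaled by c, and transforms as a² under x → a·x + b.

*Bootstrap rate comparison.* Within each species, resampling units are
drawn with replacement to original counts — colonies (with all their
recordings) at colony level, isolated individuals at individual level —
tip values are recomputed, standardized, and the BM rate refit at each
level. The one-sided p-value is the proportion of replicates whose
colony − individual rate difference fails to exceed zero, floored at
1/n_boot (so 10,000 replicates with zero exceedances report 0.0001). The
two levels' streams are seeded identically, so literally identical record
tables give a zero difference in every replicate; since the levels carry
independent data, this couples nothing otherwise.

This bootstrap sees only recording-level sampling noise. It cannot see the
across-species sampling variability of a realized evolutionary rate, so as
a test of *equal generative rates* it is conservative when tip noise
dominates (the resampled tips carry roughly twice the original noise
variance) and anti-conservative when interspecific signal dominates. The
calibration test therefore uses an equal-SD world in the intermediate,
realistic regime (interspecific log-SD 0.08 against intraspecific 0.15
with 8 records per species per level), where the empirical rejection rate
at 0.05 sits in the nominal band. This is a property of the
resample-records-and-refit design itself, not of this implementation.

*PGLS.* Both sides are whitened by the Cholesky factor of C and fit by
OLS; slope t = slope/SE with n − 2 degrees of freedom, two-sided. On a
star tree this reduces exactly to OLS. The sensitivity variant redraws
each species' x and y from Normal(tip, intraspecific SD) per iteration and
refits; the headline summary is the median p across iterations (the full
slope/t/p distributions are returned).

*Disparity.* The two levels' (rhythmicity, period) phenospaces are
standardized jointly (pooled z-score per axis) so the axes contribute
comparably, disparity is the sum of per-axis variances (n−1 denominator)
across species, species rows are resampled independently within each
level, and the one-sided p-value uses the same floor convention. Walking
speed is carried in the trait table but excluded from the phenospace.

## Synthetic data: what it emulates and what it does not

The activity generator is a phenomenological FitzHugh–Nagumo oscillator,

    dv = (v − v³/3 − w + drive) dt′ + noise_sd dW
    dw = ε (v + a − b·w) dt′,

integrated by Euler–Maruyama (dt = 1 s) with dynamical noise on the
activation variable only; one model time unit maps to `time_unit_min`
wall-clock minutes, which sets the realized period (≈ 36.6 min at the
classic ε = 0.08, a = 0.7, b = 0.8, drive = 0.5 parameterization and the
default mapping). Output is sampled at 30 s, burn-in discarded, and
rescaled to [0, 1] per series (skipped when the range is negligible, i.e.
the noise-free excitable regime at its fixed point, where rescaling would
amplify the residual transient). Rhythm *regularity* is controlled
separately by additive AR(1) observation noise (per-sample correlation
0.85, a correlation time of a few minutes): unlike white noise it is not
removed by the 15-point smoothing, and unlike dynamical noise it degrades
β without shifting the oscillator's period — measured over the working
range, the realized dominant period stays flat while β falls from ~6 to
~3.7. Four parameter presets realize the corners of the
(rhythmicity, period) phenospace: the high-β corners are the deterministic
oscillatory regime with little noise, the low-β corners are sub-threshold
(excitable) dynamics driven by strong noise.

Study-shaped datasets draw per-species latent (log rhythm-strength,
log period) pairs for each level. By default the latents evolve by
Brownian motion along a simulated pure-birth chronogram (marginal tip SD
equal to the configured interspecific SD at unit height), so the
comparative machinery sees correctly structured data; iid species effects
are available as an option. Each colony or individual receives a
log-normal intraspecific jitter, and each recording is an independent
oscillator realization. The pure-birth tree enforces a minimum terminal
branch of 10% of tree height: a species-level chronogram has no
near-zero sister distances, and without the floor any tip measurement
noise is amplified without bound by C⁻¹. The default study shape follows
the real design: 22 species, 14.5 h colony recordings (1740 frames, most
colonies recorded twice) and 8.5 h individual recordings (1020 frames),
with wider colony-level than individual-level interspecific spread in
rhythm strength.

`simulate_metric_tables` emits per-recording β and period values directly
from the latent structure, skipping the oscillator and wavelet stages.
It exists for calibration studies of the comparative stage, where
thousands of full simulations would add nothing (the oscillator → wavelet
path is exercised separately); its records need intraspecific jitter > 0
for resampling to be meaningful.

A green synthetic test therefore establishes that the pipeline recovers
known generative structure under this stated world; it does not establish
anything about ant-to-ant coupling mechanisms, non-stationary recordings,
tracking artifacts of real footage, or model misspecification beyond the
BM-vs-iid latent options.

## Known limitations

- The exact parameterization of the original oscillator illustration and
  the original wavelet's frequency grid are not public; the metrics are
  family-robust by design, but absolute β values are comparable only
  within one transform configuration.
- The record-resampling bootstrap compares *realized* rates; see the
  calibration discussion above.
- How the sensitivity-PGLS iterations are aggregated into a single
  p-value follows the median convention; other summaries are possible and
  the full distribution is returned for that reason.
- Optical flow underestimates displacements much larger than a blob
  radius per frame (no pyramidal refinement), and centroid tracking
  assumes exactly one animal per frame.
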