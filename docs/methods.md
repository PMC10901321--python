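# Methods

## Signal model

A free induction decay over `n` points is modelled as a sum of damped
complex exponentials (Lorentzian lines in the spectral domain),

    x(p) = Σ_q a_q e^{iθ_q} e^{(-d_q + i 2π f_q) p / f_s},   p = 0 … n−1,

with amplitude `a_q` (arbitrary signal units), phase `θ_q` (rad), damping
`d_q` (s⁻¹; spectral FWHM = d/π Hz) and resonance frequency `f_q` (Hz
relative to the carrier).  The default simulation phantom is the creatine
CH₃/CH₂ pair — two components with a = 15, θ = 0, d = 10 s⁻¹ and
f = 132 / 56 Hz — observed by an eight-element receive array with scale
factors (1, 0.8, 0.7, 0.6, 0.5, 0.65, 0.9, 0.93) and, by default, no
per-channel phase offsets.  Zero phase offsets are the best case for the
scalar (equal / SNR) weighting methods, which otherwise require manual or
automatic phasing before weighting; benchmark results for those methods are
therefore upper bounds on their field performance.

The sampling frequency (2000 Hz) and FID length (2048 points) are package
choices: they put both resonances comfortably in band, make the last 400
spectral bins (609–1000 Hz) peak-free for noise estimation, and keep a full
benchmark sweep affordable on a single core.  Both are configurable.

## Fourier conventions

Spectra are unnormalised DFTs with the zero-frequency bin centred; the axis
is in Hz relative to the carrier, and a ppm axis is derived for display only
as `f / (f₀·10⁻⁶)`.  The first FID point is halved before transforming
(toggleable), which removes the constant baseline offset a one-sided decay
otherwise produces; the inverse transform restores it.  Zero filling by an
integer factor interpolates the spectrum without moving on-bin values.

## Noise model

Channel noise is i.i.d. complex Gaussian per time point, specified as a
power `P` in dBm into a load impedance `Z` (default 50 Ω):

    variance = Z · 10^((P − 30)/10)    (signal units²),

split equally between the real and imaginary quadratures (toggleable to
all-real).  Cross-channel correlation is imposed by the Cholesky factor of a
unit-diagonal Hermitian correlation matrix; the default is a uniform
off-diagonal ρ = 0.2.  ρ is the one benchmark parameter with no published
reference value, and combined-SNR levels scale noticeably with it (see
*Limitations*); it is prominently configurable, and
`in_vivo_parameterized_run` accepts a measured correlation matrix directly.

The covariance convention throughout is `C_jk = E[x_j* x_k]`, which pairs
with whitening the (points × channels) data matrix as `X̃ = X L^{-H}`,
`C = L L^H`.

## Combination methods

All methods produce `combined = Σ_k w_k · channel_k` (applied identically in
the time or frequency domain by linearity).  Weights are reported at unit L2
norm (equal weighting excepted, `w_k = 1/n`): SNR and area-ratio metrics are
scale-invariant, and a common normalisation makes methods comparable.

* **equal** — `w_k = 1/n`; needs phased channels.
* **snr** — real weights ∝ per-channel matched-filter SNR; needs phased
  channels.
* **sn2** — `w_k = A_k e^{-iφ_k} / σ_k²` with `(A_k, φ_k)` from a
  damped-exponential fit of a reference peak on each channel and `σ_k²` the
  channel noise variance.  Assumes uncorrelated channel noise.
* **wsvd / wsvd_apod** — whiten the channel FID matrix with the inverse
  Cholesky factor of the noise covariance, take the rank-1 SVD: the combined
  FID is `u₁σ₁` and the leading right singular vector gives the channel
  weights.  The quality score

      Q = (n σ₁²/Σσᵢ² − 1)/(n − 1),  clipped to [0, 1],

  is exactly 1 iff the data matrix is rank one and falls as noise spreads
  energy over the remaining singular values.  The singular-value
  concentration form is this package's choice for the documented 0-to-1
  quality display; `wsvd_apod` estimates the singular vectors from a
  line-broadened (default 3 Hz) copy of the whitened data — suppressing
  high-frequency noise at low SNR — but applies the weights to the
  un-apodized data.  The SVD's arbitrary global phase is fixed by making the
  tallest combined spectral peak real-positive.
* **aoc** — the noise-adjusted matched filter
  `w = R^{-T} conj(s) / sqrt(s^H R^{-1} s)` from a coil-sensitivity estimate
  `s` (read at the single shared bin of the reference peak of an
  unsuppressed water or prominent-metabolite scan, so relative phases are
  meaningful) and the full noise correlation matrix `R`.  With `R = I` this
  reduces to sensitivity-conjugate (Roemer-style) weighting; for any noise
  of covariance `R` it maximises output SNR over all linear combinations
  (Cauchy–Schwarz), which the test suite verifies against brute-force random
  weightings.  The transpose in `R^{-T}` makes `combined = Σ w_k x_k` have
  exactly unit noise power under the covariance convention above; for the
  real correlation matrices of the benchmark it coincides with `R^{-1}`.

The "full noise correlation" matrix keeps the per-channel variances on the
diagonal and the unit-normalised correlation off it.  This mixed construct
can be marginally indefinite in degenerate cases (e.g. a duplicated
channel), so positive-definiteness is enforced at use time: whenever the
smallest eigenvalue is below 1e-10 × trace, a ridge of 1e-8 × trace is added
with a warning.

### Decision tree

`select_method` maps the user's situation to a method and a rationale
string: a water/metabolite reference *plus* noise information selects AOC;
noise information alone selects WSVD, or WSVD+Apod when the rough combined
SNR falls below 35 (down to 15) per the published guideline thresholds
(WSVD 35, WSVD+Apod 15, S/N² 60 — the combined-SNR levels above which each
method matches the optimal sensitivity-map combination); a reference peak
alone with high SNR and uncorrelated channels selects S/N²; SNR weighting
requires phased channels; equal weighting is the terminal fallback.  The
tree's exact branch structure is a reconstruction from the published
guideline and the stated preference for water-based weighting at low SNR.

## Spectral evaluation

Matched-filter SNR: apodize the FID with `exp(-π·lb·p/f_s)` (default
lb = 3 Hz; this convention adds `lb` directly to a Lorentzian's FWHM),
transform, zero-order phase the tallest peak, and report peak real
amplitude over the standard deviation of the real part in the noise region
(default: the last 400 spectral bins).  The real part is used rather than
the magnitude because magnitude noise is Rician and biases the standard
deviation; a flag switches to magnitude for comparison.  An input whose
noise region is dominated by smooth structure rather than noise — detected
by `std(Δ)/(√2·std) < 0.3` on the unfiltered spectrum, since white noise
has `std(Δ) ≈ √2·std` — is rejected as noiseless.  The filtered spectrum
cannot be used for this check because the matched filter correlates
neighbouring bins.

Linewidth is the full width at half of the real-part maximum with linear
interpolation between bins.

## Peak areas and the time-domain fit

The frequency integral of a Lorentzian line equals the FID's initial
amplitude, so the two-peak area ratio is the fitted amplitude ratio
`a₁/a₂`.  Areas come from a simultaneous nonlinear least-squares fit of all
components to the time-domain model (stacked real/imaginary residuals,
analytic Jacobian; Levenberg–Marquardt unbounded, trust-region reflective
with per-parameter bounds).  Before iterating, the complex amplitudes —
linear in the model — are re-solved exactly at the initial shapes, which
makes convergence nearly immediate for reasonable (d, f) guesses.  Parameter
covariance is `s²(JᵀJ)⁻¹` with `s²` the residual variance.  This internal
fit plays the role of the external AMARES-style quantification used in the
benchmark literature; the full prior-knowledge machinery is out of scope
since the benchmark only needs two free Lorentzians.

Degenerate outcomes: non-convergence raises a diagnostic error carrying the
last iterate; a fit driven to non-physical parameters (d ≤ 0) is treated as
a failure by the benchmark and excluded from aggregates with a per-level
failure count (a warning fires when more than 5% of repeats fail at any
(method, level), which happens routinely at the highest noise levels).

## Monte Carlo distortion benchmark

Per repeat: generate the phantom FID, replicate it over the array, add one
correlated-noise draw shared by all methods, combine with each method, fit
the two peaks and record distortion = fitted ratio − true ratio (1.0), plus
the matched-filter SNR of the combined FID.  Defaults: 300 repeats per
level, noise swept 10–50 dBm in 2.5 dBm steps, everything seeded and
reproducible (re-aggregation of the raw per-repeat table is tested).

Estimation assumptions mirror the benchmark literature: AOC receives the
true array sensitivities and true noise correlation (its water-scan
estimation step is assumed adequate); S/N² amplitudes and phases come from
per-channel reference-peak fits and the noise variances from the noise
region; WSVD estimates its covariance from the configured noise region each
repeat (a `known_covariance` flag substitutes the truth).  The area fits use
the leading 1024 FID points — the phantom has decayed to < 1% of its
initial amplitude by then, so the truncation discards essentially only
noise while halving the fit cost.

What the generator does *not* emulate: B₀ drift and frequency shifts
between channels (channels share exact frequencies, so alignment is moot in
the benchmark and defaults off), phase distortion across the array,
non-Lorentzian (Voigt) lineshapes, baseline/macromolecule signals, and
eddy-current effects.  Passing benchmarks therefore validate the
combination and quantification machinery, not robustness to those in vivo
effects.

## Limitations and known discrepancies

* With the default ρ = 0.2 correlation, the mean combined SNR at the
  guideline-verification noise levels (WSVD at 35 dBm, WSVD+Apod at
  42.5 dBm, S/N² at 30 dBm) comes out ≈ 25–31% below the published
  guideline values of 35 / 15 / 60.  The gap is almost entirely the
  correlation penalty: with all-positive weights the combined noise power
  is ≈ (1−ρ)Σw² + ρ(Σw)², a factor ≈ 2.3 at ρ = 0.2 for this array
  (≈ 1.5× in SNR), and ρ ≲ 0.1 would reproduce the guideline values
  closely.  The reference correlation values are unpublished; the default
  is kept at 0.2 and documented rather than tuned.
* At the two highest noise levels (47.5–50 dBm, combined SNR ≈ 4–6) a
  substantial fraction of area fits fail and are excluded, so the per-method
  aggregates there carry survivor bias; comparisons at those levels use a
  two-standard-error allowance.
* Varian/vendor raw formats, sub-bin frequency alignment, eddy-current
  correction and CSI grids are out of scope.
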