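# mcmrs — multi-channel MRS processing and coil combination

In vivo magnetic resonance spectroscopy (MRS) increasingly uses receive
arrays: several coils observe the same free induction decay (FID), each with
its own sensitivity, phase and noise, and the channels must be merged into a
single spectrum before quantification.  The merge is a complex weighted sum,

```
combined(f) = Σ_k w_k · S_k(f)
```

and the choice of the weights `w_k` decides both the SNR of the result and —
at low SNR — whether the combination silently *distorts* metabolite peak
areas.  `mcmrs` is a scriptable toolkit for this problem, aimed at
spectroscopists working with single-voxel data (especially x-nuclei such as
³¹P, where no strong water reference exists):

* **I/O** — jMRUI Data Textfile (ASCII) reader/writer and a native HDF5
  container, with multi-file concatenation and an append-only provenance log
  of every operation.
* **Preprocessing** — sliding-window transient averaging, 0th/1st-order
  phasing, polynomial baseline correction, zero-padding, exponential line
  broadening, reference (water) subtraction, integer-bin frequency alignment
  across channels.
* **Combination** — six literature-based weighting methods: equal, SNR,
  S/N² (complex weights from a fitted reference peak over the noise
  variance), whitened-SVD (WSVD) with and without apodized weight
  estimation, and the adaptively optimized combination (AOC, a
  noise-adjusted matched filter built from a coil-sensitivity estimate and
  the inverse full noise correlation matrix) — plus a decision tree that
  picks a method from what the user has available.
* **Evaluation** — matched-filter SNR (peak amplitude over the noise
  standard deviation after a 3 Hz exponential matched filter), FWHM
  linewidth, and a time-domain damped-exponential fit
  (`DampedExponentialModel` / `DampedExponentialResults`, statsmodels-style)
  for peak areas:

  ```
  x(p) = Σ_q a_q e^{iθ_q} e^{(-d_q + i 2π f_q) p / f_s}
  ```

* **Simulation** — a Monte Carlo benchmark that measures, per combination
  method and noise level, the *distortion* of the two-peak area ratio (the
  fitted ratio of the combined spectrum minus the noise-free model's ratio)
  and the combined SNR, locating the SNR regime where each method starts to
  bias quantification.  The default phantom is the classic creatine pair
  (CH₃ at 132 Hz, CH₂ at 56 Hz, amplitudes 15, damping 10 s⁻¹) received by
  an eight-element array with scale factors 1, 0.8, 0.7, 0.6, 0.5, 0.65,
  0.9, 0.93 and correlated channel noise specified in dBm into 50 Ω.

## Worked example

```python
import numpy as np
from mcmrs.simulate import (ArraySpec, NoiseSpec, default_two_peak_model,
                            draw_correlated_noise, generate_model_fid,
                            make_channels, uniform_correlation)
from mcmrs.combine import estimate_noise_covariance, wsvd_combine
from mcmrs.quantify import DampedExponentialModel, SnrSpec, compute_snr

fs = 2000.0
model = default_two_peak_model(fs, 2048)
fid = generate_model_fid(model)
acq = make_channels(fid, ArraySpec(), fs)          # 8 channels
noise = draw_correlated_noise(
    NoiseSpec(power_dbm=30.0, correlation=uniform_correlation(8, 0.2)),
    8, 2048, np.random.default_rng(0))
noisy = acq.evolve(acq.data + noise[:, None, :], "add_noise", {"dbm": 30.0})

cov = estimate_noise_covariance(noisy, ("last", 400))
combined, weights = wsvd_combine(noisy, cov)
print(f"quality {weights.quality:.3f}")
print(f"SNR {compute_snr(combined, fs, SnrSpec()):.1f}")
res = DampedExponentialModel(combined, fs).fit(model)
print(f"area ratio {res.area_ratio(0, 1):.4f}")
```

prints (seed 0)

```
quality 0.125
SNR 52.4
area ratio 0.9977
```

The quality score `(n σ₁²/Σσᵢ² − 1)/(n − 1)` reports how close the whitened
data matrix is to rank one (1 = pure common signal); at this noise level the
leading singular value holds only part of the energy, the matched-filter SNR
of the combined spectrum is ≈ 52, and the fitted CH₃/CH₂ area ratio deviates
from the true 1.0 by ≈ 0.2% — little combination-induced distortion, as
expected well above the distortion-onset regime.

The same run from the shell:

```bash
mcmrs simulate --seed 0 --repeats 50 --out-prefix sim   # distortion benchmark
mcmrs combine data.txt --method auto --out combined.txt --report report.json
mcmrs evaluate combined.txt
```

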