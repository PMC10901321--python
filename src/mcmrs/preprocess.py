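"""Per-channel preprocessing operators applied before coil combination.

All operators acting on an :class:`~mcmrs.core.AcquisitionSet` return a new
set with exactly one provenance record appended; spectral operators act on
:class:`~mcmrs.core.Spectrum` objects and are pure functions.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .core import AcquisitionSet, Spectrum

__all__ = [
    "PhaseParams",
    "sliding_window_average",
    "apply_phase",
    "auto_phase0",
    "baseline_correct",
    "zero_pad",
    "line_broaden",
    "subtract_reference",
    "align_frequencies",
    "AlignmentResult",
]


@dataclasses.dataclass(frozen=True)
class PhaseParams:
    """Zero- and first-order phase correction.

    ``phi1`` is the phase ramp across one full sweep width (radians per
    sweep), applied relative to ``pivot`` (Hz): a bin at frequency ``f``
    receives ``phi0 + phi1 * (f - pivot) / sweep_width``.
    """

    phi0: float
    phi1: float = 0.0
    pivot: float = 0.0


def sliding_window_average(
    acq: AcquisitionSet, window: int, step: int = 1
) -> AcquisitionSet:
    """Average transients with a sliding window (temporal-resolution studies).

    Output transient ``t`` is the complex mean of input transients
    ``[t*step, t*step + window)``; the output count is
    ``floor((n_transients - window) / step) + 1``.
    """
    if not 1 <= window <= acq.n_transients:
        raise ValueError(
            f"window must be in [1, {acq.n_transients}]; got {window}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    n_out = (acq.n_transients - window) // step + 1
    out = np.empty((acq.n_channels, n_out, acq.n_points), dtype=np.complex128)
    for t in range(n_out):
        out[:, t, :] = acq.data[:, t * step : t * step + window, :].mean(axis=1)
    return acq.evolve(
        out, "sliding_window_average", {"window": window, "step": step}
    )


def apply_phase(spec: Spectrum, params: PhaseParams) -> Spectrum:
    """Apply 0th/1st-order phase; preserves pointwise magnitude."""
    sweep = spec.sampling_frequency
    phase = params.phi0 + params.phi1 * (spec.frequency_axis - params.pivot) / sweep
    return spec.copy_with(spec.values * np.exp(1j * phase))


def auto_phase0(spec: Spectrum, peak_region: tuple[float, float]) -> float:
    """Zero-order phase that makes the tallest peak in ``peak_region`` real-positive.

    Returns ``-arg`` of the maximum-magnitude bin inside the region; apply it
    via :func:`apply_phase` with ``phi1 = 0``.
    """
    idx = spec.slice_bins(*peak_region)
    if idx.size == 0:
        raise ValueError(f"peak_region {peak_region} contains no bins")
    vals = spec.values[idx]
    k = int(np.argmax(np.abs(vals)))
    return float(-np.angle(vals[k]))


def baseline_correct(
    spec: Spectrum,
    exclude_regions: Sequence[tuple[float, float]] = (),
    poly_order: int = 2,
) -> Spectrum:
    """Subtract a least-squares polynomial baseline.

    The polynomial (default order 2) is fitted separately to the real and
    imaginary parts over all bins outside ``exclude_regions`` (the peak
    regions the user wants protected) and subtracted everywhere.
    """
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    mask = np.ones(spec.n_bins, dtype=bool)
    for region in exclude_regions:
        mask[spec.slice_bins(*region)] = False
    n_base = int(mask.sum())
    if n_base < poly_order + 1:
        raise ValueError(
            f"only {n_base} baseline bins left after exclusion; "
            f"need >= {poly_order + 1} for order {poly_order}"
        )
    # scale the axis to [-1, 1] for numerical conditioning
    x = spec.frequency_axis / (0.5 * spec.sampling_frequency)
    coef_re = np.polynomial.polynomial.polyfit(
        x[mask], spec.values.real[mask], poly_order
    )
    coef_im = np.polynomial.polynomial.polyfit(
        x[mask], spec.values.imag[mask], poly_order
    )
    baseline = np.polynomial.polynomial.polyval(
        x, coef_re
    ) + 1j * np.polynomial.polynomial.polyval(x, coef_im)
    return spec.copy_with(spec.values - baseline)


def zero_pad(fid: np.ndarray, factor: int) -> np.ndarray:
    """Append zeros so the output is ``factor`` times the input length."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    fid = np.asarray(fid, dtype=np.complex128)
    out = np.zeros(int(factor) * len(fid), dtype=np.complex128)
    out[: len(fid)] = fid
    return out


def line_broaden(fid: np.ndarray, fs: float, lb: float) -> np.ndarray:
    """Exponential apodization: sample ``p`` scaled by ``exp(-pi*lb*p/fs)``.

    With this convention ``lb`` (Hz) adds directly to the FWHM of a
    Lorentzian line.  Doubles as the matched filter used in SNR evaluation.
    """
    if lb < 0:
        raise ValueError("lb must be >= 0")
    fid = np.asarray(fid, dtype=np.complex128)
    if lb == 0:
        return fid.copy()
    p = np.arange(len(fid))
    return fid * np.exp(-np.pi * lb * p / fs)


def subtract_reference(acq: AcquisitionSet, ref: AcquisitionSet) -> AcquisitionSet:
    """Pointwise complex subtraction of a reference acquisition.

    Used e.g. to remove the water peak or broad macromolecule baseline.  A
    single-transient reference is broadcast over all transients.
    """
    if (
        ref.n_channels != acq.n_channels
        or ref.n_points != acq.n_points
        or ref.sampling_frequency != acq.sampling_frequency
    ):
        raise ValueError(
            "reference acquisition does not match: "
            f"channels {ref.n_channels}/{acq.n_channels}, "
            f"points {ref.n_points}/{acq.n_points}, "
            f"fs {ref.sampling_frequency}/{acq.sampling_frequency}"
        )
    if ref.n_transients == acq.n_transients:
        out = acq.data - ref.data
    elif ref.n_transients == 1:
        out = acq.data - ref.data[:, :1, :]
    else:
        raise ValueError(
            f"reference transient count {ref.n_transients} is neither 1 nor "
            f"{acq.n_transients}"
        )
    return acq.evolve(
        out, "subtract_reference", {"ref_digest": ref.digest()}
    )


@dataclasses.dataclass
class AlignmentResult:
    shifts: np.ndarray  # integer bins per channel
    aligned: list[Spectrum]
    low_confidence: np.ndarray  # bool per channel
    reference_channel: int


def align_frequencies(
    spectra: Sequence[Spectrum],
    reference_channel: int | str = "auto",
    search_window: int = 25,
) -> AlignmentResult:
    """Align per-channel spectra by integer-bin circular shifts.

    Each channel is shifted by the lag (within ``±search_window`` bins) that
    maximises the cross-correlation of its magnitude spectrum with the
    reference channel's.  ``"auto"`` picks the channel whose magnitude
    spectrum has the largest maximum.  A channel whose correlation peak has
    prominence below twice the off-peak baseline is flagged low-confidence.
    """
    if len(spectra) < 2:
        raise ValueError("alignment needs at least 2 channels")
    n_bins = spectra[0].n_bins
    if search_window >= n_bins // 2:
        raise ValueError("search_window must be < half the spectrum length")
    mags = np.array([np.abs(s.values) for s in spectra])
    if reference_channel == "auto":
        ref = int(np.argmax(mags.max(axis=1)))
    else:
        ref = int(reference_channel)
    ref_mag = mags[ref]

    lags = np.arange(-search_window, search_window + 1)
    shifts = np.zeros(len(spectra), dtype=int)
    low_conf = np.zeros(len(spectra), dtype=bool)
    for c, mag in enumerate(mags):
        if c == ref:
            continue
        corr = np.array(
            [np.dot(np.roll(mag, lag), ref_mag) for lag in lags]
        )
        best = int(np.argmax(corr))
        shifts[c] = lags[best]
        others = np.delete(corr, best)
        baseline = float(np.median(others))
        prominence = corr[best] - baseline
        off_spread = float(np.max(others) - baseline)
        low_conf[c] = prominence < 2.0 * off_spread if off_spread > 0 else False
    aligned = [
        s.copy_with(np.roll(s.values, int(shifts[c]))) for c, s in enumerate(spectra)
    ]
    return AlignmentResult(
        shifts=shifts, aligned=aligned, low_confidence=low_conf, reference_channel=ref
    )
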