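"""Multi-channel coil combination.

A combined spectrum is a complex weighted sum of the per-channel spectra,
``combined(f) = sum_k w_k * S_k(f)``; because the weighting is linear it is
applied identically in the time domain when a combined FID is wanted.  Six
weighting methods are provided:

``equal``
    w_k = 1/n.  Needs phased channels.
``snr``
    Real weights proportional to each channel's matched-filter SNR.  Needs
    phased channels.
``sn2``
    Complex weights A_k * exp(-i*phi_k) / sigma_k^2 from a fitted reference
    peak (amplitude and phase) over the channel noise variance.
``wsvd`` / ``wsvd_apod``
    Noise-whitened rank-1 SVD of the channel FID matrix.  The +Apod variant
    estimates the channel weight vector from a line-broadened copy of the
    whitened data (suppressing high-frequency noise at low SNR) but applies
    it to the un-apodized data.
``aoc``
    Noise-adjusted matched filter from a coil-sensitivity estimate (e.g. an
    unsuppressed water scan) and the inverse of the full noise correlation
    matrix; optimal output SNR among all linear combinations for the given
    noise covariance.

The first three methods assume uncorrelated channel noise; WSVD and AOC
account for correlation through the covariance / full correlation matrix.
:func:`select_method` implements the decision tree that picks a method from
what the user has available (water reference, noise region/scan, channel
correlation, rough SNR, phasing state).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import scipy.linalg

from .core import AcquisitionSet, Spectrum, fid_to_spectrum
from .preprocess import line_broaden
from .quantify import SnrSpec, _noise_bins

__all__ = [
    "NoiseCovariance",
    "CombinationWeights",
    "SensitivityEstimate",
    "estimate_noise_covariance",
    "weights_equal",
    "weights_snr",
    "weights_sn2",
    "apply_weights",
    "wsvd_combine",
    "estimate_sensitivities",
    "aoc_combine",
    "CombinationContext",
    "select_method",
    "combine_fids",
    "METHODS",
    "RODGERS_SNR_THRESHOLDS",
]

METHODS = ("equal", "snr", "sn2", "wsvd", "wsvd_apod", "aoc")

#: Combined-SNR levels above which WSVD, WSVD+Apod and S/N^2 match the
#: optimal (sensitivity-map) combination, per the Rodgers guideline.
RODGERS_SNR_THRESHOLDS = {"wsvd": 35.0, "wsvd_apod": 15.0, "sn2": 60.0}


@dataclasses.dataclass
class NoiseCovariance:
    """Hermitian channel-by-channel noise covariance.

    ``kind="plain"`` is the sample covariance.  ``kind="full_correlation"``
    is the full noise correlation matrix: unit-normalised correlation off
    the diagonal with the per-channel covariances (variances) retained on
    the diagonal, capturing both intrinsic and extrinsic noise coupling.
    """

    matrix: np.ndarray
    n_samples_used: int
    kind: str = "plain"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.complex128)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(self.matrix, self.matrix.conj().T, atol=1e-12 * max(1.0, abs(np.trace(self.matrix)))):
            raise ValueError("covariance must be Hermitian")
        if self.kind == "plain":
            # the full-correlation variant mixes units on/off the diagonal
            # and can be slightly indefinite in degenerate cases; it is
            # regularized at use time instead
            eigs = np.linalg.eigvalsh(self.matrix)
            if eigs.min() < -1e-10 * max(np.trace(self.matrix).real, 1.0):
                raise ValueError("covariance must be positive semidefinite")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def regularized(self) -> np.ndarray:
        """Matrix with a ridge added if (near-)singular, with a warning."""
        tr = float(np.trace(self.matrix).real)
        eigs = np.linalg.eigvalsh(self.matrix)
        if eigs.min() < 1e-10 * tr:
            warnings.warn(
                "noise covariance is singular or ill-conditioned; adding "
                "ridge 1e-8 * trace to the diagonal",
                stacklevel=3,
            )
            return self.matrix + 1e-8 * tr * np.eye(self.n_channels)
        return self.matrix


@dataclasses.dataclass
class CombinationWeights:
    """Complex per-channel weights plus the method that produced them."""

    w: np.ndarray
    method: str
    quality: float | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.complex128)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        needs_quality = self.method in ("wsvd", "wsvd_apod", "aoc")
        if needs_quality != (self.quality is not None):
            raise ValueError(
                f"quality must be present iff method is wsvd/wsvd_apod/aoc "
                f"(method={self.method}, quality={self.quality})"
            )


@dataclasses.dataclass
class SensitivityEstimate:
    """Relative complex coil sensitivities (amplitude and phase per channel)."""

    s: np.ndarray
    source: str = "water_reference"
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.complex128)
        if np.all(self.s == 0):
            raise ValueError("sensitivities must not be all zero")


# ---------------------------------------------------------------------------
# Noise covariance
# ---------------------------------------------------------------------------


def estimate_noise_covariance(
    acq: AcquisitionSet,
    noise_source: tuple | AcquisitionSet = ("last", 400),
    kind: str = "plain",
    transient: int = 0,
) -> NoiseCovariance:
    """Estimate the channel noise covariance.

    ``noise_source`` is either a spectral region of the data itself — the
    ``("last", k)`` convention or a Hz interval, assumed peak-free by the
    caller — or a separate noise-only acquisition (transmitter off), whose
    full time series is used.
    """
    if kind not in ("plain", "full_correlation"):
        raise ValueError(f"unknown covariance kind {kind!r}")
    if isinstance(noise_source, AcquisitionSet):
        samples = noise_source.data.reshape(noise_source.n_channels, -1).T
    else:
        spectra = np.stack(
            [
                fid_to_spectrum(
                    acq.data[c, transient], acq.sampling_frequency,
                    halve_first_point=False,
                ).values
                for c in range(acq.n_channels)
            ],
            axis=1,
        )
        ref = fid_to_spectrum(
            acq.data[0, transient], acq.sampling_frequency, halve_first_point=False
        )
        idx = _noise_bins(ref, noise_source)
        samples = spectra[idx]  # (n_samples, n_channels)
    n_samples, n_ch = samples.shape
    if n_samples < 2 * n_ch:
        raise ValueError(
            f"need at least {2 * n_ch} noise samples for {n_ch} channels; got {n_samples}"
        )
    if n_samples < 10 * n_ch:
        warnings.warn(
            f"only {n_samples} noise samples for {n_ch} channels; the "
            "covariance estimate will be noisy",
            stacklevel=2,
        )
    centered = samples - samples.mean(axis=0)
    cov = centered.conj().T @ centered / (n_samples - 1)
    cov = 0.5 * (cov + cov.conj().T)
    if kind == "full_correlation":
        var = np.real(np.diag(cov)).copy()
        denom = np.sqrt(np.outer(var, var))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, cov / denom, 0.0)
        np.fill_diagonal(corr, var)
        cov = 0.5 * (corr + corr.conj().T)
    return NoiseCovariance(matrix=cov, n_samples_used=n_samples, kind=kind)


# ---------------------------------------------------------------------------
# Weight constructors
# ---------------------------------------------------------------------------


def weights_equal(n_channels: int) -> CombinationWeights:
    if n_channels < 1:
        raise ValueError("need at least one channel")
    return CombinationWeights(
        w=np.full(n_channels, 1.0 / n_channels, dtype=np.complex128),
        method="equal",
    )


def weights_snr(per_channel_snr: Sequence[float]) -> CombinationWeights:
    """Real weights proportional to per-channel SNR (channels must be phased)."""
    snr = np.asarray(per_channel_snr, dtype=float)
    if np.any(snr < 0):
        raise ValueError("SNR values must be >= 0")
    total = snr.sum()
    if total == 0:
        raise ValueError("all-zero SNRs: cannot form weights")
    return CombinationWeights(w=(snr / total).astype(np.complex128), method="snr")


def weights_sn2(
    ref_peak_fits: Sequence[tuple[float, float]],
    noise_vars: Sequence[float],
) -> CombinationWeights:
    """S/N^2 weights from reference-peak fits: A_k * exp(-i*phi_k) / sigma_k^2.

    ``ref_peak_fits`` holds per-channel (amplitude, phase) of the fitted
    reference peak; the conjugate phase aligns all channels before summation.
    Weights are normalised to unit L2 norm (SNR and area-ratio metrics are
    invariant to the overall scale).
    """
    amps = np.array([a for a, _ in ref_peak_fits], dtype=float)
    phases = np.array([p for _, p in ref_peak_fits], dtype=float)
    sig2 = np.asarray(noise_vars, dtype=float)
    if amps.shape != sig2.shape:
        raise ValueError("ref_peak_fits and noise_vars must have equal length")
    if np.any(sig2 <= 0):
        raise ValueError("all noise variances must be > 0")
    w = amps * np.exp(-1j * phases) / sig2
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("all-zero weights")
    return CombinationWeights(w=w / norm, method="sn2")


def apply_weights(
    spectra: Sequence[Spectrum], weights: CombinationWeights
) -> Spectrum:
    """Weighted sum of per-channel spectra: combined(f) = sum_k w_k S_k(f)."""
    if len(spectra) != len(weights.w):
        raise ValueError(
            f"{len(spectra)} spectra but {len(weights.w)} weights"
        )
    vals = np.zeros_like(spectra[0].values)
    for wk, s in zip(weights.w, spectra):
        vals = vals + wk * s.values
    return spectra[0].copy_with(vals)


def combine_fids(data: np.ndarray, weights: CombinationWeights) -> np.ndarray:
    """Time-domain equivalent of :func:`apply_weights` for (channel, point) data."""
    data = np.asarray(data, dtype=np.complex128)
    return weights.w @ data


# ---------------------------------------------------------------------------
# WSVD
# ---------------------------------------------------------------------------


def _phase_fix(fid: np.ndarray, fs: float) -> complex:
    """Unit phasor making the tallest spectral peak real-positive."""
    spec = fid_to_spectrum(fid, fs)
    k = int(np.argmax(np.abs(spec.values)))
    return np.exp(-1j * np.angle(spec.values[k]))


def wsvd_combine(
    acq: AcquisitionSet,
    cov: NoiseCovariance,
    apod_lb: float = 0.0,
    transient: int = 0,
) -> tuple[np.ndarray, CombinationWeights]:
    """Whitened-SVD combination of one (pre-averaged) transient.

    The channel FID matrix is noise-whitened with the inverse Cholesky
    factor of the covariance, and the rank-1 SVD gives the combined FID
    (``u1 * sigma1``) with the leading right singular vector as channel
    weights in whitened space.  With ``apod_lb > 0`` the singular vectors
    are estimated from a line-broadened copy but applied to the un-apodized
    whitened data.  The quality score

        Q = (n_ch * sigma1^2 / sum_i sigma_i^2 - 1) / (n_ch - 1)

    is 1 exactly when the data matrix is rank one (pure common signal) and
    falls toward 0 as noise spreads energy over the remaining singular
    values.
    """
    if apod_lb < 0:
        raise ValueError("apod_lb must be >= 0")
    X = acq.data[:, transient, :].T  # (n_points, n_channels)
    if not np.any(X):
        raise ValueError("all-zero data")
    n_ch = X.shape[1]
    R = cov.regularized()
    L = np.linalg.cholesky(R)
    # X_white = X @ L^{-H}
    Xw = scipy.linalg.solve_triangular(L, X.conj().T, lower=True).conj().T

    if apod_lb > 0:
        p = np.arange(X.shape[0])
        window = np.exp(-np.pi * apod_lb * p / acq.sampling_frequency)
        X_est = Xw * window[:, None]
    else:
        X_est = Xw
    u, svals, vh = np.linalg.svd(X_est, full_matrices=False)
    v1 = vh[0].conj()
    combined = Xw @ v1
    if n_ch > 1:
        q = (n_ch * svals[0] ** 2 / np.sum(svals**2) - 1.0) / (n_ch - 1.0)
    else:
        q = 1.0
    q = float(np.clip(q, 0.0, 1.0))

    phasor = _phase_fix(combined, acq.sampling_frequency)
    combined = combined * phasor
    # weights on the ORIGINAL (unwhitened) channels satisfy combined = X @ w
    # before normalisation; reported at unit L2 norm like the other methods
    w = phasor * scipy.linalg.solve_triangular(L.conj().T, v1, lower=False)
    weights = CombinationWeights(
        w=w / np.linalg.norm(w),
        method="wsvd_apod" if apod_lb > 0 else "wsvd",
        quality=q,
    )
    return combined, weights


# ---------------------------------------------------------------------------
# AOC
# ---------------------------------------------------------------------------


def estimate_sensitivities(
    water_acq: AcquisitionSet,
    peak_region: tuple[float, float] | None = None,
    transient: int = 0,
) -> SensitivityEstimate:
    """Relative coil sensitivities from an unsuppressed water (or prominent
    metabolite) acquisition.

    All channels are read at the single spectral bin where the reference
    channel (the one with the largest peak) is maximal, so the relative
    phases are meaningful.  A low-confidence flag is attached when every
    channel's peak magnitude is below 3x the local noise floor.
    """
    fs = water_acq.sampling_frequency
    spectra = np.stack(
        [
            fid_to_spectrum(water_acq.data[c, transient], fs).values
            for c in range(water_acq.n_channels)
        ]
    )
    ref_spec = fid_to_spectrum(water_acq.data[0, transient], fs)
    if peak_region is None:
        idx = np.arange(ref_spec.n_bins)
    else:
        idx = ref_spec.slice_bins(*peak_region)
        if idx.size == 0:
            raise ValueError(f"peak_region {peak_region} contains no bins")
    mags = np.abs(spectra[:, idx])
    ref_ch = int(np.argmax(mags.max(axis=1)))
    k = int(idx[np.argmax(mags[ref_ch])])
    s = spectra[:, k]

    n_tail = min(400, ref_spec.n_bins // 4)
    noise_rms = np.sqrt(np.mean(np.abs(spectra[:, -n_tail:]) ** 2, axis=1))
    # the tallest of n noise bins reaches ~rms*sqrt(ln n); a credible peak
    # must clear 3x that order statistic
    floor = 3.0 * noise_rms * np.sqrt(np.log(max(ref_spec.n_bins, 2)))
    low_conf = bool(np.all(np.abs(s) < np.maximum(floor, 1e-300)))
    if low_conf:
        warnings.warn(
            "all-channel reference peak below 3x local noise; sensitivity "
            "estimate is low-confidence",
            stacklevel=2,
        )
    return SensitivityEstimate(s=s, low_confidence=low_conf)


def aoc_combine(
    acq: AcquisitionSet,
    sens: SensitivityEstimate,
    full_corr: NoiseCovariance,
    transient: int = 0,
) -> tuple[np.ndarray, CombinationWeights]:
    """Adaptively optimized combination (noise-adjusted matched filter).

    With sensitivities ``s`` and noise matrix ``R`` the weights are

        w = R^{-1} conj(s) / sqrt(s^H R^{-1} s)

    (the Hermitian quadratic form is real for PSD ``R``), normalising the
    combined output to unit noise power; with ``R = I`` this reduces to
    Roemer's sensitivity-conjugate weighting.  For any noise with covariance
    ``R`` this maximises the combined SNR over all linear combinations.
    """
    if full_corr.n_channels != acq.n_channels:
        raise ValueError(
            f"correlation matrix is {full_corr.n_channels}-channel but data "
            f"has {acq.n_channels}"
        )
    if len(sens.s) != acq.n_channels:
        raise ValueError("sensitivity estimate does not match channel count")
    R = full_corr.regularized()
    # solve in the transposed system so that combined = sum_k w_k x_k has
    # unit noise power: w = R^{-T} conj(s) / sqrt(s^H R^{-1} s)
    s = sens.s
    Rinv_s = np.linalg.solve(R, s)
    norm2 = float(np.real(s.conj() @ Rinv_s))  # s^H R^{-1} s, real for PSD R
    if norm2 <= 0:
        raise ValueError("sensitivity vector is null with respect to R")
    w = np.linalg.solve(R.T, s.conj()) / np.sqrt(norm2)
    combined = w @ acq.data[:, transient, :]
    # quality of the full-correlation estimate grows with the sample count
    # used to build it; saturates at 10 samples per channel entry
    quality = float(
        np.clip(full_corr.n_samples_used / (10.0 * acq.n_channels), 0.0, 1.0)
    )
    if sens.low_confidence:
        quality = 0.0
    weights = CombinationWeights(w=w, method="aoc", quality=quality)
    return combined, weights


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CombinationContext:
    """What the user has available when choosing a combination method."""

    has_water_or_prominent_ref: bool
    has_noise_region_or_scan: bool
    channels_correlated: bool
    est_combined_snr: float | None  # None = unknown
    channels_phased: bool


def select_method(ctx: CombinationContext) -> tuple[str, str]:
    """Decision tree: pick a combination method from the available context.

    Preference order: AOC when both a water/metabolite reference and noise
    information exist; otherwise the whitened-SVD family when a noise
    region/scan allows covariance estimation, using the Rodgers combined-SNR
    guideline (WSVD above ~35, WSVD+Apod above ~15, S/N^2 above ~60) to
    choose the variant; SNR or equal weighting as terminal fallbacks.
    Always returns a method plus a human-readable rationale naming the
    branch taken.
    """
    snr = ctx.est_combined_snr
    if ctx.has_water_or_prominent_ref and ctx.has_noise_region_or_scan:
        return (
            "aoc",
            "water/prominent reference and noise information available: AOC "
            "uses the sensitivity estimate with the inverse full noise "
            "correlation matrix and is most accurate at low SNR",
        )
    if ctx.has_noise_region_or_scan:
        if snr is None or snr >= RODGERS_SNR_THRESHOLDS["wsvd"]:
            return (
                "wsvd",
                "noise covariance estimable and combined SNR "
                f"{'unknown' if snr is None else f'~{snr:g}'} >= 35 "
                "(Rodgers guideline): WSVD",
            )
        if snr >= RODGERS_SNR_THRESHOLDS["wsvd_apod"]:
            return (
                "wsvd_apod",
                f"combined SNR ~{snr:g} below the WSVD guideline of 35 but "
                "above 15: apodized weight estimation (WSVD+Apod)",
            )
        if ctx.channels_phased:
            return (
                "snr",
                f"combined SNR ~{snr:g} below the WSVD+Apod guideline of 15; "
                "channels are phased, so SNR weighting is the safest scalar "
                "method",
            )
        return (
            "equal",
            f"combined SNR ~{snr:g} too low for SVD-based weighting and "
            "channels unphased: equal weighting fallback",
        )
    if ctx.has_water_or_prominent_ref:
        if (snr is None or snr >= RODGERS_SNR_THRESHOLDS["sn2"]) and not ctx.channels_correlated:
            return (
                "sn2",
                "reference peak available, no noise region, channels "
                "uncorrelated and combined SNR "
                f"{'unknown' if snr is None else f'~{snr:g}'} >= 60 "
                "(Rodgers guideline): S/N^2 weighting",
            )
        if ctx.channels_phased:
            return (
                "snr",
                "reference peak available but correlation or low SNR rules "
                "out S/N^2; channels phased: SNR weighting",
            )
        return (
            "equal",
            "reference peak available but no noise information, low/unknown "
            "SNR and unphased channels: equal weighting fallback",
        )
    if ctx.channels_phased:
        return (
            "snr",
            "no reference and no noise information; channels phased: SNR "
            "weighting",
        )
    return (
        "equal",
        "no reference, no noise information and unphased channels: equal "
        "weighting is the terminal fallback",
    )
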