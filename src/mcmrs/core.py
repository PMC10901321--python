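"""Core containers and Fourier conventions for multi-channel MRS data.

An :class:`AcquisitionSet` holds complex free-induction-decay (FID) samples
indexed ``(channel, transient, point)`` together with the sampling frequency,
the carrier (transmitter) frequency and an append-only provenance log.  A
:class:`Spectrum` is the frequency-domain counterpart: a complex trace on a
uniform, zero-centred axis in Hz relative to the carrier.

Fourier convention
------------------
The forward transform is the unnormalised DFT with the zero-frequency bin
centred (``fftshift``).  By default the first FID point is halved before the
transform; this standard trick removes the constant baseline offset that the
one-sided (causal) FID otherwise produces.  The inverse transform undoes the
halving so that ``spectrum_to_fid(fid_to_spectrum(x)) == x``.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping, Sequence

import numpy as np

from .provenance import OperationRecord, data_digest

__all__ = [
    "AcquisitionSet",
    "Spectrum",
    "concat_acquisitions",
    "fid_to_spectrum",
    "spectrum_to_fid",
]


@dataclasses.dataclass
class AcquisitionSet:
    """Multi-channel, multi-transient time-domain acquisition.

    Parameters
    ----------
    data
        Complex array of shape ``(n_channels, n_transients, n_points)``.
    sampling_frequency
        Spectral bandwidth in Hz (inverse of the dwell time).
    center_frequency
        Transmitter/carrier frequency in Hz; used only to derive a ppm axis
        for display.
    provenance
        Ordered operation records.  Treated as append-only: operators return
        new sets via :meth:`evolve`, which appends exactly one record.
    """

    data: np.ndarray
    sampling_frequency: float
    center_frequency: float
    provenance: list[OperationRecord] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim == 1:
            self.data = self.data[np.newaxis, np.newaxis, :]
        elif self.data.ndim == 2:  # (channel, point): single transient
            self.data = self.data[:, np.newaxis, :]
        if self.data.ndim != 3:
            raise ValueError(
                f"data must have shape (channel, transient, point); got {self.data.shape}"
            )
        if self.data.shape[-1] == 0:
            raise ValueError("acquisition must contain at least one point")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("acquisition contains non-finite samples")
        if not self.sampling_frequency > 0:
            raise ValueError("sampling_frequency must be positive")

    # -- shape accessors ---------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_transients(self) -> int:
        return self.data.shape[1]

    @property
    def n_points(self) -> int:
        return self.data.shape[2]

    @property
    def dwell_time(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sampling_frequency

    def digest(self) -> str:
        return data_digest(self.data)

    def evolve(
        self,
        data: np.ndarray,
        operation: str,
        parameters: Mapping[str, Any] | None = None,
        **meta_overrides: float,
    ) -> "AcquisitionSet":
        """Return a new set with ``data`` and one appended provenance record."""
        new = AcquisitionSet(
            data=np.asarray(data, dtype=np.complex128),
            sampling_frequency=meta_overrides.get(
                "sampling_frequency", self.sampling_frequency
            ),
            center_frequency=meta_overrides.get(
                "center_frequency", self.center_frequency
            ),
            provenance=list(self.provenance),
        )
        prev = new.provenance[-1] if new.provenance else None
        new.provenance.append(
            OperationRecord.create(
                name=operation,
                parameters=parameters or {},
                input_digest=self.digest(),
                output_digest=new.digest(),
                previous=prev,
            )
        )
        return new


@dataclasses.dataclass
class Spectrum:
    """Complex frequency-domain trace on a uniform zero-centred axis (Hz)."""

    values: np.ndarray
    frequency_axis: np.ndarray
    sampling_frequency: float
    zero_fill_factor: int = 1
    apodization_hz: float = 0.0
    first_point_halved: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.frequency_axis = np.asarray(self.frequency_axis, dtype=np.float64)
        if self.values.shape != self.frequency_axis.shape:
            raise ValueError("values and frequency_axis must have equal length")
        if len(self.values) < 2:
            raise ValueError("spectrum needs at least 2 bins")
        steps = np.diff(self.frequency_axis)
        if not np.all(steps > 0):
            raise ValueError("frequency_axis must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValueError("frequency_axis must be uniform")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def bin_width(self) -> float:
        return self.sampling_frequency / self.n_bins

    def ppm_axis(self, reference_hz: float, center_frequency: float) -> np.ndarray:
        """Display-only chemical-shift axis: (f - ref) / (f0 * 1e-6)."""
        return (self.frequency_axis - reference_hz) / (center_frequency * 1e-6)

    def slice_bins(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Indices of bins with frequency in [f_lo, f_hi]."""
        if f_hi < f_lo:
            f_lo, f_hi = f_hi, f_lo
        idx = np.nonzero(
            (self.frequency_axis >= f_lo) & (self.frequency_axis <= f_hi)
        )[0]
        return idx

    def copy_with(self, values: np.ndarray) -> "Spectrum":
        return Spectrum(
            values=values,
            frequency_axis=self.frequency_axis.copy(),
            sampling_frequency=self.sampling_frequency,
            zero_fill_factor=self.zero_fill_factor,
            apodization_hz=self.apodization_hz,
            first_point_halved=self.first_point_halved,
        )


def concat_acquisitions(parts: Sequence[AcquisitionSet]) -> AcquisitionSet:
    """Concatenate acquisitions along the transient axis, in load order.

    All parts must agree in channel count, point count, sampling and
    center frequency; later files are treated as a continuation of the
    earlier ones.
    """
    if not parts:
        raise ValueError("concat_acquisitions requires at least one part")
    first = parts[0]
    for i, p in enumerate(parts[1:], start=1):
        for field, a, b in [
            ("n_channels", first.n_channels, p.n_channels),
            ("n_points", first.n_points, p.n_points),
            ("sampling_frequency", first.sampling_frequency, p.sampling_frequency),
            ("center_frequency", first.center_frequency, p.center_frequency),
        ]:
            if a != b:
                raise ValueError(
                    f"incompatible acquisitions: part {i} differs in {field} ({b} != {a})"
                )
    if len(parts) == 1:
        return first
    data = np.concatenate([p.data for p in parts], axis=1)
    return first.evolve(
        data,
        "concat_acquisitions",
        {"n_parts": len(parts), "n_transients": [p.n_transients for p in parts]},
    )


def fid_to_spectrum(
    fid: np.ndarray,
    fs: float,
    zero_fill_factor: int = 1,
    halve_first_point: bool = True,
) -> Spectrum:
    """Unnormalised, zero-centred DFT of a FID.

    ``zero_fill_factor`` pads the FID with zeros to ``factor * n`` points,
    interpolating the spectrum without changing on-bin peak values.  The
    first point is halved by default to suppress the baseline offset of a
    one-sided decay.
    """
    fid = np.asarray(fid, dtype=np.complex128)
    if fid.size == 0:
        raise ValueError("fid must be non-empty")
    if zero_fill_factor < 1:
        raise ValueError("zero_fill_factor must be >= 1")
    x = fid.copy()
    if halve_first_point:
        x[0] = 0.5 * x[0]
    n_out = int(zero_fill_factor) * len(x)
    values = np.fft.fftshift(np.fft.fft(x, n=n_out))
    axis = np.fft.fftshift(np.fft.fftfreq(n_out, d=1.0 / fs))
    return Spectrum(
        values=values,
        frequency_axis=axis,
        sampling_frequency=fs,
        zero_fill_factor=int(zero_fill_factor),
        first_point_halved=halve_first_point,
    )


def spectrum_to_fid(spec: Spectrum, n_points: int | None = None) -> np.ndarray:
    """Invert :func:`fid_to_spectrum` (undoing zero fill and first-point halving)."""
    x = np.fft.ifft(np.fft.ifftshift(spec.values))
    if n_points is None:
        n_points = spec.n_bins // spec.zero_fill_factor
    x = x[:n_points].copy()
    if spec.first_point_halved:
        x[0] = 2.0 * x[0]
    return x
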