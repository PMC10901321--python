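"""Reader/writer for the jMRUI Data Textfile (ASCII) dialect.

The format is a plain-text header of ``Key: value`` lines followed by one
numeric block per signal.  The keys honoured here are the common set:

* ``PointsInDataset`` — points per signal (mandatory)
* ``DatasetsInFile`` — number of signals (default 1)
* ``SamplingInterval`` — dwell time in **milliseconds** (mandatory)
* ``TransmitterFrequency`` — carrier in Hz (mandatory)
* ``ChannelsInFile`` — extension key: consecutive signals are receive
  channels (channel index varies fastest).  The single-signal jMRUI format
  has no native notion of a coil channel, so this mapping is a convention of
  this package; ``signals_as="transients"`` reinterprets every signal as a
  transient of a single channel instead.

Numeric rows carry four whitespace-separated columns — Re/Im of the FID and
Re/Im of its FFT — matching what jMRUI itself writes; only the first two are
used on read.  Lines starting with ``#`` are comments (used to serialize the
provenance log) and are ignored by the reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import AcquisitionSet
from .provenance import OperationRecord

__all__ = ["read_jmrui_text", "write_jmrui_text", "JmruiFormatError"]

_MANDATORY_KEYS = ("PointsInDataset", "SamplingInterval", "TransmitterFrequency")


class JmruiFormatError(ValueError):
    """Raised when a file does not follow the jMRUI text dialect."""


def read_jmrui_text(
    path: str | Path, signals_as: str = "auto"
) -> AcquisitionSet:
    """Load a jMRUI Data Textfile.

    Parameters
    ----------
    path
        Input file.
    signals_as
        ``"auto"`` honours a ``ChannelsInFile`` key when present;
        ``"transients"`` forces every signal to be a transient of one
        channel; ``"channels"`` forces every signal to be a channel.
    """
    if signals_as not in ("auto", "transients", "channels"):
        raise ValueError(f"unknown signals_as: {signals_as!r}")
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[list[complex]] = []
    current: list[complex] | None = None
    provenance: list[OperationRecord] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# provenance:"):
                    try:
                        provenance.append(
                            OperationRecord.from_dict(
                                json.loads(line[len("# provenance:") :])
                            )
                        )
                    except (json.JSONDecodeError, KeyError):
                        pass  # malformed provenance comments are non-fatal
                continue
            if line.lower().startswith("signal ") or line.lower().startswith("sig(t)"):
                # "Signal N out of M in file" marks the start of a block
                if line.lower().startswith("signal ") and "out of" in line.lower():
                    current = []
                    rows.append(current)
                continue
            if ":" in line and not _looks_numeric(line):
                key, _, value = line.partition(":")
                header[key.strip()] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            try:
                nums = [float(p) for p in parts]
            except ValueError:
                if current is None:
                    continue  # free text (banner lines) before any signal block
                raise JmruiFormatError(
                    f"{path.name}:{lineno}: non-numeric sample line: {line!r}"
                ) from None
            if len(nums) < 2:
                raise JmruiFormatError(
                    f"{path.name}:{lineno}: expected at least 2 columns, got {len(nums)}"
                )
            if current is None:  # tolerate files without explicit signal markers
                current = []
                rows.append(current)
            current.append(complex(nums[0], nums[1]))

    for key in _MANDATORY_KEYS:
        if key not in header:
            raise JmruiFormatError(f"{path.name}: missing mandatory header key {key!r}")

    n_points = int(float(header["PointsInDataset"]))
    n_signals = int(float(header.get("DatasetsInFile", len(rows) or 1)))
    dwell_ms = float(header["SamplingInterval"])
    fs = 1.0 / (dwell_ms * 1e-3)
    f0 = float(header["TransmitterFrequency"])

    samples = [s for s in rows if s]
    if len(samples) != n_signals:
        raise JmruiFormatError(
            f"{path.name}: header declares {n_signals} signals, found {len(samples)}"
        )
    for i, s in enumerate(samples):
        if len(s) != n_points:
            raise JmruiFormatError(
                f"{path.name}: signal {i + 1} has {len(s)} points, expected {n_points}"
            )

    flat = np.array(samples, dtype=np.complex128)  # (signal, point)
    n_channels = int(float(header.get("ChannelsInFile", 1)))
    if signals_as == "transients":
        n_channels = 1
    elif signals_as == "channels":
        n_channels = n_signals
    if n_signals % n_channels != 0:
        raise JmruiFormatError(
            f"{path.name}: {n_signals} signals not divisible by {n_channels} channels"
        )
    n_transients = n_signals // n_channels
    # channel index varies fastest: signal = transient * n_channels + channel
    data = flat.reshape(n_transients, n_channels, n_points).transpose(1, 0, 2)
    return AcquisitionSet(
        data=data,
        sampling_frequency=fs,
        center_frequency=f0,
        provenance=provenance,
    )


def write_jmrui_text(acq: AcquisitionSet, path: str | Path) -> None:
    """Write an acquisition as a jMRUI Data Textfile (re-readable)."""
    path = Path(path)
    n_signals = acq.n_channels * acq.n_transients
    lines = [
        "jMRUI Data Textfile",
        "",
        f"Filename: {path.name}",
        "",
        f"PointsInDataset: {acq.n_points}",
        f"DatasetsInFile: {n_signals}",
        f"SamplingInterval: {acq.dwell_time * 1e3!r}",
        "ZeroOrderPhase: 0",
        "BeginTime: 0",
        f"TransmitterFrequency: {acq.center_frequency!r}",
        "MagneticField: 0",
        "TypeOfNucleus: 0",
        f"ChannelsInFile: {acq.n_channels}",
        "NameOfPatient: ",
        "DateOfExperiment: ",
        "Spectrometer: ",
        "AdditionalInfo: ",
    ]
    for rec in acq.provenance:
        lines.append("# provenance:" + json.dumps(rec.to_dict(), sort_keys=True))
    lines += ["", "Signal and FFT", "sig(t)\tfft(t)"]
    for t in range(acq.n_transients):
        for c in range(acq.n_channels):
            sig_idx = t * acq.n_channels + c
            lines.append(f"Signal number: {sig_idx + 1} out of {n_signals} in file")
            fid = acq.data[c, t]
            fft = np.fft.fftshift(np.fft.fft(fid))
            for p in range(acq.n_points):
                lines.append(
                    f"{float(fid[p].real)!r}\t{float(fid[p].imag)!r}\t"
                    f"{float(fft[p].real)!r}\t{float(fft[p].imag)!r}"
                )
    path.write_text("\n".join(lines) + "\n")


def _looks_numeric(line: str) -> bool:
    parts = line.replace(",", " ").split()
    if len(parts) < 2:
        return False
    try:
        [float(p) for p in parts]
        return True
    except ValueError:
        return False
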