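"""Native hierarchical container: single-file HDF5 round-trip storage.

Complex samples are stored as separate float64 real/imaginary arrays so the
container round-trips bit-exactly; metadata live as root attributes and the
provenance chain as a JSON string dataset.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import AcquisitionSet
from .provenance import OperationRecord

__all__ = ["read_native", "write_native"]

_FORMAT_MARK = "mcmrs-native"
_FORMAT_VERSION = 1


def write_native(acq: AcquisitionSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT_MARK
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["sampling_frequency"] = float(acq.sampling_frequency)
        f.attrs["center_frequency"] = float(acq.center_frequency)
        f.create_dataset("data_real", data=np.ascontiguousarray(acq.data.real))
        f.create_dataset("data_imag", data=np.ascontiguousarray(acq.data.imag))
        prov = json.dumps([r.to_dict() for r in acq.provenance], sort_keys=True)
        f.create_dataset("provenance", data=prov)


def read_native(path: str | Path) -> AcquisitionSet:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != _FORMAT_MARK:
            raise ValueError(f"{path}: not a recognised native container")
        data = np.asarray(f["data_real"]) + 1j * np.asarray(f["data_imag"])
        prov_raw = f["provenance"][()]
        if isinstance(prov_raw, bytes):
            prov_raw = prov_raw.decode()
        provenance = [OperationRecord.from_dict(d) for d in json.loads(prov_raw)]
        return AcquisitionSet(
            data=data,
            sampling_frequency=float(f.attrs["sampling_frequency"]),
            center_frequency=float(f.attrs["center_frequency"]),
            provenance=provenance,
        )
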