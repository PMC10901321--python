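"""Append-only provenance records for reproducible processing chains.

Every mutating operation on an :class:`~mcmrs.core.AcquisitionSet` appends
exactly one :class:`OperationRecord`.  Records carry the operation name, its
fully serialized parameters, digests of the input and output sample arrays,
and a chain digest linking each record to its predecessor, so a pipeline can
be audited (and replayed) from the log alone.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from typing import Any, Mapping, Sequence

import numpy as np

from . import __version__

__all__ = ["OperationRecord", "data_digest", "verify_chain"]


def data_digest(data: np.ndarray) -> str:
    """SHA-256 digest of a sample array (shape + contiguous bytes)."""
    arr = np.ascontiguousarray(data)
    h = hashlib.sha256()
    h.update(str(arr.shape).encode())
    h.update(str(arr.dtype).encode())
    h.update(arr.tobytes())
    return h.hexdigest()


def _jsonable(value: Any) -> Any:
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, complex):
        return {"re": value.real, "im": value.imag}
    if isinstance(value, np.ndarray):
        return _jsonable(value.tolist())
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, Mapping):
        return {str(k): _jsonable(v) for k, v in value.items()}
    return value


@dataclasses.dataclass(frozen=True)
class OperationRecord:
    """One immutable entry in a provenance chain."""

    name: str
    parameters: dict
    input_digest: str
    output_digest: str
    timestamp: str
    version: str
    chain_digest: str

    @classmethod
    def create(
        cls,
        name: str,
        parameters: Mapping[str, Any],
        input_digest: str,
        output_digest: str,
        previous: "OperationRecord | None",
    ) -> "OperationRecord":
        params = _jsonable(dict(parameters))
        prev = previous.chain_digest if previous is not None else ""
        payload = json.dumps(
            [prev, name, params, input_digest, output_digest], sort_keys=True
        )
        chain = hashlib.sha256(payload.encode()).hexdigest()
        return cls(
            name=name,
            parameters=params,
            input_digest=input_digest,
            output_digest=output_digest,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            version=__version__,
            chain_digest=chain,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "OperationRecord":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})


def verify_chain(records: Sequence[OperationRecord]) -> bool:
    """Check that each record's chain digest follows from its predecessor.

    Timestamps and software version are deliberately outside the digest so
    that replaying a pipeline on the same inputs reproduces the same chain.
    """
    prev = None
    for rec in records:
        payload = json.dumps(
            [
                prev.chain_digest if prev is not None else "",
                rec.name,
                rec.parameters,
                rec.input_digest,
                rec.output_digest,
            ],
            sort_keys=True,
        )
        if hashlib.sha256(payload.encode()).hexdigest() != rec.chain_digest:
            return False
        prev = rec
    return True
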