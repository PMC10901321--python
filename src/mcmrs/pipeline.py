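"""Config-driven processing pipeline: load -> preprocess -> combine -> report.

A pipeline is a YAML/JSON mapping with the stages

.. code-block:: yaml

    load:
      files: [a.txt, b.txt]        # concatenated as continued transients
      format: jmrui                # or native
    preprocess:                    # optional, applied in listed order
      - {op: sliding_window_average, window: 4, step: 4}
      - {op: line_broaden, lb: 3.0}
    combine:                       # optional
      method: auto                 # or equal/snr/sn2/wsvd/wsvd_apod/aoc
      noise_region: 400            # last-k spectral bins
      water_ref: water.txt         # enables aoc
      apod_lb: 3.0
    evaluate:                      # optional
      matched_lb: 3.0
      noise_region: 400
    export:
      path: out.txt
      format: jmrui                # or native

Every stage appends to the acquisition's provenance chain; the JSON report
collects weights, quality, SNR, linewidth and the decision-tree rationale.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import combine as comb
from . import preprocess as prep
from .core import AcquisitionSet, concat_acquisitions, fid_to_spectrum
from .jmrui import read_jmrui_text, write_jmrui_text
from .native import read_native, write_native
from .quantify import SnrSpec, compute_snr, linewidth_fwhm

__all__ = ["run_pipeline", "export_for_quantification", "PipelineConfigError"]


class PipelineConfigError(ValueError):
    """Schema violation in a pipeline config; carries the offending field path."""


def _load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config: top level must be a mapping")
    if "load" not in cfg:
        raise PipelineConfigError("config.load: required")
    if "files" not in cfg["load"]:
        raise PipelineConfigError("config.load.files: required")
    return cfg


def _read(path: str | Path, fmt: str) -> AcquisitionSet:
    if fmt == "jmrui":
        return read_jmrui_text(path)
    if fmt == "native":
        return read_native(path)
    raise PipelineConfigError(f"unknown format {fmt!r} (expected jmrui or native)")


def export_for_quantification(
    acq: AcquisitionSet, path: str | Path, format: str = "jmrui"
) -> None:
    """Write an acquisition for external quantification software; both
    formats re-load cleanly for further preprocessing."""
    if format == "jmrui":
        write_jmrui_text(acq, path)
    elif format == "native":
        write_native(acq, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected jmrui or native)")


_PREP_OPS = {"sliding_window_average", "line_broaden", "zero_pad", "subtract_reference"}


def _apply_preprocess(acq: AcquisitionSet, steps: list[dict]) -> AcquisitionSet:
    for i, step in enumerate(steps):
        op = step.get("op")
        if op not in _PREP_OPS:
            raise PipelineConfigError(
                f"config.preprocess[{i}].op: unknown operation {op!r}"
            )
        if op == "sliding_window_average":
            acq = prep.sliding_window_average(
                acq, int(step["window"]), int(step.get("step", 1))
            )
        elif op == "line_broaden":
            lb = float(step["lb"])
            out = np.stack(
                [
                    [
                        prep.line_broaden(acq.data[c, t], acq.sampling_frequency, lb)
                        for t in range(acq.n_transients)
                    ]
                    for c in range(acq.n_channels)
                ]
            )
            acq = acq.evolve(out, "line_broaden", {"lb": lb})
        elif op == "zero_pad":
            factor = int(step["factor"])
            out = np.stack(
                [
                    [
                        prep.zero_pad(acq.data[c, t], factor)
                        for t in range(acq.n_transients)
                    ]
                    for c in range(acq.n_channels)
                ]
            )
            acq = acq.evolve(out, "zero_pad", {"factor": factor})
        elif op == "subtract_reference":
            ref = _read(step["file"], step.get("format", "jmrui"))
            acq = prep.subtract_reference(acq, ref)
    return acq


def _combine_stage(acq: AcquisitionSet, spec: dict, report: dict) -> AcquisitionSet:
    noise_k = int(spec.get("noise_region", 400))
    apod_lb = float(spec.get("apod_lb", 3.0))
    method = spec.get("method", "auto")
    water_path = spec.get("water_ref")
    water = _read(water_path, spec.get("format", "jmrui")) if water_path else None

    if method == "auto":
        snr_est = None
        try:
            probe = acq.data.mean(axis=0)[0]
            snr_est = compute_snr(
                probe, acq.sampling_frequency, SnrSpec(noise_region=("last", noise_k))
            )
        except ValueError:
            pass
        ctx = comb.CombinationContext(
            has_water_or_prominent_ref=water is not None,
            has_noise_region_or_scan=True,
            channels_correlated=bool(spec.get("channels_correlated", False)),
            est_combined_snr=snr_est,
            channels_phased=bool(spec.get("channels_phased", False)),
        )
        method, rationale = comb.select_method(ctx)
        report["decision_rationale"] = rationale
    report["method"] = method

    fs = acq.sampling_frequency
    data = acq.data[:, 0, :]
    quality = None
    if method == "equal":
        w = comb.weights_equal(acq.n_channels)
        combined = w.w @ data
    elif method == "snr":
        snrs = [
            compute_snr(data[c], fs, SnrSpec(noise_region=("last", noise_k)))
            for c in range(acq.n_channels)
        ]
        w = comb.weights_snr(snrs)
        combined = w.w @ data
    elif method == "sn2":
        raise PipelineConfigError(
            "config.combine.method: sn2 requires per-channel reference-peak "
            "fits; run `mcmrs fit` per channel and use the library API"
        )
    elif method in ("wsvd", "wsvd_apod"):
        cov = comb.estimate_noise_covariance(acq, ("last", noise_k), kind="plain")
        combined, w = comb.wsvd_combine(
            acq, cov, apod_lb=apod_lb if method == "wsvd_apod" else 0.0
        )
        quality = w.quality
    elif method == "aoc":
        if water is None:
            raise PipelineConfigError("config.combine.water_ref: required for aoc")
        sens = comb.estimate_sensitivities(water)
        full = comb.estimate_noise_covariance(
            acq, ("last", noise_k), kind="full_correlation"
        )
        combined, w = comb.aoc_combine(acq, sens, full)
        quality = w.quality
    else:
        raise PipelineConfigError(f"config.combine.method: unknown {method!r}")

    report["weights"] = [{"re": float(x.real), "im": float(x.imag)} for x in w.w]
    if quality is not None:
        report["quality"] = quality
    return acq.evolve(
        combined[np.newaxis, np.newaxis, :],
        "combine",
        {"method": method, "noise_region": noise_k},
    )


def run_pipeline(config_path: str | Path) -> tuple[AcquisitionSet, dict]:
    """Execute a pipeline config; returns the final acquisition and the report.

    Raises :class:`PipelineConfigError` on schema violations; stage failures
    propagate with the completed stages recorded in the report.
    """
    cfg = _load_config(config_path)
    report: dict[str, Any] = {"stages_completed": []}
    fmt = cfg["load"].get("format", "jmrui")
    parts = [_read(f, fmt) for f in cfg["load"]["files"]]
    acq = concat_acquisitions(parts)
    report["stages_completed"].append("load")

    if "preprocess" in cfg:
        acq = _apply_preprocess(acq, cfg["preprocess"] or [])
        report["stages_completed"].append("preprocess")

    if "combine" in cfg:
        acq = _combine_stage(acq, cfg["combine"], report)
        report["stages_completed"].append("combine")

    if "evaluate" in cfg:
        ev = cfg["evaluate"] or {}
        spec = SnrSpec(
            noise_region=("last", int(ev.get("noise_region", 400))),
            matched_lb=float(ev.get("matched_lb", 3.0)),
        )
        fid = acq.data[0, 0]
        report["snr"] = compute_snr(fid, acq.sampling_frequency, spec)
        try:
            report["linewidth_hz"] = linewidth_fwhm(
                fid_to_spectrum(fid, acq.sampling_frequency, zero_fill_factor=4)
            )
        except ValueError as exc:
            report["linewidth_hz"] = None
            report["linewidth_error"] = str(exc)
        report["stages_completed"].append("evaluate")

    if "export" in cfg:
        export_for_quantification(
            acq, cfg["export"]["path"], cfg["export"].get("format", "jmrui")
        )
        report["stages_completed"].append("export")
        report["output_digest"] = acq.digest()

    report["provenance"] = [r.to_dict() for r in acq.provenance]
    return acq, report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
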