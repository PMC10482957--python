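"""Shared file dialects.

Trial logs and feature tables are CSV with documented headers (see the
module docstrings that produce them). Multi-channel trace data use a
simple on-disk container: a directory holding a ``header.json`` (format
name, version, sampling rate, shapes) next to ``.npy`` arrays — chosen
over a bespoke binary dialect so every artifact stays inspectable with
standard tools. Times are stored in seconds (microsecond precision),
sample indices are 0-based, windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nsr.optotag import StimTrialEnsemble
from nsr.photometry import PhotometryTrace

FORMAT_NAME = "nsr-trace-container"
FORMAT_VERSION = 1


def _write_container(path: Path, header: dict, arrays: dict[str, np.ndarray]) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    header = dict(header, format=FORMAT_NAME, version=FORMAT_VERSION, arrays=sorted(arrays))
    (path / "header.json").write_text(json.dumps(header, indent=2))
    for name, arr in arrays.items():
        np.save(path / f"{name}.npy", arr)
    return path


def _read_container(path: Path) -> tuple[dict, dict[str, np.ndarray]]:
    header = json.loads((path / "header.json").read_text())
    if header.get("format") != FORMAT_NAME:
        raise ValueError(f"{path} is not an {FORMAT_NAME} container")
    arrays = {name: np.load(path / f"{name}.npy") for name in header["arrays"]}
    return header, arrays


def save_photometry(trace: PhotometryTrace, path: str | Path) -> Path:
    return _write_container(
        Path(path),
        {
            "kind": "photometry",
            "fs_acquired": trace.fs_acquired,
            "fs_analysis": trace.fs_analysis,
            "t0": trace.t0,
            "channels": {"470": "signal_470", "405": "isosbestic_405"},
        },
        {"signal_470": trace.signal_470, "isosbestic_405": trace.isosbestic_405},
    )


def load_photometry(path: str | Path) -> PhotometryTrace:
    header, arrays = _read_container(Path(path))
    return PhotometryTrace(
        signal_470=arrays["signal_470"],
        isosbestic_405=arrays["isosbestic_405"],
        fs_acquired=header["fs_acquired"],
        fs_analysis=header["fs_analysis"],
        t0=header.get("t0", 0.0),
    )


def save_ensemble(ensemble: StimTrialEnsemble, path: str | Path) -> Path:
    return _write_container(
        Path(path),
        {"kind": "stim_ensemble", "fs": ensemble.fs, "stim_sample": ensemble.stim_sample},
        {"control_traces": ensemble.control_traces, "test_traces": ensemble.test_traces},
    )


def load_ensemble(path: str | Path) -> StimTrialEnsemble:
    header, arrays = _read_container(Path(path))
    return StimTrialEnsemble(
        control_traces=arrays["control_traces"],
        test_traces=arrays["test_traces"],
        fs=header["fs"],
        stim_sample=header["stim_sample"],
    )


def save_spikes(spikes_by_unit: dict[str, np.ndarray], path: str | Path) -> Path:
    """Spike-time table CSV with columns ``unit, time`` (seconds)."""
    rows = []
    for unit, times in spikes_by_unit.items():
        for t in np.asarray(times, dtype=float):
            rows.append({"unit": unit, "time": f"{t:.6f}"})
    path = Path(path)
    pd.DataFrame(rows, columns=["unit", "time"]).to_csv(path, index=False)
    return path


def load_spikes(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        str(unit): grp["time"].to_numpy(dtype=float) for unit, grp in df.groupby("unit")
    }


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    p = Path(path)
    if p.is_dir():
        for child in sorted(p.rglob("*")):
            if child.is_file():
                h.update(child.name.encode())
                h.update(child.read_bytes())
    else:
        h.update(p.read_bytes())
    return h.hexdigest()
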