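"""Readers, writers and run configuration.

CSV is the interchange default (rows = channels, columns = samples, optional
header row of channel labels); EDF is read-only through ``mne`` when that
package is available.  Output writers are deterministic: identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import CCCAResult, ExtractedComponent, WeightSolution
from .types import MultiChannelRecording

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Validated configuration of one CLI run."""

    input: str
    fs: float
    n_bands: int = 5
    band_indices: list[int] | None = None
    mu: float | str = "auto"
    method: str = "ccca"
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    _KNOWN = ("input", "fs", "n_bands", "band_indices", "mu", "method",
              "seed", "output_dir", "log_level")

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if self.method not in ("ccca", "pca", "ica"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.mu != "auto" and not (0 < float(self.mu) < 0.5):
            raise ValueError("mu must be 'auto' or in (0, 0.5)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls._KNOWN)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _looks_numeric(row: list[str]) -> bool:
    try:
        [float(v) for v in row]
        return True
    except ValueError:
        return False


def read_recording(path, fs: float, fmt: str = "csv") -> MultiChannelRecording:
    """Read a channels-by-samples recording from CSV or EDF.

    CSV dialect: comma-separated, rows = channels, optional first header row
    of channel labels.  EDF requires all signals to share one sampling rate
    (which then overrides ``fs``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "edf":
        return _read_edf(path)
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    labels = None
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, raw in enumerate(reader, start=1):
            if not raw:
                continue
            if lineno == 1 and not _looks_numeric(raw):
                labels = [v.strip() for v in raw]
                continue
            try:
                rows.append([float(v) for v in raw])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({e})")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged rows with lengths {sorted(lengths)}")
    return MultiChannelRecording(np.array(rows), fs, labels)


def _read_edf(path: Path) -> MultiChannelRecording:
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires the 'mne' package") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rates = {raw.info["sfreq"]}
    if len(rates) != 1:  # pragma: no cover - mne resamples to a common rate
        raise ValueError(f"{path}: mixed sampling rates {sorted(rates)}")
    return MultiChannelRecording(raw.get_data(), float(raw.info["sfreq"]),
                                 list(raw.ch_names))


def write_recording(recording: MultiChannelRecording, path,
                    labels: bool = True) -> None:
    """Write a recording as CSV (rows = channels, optional label header)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if labels and recording.channel_labels:
            writer.writerow(recording.channel_labels)
        for row in recording.data:
            writer.writerow([_FLOAT_FMT % v for v in row])


def _write_matrix(mat: np.ndarray, path: Path) -> None:
    np.savetxt(path, np.atleast_2d(mat), delimiter=",", fmt=_FLOAT_FMT)


def write_outputs(component: ExtractedComponent, solution: WeightSolution,
                  out_dir, fs: float | None = None,
                  boundaries_hz=None, mu: float | None = None,
                  seed: int | None = None) -> dict[str, Path]:
    """Write extraction artifacts: y, s_i, weights, eigenvalues, metadata.

    Files (all deterministic given identical inputs):
    y.csv (1 x T), s_per_channel.csv (n_c x T), weights.csv (m x m, columns
    ordered by descending eigenvalue), eigenvalues.csv, metadata.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "y": out / "y.csv",
        "s_per_channel": out / "s_per_channel.csv",
        "weights": out / "weights.csv",
        "eigenvalues": out / "eigenvalues.csv",
        "metadata": out / "metadata.json",
    }
    _write_matrix(component.y, files["y"])
    _write_matrix(component.per_channel_s, files["s_per_channel"])
    _write_matrix(solution.W, files["weights"])
    _write_matrix(solution.eigenvalues, files["eigenvalues"])
    meta = {
        "boundaries_hz": (None if boundaries_hz is None
                          else [float(b) for b in boundaries_hz]),
        "mu": mu,
        "fs": fs,
        "ridge": solution.pencil.ridge,
        "seed": seed,
        "weight_set_used": component.weight_set_used,
        "eigenvalues": [float(v) for v in solution.eigenvalues],
        "Q": [[float(v) for v in row] for row in solution.pencil.Q],
    }
    with open(files["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return files


def write_result(result: CCCAResult, out_dir, fs: float,
                 seed: int | None = None) -> dict[str, Path]:
    """Write a full pipeline result, pulling boundaries and mu from the bank."""
    bank = result.filter_bank
    return write_outputs(
        result.component, result.solution, out_dir, fs=fs,
        boundaries_hz=bank.boundaries_hz(fs), mu=bank.mu, seed=seed,
    )
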