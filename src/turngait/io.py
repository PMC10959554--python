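"""Marker-trajectory and tabular I/O.

The canonical in-memory container is :class:`TrialRecording`: a set of named
3D marker series sampled at a fixed rate, positions in meters in a
right-handed lab frame with z vertical, time in seconds from frame 0
(``t = frame / rate``).  Interchange formats are TRC (the tab-delimited
mocap format) and a documented wide CSV; ground truth and analysis reports
travel as JSON sidecars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Markers every trial must provide: bilateral posterior-calcaneus (heel) and
#: second-metatarsal-head (toe) markers, plus the four iliac-spine markers.
REQUIRED_MARKERS = (
    "L_HEEL", "R_HEEL", "L_TOE", "R_TOE", "LASI", "RASI", "LPSI", "RPSI",
)

#: Common vendor spellings mapped onto the canonical names.  Extend via the
#: ``aliases`` argument of the readers.
DEFAULT_ALIASES: dict[str, str] = {
    "LHEE": "L_HEEL", "RHEE": "R_HEEL",
    "LHEEL": "L_HEEL", "RHEEL": "R_HEEL",
    "LTOE": "L_TOE", "RTOE": "R_TOE",
    "LMT2": "L_TOE", "RMT2": "R_TOE",
    "L_ASIS": "LASI", "R_ASIS": "RASI",
    "L_PSIS": "LPSI", "R_PSIS": "RPSI",
}

#: Row order for results tables, mirroring the standard presentation of
#: whole-turn parameters followed by per-leg parameters.
RESULTS_PARAMETER_ORDER = (
    "speed",
    "duration",
    "n_steps",
    "cadence",
    "stride_length_internal",
    "stride_length_external",
    "step_length_internal",
    "step_length_external",
    "stride_width_internal",
    "stride_width_external",
    "gait_cycle_internal",
    "gait_cycle_external",
    "stance_internal",
    "stance_external",
    "initial_double_support_internal",
    "initial_double_support_external",
    "stance_cycle_ratio_internal",
    "stance_cycle_ratio_external",
)


class TrajectoryFormatError(ValueError):
    """Raised for malformed or inconsistent trajectory files."""


@dataclass
class TrialRecording:
    """Time-synchronized 3D marker series for one walking trial.

    Parameters
    ----------
    sampling_rate : float
        Frames per second (Hz), > 0.
    markers : mapping of str to (n_frames, 3) float arrays
        Positions in meters.  All series must share the same length.
    metadata : dict
        Free-form trial metadata (subject id, condition, amplitude,
        direction, ...), persisted where the format allows.
    """

    sampling_rate: float
    markers: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {name: len(arr) for name, arr in self.markers.items()}
        if len(set(lengths.values())) > 1:
            raise TrajectoryFormatError(f"marker series length mismatch: {lengths}")
        self.markers = {
            name: np.asarray(arr, dtype=float).reshape(-1, 3)
            for name, arr in self.markers.items()
        }

    @property
    def n_frames(self) -> int:
        return 0 if not self.markers else len(next(iter(self.markers.values())))

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, ``frame / sampling_rate`` from frame 0."""
        return np.arange(self.n_frames) / self.sampling_rate

    def require(self, *names: str) -> None:
        missing = [n for n in (names or REQUIRED_MARKERS) if n not in self.markers]
        if missing:
            raise TrajectoryFormatError(f"required marker(s) missing: {', '.join(missing)}")

    def time_to_frame(self, t: float) -> int:
        return int(round(t * self.sampling_rate))


def _normalize_name(name: str, aliases: Mapping[str, str] | None) -> str:
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update(aliases)
    return table.get(name, table.get(name.upper(), name))


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(recording: TrialRecording, path: str | Path) -> None:
    """Write a recording as a standard TRC file (units m).

    Layout: PathFileType line, header-key line, header-value line, two
    marker-name / XYZ-label lines, blank line, then one row per frame
    (1-based frame number, time, X/Y/Z per marker).
    """
    if recording.n_frames == 0 or not recording.markers:
        raise ValueError("cannot write an empty recording")
    path = Path(path)
    names = list(recording.markers)
    rate = recording.sampling_rate
    nf, nm = recording.n_frames, len(names)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:g}\t{rate:g}\t{nf}\t{nm}\tm\t{rate:g}\t1\t{nf}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        axis_cells = "\t".join(
            f"X{i}\tY{i}\tZ{i}" for i in range(1, nm + 1)
        )
        fh.write("\t\t" + axis_cells + "\n\n")
        data = np.hstack([recording.markers[n] for n in names])
        for i in range(nf):
            row = "\t".join(f"{v:.8f}" for v in data[i])
            fh.write(f"{i + 1}\t{i / rate:.8f}\t{row}\n")


def read_trc(path: str | Path,
             aliases: Mapping[str, str] | None = None,
             require: bool = True) -> TrialRecording:
    """Read a TRC file into a :class:`TrialRecording` (positions in m).

    Units declared in the header (``mm`` or ``m``) are converted; marker
    names are normalized through the alias map.  Frame-count mismatches and
    truncated rows raise :class:`TrajectoryFormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise TrajectoryFormatError(f"{path}: not a TRC file")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    header = dict(zip(keys, vals))
    try:
        rate = float(header["DataRate"])
        n_frames = int(header["NumFrames"])
        units = header.get("Units", "mm").strip().lower()
    except (KeyError, ValueError) as exc:
        raise TrajectoryFormatError(f"{path}: malformed TRC header ({exc})") from exc
    if units not in ("m", "mm"):
        raise TrajectoryFormatError(f"{path}: unsupported units {units!r}")
    scale = 1.0 if units == "m" else 1e-3
    names = [_normalize_name(c, aliases) for c in lines[3].split("\t")[2:] if c.strip()]

    rows: list[list[float]] = []
    for raw in lines[5:]:
        if not raw.strip():
            continue
        cells = raw.split("\t")
        try:
            rows.append([float(c) for c in cells[2:2 + 3 * len(names)]])
        except ValueError as exc:
            raise TrajectoryFormatError(f"{path}: unparseable data row ({exc})") from exc
        if len(rows[-1]) != 3 * len(names):
            raise TrajectoryFormatError(
                f"{path}: truncated data row (frame {len(rows)}): "
                f"expected {3 * len(names)} values, got {len(rows[-1])}")
    if len(rows) != n_frames:
        raise TrajectoryFormatError(
            f"{path}: header declares {n_frames} frames but file has {len(rows)}")
    data = np.asarray(rows) * scale
    markers = {name: data[:, 3 * i:3 * i + 3] for i, name in enumerate(names)}
    rec = TrialRecording(sampling_rate=rate, markers=markers)
    if require:
        rec.require()
    return rec


# ---------------------------------------------------------------------------
# CSV trajectories
# ---------------------------------------------------------------------------

def write_csv_trajectories(recording: TrialRecording, path: str | Path) -> None:
    """Write a wide CSV: ``frame,time,<marker>_x,<marker>_y,<marker>_z,...``.

    Metadata (including the sampling rate) goes into ``#`` comment lines
    before the header so the file round-trips.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(recording.n_frames),
        "time": recording.times,
    }
    for name, arr in recording.markers.items():
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = arr[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate: {recording.sampling_rate:g}\n")
        for key, val in recording.metadata.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_csv_trajectories(path: str | Path,
                          aliases: Mapping[str, str] | None = None,
                          require: bool = True) -> TrialRecording:
    """Read the wide-CSV trajectory schema written by
    :func:`write_csv_trajectories` (units m)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if "sampling_rate" not in meta:
        raise TrajectoryFormatError(f"{path}: missing '# sampling_rate:' comment line")
    rate = float(meta.pop("sampling_rate"))
    markers: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col.endswith("_x"):
            stem = col[:-2]
            for ax in ("y", "z"):
                if f"{stem}_{ax}" not in df.columns:
                    raise TrajectoryFormatError(
                        f"{path}: marker {stem} missing {ax} column")
            name = _normalize_name(stem, aliases)
            markers[name] = df[[f"{stem}_x", f"{stem}_y", f"{stem}_z"]].to_numpy(float)
    if not markers:
        raise TrajectoryFormatError(f"{path}: no '<marker>_x/_y/_z' columns found")
    rec = TrialRecording(sampling_rate=rate, markers=markers, metadata=meta)
    if require:
        rec.require()
    return rec


# ---------------------------------------------------------------------------
# Results tables and JSON sidecars
# ---------------------------------------------------------------------------

def write_results_table(rows: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Write an analysis results table as CSV.

    If a ``parameter`` column is present, rows are ordered by the canonical
    parameter list (whole-turn rows first, then per-leg rows); unknown
    parameters keep their relative order at the end.
    """
    df = pd.DataFrame(rows)
    if "parameter" in df.columns:
        order = {p: i for i, p in enumerate(RESULTS_PARAMETER_ORDER)}
        df = df.sort_values(
            "parameter", key=lambda s: s.map(lambda p: order.get(p, len(order))),
            kind="stable",
        )
    df.to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
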