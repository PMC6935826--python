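"""Marker-trajectory I/O, gait-cycle extraction and time normalization.

Marker positions are stored in millimetres in the laboratory frame
(X anterior, Y superior, Z to the subject's left, right-handed).  A gait
cycle is the interval between subsequent heel strikes of the same leg; any
per-frame series restricted to one cycle can be resampled onto the standard
0–100 % grid with 101 points.

Two text dialects are supported: the common TRC motion-capture layout
(tab-separated, header with rate/units) and a long-form CSV
(frame, marker, x, y, z).  Heel-strike events travel in a sidecar CSV
(label, frame) next to the marker file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import (
    DegenerateCycleError,
    FormatError,
    InsufficientEventsError,
    MissingLandmarkError,
)

#: Bony landmarks required for spine-rhythm extraction.
REQUIRED_LANDMARKS = ("T3", "T7", "L1", "L3", "L5", "LPSIS", "RPSIS", "IC")

#: Number of samples on the normalized 0–100 % cycle grid.
CYCLE_POINTS = 101

Dialect = Literal["trc", "csv"]


@dataclass
class MarkerTrajectory:
    """One landmark's 3-D time series.

    Parameters
    ----------
    name : str
        Landmark label (e.g. ``"L5"``).
    positions : ndarray, shape (n_frames, 3)
        Coordinates in millimetres, lab frame.
    rate : float
        Sample rate in Hz (> 0).
    """

    name: str
    positions: np.ndarray
    rate: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise FormatError(
                f"trajectory {self.name!r}: positions must be (n, 3), "
                f"got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise FormatError(f"trajectory {self.name!r} contains non-finite coordinates")
        if not self.rate > 0:
            raise FormatError(f"trajectory {self.name!r}: rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class MarkerSet:
    """A named collection of marker trajectories sharing frame count and rate."""

    trajectories: dict[str, MarkerTrajectory]
    rate: float

    def __post_init__(self):
        counts = {t.n_frames for t in self.trajectories.values()}
        if len(counts) > 1:
            raise FormatError(f"ragged frame counts across markers: {sorted(counts)}")
        for t in self.trajectories.values():
            if t.rate != self.rate:
                raise FormatError(
                    f"marker {t.name!r} rate {t.rate} differs from set rate {self.rate}"
                )

    @property
    def n_frames(self) -> int:
        if not self.trajectories:
            return 0
        return next(iter(self.trajectories.values())).n_frames

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.trajectories)

    def __getitem__(self, name: str) -> MarkerTrajectory:
        try:
            return self.trajectories[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def require(self, names: Iterable[str] = REQUIRED_LANDMARKS) -> None:
        """Raise :class:`MissingLandmarkError` for the first absent landmark."""
        for n in names:
            if n not in self.trajectories:
                raise MissingLandmarkError(n)

    def unknown_labels(self) -> tuple[str, ...]:
        """Labels present in the set but not in the standard landmark list."""
        return tuple(n for n in self.trajectories if n not in REQUIRED_LANDMARKS)


@dataclass
class EventTrack:
    """Ordered gait events: ``(label, frame)`` with labels
    ``heel_strike_L`` / ``heel_strike_R``; frames strictly increasing."""

    events: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        frames = [f for _, f in self.events]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise FormatError("event frames must be strictly increasing")

    def strikes(self, leg: Literal["L", "R"]) -> list[int]:
        label = f"heel_strike_{leg}"
        return [f for lab, f in self.events if lab == label]


@dataclass
class NormalizedSeries:
    """A series resampled onto the 0–100 % cycle grid (101 samples)."""

    values: np.ndarray        # shape (101,) or (101, k)
    percent: np.ndarray = field(
        default_factory=lambda: np.arange(CYCLE_POINTS, dtype=float)
    )

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != CYCLE_POINTS:
            raise FormatError(
                f"normalized series must have {CYCLE_POINTS} samples, "
                f"got {self.values.shape[0]}"
            )


# ---------------------------------------------------------------------------
# cycle extraction and normalization


def extract_cycle(
    series: np.ndarray,
    events: EventTrack,
    leg: Literal["L", "R"] = "L",
    cycle: int = 0,
) -> np.ndarray:
    """Restrict a per-frame series to one gait cycle.

    The window spans ``[strike_k, strike_{k+1}]`` inclusive of both boundary
    frames; ``cycle`` selects k among the complete cycles (default: first).
    """
    series = np.asarray(series)
    strikes = events.strikes(leg)
    if len(strikes) < 2:
        raise InsufficientEventsError(
            f"need >= 2 heel strikes for leg {leg!r}, found {len(strikes)}"
        )
    n_cycles = len(strikes) - 1
    if not 0 <= cycle < n_cycles:
        raise InsufficientEventsError(
            f"cycle index {cycle} out of range: only {n_cycles} complete cycle(s)"
        )
    a, b = strikes[cycle], strikes[cycle + 1]
    if b >= series.shape[0]:
        raise InsufficientEventsError(
            f"heel strike at frame {b} beyond series length {series.shape[0]}"
        )
    return series[a : b + 1]


def time_normalize(series: np.ndarray) -> NormalizedSeries:
    """Linearly resample one cycle onto the 0–100 % grid with 101 points.

    Endpoints are preserved exactly and the operation is idempotent on
    101-sample input.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < 2:
        raise DegenerateCycleError(f"cannot normalize a cycle of {n} frame(s)")
    x = np.linspace(0.0, 100.0, n)
    grid = np.arange(CYCLE_POINTS, dtype=float)
    if series.ndim == 1:
        vals = np.interp(grid, x, series)
    else:
        flat = series.reshape(n, -1)
        vals = np.column_stack([np.interp(grid, x, flat[:, j]) for j in range(flat.shape[1])])
        vals = vals.reshape((CYCLE_POINTS,) + series.shape[1:])
    return NormalizedSeries(vals)


# ---------------------------------------------------------------------------
# TRC dialect


def _write_trc(markers: MarkerSet, path: Path) -> None:
    names = list(markers.names)
    n = markers.n_frames
    rate = markers.rate
    with open(path, "w", newline="") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(names)}\tmm\t{rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\n")
        sub = ["", ""]
        for i in range(len(names)):
            sub += [f"X{i+1}", f"Y{i+1}", f"Z{i+1}"]
        fh.write("\t".join(sub) + "\n")
        data = np.hstack([markers.trajectories[nm].positions for nm in names])
        for i in range(n):
            row = [str(i + 1), f"{i / rate:.6f}"] + [f"{v:.9f}" for v in data[i]]
            fh.write("\t".join(row) + "\n")


def _read_trc(path: Path) -> MarkerSet:
    lines = path.read_text().splitlines()
    if len(lines) < 5 or not lines[0].startswith("PathFileType"):
        raise FormatError(f"{path}: not a TRC file")
    meta = lines[2].split("\t")
    try:
        rate = float(meta[0])
        n_frames = int(meta[2])
        n_markers = int(meta[3])
        units = meta[4]
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed TRC header") from exc
    if units != "mm":
        raise FormatError(f"{path}: units must be mm, got {units!r}")
    names = [s for s in lines[3].split("\t")[2:] if s.strip()]
    if len(names) != n_markers:
        raise FormatError(
            f"{path}: header announces {n_markers} markers but names row has {len(names)}"
        )
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 + 3 * n_markers:
            raise FormatError(f"{path}: ragged data row with {len(parts)} fields")
        rows.append([float(v) for v in parts[2:]])
    if len(rows) != n_frames:
        raise FormatError(f"{path}: header announces {n_frames} frames, found {len(rows)}")
    data = np.asarray(rows)
    trajs = {
        nm: MarkerTrajectory(nm, data[:, 3 * i : 3 * i + 3], rate)
        for i, nm in enumerate(names)
    }
    return MarkerSet(trajs, rate)


# ---------------------------------------------------------------------------
# long-form CSV dialect: frame,marker,x,y,z (header row; rate in a comment)


def _write_csv(markers: MarkerSet, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# rate_hz={markers.rate:g} units=mm\n")
        w = csv.writer(fh)
        w.writerow(["frame", "marker", "x", "y", "z"])
        for nm in markers.names:
            pos = markers.trajectories[nm].positions
            for i, (x, y, z) in enumerate(pos):
                w.writerow([i, nm, f"{x:.9f}", f"{y:.9f}", f"{z:.9f}"])


def _read_csv(path: Path) -> MarkerSet:
    rate = None
    with open(path, newline="") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if token.startswith("rate_hz="):
                    rate = float(token.split("=", 1)[1])
        else:
            fh.seek(0)
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < {"frame", "marker", "x", "y", "z"}:
            raise FormatError(f"{path}: expected columns frame,marker,x,y,z")
        per: dict[str, dict[int, list[float]]] = {}
        for row in reader:
            per.setdefault(row["marker"], {})[int(row["frame"])] = [
                float(row["x"]), float(row["y"]), float(row["z"]),
            ]
    if rate is None:
        rate = 100.0
    if not per:
        raise FormatError(f"{path}: no marker rows")
    counts = {len(frames) for frames in per.values()}
    if len(counts) > 1:
        raise FormatError(f"{path}: ragged frame counts {sorted(counts)}")
    trajs = {}
    for nm, frames in per.items():
        n = len(frames)
        if sorted(frames) != list(range(n)):
            raise FormatError(f"{path}: marker {nm!r} has non-contiguous frames")
        trajs[nm] = MarkerTrajectory(nm, np.asarray([frames[i] for i in range(n)]), rate)
    return MarkerSet(trajs, rate)


# ---------------------------------------------------------------------------
# events sidecar


def events_path_for(path: Path) -> Path:
    return path.with_name(path.stem + "_events.csv")


def write_events(events: EventTrack, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "frame"])
        for lab, frame in events.events:
            w.writerow([lab, frame])


def read_events(path: Path) -> EventTrack:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < {"label", "frame"}:
            raise FormatError(f"{path}: expected columns label,frame")
        evts = [(row["label"], int(row["frame"])) for row in reader]
    return EventTrack(evts)


# ---------------------------------------------------------------------------
# public read/write


def write_markers(
    markers: MarkerSet,
    path: str | Path,
    dialect: Dialect = "trc",
    events: EventTrack | None = None,
) -> Path:
    """Write a marker set (and optional events sidecar); re-readable by
    :func:`read_markers` with coordinates preserved to 1e-9 mm."""
    path = Path(path)
    if not markers.trajectories:
        raise FormatError("cannot write an empty marker set")
    if dialect == "trc":
        _write_trc(markers, path)
    elif dialect == "csv":
        _write_csv(markers, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    if events is not None:
        write_events(events, events_path_for(path))
    return path


def read_markers(
    path: str | Path, dialect: Dialect = "trc"
) -> tuple[MarkerSet, EventTrack | None]:
    """Read a marker file; returns the set plus events if a sidecar exists."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    markers = _read_trc(path) if dialect == "trc" else _read_csv(path)
    ev_path = events_path_for(path)
    events = read_events(ev_path) if ev_path.exists() else None
    return markers, events


def write_normalized_csv(
    series: NormalizedSeries, path: str | Path, columns: Sequence[str]
) -> Path:
    """Write a normalized series as CSV with a leading percent column."""
    path = Path(path)
    vals = series.values.reshape(CYCLE_POINTS, -1)
    if vals.shape[1] != len(columns):
        raise FormatError(f"{len(columns)} column names for {vals.shape[1]} columns")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["percent", *columns])
        for p, row in zip(series.percent, vals):
            w.writerow([f"{p:g}", *[f"{v:.9g}" for v in row]])
    return path
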