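"""Trajectory data model, tabular I/O, resampling and displacement steps.

A :class:`Track` is one cell's time-ordered sequence of positions, as
produced by time-lapse tracking software.  A :class:`TrackSet` bundles the
tracks of one experiment together with the analysis time step ``interval``
(minutes).  Displacement :class:`Step` records — a vector per consecutive
sample pair, each carrying the unit direction of its predecessor — are the
raw material of every downstream analysis.

Coordinate convention: mathematical (x right, y up, angles counterclockwise
from +x, radians).  Files exported by imaging software that use a
y-down image convention can be read with ``image_y_down=True``, which
negates y on input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "Step",
    "TrackSet",
    "FormatError",
    "TrackValidationError",
    "read_tracks",
    "write_tracks",
    "resample",
    "steps",
    "REQUIRED_COLUMNS",
]

#: Mandatory header of the tabular track interchange format.
REQUIRED_COLUMNS = ["track_id", "frame", "time_min", "x_um", "y_um"]

#: Optional columns recognised (parsed, never interpreted).
LABEL_COLUMNS = ["origin", "destiny"]


class FormatError(ValueError):
    """The file does not conform to the tabular track format."""


class TrackValidationError(ValueError):
    """A track violates an invariant (e.g. non-monotone frames)."""


@dataclass
class Track:
    """One cell's path: positions (μm) sampled at increasing times (min).

    Parameters
    ----------
    id:
        Opaque track identifier.
    frames:
        Integer frame indices, strictly increasing, 0-based.
    times:
        Acquisition times in minutes, strictly increasing.  Time is
        authoritative; frames are bookkeeping.
    xy:
        ``(n, 2)`` array of positions in μm.
    origin, destiny:
        Optional free-text labels describing how the track begins/ends
        (e.g. "start", "gone out").  Stored, never interpreted.
    meta:
        Unknown extra columns from the input file, kept opaque.
    """

    id: str
    frames: np.ndarray
    times: np.ndarray
    xy: np.ndarray
    origin: Optional[str] = None
    destiny: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise TrackValidationError(
                f"track {self.id!r}: positions must be an (n, 2) array"
            )
        n = len(self.frames)
        if n < 1:
            raise TrackValidationError(f"track {self.id!r}: needs >= 1 sample")
        if len(self.times) != n or len(self.xy) != n:
            raise TrackValidationError(
                f"track {self.id!r}: frames/times/positions length mismatch"
            )
        if n > 1:
            if np.any(np.diff(self.frames) <= 0):
                raise TrackValidationError(
                    f"track {self.id!r}: frames not strictly increasing"
                )
            if np.any(np.diff(self.times) <= 0):
                raise TrackValidationError(
                    f"track {self.id!r}: times not strictly increasing"
                )

    @property
    def n_samples(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Elapsed time (min) between first and last sample."""
        return float(self.times[-1] - self.times[0])


@dataclass
class Step:
    """A displacement vector over one analysis interval.

    ``prev_dir`` is the unit direction of the preceding displacement of the
    same track, or ``None`` for a track's first step and for steps whose
    predecessor had zero length.
    """

    track_id: str
    t_start: float
    d: np.ndarray
    prev_dir: Optional[np.ndarray] = None

    @property
    def length(self) -> float:
        return float(np.hypot(self.d[0], self.d[1]))


@dataclass
class TrackSet:
    """A collection of tracks sharing one time unit and analysis interval."""

    tracks: list
    interval: float = 40.0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


def _infer_frame_duration(tracks: Sequence[Track]) -> float:
    """Minutes per frame index, from the affine frame->time relation."""
    ratios = []
    for tr in tracks:
        if tr.n_samples > 1:
            ratios.extend(np.diff(tr.times) / np.diff(tr.frames))
    if not ratios:
        raise ValueError("cannot infer sampling interval: no track has >= 2 samples")
    return float(np.median(ratios))


def read_tracks(
    path: Union[str, Path],
    dialect: str = "tsv",
    image_y_down: bool = False,
) -> TrackSet:
    """Read a tabular track file into a :class:`TrackSet`.

    The file must have a header with the columns ``track_id``, ``frame``,
    ``time_min``, ``x_um``, ``y_um``; rows may be interleaved across tracks
    and are sorted by frame within each track.  Extra columns are preserved
    as opaque per-track metadata; ``origin``/``destiny`` columns, if
    present, populate the corresponding labels.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"tsv"`` (default) or ``"csv"``.
    image_y_down:
        If true, negate y on input (image convention -> mathematical
        convention).
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS + LABEL_COLUMNS]
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=np.int64)
        if len(np.unique(frames)) != len(frames):
            raise TrackValidationError(
                f"track {tid!r}: duplicate frames in input file"
            )
        xy = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        if image_y_down:
            xy = xy * np.array([1.0, -1.0])
        origin = destiny = None
        if "origin" in grp.columns:
            origin = str(grp["origin"].iloc[0])
        if "destiny" in grp.columns:
            destiny = str(grp["destiny"].iloc[-1])
        meta = {c: grp[c].tolist() for c in extra}
        tracks.append(
            Track(
                id=str(tid),
                frames=frames,
                times=grp["time_min"].to_numpy(dtype=float),
                xy=xy,
                origin=origin,
                destiny=destiny,
                meta=meta,
            )
        )
    if tracks:
        try:
            interval = _infer_frame_duration(tracks)
        except ValueError:
            interval = 40.0
    else:
        interval = 40.0
    return TrackSet(tracks=tracks, interval=interval)


def write_tracks(ts: TrackSet, path: Union[str, Path], dialect: str = "tsv") -> None:
    """Write a :class:`TrackSet` in the tabular interchange format.

    Floats are written with full round-trip precision, so
    ``read_tracks(write_tracks(ts))`` reproduces positions bit-exactly.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
    records = []
    has_labels = any(tr.origin is not None or tr.destiny is not None for tr in ts)
    for tr in ts:
        for i in range(tr.n_samples):
            rec = {
                "track_id": tr.id,
                "frame": int(tr.frames[i]),
                "time_min": float(tr.times[i]),
                "x_um": float(tr.xy[i, 0]),
                "y_um": float(tr.xy[i, 1]),
            }
            if has_labels:
                rec["origin"] = tr.origin if tr.origin is not None else ""
                rec["destiny"] = tr.destiny if tr.destiny is not None else ""
            for k, v in tr.meta.items():
                rec[k] = v[i]
            records.append(rec)
    cols = REQUIRED_COLUMNS + (["origin", "destiny"] if has_labels else [])
    df = pd.DataFrame.from_records(records, columns=None)
    if df.empty:
        df = pd.DataFrame(columns=cols)
    # %.17g guarantees exact float round-trip through text
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def resample(ts: TrackSet, target_interval: float) -> TrackSet:
    """Thin a TrackSet to a coarser analysis interval.

    Keeps every k-th frame starting from each track's first frame, where
    k = target_interval / native frame duration (must be an integer ratio).
    A target frame that is missing from the track splits it: no step is
    fabricated across the gap, the remaining stride positions continue as a
    new track segment (id suffixed ``/1``, ``/2``, ...).
    """
    native = _infer_frame_duration(ts.tracks)
    ratio = target_interval / native
    k = round(ratio)
    if k < 1 or abs(ratio - k) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(
            f"target interval {target_interval} is not an integer multiple "
            f"of the native interval {native}"
        )
    out = []
    for tr in ts:
        index_of = {int(f): i for i, f in enumerate(tr.frames)}
        f0, f_last = int(tr.frames[0]), int(tr.frames[-1])
        segments: list[list[int]] = []
        current: list[int] = []
        for f in range(f0, f_last + 1, k):
            i = index_of.get(f)
            if i is None:  # gap: close the current segment
                if current:
                    segments.append(current)
                    current = []
            else:
                current.append(i)
        if current:
            segments.append(current)
        for s, idx in enumerate(segments):
            out.append(
                Track(
                    id=tr.id if s == 0 else f"{tr.id}/{s}",
                    frames=tr.frames[idx],
                    times=tr.times[idx],
                    xy=tr.xy[idx],
                    origin=tr.origin,
                    destiny=tr.destiny,
                    meta={c: [v[i] for i in idx] for c, v in tr.meta.items()},
                )
            )
    return TrackSet(tracks=out, interval=float(target_interval))


def steps(ts: TrackSet) -> list:
    """Extract displacement steps from a (resampled) TrackSet.

    Per track, the displacement vectors between consecutive samples; each
    step carries the unit direction of its predecessor.  The first step of
    each track, and any step whose predecessor has zero length, has
    ``prev_dir`` undefined (``None``).  Tracks with fewer than two samples
    contribute no steps.
    """
    result = []
    for tr in ts:
        if tr.n_samples < 2:
            continue
        d = np.diff(tr.xy, axis=0)
        lengths = np.hypot(d[:, 0], d[:, 1])
        for i in range(len(d)):
            prev_dir = None
            if i > 0 and lengths[i - 1] > 0.0:
                prev_dir = d[i - 1] / lengths[i - 1]
            result.append(
                Step(
                    track_id=tr.id,
                    t_start=float(tr.times[i]),
                    d=d[i],
                    prev_dir=prev_dir,
                )
            )
    return result


def wrap_angle(a: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    a = math.remainder(a, 2.0 * math.pi)
    if a <= -math.pi:
        a += 2.0 * math.pi
    return a
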