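"""Track data model, delimited-table ingestion, and track-level filters.

Coordinates are in micrometres, time in minutes, frame indices 0-based.
Tracks are time-ordered per-cell position series (2D or 3D) read from
delimited text exports of tracking tools; a TrackMate-style column dialect
is supported read-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: column names per dialect, in (track_id, frame, x, y, z) order
_DIALECTS = {
    "generic": ("track_id", "frame", "x", "y", "z"),
    "trackmate": ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y", "POSITION_Z"),
}


class TrackTableError(ValueError):
    """Raised for malformed track tables (missing columns, duplicates, ...)."""


@dataclass(frozen=True)
class Track:
    """One cell's time-ordered positions.

    Parameters
    ----------
    track_id : str
        Identifier of the cell track (unique within a TrackSet).
    condition : str
        Experimental condition label (e.g. ``"untreated"``, ``"treated"``).
    frame_interval : float
        Minutes per frame.
    frames : ndarray of int
        Strictly increasing frame indices; gaps are allowed.
    positions : ndarray, shape (n, d)
        Positions in μm, d ∈ {2, 3}, one row per frame.
    """

    track_id: str
    condition: str
    frame_interval: float
    frames: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        positions = np.asarray(self.positions, dtype=np.float64)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "positions", positions)
        if positions.ndim != 2 or positions.shape[1] not in (2, 3):
            raise ValueError(f"positions must be (n, 2) or (n, 3), got {positions.shape}")
        if len(frames) != len(positions):
            raise ValueError("frames and positions must have equal length")
        if len(frames) < 2:
            raise ValueError("a Track needs at least 2 points")
        if not np.all(np.diff(frames) > 0):
            raise ValueError(f"frames of track {self.track_id!r} not strictly increasing")
        if not np.all(np.isfinite(positions)):
            raise ValueError(f"track {self.track_id!r} has non-finite coordinates")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Track duration in minutes."""
        return float(self.frames[-1] - self.frames[0]) * self.frame_interval

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.frames) > 1))


@dataclass
class TrackSet:
    """A dimension-consistent collection of tracks plus acquisition metadata.

    field_bounds, when set, is an axis-aligned box ``(d, 2)`` of
    ``[lo, hi]`` per axis in μm (the imaged field of view).
    """

    tracks: list[Track]
    frame_interval: float
    field_bounds: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.field_bounds is not None:
            self.field_bounds = np.asarray(self.field_bounds, dtype=np.float64)
        dims = {t.ndim for t in self.tracks}
        if len(dims) > 1:
            raise ValueError(f"tracks mix dimensionalities {sorted(dims)}")
        for t in self.tracks:
            if t.frame_interval != self.frame_interval:
                raise ValueError(
                    f"track {t.track_id!r} frame_interval {t.frame_interval} "
                    f"differs from TrackSet's {self.frame_interval}"
                )

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    @property
    def ndim(self) -> int:
        if not self.tracks:
            raise ValueError("empty TrackSet has no dimensionality")
        return self.tracks[0].ndim


def track_steps(t: Track) -> tuple[np.ndarray, np.ndarray]:
    """Step vectors (μm) and step speeds (μm/min) of a track.

    Each step spans its own frame gap, so speeds are time-normalized:
    ``speed_i = |step_i| / (Δframes_i × frame_interval)``.
    """
    steps = np.diff(t.positions, axis=0)
    dt = np.diff(t.frames) * t.frame_interval
    speeds = np.linalg.norm(steps, axis=1) / dt
    return steps, speeds


def fill_gaps(t: Track, max_gap: int = 2) -> Track | None:
    """Linearly interpolate missing frames when every gap is ≤ ``max_gap``.

    Returns the gap-free track (unchanged if already gap-free) or None when
    some gap exceeds ``max_gap`` — lag-based statistics must then skip it.
    """
    gaps = np.diff(t.frames)
    if np.all(gaps == 1):
        return t
    if np.any(gaps > max_gap + 1):
        return None
    full = np.arange(t.frames[0], t.frames[-1] + 1)
    pos = np.column_stack(
        [np.interp(full, t.frames, t.positions[:, ax]) for ax in range(t.ndim)]
    )
    return replace(t, frames=full, positions=pos)


def read_tracks_table(
    path: str | Path,
    dialect: str = "generic",
    frame_interval: float = 10.0,
    condition: str = "unspecified",
    field_bounds: np.ndarray | Sequence | None = None,
) -> TrackSet:
    """Read a per-cell tracking table into a TrackSet.

    Delimiter (comma or tab) is auto-detected; a header row is mandatory and
    lines starting with ``#`` are treated as comments.  One Track is built per
    distinct id with rows sorted by frame; single-point tracks are dropped
    with a logged count; duplicate (id, frame) rows are an error.

    A ``condition`` column in a generic-dialect table assigns per-track
    labels; the ``condition`` argument is the fallback for tables without
    one (and for the TrackMate dialect, which defines no such column).
    """
    if dialect not in _DIALECTS:
        raise TrackTableError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    id_col, frame_col, *coord_cols = _DIALECTS[dialect]
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    present_coords = [c for c in coord_cols if c in df.columns]
    missing = [c for c in (id_col, frame_col, *coord_cols[:2]) if c not in df.columns]
    if missing:
        raise TrackTableError(f"missing required column(s) {missing} in {path}")
    has_condition = dialect == "generic" and "condition" in df.columns
    use = [id_col, frame_col] + present_coords + (
        ["condition"] if has_condition else []
    )
    df = df[use]
    for c in [frame_col] + present_coords:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any() and not df[c].isna().any():
            bad = df[c][vals.isna()].iloc[0]
            raise TrackTableError(f"non-numeric value {bad!r} in column {c!r}")
        df[c] = vals
    if df[[id_col, frame_col]].duplicated().any():
        dup = df[df[[id_col, frame_col]].duplicated()].iloc[0]
        raise TrackTableError(
            f"duplicate frame {int(dup[frame_col])} within track {dup[id_col]!r}"
        )

    tracks: list[Track] = []
    n_dropped = 0
    for tid, grp in df.groupby(id_col, sort=True):
        grp = grp.sort_values(frame_col)
        if len(grp) < 2:
            n_dropped += 1
            continue
        tracks.append(
            Track(
                track_id=str(tid),
                condition=str(grp["condition"].iloc[0]) if has_condition else condition,
                frame_interval=frame_interval,
                frames=grp[frame_col].to_numpy(dtype=np.int64),
                positions=grp[present_coords].to_numpy(dtype=np.float64),
            )
        )
    if n_dropped:
        logger.info("dropped %d single-point track(s) from %s", n_dropped, path)
    return TrackSet(
        tracks=tracks,
        frame_interval=frame_interval,
        field_bounds=None if field_bounds is None else np.asarray(field_bounds, float),
        meta={"source": str(path), "n_single_point_dropped": n_dropped},
    )


def write_tracks_table(
    ts: TrackSet, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write a TrackSet as generic-dialect CSV with '#'-prefixed provenance."""
    cols = ["x", "y", "z"][: ts.ndim] if ts.tracks else ["x", "y"]
    rows = []
    for t in ts:
        d = pd.DataFrame(t.positions, columns=cols)
        d.insert(0, "frame", t.frames)
        d.insert(0, "track_id", t.track_id)
        d["condition"] = t.condition
        rows.append(d)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["track_id", "frame", *cols, "condition"]
    )
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False, float_format="%.6f")


def filter_tracks(
    ts: TrackSet, min_length: int = 61, require_in_field: bool = False
) -> TrackSet:
    """Keep tracks with ≥ ``min_length`` observed frames (default 61, i.e.
    length > 60) that never leave the field of view.

    With ``require_in_field`` the TrackSet must carry field_bounds; any track
    with a position outside the box is dropped.  Order is preserved and the
    operation is idempotent.
    """
    if min_length < 2:
        raise ValueError("min_length must be ≥ 2")
    if require_in_field and ts.field_bounds is None:
        raise ValueError("require_in_field=True but TrackSet has no field_bounds")
    kept = []
    for t in ts:
        if len(t) < min_length:
            continue
        if require_in_field:
            lo, hi = ts.field_bounds[:, 0], ts.field_bounds[:, 1]
            if np.any(t.positions < lo) or np.any(t.positions > hi):
                continue
        kept.append(t)
    return TrackSet(
        tracks=kept,
        frame_interval=ts.frame_interval,
        field_bounds=ts.field_bounds,
        meta={**ts.meta, "n_filtered_out": len(ts) - len(kept)},
    )
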