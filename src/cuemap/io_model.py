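"""Session containers, TSV readers/writers, and shared binning conventions.

All positions are in cm, times in seconds, firing rates in Hz. Track bins
follow a 0-based half-open convention: bin ``i`` covers
``[i * bin_size, (i + 1) * bin_size)`` cm. Every file the package reads or
writes is UTF-8, tab-separated, with a header row and '.' as the decimal
separator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrackSession",
    "ArenaSession",
    "CueTemplate",
    "RateMap",
    "ScorePanel",
    "DEFAULT_CONFIG",
    "load_config",
    "config_hash",
    "read_track_session",
    "read_arena_session",
    "read_cue_template",
    "write_cue_template",
    "write_score_table",
    "read_score_table",
    "write_table",
    "read_table",
    "position_to_bin",
    "assign_run_ids",
    "slice_session",
]

#: Default analysis configuration. Keys mirror the TSV/YAML config files.
DEFAULT_CONFIG: dict = {
    "track_length_cm": 800.0,
    "track_bin_cm": 5.0,
    "arena_size_cm": 50.0,
    "arena_bin_cm": 2.5,
    "hd_bin_deg": 3.0,
    "speed_threshold_cm_s": 1.0,
    "n_shuffles": 100,
    "shuffle_percentile": 95.0,
    "seed": 0,
}

_POSITION_TOL_CM = 1.0


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Load a YAML config file merged over :data:`DEFAULT_CONFIG`."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg.update(user)
    cfg.update(overrides)
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps({k: cfg[k] for k in sorted(cfg)}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TrackSession:
    """Time-aligned trajectory and spikes for one linear-track recording.

    ``run_ids`` increments at each teleport back to the track start;
    ``dff_per_cell`` optionally carries a ΔF/F sample per trajectory sample
    for imaging sessions.
    """

    sample_times: np.ndarray
    positions: np.ndarray
    run_ids: np.ndarray
    track_length: float
    spike_times_per_unit: dict = field(default_factory=dict)
    dff_per_cell: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)

    @property
    def duration(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.sample_times[-1] - self.sample_times[0])

    def validate(self) -> None:
        t = np.asarray(self.sample_times, float)
        if len(t) and np.any(np.diff(t) <= 0):
            row = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValueError(f"sample times not strictly increasing at row {row}")
        p = np.asarray(self.positions, float)
        if len(p) and (p.min() < -1e-9 or p.max() > self.track_length + 1e-9):
            raise ValueError("positions outside [0, track_length]")
        if len(self.run_ids) and np.any(np.diff(self.run_ids) < 0):
            raise ValueError("run_ids must be non-decreasing")
        for unit, st in self.spike_times_per_unit.items():
            st = np.asarray(st, float)
            if len(st) and len(t) and (st.min() < t[0] or st.max() > t[-1]):
                bad = st[(st < t[0]) | (st > t[-1])][0]
                raise ValueError(
                    f"spike at t={bad:g}s of unit {unit!r} outside trajectory span "
                    f"[{t[0]:g}, {t[-1]:g}]"
                )


@dataclass
class ArenaSession:
    """Trajectory with 2D position and head direction for an open arena."""

    sample_times: np.ndarray
    xy: np.ndarray  # (n, 2) in cm
    head_direction: np.ndarray  # degrees in [0, 360)
    arena_size: float
    spike_times_per_unit: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)

    def validate(self) -> None:
        t = np.asarray(self.sample_times, float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("sample times not strictly increasing")
        xy = np.asarray(self.xy, float)
        if len(xy) and (xy.min() < -1e-9 or xy.max() > self.arena_size + 1e-9):
            raise ValueError("xy outside arena bounds")
        hd = np.asarray(self.head_direction, float)
        if len(hd) and (hd.min() < 0 or hd.max() >= 360):
            raise ValueError("head_direction must be wrapped to [0, 360)")
        for unit, st in self.spike_times_per_unit.items():
            st = np.asarray(st, float)
            if len(st) and len(t) and (st.min() < t[0] or st.max() > t[-1]):
                raise ValueError(f"spike of unit {unit!r} outside trajectory span")


@dataclass
class CueTemplate:
    """Binary indicator of cue occupancy over track bins.

    ``values[i]`` is 1 iff bin ``i`` overlaps the extent ``[start, end)`` of
    some cue; a cue edge falling mid-bin marks the whole bin.
    """

    track_length: float
    bin_size: float
    cues: list  # of (start_cm, end_cm, side)
    values: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.values is None:
            self.values = rasterize_cues(self.cues, self.track_length, self.bin_size)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def side_template(self, side: str) -> "CueTemplate":
        """Template restricted to cues of one side ('left' or 'right')."""
        sub = [c for c in self.cues if c[2] in (side, "both")]
        return CueTemplate(self.track_length, self.bin_size, sub)

    def cue_widths(self) -> np.ndarray:
        return np.array([c[1] - c[0] for c in self.cues], float)

    def n_cue_runs(self) -> int:
        """Number of contiguous 1-runs (merged cue intervals)."""
        v = np.asarray(self.values)
        return int(np.sum(np.diff(np.r_[0, v, 0]) == 1))


def rasterize_cues(cues: Sequence, track_length: float, bin_size: float) -> np.ndarray:
    n_bins = int(np.ceil(track_length / bin_size - 1e-9))
    vals = np.zeros(n_bins, dtype=np.int8)
    for start, end, *_ in cues:
        if end <= start:
            raise ValueError(f"cue [{start}, {end}) has non-positive width")
        lo = int(np.floor(start / bin_size + 1e-9))
        hi = int(np.ceil(end / bin_size - 1e-9))
        vals[max(lo, 0) : min(hi, n_bins)] = 1
    return vals


@dataclass
class RateMap:
    """Occupancy, spike counts and smoothed rate over spatial/angular bins.

    ``occupancy_s`` and ``spike_count`` are the raw (unsmoothed) per-bin
    values; ``rate_hz`` is the smoothed occupancy-normalised rate. ``valid``
    marks the bins where the module's occupancy rule defines the rate.
    """

    kind: str  # 'track' | 'arena' | 'angular'
    occupancy_s: np.ndarray
    spike_count: np.ndarray
    rate_hz: np.ndarray
    valid: np.ndarray
    bin_edges: object  # 1D edges, or (x_edges, y_edges) for arena

    @property
    def masked_rate(self) -> np.ndarray:
        out = np.asarray(self.rate_hz, float).copy()
        out[~self.valid] = np.nan
        return out


@dataclass
class ScorePanel:
    """Per-cell score table: one row per cell, scores + thresholds + flags."""

    per_cell: pd.DataFrame
    thresholds: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# binning / run helpers
# ---------------------------------------------------------------------------


def position_to_bin(pos, bin_size: float, n_bins: int) -> np.ndarray:
    """Bin index under the half-open convention; pos == track end maps to
    the last bin."""
    idx = np.floor(np.asarray(pos, float) / bin_size).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def assign_run_ids(positions: np.ndarray, track_length: float) -> np.ndarray:
    """Run labels incremented at each teleport (backward jump of more than
    half the track length between consecutive samples)."""
    p = np.asarray(positions, float)
    if len(p) == 0:
        return np.zeros(0, dtype=int)
    jumps = np.diff(p) < -track_length / 2.0
    return np.r_[0, np.cumsum(jumps)].astype(int)


def slice_session(session, t_from: float, t_to: float):
    """Restrict a session to samples (and spikes) with t_from <= t < t_to."""
    t = np.asarray(session.sample_times, float)
    keep = (t >= t_from) & (t < t_to)
    spikes = {
        u: np.asarray(st, float)[(np.asarray(st, float) >= t_from) & (np.asarray(st, float) < t_to)]
        for u, st in session.spike_times_per_unit.items()
    }
    if isinstance(session, TrackSession):
        return TrackSession(
            sample_times=t[keep],
            positions=np.asarray(session.positions, float)[keep],
            run_ids=np.asarray(session.run_ids, int)[keep],
            track_length=session.track_length,
            spike_times_per_unit=spikes,
            dff_per_cell={c: np.asarray(v, float)[keep] for c, v in session.dff_per_cell.items()},
        )
    return ArenaSession(
        sample_times=t[keep],
        xy=np.asarray(session.xy, float)[keep],
        head_direction=np.asarray(session.head_direction, float)[keep],
        arena_size=session.arena_size,
        spike_times_per_unit=spikes,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path, required_cols):
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _read_spikes(path) -> dict:
    df = _read_tsv(path, ["unit_id", "time_s"])
    out = {}
    for unit, grp in df.groupby("unit_id"):
        out[unit] = np.sort(grp["time_s"].to_numpy(float))
    return out


def read_track_session(
    trajectory_path, spikes_path=None, config: Mapping | None = None, *, dff_path=None
) -> TrackSession:
    """Read a linear-track session from trajectory/spike TSVs.

    The trajectory file needs columns ``time_s`` and ``pos_cm``; the spike
    file ``unit_id`` and ``time_s``. Run boundaries are detected from
    backward position jumps larger than half the track length.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    L = float(cfg["track_length_cm"])
    df = _read_tsv(trajectory_path, ["time_s", "pos_cm"])
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"{trajectory_path}: non-monotonic time at row {row}")
    p = df["pos_cm"].to_numpy(float)
    bad = (p < -_POSITION_TOL_CM) | (p > L + _POSITION_TOL_CM)
    if np.any(bad):
        row = int(np.argmax(bad))
        raise ValueError(
            f"{trajectory_path}: position {p[row]:g} cm at row {row} outside [0, {L:g}]"
        )
    p = np.clip(p, 0.0, L)
    spikes = _read_spikes(spikes_path) if spikes_path is not None else {}
    dff = {}
    if dff_path is not None:
        ddf = _read_tsv(dff_path, ["cell_id", "frame_time_s", "dff"])
        for cell, grp in ddf.groupby("cell_id"):
            grp = grp.sort_values("frame_time_s")
            v = np.interp(t, grp["frame_time_s"].to_numpy(float), grp["dff"].to_numpy(float))
            dff[cell] = v
    sess = TrackSession(
        sample_times=t,
        positions=p,
        run_ids=assign_run_ids(p, L),
        track_length=L,
        spike_times_per_unit=spikes,
        dff_per_cell=dff,
    )
    sess.validate()
    return sess


def read_arena_session(trajectory_path, spikes_path=None, config: Mapping | None = None) -> ArenaSession:
    """Read an open-arena session (columns time_s, x_cm, y_cm, hd_deg)."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    size = float(cfg["arena_size_cm"])
    df = _read_tsv(trajectory_path, ["time_s", "x_cm", "y_cm", "hd_deg"])
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"{trajectory_path}: non-monotonic time at row {row}")
    xy = df[["x_cm", "y_cm"]].to_numpy(float)
    bad = (xy < -_POSITION_TOL_CM) | (xy > size + _POSITION_TOL_CM)
    if np.any(bad):
        row = int(np.argmax(bad.any(axis=1)))
        raise ValueError(f"{trajectory_path}: xy at row {row} outside the {size:g} cm arena")
    xy = np.clip(xy, 0.0, size)
    hd = np.mod(df["hd_deg"].to_numpy(float), 360.0)
    spikes = _read_spikes(spikes_path) if spikes_path is not None else {}
    sess = ArenaSession(
        sample_times=t, xy=xy, head_direction=hd, arena_size=size, spike_times_per_unit=spikes
    )
    sess.validate()
    return sess


def read_cue_template(path, config: Mapping | None = None) -> CueTemplate:
    """Read cues.tsv (cue_id, start_cm, end_cm, side) into a CueTemplate."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    df = _read_tsv(path, ["start_cm", "end_cm", "side"])
    cues = [
        (float(r.start_cm), float(r.end_cm), str(r.side)) for r in df.itertuples(index=False)
    ]
    return CueTemplate(float(cfg["track_length_cm"]), float(cfg["track_bin_cm"]), cues)


def write_cue_template(template: CueTemplate, path) -> None:
    df = pd.DataFrame(
        [
            {"cue_id": i, "start_cm": s, "end_cm": e, "side": side}
            for i, (s, e, side) in enumerate(template.cues)
        ],
        columns=["cue_id", "start_cm", "end_cm", "side"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV whose floats round-trip bit-exactly (repr formatting)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_score_table(panel: ScorePanel, path) -> None:
    """One row per cell with ids, scores, shifts, thresholds and class flags."""
    write_table(panel.per_cell, path)


def read_score_table(path) -> ScorePanel:
    return ScorePanel(per_cell=read_table(path))
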