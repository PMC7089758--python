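"""Calcium-imaging branch: dF/F, significant transients, in/out-of-field
periods, candidate gating, and cross-environment identity analysis.

The cue-score machinery is shared with the spike pipeline: a cell's mean
dF/F per 5 cm bin (computed with the >= 1 cm/s speed gate) plays the role
of the spatial firing rate and is scored against cue templates unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import TrackSession, position_to_bin
from .ratemaps import smoothed_speed

__all__ = [
    "DffTrace",
    "FieldPeriods",
    "CommonalityResult",
    "compute_dff",
    "detect_transients",
    "mean_dff_map",
    "field_periods",
    "candidate_cells",
    "cross_env_commonality",
    "cross_env_shift_consistency",
]

TRANSIENT_K_GRID = (2.0, 2.5, 3.0, 3.5, 4.0)
TRANSIENT_D_GRID_S = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class DffTrace:
    """Fractional fluorescence change with optional transient annotation."""

    frame_times: np.ndarray
    dff: np.ndarray
    frame_rate: float
    transient_mask: np.ndarray | None = None


def compute_dff(
    F: np.ndarray,
    frame_rate: float,
    baseline_window_s: float = 60.0,
    baseline_percentile: float = 8.0,
) -> DffTrace:
    """dF/F = (F - F0) / F0 with F0 a rolling low-percentile baseline.

    F0 is the rolling ``baseline_percentile`` (default 8th) of the raw
    fluorescence over a centred window; an F0 <= 0 anywhere is an error.
    """
    F = np.asarray(F, float)
    win = max(3, int(round(baseline_window_s * frame_rate)))
    f0 = (
        pd.Series(F)
        .rolling(win, center=True, min_periods=1)
        .quantile(baseline_percentile / 100.0)
        .to_numpy()
    )
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 <= 0; dF/F undefined")
    dff = (F - f0) / f0
    times = np.arange(len(F)) / frame_rate
    return DffTrace(times, dff, frame_rate)


def _run_lengths(above: np.ndarray):
    """Start index and length of each True run."""
    d = np.diff(np.r_[0, above.astype(int), 0])
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts, ends - starts


def _count_events(x, thresh, min_frames):
    starts, lens = _run_lengths(x > thresh)
    return int(np.sum(lens >= min_frames))


def detect_transients(
    trace: DffTrace,
    fp_target: float = 0.01,
    k_grid=TRANSIENT_K_GRID,
    d_grid_s=TRANSIENT_D_GRID_S,
) -> np.ndarray:
    """Boolean mask of significant calcium transients.

    Candidate events are excursions above k*sigma lasting at least d
    seconds (sigma from the median absolute deviation of the trace). Among
    (k, d) pairs for which matching negative-going excursions amount to at
    most ``fp_target`` of the positive events, the pair detecting the most
    positive events is used. If no pair qualifies the mask is empty.
    """
    x = np.asarray(trace.dff, float)
    sigma = 1.4826 * np.median(np.abs(x - np.median(x)))
    if sigma <= 0:
        raise ValueError("noise sigma is zero; cannot calibrate transients")
    best = None
    for k in k_grid:
        for d in d_grid_s:
            min_frames = max(1, int(round(d * trace.frame_rate)))
            pos = _count_events(x, k * sigma, min_frames)
            neg = _count_events(-x, k * sigma, min_frames)
            if pos == 0:
                ok = neg == 0
            else:
                ok = neg <= fp_target * pos
            if ok and (best is None or pos > best[0]):
                best = (pos, k, min_frames)
    mask = np.zeros(len(x), dtype=bool)
    if best is None or best[0] == 0:
        trace.transient_mask = mask
        return mask
    _, k, min_frames = best
    starts, lens = _run_lengths(x > k * sigma)
    for s, ln in zip(starts, lens):
        if ln >= min_frames:
            mask[s : s + ln] = True
    trace.transient_mask = mask
    return mask


def _speed_gate(session: TrackSession, threshold: float = 1.0) -> np.ndarray:
    # imaging analyses keep samples at or above the speed threshold
    return smoothed_speed(session) >= threshold


def mean_dff_map(session: TrackSession, cell, bin_size: float = 5.0,
                 gate: np.ndarray | None = None) -> np.ndarray:
    """Mean dF/F per 5 cm track bin over speed-gated samples (nan where
    unvisited)."""
    if gate is None:
        gate = _speed_gate(session)
    dff = np.asarray(session.dff_per_cell[cell], float)
    n_bins = int(np.ceil(session.track_length / bin_size - 1e-9))
    bins = position_to_bin(session.positions, bin_size, n_bins)
    cnt = np.bincount(bins[gate], minlength=n_bins)
    tot = np.bincount(bins[gate], weights=dff[gate], minlength=n_bins)
    out = np.full(n_bins, np.nan)
    out[cnt > 0] = tot[cnt > 0] / cnt[cnt > 0]
    return out


@dataclass
class FieldPeriods:
    """In/out-of-field periods of one imaged cell (bin intervals, half-open)."""

    in_periods: list
    out_periods: list
    p: np.ndarray

    @property
    def is_candidate(self) -> bool:
        return bool(self.in_periods) and bool(self.out_periods)


def field_periods(
    session: TrackSession,
    cell,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    bin_size: float = 5.0,
    transient_mask: np.ndarray | None = None,
    p_in: float = 0.2,
    p_out: float = 0.75,
    min_run_fraction: float = 0.1,
) -> FieldPeriods:
    """In- and out-of-field periods from a circular-rotation bootstrap.

    The per-bin p-value is the fraction of rotated dF/F traces (offsets
    uniform in [0.05 N, 0.95 N] samples) whose bin mean exceeds the real
    bin mean. In-field periods are runs of >= 3 adjacent bins with
    p <= 0.2 (>= 2 suffice at the track ends) in which at least 10% of the
    runs contain a significant transient; out-of-field periods are runs of
    >= 2 bins with p >= 0.75. ``transient_mask`` is per trajectory sample;
    when omitted every sample counts as a transient (the participation
    gate is then vacuous).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(session.track_length / bin_size - 1e-9))
    if n_bins < 3:
        raise ValueError("track too short for field periods")
    gate = _speed_gate(session)
    dff = np.asarray(session.dff_per_cell[cell], float)[gate]
    bins = position_to_bin(session.positions, bin_size, n_bins)[gate]
    runs = np.asarray(session.run_ids, int)[gate]
    N = len(dff)
    cnt = np.bincount(bins, minlength=n_bins)
    visited = cnt > 0
    real = np.full(n_bins, np.nan)
    real[visited] = np.bincount(bins, weights=dff, minlength=n_bins)[visited] / cnt[visited]
    offsets = rng.integers(int(np.ceil(0.05 * N)), int(np.floor(0.95 * N)) + 1, size=n_boot)
    exceed = np.zeros(n_bins)
    for off in offsets:
        rolled = np.roll(dff, off)
        m = np.full(n_bins, np.nan)
        m[visited] = np.bincount(bins, weights=rolled, minlength=n_bins)[visited] / cnt[visited]
        exceed[visited] += m[visited] > real[visited]
    p = np.ones(n_bins)
    p[visited] = exceed[visited] / n_boot

    if transient_mask is None:
        tmask = np.ones(len(gate), dtype=bool)
    else:
        tmask = np.asarray(transient_mask, bool)
    tmask = tmask[gate]
    n_runs = runs.max() + 1 if len(runs) else 0

    def participation(b0, b1):
        in_period = (bins >= b0) & (bins < b1)
        if n_runs == 0:
            return 0.0
        hit = np.unique(runs[in_period & tmask])
        return len(hit) / n_runs

    in_periods, out_periods = [], []
    d = np.diff(np.r_[0, (p <= p_in).astype(int) & visited.astype(int), 0])
    for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        min_len = 2 if (s == 0 or e == n_bins) else 3
        if e - s >= min_len and participation(s, e) >= min_run_fraction:
            in_periods.append((int(s), int(e)))
    d = np.diff(np.r_[0, ((p >= p_out) & visited).astype(int), 0])
    for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if e - s >= 2:
            out_periods.append((int(s), int(e)))
    return FieldPeriods(in_periods, out_periods, p)


def candidate_cells(periods_by_cell: dict) -> list:
    """Cells with at least one in-field and one out-of-field period."""
    return [c for c, fp in periods_by_cell.items() if fp.is_candidate]


@dataclass
class CommonalityResult:
    pct_common_cue: float
    pct_common_noncue: float
    random_cue_mean: float
    random_cue_std: float
    random_noncue_mean: float
    random_noncue_std: float


def _common_pcts(a: np.ndarray, b: np.ndarray):
    n_cue = a.sum()
    n_non = (~a).sum()
    cue = 100.0 * np.sum(a & b) / n_cue if n_cue else np.nan
    non = 100.0 * np.sum(~a & ~b) / n_non if n_non else np.nan
    return cue, non


def cross_env_commonality(class_a: dict, class_b: dict, n_random: int = 50,
                          seed: int | None = None) -> CommonalityResult:
    """Fraction of track-A cue (and non-cue) cells keeping their class on
    track B, with a chance band from random reassignments that preserve the
    per-track class counts."""
    ids = sorted(set(class_a) & set(class_b), key=str)
    if not ids:
        raise ValueError("no common cell ids between the two tracks")
    a = np.array([bool(class_a[i]) for i in ids])
    b = np.array([bool(class_b[i]) for i in ids])
    cue, non = _common_pcts(a, b)
    if not a.any() or not b.any():
        warnings.warn("zero cue cells on one track; cue commonality undefined")
    rng = np.random.default_rng(seed)
    rc, rn = [], []
    for _ in range(n_random):
        pa = rng.permutation(a)
        pb = rng.permutation(b)
        c, n = _common_pcts(pa, pb)
        rc.append(c)
        rn.append(n)
    rc, rn = np.asarray(rc, float), np.asarray(rn, float)
    return CommonalityResult(
        cue, non,
        float(np.nanmean(rc)), float(np.nanstd(rc)),
        float(np.nanmean(rn)), float(np.nanstd(rn)),
    )


def cross_env_shift_consistency(results_a: dict, results_b: dict):
    """Paired (shift A, shift B) of common cue cells and their Pearson
    correlation (nan below 3 common cells)."""
    ids = sorted(set(results_a) & set(results_b), key=str)
    pairs = []
    for i in ids:
        sa = results_a[i].shift_cm if hasattr(results_a[i], "shift_cm") else results_a[i]
        sb = results_b[i].shift_cm if hasattr(results_b[i], "shift_cm") else results_b[i]
        if np.isfinite(sa) and np.isfinite(sb):
            pairs.append((sa, sb))
    pairs = np.asarray(pairs, float).reshape(-1, 2)
    if len(pairs) < 3:
        return pairs, np.nan
    from .cue_scoring import _pearson

    return pairs, _pearson(pairs[:, 0], pairs[:, 1])
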