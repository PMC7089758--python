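"""Velocity gating and occupancy-normalised rate maps.

Track rate maps use 5 cm bins smoothed with a 3-point Gaussian (sigma = 1
bin); arena maps use 2.5 cm bins smoothed with a 5 x 5 Gaussian (sigma = 1
bin); head-direction tuning uses 3-degree bins smoothed with a 15-degree
(5-bin) circular boxcar. In every case the spike count and the occupancy
are smoothed separately and then divided. Kernels are truncated at the map
edges and renormalised (no wraparound on the linear track; the angular
smoothing is circular). Only samples on which the 1-second boxcar-smoothed
speed exceeds 1 cm/s contribute, and spikes inherit the retention mask of
their enclosing trajectory sample.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve2d
from scipy.ndimage import convolve1d

from .io_model import ArenaSession, RateMap, TrackSession, position_to_bin

__all__ = [
    "smoothed_speed",
    "velocity_filter",
    "spike_sample_indices",
    "retained_spike_samples",
    "track_ratemap",
    "arena_ratemap",
    "hd_tuning",
    "sample_durations",
    "gaussian_kernel_1d",
    "gaussian_kernel_2d",
]

SPEED_WINDOW_S = 1.0
SPEED_THRESHOLD_CM_S = 1.0
TRACK_BIN_CM = 5.0
ARENA_BIN_CM = 2.5
HD_BIN_DEG = 3.0
MIN_ARENA_OCCUPANCY_S = 0.3


def gaussian_kernel_1d() -> np.ndarray:
    """3-point Gaussian, sigma = 1 bin, normalised to sum 1."""
    w = np.exp(-0.5)
    k = np.array([w, 1.0, w])
    return k / k.sum()


def gaussian_kernel_2d() -> np.ndarray:
    """5 x 5 Gaussian, sigma = 1 bin, normalised to sum 1."""
    ax = np.arange(5) - 2.0
    g = np.exp(-0.5 * ax**2)
    k = np.outer(g, g)
    return k / k.sum()


def sample_durations(times: np.ndarray) -> np.ndarray:
    """Duration attributed to each sample: the interval to the next sample
    (the last sample inherits the median interval)."""
    t = np.asarray(times, float)
    if len(t) < 2:
        return np.full(len(t), np.nan)
    d = np.diff(t)
    return np.r_[d, np.median(d)]


def _smooth1d_truncated(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def smoothed_speed(session) -> np.ndarray:
    """Per-sample speed (cm/s): instantaneous displacement rate smoothed
    with a 1-second moving boxcar.

    On the track, displacements across a teleport are excluded by carrying
    the previous within-run speed forward.
    """
    t = np.asarray(session.sample_times, float)
    if len(t) < 2:
        raise ValueError("speed requires at least two samples")
    dt = np.diff(t)
    if isinstance(session, TrackSession):
        disp = np.abs(np.diff(np.asarray(session.positions, float)))
        same_run = np.diff(np.asarray(session.run_ids, int)) == 0
    else:
        xy = np.asarray(session.xy, float)
        disp = np.hypot(*np.diff(xy, axis=0).T)
        same_run = np.ones(len(disp), dtype=bool)
    v = disp / dt
    # forward-fill across teleports, then pad the first sample
    for i in np.flatnonzero(~same_run):
        v[i] = v[i - 1] if i > 0 else 0.0
    v = np.r_[v[0], v]
    win = max(1, int(round(SPEED_WINDOW_S / np.median(dt))))
    if win % 2 == 0:
        win += 1
    return _smooth1d_truncated(v, np.ones(win) / win)


def velocity_filter(session, speed: np.ndarray | None = None,
                    threshold: float = SPEED_THRESHOLD_CM_S) -> np.ndarray:
    """Boolean mask of samples whose smoothed speed exceeds the threshold."""
    if speed is None:
        speed = smoothed_speed(session)
    return np.asarray(speed, float) > threshold


def spike_sample_indices(session, unit) -> np.ndarray:
    """Index of the enclosing (nearest preceding) trajectory sample for each
    spike of a unit."""
    t = np.asarray(session.sample_times, float)
    st = np.asarray(session.spike_times_per_unit.get(unit, ()), float)
    idx = np.searchsorted(t, st, side="right") - 1
    return np.clip(idx, 0, max(len(t) - 1, 0))


def retained_spike_samples(session, unit, mask: np.ndarray) -> np.ndarray:
    """Sample indices of the unit's spikes that fall on retained samples."""
    idx = spike_sample_indices(session, unit)
    return idx[mask[idx]] if len(idx) else idx


def track_ratemap(
    session: TrackSession,
    unit,
    velocity_mask: np.ndarray | None = None,
    bin_size: float = TRACK_BIN_CM,
) -> RateMap:
    """1D spatial firing rate along the track (5 cm bins, 3-point Gaussian)."""
    if velocity_mask is None:
        velocity_mask = velocity_filter(session)
    n_bins = int(np.ceil(session.track_length / bin_size - 1e-9))
    dur = sample_durations(session.sample_times)
    bins = position_to_bin(session.positions, bin_size, n_bins)
    occ = np.bincount(bins[velocity_mask], weights=dur[velocity_mask], minlength=n_bins)
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy after velocity filtering")
    sp_idx = retained_spike_samples(session, unit, velocity_mask)
    counts = np.bincount(bins[sp_idx], minlength=n_bins).astype(float)
    k = gaussian_kernel_1d()
    s_occ = _smooth1d_truncated(occ, k)
    s_cnt = _smooth1d_truncated(counts, k)
    valid = s_occ > 0
    rate = np.zeros(n_bins)
    rate[valid] = s_cnt[valid] / s_occ[valid]
    return RateMap(
        kind="track",
        occupancy_s=occ,
        spike_count=counts,
        rate_hz=rate,
        valid=valid,
        bin_edges=np.arange(n_bins + 1) * bin_size,
    )


def arena_ratemap(
    session: ArenaSession,
    unit,
    velocity_mask: np.ndarray | None = None,
    bin_size: float = ARENA_BIN_CM,
    min_occupancy_s: float = MIN_ARENA_OCCUPANCY_S,
) -> RateMap:
    """2D firing rate in the arena (2.5 cm bins, 5x5 Gaussian smoothing).

    Bins visited for less than ``min_occupancy_s`` (raw occupancy) have an
    undefined rate and are masked invalid.
    """
    if velocity_mask is None:
        velocity_mask = velocity_filter(session)
    n_bins = int(np.ceil(session.arena_size / bin_size - 1e-9))
    dur = sample_durations(session.sample_times)
    xy = np.asarray(session.xy, float)
    ix = position_to_bin(xy[:, 0], bin_size, n_bins)
    iy = position_to_bin(xy[:, 1], bin_size, n_bins)
    flat = ix * n_bins + iy
    occ = np.bincount(flat[velocity_mask], weights=dur[velocity_mask],
                      minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy after velocity filtering")
    sp_idx = retained_spike_samples(session, unit, velocity_mask)
    counts = np.bincount(flat[sp_idx], minlength=n_bins * n_bins).reshape(n_bins, n_bins).astype(float)
    k = gaussian_kernel_2d()
    den = convolve2d(np.ones_like(occ), k, mode="same")
    s_occ = convolve2d(occ, k, mode="same") / den
    s_cnt = convolve2d(counts, k, mode="same") / den
    valid = occ >= min_occupancy_s
    rate = np.zeros_like(occ)
    pos = s_occ > 0
    rate[pos] = s_cnt[pos] / s_occ[pos]
    edges = np.arange(n_bins + 1) * bin_size
    return RateMap(
        kind="arena",
        occupancy_s=occ,
        spike_count=counts,
        rate_hz=rate,
        valid=valid & pos,
        bin_edges=(edges, edges),
    )


def hd_tuning(
    session: ArenaSession,
    unit,
    velocity_mask: np.ndarray | None = None,
    bin_deg: float = HD_BIN_DEG,
) -> RateMap:
    """Head-direction tuning (3-degree bins, circular 5-bin boxcar)."""
    if velocity_mask is None:
        velocity_mask = velocity_filter(session)
    n_bins = int(round(360.0 / bin_deg))
    dur = sample_durations(session.sample_times)
    bins = position_to_bin(session.head_direction, bin_deg, n_bins)
    occ = np.bincount(bins[velocity_mask], weights=dur[velocity_mask], minlength=n_bins)
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy after velocity filtering")
    sp_idx = retained_spike_samples(session, unit, velocity_mask)
    counts = np.bincount(bins[sp_idx], minlength=n_bins).astype(float)
    box = np.ones(5) / 5.0
    s_occ = convolve1d(occ, box, mode="wrap")
    s_cnt = convolve1d(counts, box, mode="wrap")
    valid = s_occ > 0
    rate = np.zeros(n_bins)
    rate[valid] = s_cnt[valid] / s_occ[valid]
    return RateMap(
        kind="angular",
        occupancy_s=occ,
        spike_count=counts,
        rate_hz=rate,
        valid=valid,
        bin_edges=np.arange(n_bins + 1) * bin_deg,
    )
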