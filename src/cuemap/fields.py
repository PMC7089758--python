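"""Shuffle-based detection of spatial firing fields on the track.

The recording is reduced to 100 ms time bins carrying (a) the spike count
and (b) the spatial bin of the mean position in that interval. The spike
count series is circularly rotated by a random offset between 0.05 and
0.95 of its length, a smoothed rate map is rebuilt from each rotation
(occupancy is unchanged since only the spikes rotate), and the per-bin
p-value is the fraction of rotations whose rate exceeds the actual rate.
Bins with p < 0.3 are field bins. A rotation rate exactly equal to the
actual rate counts as not exceeding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import CueTemplate, TrackSession, position_to_bin
from .ratemaps import (
    gaussian_kernel_1d,
    retained_spike_samples,
    velocity_filter,
)

__all__ = [
    "FieldMask",
    "detect_fields",
    "population_field_distribution",
    "cue_region_field_contrast",
]

CHUNK_S = 0.1
FIELD_P = 0.3


@dataclass
class FieldMask:
    """Per-bin field flags and shuffle p-values for one unit."""

    is_field: np.ndarray  # bool per 5 cm bin
    p: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.is_field)


def _smooth1d(x, kernel):
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _chunk_series(session: TrackSession, unit, velocity_mask, bin_size):
    """100 ms chunk series (spike count, spatial bin) over retained samples."""
    t = np.asarray(session.sample_times, float)
    dt = np.median(np.diff(t)) if len(t) > 1 else 0.02
    per_chunk = max(1, int(round(CHUNK_S / dt)))
    keep = np.flatnonzero(velocity_mask)
    n_chunks = len(keep) // per_chunk
    if n_chunks == 0:
        raise ValueError("too few retained samples for 100 ms chunking")
    keep = keep[: n_chunks * per_chunk].reshape(n_chunks, per_chunk)
    n_bins = int(np.ceil(session.track_length / bin_size - 1e-9))
    mean_pos = np.asarray(session.positions, float)[keep].mean(axis=1)
    chunk_bins = position_to_bin(mean_pos, bin_size, n_bins)
    sp_idx = retained_spike_samples(session, unit, velocity_mask)
    spikes_per_sample = np.bincount(sp_idx, minlength=len(t))
    chunk_counts = spikes_per_sample[keep].sum(axis=1).astype(float)
    return chunk_counts, chunk_bins, n_bins


def _chunk_ratemap(counts, chunk_bins, n_bins, kernel):
    occ = np.bincount(chunk_bins, minlength=n_bins).astype(float) * CHUNK_S
    cnt = np.bincount(chunk_bins, weights=counts, minlength=n_bins)
    s_occ = _smooth1d(occ, kernel)
    s_cnt = _smooth1d(cnt, kernel)
    rate = np.full(n_bins, np.nan)
    pos = s_occ > 0
    rate[pos] = s_cnt[pos] / s_occ[pos]
    return rate


def detect_fields(
    session: TrackSession,
    unit,
    n_shuffles: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    bin_size: float = 5.0,
    velocity_mask: np.ndarray | None = None,
) -> FieldMask:
    """Field bins of one unit from the circular-permutation shuffle test.

    A unit with zero retained spikes gets an all-false mask with p = 1 by
    convention.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if velocity_mask is None:
        velocity_mask = velocity_filter(session)
    counts, chunk_bins, n_bins = _chunk_series(session, unit, velocity_mask, bin_size)
    if counts.sum() == 0:
        return FieldMask(np.zeros(n_bins, bool), np.ones(n_bins))
    kernel = gaussian_kernel_1d()
    actual = _chunk_ratemap(counts, chunk_bins, n_bins, kernel)
    L = len(counts)
    offsets = np.round(rng.uniform(0.05 * L, 0.95 * L, size=n_shuffles)).astype(int)
    exceed = np.zeros(n_bins)
    defined = np.isfinite(actual)
    for off in offsets:
        shuf = _chunk_ratemap(np.roll(counts, off), chunk_bins, n_bins, kernel)
        exceed[defined] += shuf[defined] > actual[defined]
    p = np.ones(n_bins)
    p[defined] = exceed[defined] / n_shuffles
    return FieldMask(p < FIELD_P, p)


def population_field_distribution(masks: list) -> np.ndarray:
    """Per-bin fraction of cells with a field in that bin."""
    if len(masks) == 0:
        raise ValueError("need at least one field mask")
    lengths = {m.n_bins for m in masks}
    if len(lengths) != 1:
        raise ValueError("field masks have mismatched lengths")
    return np.mean([m.is_field for m in masks], axis=0)


def cue_region_field_contrast(distribution: np.ndarray, template: CueTemplate):
    """(mean in-cue fraction, mean out-of-cue fraction) of a population
    field distribution."""
    d = np.asarray(distribution, float)
    v = np.asarray(template.values).astype(bool)
    if len(d) != len(v):
        raise ValueError("distribution and template lengths differ")
    if v.all() or not v.any():
        raise ValueError("template must contain both cue and non-cue bins")
    return float(d[v].mean()), float(d[~v].mean())
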