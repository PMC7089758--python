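"""Grid, head-direction, border, and split-half stability scores, their
circular spike-time shuffle thresholds, and duplicate-unit removal.

Scores follow the standard open-arena definitions: the grid score compares
annuli of the unbiased 2D rate-map autocorrelation with their 30-150 degree
rotations; the head-direction score is the mean vector length of the
angular tuning curve; the border score combines wall coverage of supra-
threshold firing fields with their rate-weighted distance to the nearest
wall; stability is the Pearson correlation of maps from the two session
halves. Undefined scores propagate as nan, never as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.ndimage import rotate as nd_rotate
from scipy.signal import correlate2d

from .io_model import ArenaSession, RateMap, TrackSession, slice_session
from .ratemaps import arena_ratemap, hd_tuning, track_ratemap
from .cue_scoring import ShuffleDistribution, _pearson

__all__ = [
    "autocorr2d",
    "grid_score",
    "hd_score",
    "border_score",
    "split_half_stability",
    "score_shuffle_threshold",
    "deduplicate_units",
    "within_day_duplicate",
    "cross_day_duplicate",
    "passes_inclusion_gates",
    "isi_histogram",
]

MIN_AC_OVERLAP = 20
_EPS = 1e-12


def autocorr2d(ratemap, valid=None, min_overlap: int = MIN_AC_OVERLAP) -> np.ndarray:
    """Unbiased spatial autocorrelation of a 2D rate map.

    At every 2D offset the Pearson correlation is computed over the
    mutually valid overlapping bins; offsets with fewer than ``min_overlap``
    such bins are nan. Accepts a RateMap or a plain array (+ valid mask).
    """
    if isinstance(ratemap, RateMap):
        m = np.asarray(ratemap.rate_hz, float)
        valid = np.asarray(ratemap.valid, bool)
    else:
        m = np.asarray(ratemap, float)
        if valid is None:
            valid = np.isfinite(m)
    if valid.sum() < min_overlap:
        raise ValueError("too few valid bins for autocorrelation")
    a = np.where(valid, m, 0.0)
    w = valid.astype(float)
    n = correlate2d(w, w, mode="full")
    sx = correlate2d(a, w, mode="full")
    sy = correlate2d(w, a, mode="full")
    sxy = correlate2d(a, a, mode="full")
    sxx = correlate2d(a * a, w, mode="full")
    syy = correlate2d(w, a * a, mode="full")
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        ac = cov / np.sqrt(vx * vy)
    ac[(n < min_overlap) | (vx <= _EPS * n) | (vy <= _EPS * n)] = np.nan
    return ac


def _radial_profile(ac: np.ndarray):
    c = (np.array(ac.shape) - 1) / 2.0
    yy, xx = np.indices(ac.shape)
    d = np.hypot(yy - c[0], xx - c[1])
    rmax = int(np.floor(d.max()))
    rad = np.full(rmax + 1, np.nan)
    ring = np.round(d).astype(int)
    for r in range(rmax + 1):
        vals = ac[(ring == r) & np.isfinite(ac)]
        if len(vals):
            rad[r] = vals.mean()
    return rad


def _inner_radius_bins(ac: np.ndarray, bin_size_cm: float) -> int:
    rad = _radial_profile(ac)
    first_min = None
    for r in range(1, len(rad) - 1):
        if np.isfinite(rad[r - 1 : r + 2]).all() and rad[r] < rad[r - 1] and rad[r] <= rad[r + 1]:
            first_min = r
            break
    first_neg = None
    neg = np.flatnonzero(np.isfinite(rad) & (rad < 0))
    if len(neg):
        first_neg = int(neg[0])
    ten_cm = max(1, int(round(10.0 / bin_size_cm)))
    options = [x for x in (first_min, first_neg, ten_cm) if x is not None]
    return max(1, min(options))


def grid_score(ratemap, valid=None, bin_size_cm: float = 2.5,
               ac: np.ndarray | None = None) -> float:
    """Hexagonal periodicity score of an arena rate map.

    For each annulus between the inner radius (first radial minimum, first
    negative crossing, or 10 cm, whichever is smallest) and a range of
    outer radii, the annulus is correlated with its rotations in 30-degree
    steps; the score is the best over annuli of
    max(r60, r120) - min(r30, r90, r150). Returns nan when no admissible
    annulus exists.
    """
    if ac is None:
        ac = autocorr2d(ratemap, valid)
    c = (np.array(ac.shape) - 1) / 2.0
    yy, xx = np.indices(ac.shape)
    dist = np.hypot(yy - c[0], xx - c[1])
    inner = _inner_radius_bins(ac, bin_size_cm)
    # outer radii run to the edge of the autocorrelogram (its corners carry
    # the rings of large-spacing grids), less the 4-bin margin
    max_outer = int(np.floor(dist.max())) - 4
    outers = range(inner + 4, max_outer + 1)
    rots = {
        ang: nd_rotate(ac, ang, reshape=False, order=1, mode="constant", cval=np.nan)
        for ang in (30, 60, 90, 120, 150)
    }
    best = np.nan
    for outer in outers:
        annulus = (dist > inner) & (dist <= outer)
        base = ac[annulus]
        corrs = {}
        for ang, rot in rots.items():
            rv = rot[annulus]
            ok = np.isfinite(base) & np.isfinite(rv)
            if ok.sum() < MIN_AC_OVERLAP:
                corrs = None
                break
            corrs[ang] = _pearson(base[ok], rv[ok])
        if corrs is None or any(not np.isfinite(v) for v in corrs.values()):
            continue
        val = max(corrs[60], corrs[120]) - min(corrs[30], corrs[90], corrs[150])
        if not np.isfinite(best) or val > best:
            best = val
    return float(best)


def hd_score(tuning) -> tuple[float, float]:
    """Mean vector length and preferred angle (deg) of an angular tuning
    curve. Returns (nan, nan) for an all-zero tuning."""
    if isinstance(tuning, RateMap):
        rate = np.asarray(tuning.rate_hz, float)
        edges = np.asarray(tuning.bin_edges, float)
        centers = np.deg2rad((edges[:-1] + edges[1:]) / 2.0)
    else:
        rate = np.asarray(tuning, float)
        centers = (np.arange(len(rate)) + 0.5) * (2 * np.pi / len(rate))
    total = rate.sum()
    if total <= 0:
        return np.nan, np.nan
    vec = np.sum(rate * np.exp(1j * centers)) / total
    return float(np.abs(vec)), float(np.rad2deg(np.angle(vec)) % 360.0)


def border_score(
    ratemap,
    valid=None,
    bin_size_cm: float = 2.5,
    field_threshold_frac: float = 0.3,
    min_field_area_cm2: float = 200.0,
) -> float:
    """Border score: (cM - dM) / (cM + dM).

    Fields are 4-connected components of bins above 30% of the peak rate
    covering at least 200 cm^2. cM is the best single-wall coverage of any
    field; dM the rate-weighted mean distance of field bins to their
    nearest wall, normalised by half the arena width. Returns nan when no
    field qualifies.
    """
    if isinstance(ratemap, RateMap):
        m = np.asarray(ratemap.rate_hz, float)
        valid = np.asarray(ratemap.valid, bool)
    else:
        m = np.asarray(ratemap, float)
        if valid is None:
            valid = np.isfinite(m)
    rate = np.where(valid, m, 0.0)
    peak = rate.max()
    if peak <= 0:
        return np.nan
    above = rate > field_threshold_frac * peak
    labels, n_fields = cc_label(above)
    min_bins = int(np.ceil(min_field_area_cm2 / bin_size_cm**2))
    keep = [k for k in range(1, n_fields + 1) if (labels == k).sum() >= min_bins]
    if not keep:
        return np.nan
    n = rate.shape[0]
    walls = [
        (labels[0, :], n),  # x = 0 wall
        (labels[-1, :], n),  # x = max wall
        (labels[:, 0], n),  # y = 0 wall
        (labels[:, -1], n),  # y = max wall
    ]
    cM = max(
        (wall == k).sum() / float(nw) for k in keep for wall, nw in walls
    )
    ii, jj = np.indices(rate.shape)
    dist_bins = np.minimum.reduce([ii, jj, n - 1 - ii, n - 1 - jj]).astype(float)
    in_field = np.isin(labels, keep)
    w = rate[in_field]
    d = dist_bins[in_field] * bin_size_cm
    half_width = n * bin_size_cm / 2.0
    dM = float(np.sum(w * d) / np.sum(w)) / half_width
    return float((cM - dM) / (cM + dM))


def split_half_stability(session, unit, kind: str = "spatial",
                         min_overlap: int = 20) -> float:
    """Pearson correlation of the two half-session maps of a unit.

    ``kind`` is 'spatial' (track or arena map, by session type) or 'hd'
    (arena only). Undefined (< ``min_overlap`` mutually valid bins) -> nan.
    """
    t = np.asarray(session.sample_times, float)
    if len(t) < 4:
        return np.nan
    mid = t[0] + (t[-1] - t[0]) / 2.0
    halves = [slice_session(session, t[0], mid), slice_session(session, mid, t[-1] + 1e-9)]
    maps = []
    for h in halves:
        try:
            if kind == "hd":
                maps.append(hd_tuning(h, unit))
            elif isinstance(session, ArenaSession):
                maps.append(arena_ratemap(h, unit))
            else:
                maps.append(track_ratemap(h, unit))
        except ValueError:
            return np.nan
    a, b = maps
    ok = np.asarray(a.valid, bool) & np.asarray(b.valid, bool)
    if ok.sum() < min_overlap:
        return np.nan
    return _pearson(np.asarray(a.rate_hz)[ok], np.asarray(b.rate_hz)[ok])


def _with_shifted_spikes(session, unit, offset_s: float):
    t = np.asarray(session.sample_times, float)
    st = np.asarray(session.spike_times_per_unit[unit], float)
    T = t[-1] - t[0]
    shifted = t[0] + np.sort((st - t[0] + offset_s) % T)
    spikes = dict(session.spike_times_per_unit)
    spikes[unit] = shifted
    return replace(session, spike_times_per_unit=spikes)


def score_shuffle_threshold(
    sessions,
    units,
    score_fn,
    n_shuffles: int = 100,
    percentile: float = 95.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ShuffleDistribution:
    """Pooled circular spike-time shuffle null for any arena score.

    For each (session, unit) pair the unit's spike times are circularly
    permuted by offsets uniform in [0.5, 0.95] x recording length and the
    score recomputed; all finite shuffled scores are pooled and the
    threshold is the pooled percentile. ``score_fn(session, unit)`` must
    return a float.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = []
    for sess, unit in zip(sessions, units):
        T = float(sess.sample_times[-1] - sess.sample_times[0])
        offsets = rng.uniform(0.5 * T, 0.95 * T, size=n_shuffles)
        for off in offsets:
            val = score_fn(_with_shifted_spikes(sess, unit, off), unit)
            if np.isfinite(val):
                pool.append(float(val))
    if not pool:
        raise ValueError("all shuffled scores undefined")
    pool = np.asarray(pool)
    return ShuffleDistribution(pool, percentile, float(np.percentile(pool, percentile)))


# ---------------------------------------------------------------------------
# duplicate-unit removal
# ---------------------------------------------------------------------------


def passes_inclusion_gates(n_spikes: int, track_rate: np.ndarray) -> bool:
    """Cluster inclusion: >= 100 spikes, track-rate minimum <= 10 Hz and
    maximum <= 50 Hz."""
    r = np.asarray(track_rate, float)
    return bool(n_spikes >= 100 and np.nanmin(r) <= 10.0 and np.nanmax(r) <= 50.0)


def isi_histogram(spike_times, bins=None) -> np.ndarray:
    """Normalised log-binned inter-spike-interval histogram."""
    if bins is None:
        bins = np.logspace(-3, 2, 51)
    isi = np.diff(np.sort(np.asarray(spike_times, float)))
    h, _ = np.histogram(isi, bins=bins)
    total = h.sum()
    return h / total if total else h.astype(float)


def _map_corr(a, b):
    if a is None or b is None:
        return None
    av = np.asarray(a.rate_hz if isinstance(a, RateMap) else a, float).ravel()
    bv = np.asarray(b.rate_hz if isinstance(b, RateMap) else b, float).ravel()
    ok = np.isfinite(av) & np.isfinite(bv)
    return _pearson(av[ok], bv[ok])


def within_day_duplicate(rec_a: dict, rec_b: dict, threshold: float = 2.25) -> bool:
    """Same-day duplicate rule: arena-map correlation + track-map
    correlation + merged-ISI similarity summed; a sum above the threshold
    marks the pair as one cell.

    The ISI component is the mean correlation of the merged spike train's
    log-binned ISI histogram with each cluster's own histogram (the exact
    construction of this component is an assumption of this package).
    """
    ca = _map_corr(rec_a.get("arena_map"), rec_b.get("arena_map"))
    ct = _map_corr(rec_a.get("track_map"), rec_b.get("track_map"))
    if ca is None or ct is None:
        warnings.warn("pair skipped: missing arena or track map")
        return False
    merged = np.concatenate([rec_a["spike_times"], rec_b["spike_times"]])
    hm = isi_histogram(merged)
    ci = np.nanmean([
        _pearson(hm, isi_histogram(rec_a["spike_times"])),
        _pearson(hm, isi_histogram(rec_b["spike_times"])),
    ])
    total = np.nansum([ca, ct, ci])
    return bool(total > threshold)


def cross_day_duplicate(rec_a: dict, rec_b: dict,
                        arena_threshold: float = 0.8,
                        track_threshold: float = 0.75) -> bool:
    """Cross-day duplicate rule: mean-subtracted (Pearson) correlation of
    arena maps >= 0.8 or of track maps >= 0.75."""
    ca = _map_corr(rec_a.get("arena_map"), rec_b.get("arena_map"))
    ct = _map_corr(rec_a.get("track_map"), rec_b.get("track_map"))
    if ca is None and ct is None:
        warnings.warn("pair skipped: missing maps")
        return False
    return bool((ca is not None and np.isfinite(ca) and ca >= arena_threshold)
                or (ct is not None and np.isfinite(ct) and ct >= track_threshold))


def _arena_peak(rec: dict) -> float:
    if "arena_peak" in rec:
        return float(rec["arena_peak"])
    m = rec["arena_map"]
    arr = m.rate_hz if isinstance(m, RateMap) else m
    return float(np.nanmax(np.asarray(arr, float)))


def deduplicate_units(records: dict, pairs, mode: str = "within_day") -> list:
    """Resolve candidate duplicate pairs and return the kept unit ids.

    ``records`` maps unit id -> dict with keys ``arena_map``, ``track_map``,
    ``spike_times`` (and optionally ``arena_peak``). Within-day duplicates
    keep the cluster with more spikes; cross-day duplicates keep the higher
    arena peak rate.
    """
    discard = set()
    for a, b in pairs:
        ra, rb = records[a], records[b]
        if mode == "within_day":
            if within_day_duplicate(ra, rb):
                na, nb = len(ra["spike_times"]), len(rb["spike_times"])
                discard.add(a if na < nb else b)
        elif mode == "cross_day":
            if cross_day_duplicate(ra, rb):
                discard.add(a if _arena_peak(ra) < _arena_peak(rb) else b)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return [u for u in records if u not in discard]
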