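"""Cue score: template alignment, per-cue local correlations, shuffle
thresholds, cue-cell classification, side-specific and bilateral variants.

The cue score of a cell measures how well its spatial firing rate tracks a
binary cue template. The template is first displaced by the lag (within
+/-300 cm) at which the lagged Pearson correlation between rate and
template has the local peak nearest zero; the rate is then correlated with
the displaced template locally around each cue (the cue extent plus half a
cue width on each side), and the score is the mean of those per-cue
correlations. The sign convention: a positive shift displaces the template
toward larger track positions to align it with the rate.

Classification thresholds come from a location-shuffle null: each cell is
re-scored against templates whose cues are redistributed uniformly at
random (identical widths, no overlap), all cells' shuffled scores are
pooled, and the threshold is the pooled 95th percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_model import CueTemplate

__all__ = [
    "CueScoreResult",
    "ShuffleDistribution",
    "lag_correlation",
    "nearest_zero_peak",
    "cue_shift_and_score",
    "local_score_at_shift",
    "shuffled_template",
    "cue_threshold",
    "classify_cue_cells",
    "side_classify",
    "bilateral_score",
    "random_template_percentage_control",
]

MAX_SHIFT_CM = 300.0
MIN_OVERLAP_BINS = 10
MIN_WINDOW_BINS = 3
_EPS = 1e-12


@dataclass
class CueScoreResult:
    """Outcome of aligning one rate vector to one cue template."""

    score: float  # mean per-cue Pearson r; nan if undefined
    shift_cm: float  # signed template displacement (positive -> larger pos.)
    per_cue_r: np.ndarray  # nan where a cue's correlation is undefined
    aligned: bool  # False when no usable correlation peak existed
    lags_cm: np.ndarray = field(default=None, repr=False)
    lag_r: np.ndarray = field(default=None, repr=False)


@dataclass
class ShuffleDistribution:
    values: np.ndarray
    percentile: float
    threshold: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2:
        return np.nan
    xd = x - x.mean()
    yd = y - y.mean()
    den = np.sqrt((xd @ xd) * (yd @ yd))
    if den <= _EPS * len(x):
        return np.nan
    return float((xd @ yd) / den)


def lag_correlation(
    rate: np.ndarray,
    template_values: np.ndarray,
    max_lag_bins: int,
    min_overlap: int = MIN_OVERLAP_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of ``rate`` with the template displaced by every
    lag in ``[-max_lag_bins, max_lag_bins]``.

    Lag ``l`` means the template is displaced by ``l`` bins toward larger
    positions (shifted template ``T[i] = template[i - l]``); only the
    overlapping segment is used at each lag, and lags leaving fewer than
    ``min_overlap`` bins are undefined (nan).
    """
    r = np.asarray(rate, float)
    t = np.asarray(template_values, float)
    n = len(r)
    if len(t) != n:
        raise ValueError("rate and template must share binning")
    max_lag = min(max_lag_bins, n - 1)
    lags = np.arange(-max_lag, max_lag + 1)
    # cumulative sums for windowed moments
    cr, cr2 = np.r_[0, np.cumsum(r)], np.r_[0, np.cumsum(r * r)]
    ct, ct2 = np.r_[0, np.cumsum(t)], np.r_[0, np.cumsum(t * t)]
    cross_full = np.correlate(r, t, mode="full")  # index l + n - 1 = sum r[i] t[i-l]
    nl = (n - np.abs(lags)).astype(float)
    pos = lags >= 0
    sr = np.where(pos, cr[-1] - cr[np.abs(lags)], cr[n + np.minimum(lags, 0)])
    sr2 = np.where(pos, cr2[-1] - cr2[np.abs(lags)], cr2[n + np.minimum(lags, 0)])
    st = np.where(pos, ct[n - np.abs(lags)], ct[-1] - ct[np.abs(lags)])
    st2 = np.where(pos, ct2[n - np.abs(lags)], ct2[-1] - ct2[np.abs(lags)])
    cross = cross_full[lags + n - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = cross - sr * st / nl
        var_r = sr2 - sr * sr / nl
        var_t = st2 - st * st / nl
        corr = cov / np.sqrt(var_r * var_t)
    corr[(var_r <= _EPS * nl) | (var_t <= _EPS * nl)] = np.nan
    corr[nl < min_overlap] = np.nan
    return lags, corr


def nearest_zero_peak(lags: np.ndarray, corr: np.ndarray) -> int | None:
    """Index into ``lags`` of the local correlation maximum nearest zero lag.

    Strict local maxima are found within each contiguous finite stretch
    (endpoints compared one-sided); a plateau contributes its point nearest
    zero. Ties in |lag| go to the higher correlation. When no local maximum
    exists the global maximum is used; all-nan input returns None.
    """
    finite = np.isfinite(corr)
    if not finite.any():
        return None
    candidates = []
    i = 0
    n = len(corr)
    while i < n:
        if not finite[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and finite[j + 1]:
            j += 1
        # segment [i, j]
        k = i
        while k <= j:
            m = k
            while m + 1 <= j and corr[m + 1] == corr[k]:
                m += 1
            left_ok = (k == i) or (corr[k - 1] < corr[k])
            right_ok = (m == j) or (corr[m + 1] < corr[k])
            interior = not (k == i and m == j)  # whole-segment plateau is not a peak
            if left_ok and right_ok and interior:
                plateau = np.arange(k, m + 1)
                candidates.append(plateau[np.argmin(np.abs(lags[plateau]))])
            k = m + 1
        i = j + 1
    if not candidates:
        candidates = [int(np.nanargmax(np.where(finite, corr, -np.inf)))]
    key = sorted(candidates, key=lambda c: (abs(int(lags[c])), -corr[c], int(lags[c])))
    return int(key[0])


def _displaced_values(template: CueTemplate, shift_bins: int) -> np.ndarray:
    v = np.asarray(template.values, float)
    out = np.zeros_like(v)
    n = len(v)
    if shift_bins >= 0:
        out[shift_bins:] = v[: n - shift_bins] if shift_bins < n else []
    else:
        out[: n + shift_bins] = v[-shift_bins:]
    return out


def _cue_window_bins(start: float, end: float, shift_cm: float, bin_size: float, n_bins: int):
    w = end - start
    lo = start + shift_cm - w / 2.0
    hi = end + shift_cm + w / 2.0
    b0 = max(int(np.floor(lo / bin_size + 1e-9)), 0)
    b1 = min(int(np.ceil(hi / bin_size - 1e-9)), n_bins)
    return b0, b1


def local_score_at_shift(rate: np.ndarray, template: CueTemplate, shift_cm: float):
    """Mean per-cue local correlation with the template displaced by a
    given shift. Returns (score, per_cue_r)."""
    rate = np.asarray(rate, float)
    n_bins = template.n_bins
    bs = template.bin_size
    shift_bins = int(round(shift_cm / bs))
    shifted = _displaced_values(template, shift_bins)
    per_cue = np.full(len(template.cues), np.nan)
    for ci, (start, end, _side) in enumerate(template.cues):
        b0, b1 = _cue_window_bins(start, end, shift_bins * bs, bs, n_bins)
        if b1 - b0 < MIN_WINDOW_BINS:
            continue
        per_cue[ci] = _pearson(rate[b0:b1], shifted[b0:b1])
    score = np.nan if np.all(np.isnan(per_cue)) else float(np.nanmean(per_cue))
    return score, per_cue


def cue_shift_and_score(
    rate: np.ndarray,
    template: CueTemplate,
    max_shift_cm: float = MAX_SHIFT_CM,
    min_overlap_bins: int = MIN_OVERLAP_BINS,
) -> CueScoreResult:
    """Align the cue template to a rate vector and compute the cue score.

    Returns a result whose ``score`` is nan (and ``aligned`` False) when the
    rate is constant at every local window or no lag correlation is defined.
    """
    rate = np.asarray(rate, float)
    bs = template.bin_size
    max_lag = int(round(max_shift_cm / bs))
    lags, corr = lag_correlation(rate, template.values, max_lag, min_overlap_bins)
    peak = nearest_zero_peak(lags, corr)
    if peak is None:
        return CueScoreResult(np.nan, np.nan, np.full(len(template.cues), np.nan), False,
                              lags * bs, corr)
    shift_cm = float(lags[peak] * bs)
    score, per_cue = local_score_at_shift(rate, template, shift_cm)
    return CueScoreResult(score, shift_cm, per_cue, np.isfinite(score), lags * bs, corr)


def shuffled_template(template: CueTemplate, rng: np.random.Generator) -> CueTemplate:
    """Template with the same number of cues and identical widths placed
    uniformly at random, without overlap, fully on the track."""
    widths = template.cue_widths()
    sides = [c[2] for c in template.cues]
    L = template.track_length
    free = L - widths.sum()
    if free <= 0:
        raise ValueError("cues cannot be redistributed without overlap")
    order = rng.permutation(len(widths))
    gaps = np.sort(rng.uniform(0.0, free, size=len(widths)))
    cues = []
    acc = 0.0
    for slot, idx in enumerate(order):
        start = gaps[slot] + acc
        cues.append((float(start), float(start + widths[idx]), sides[idx]))
        acc += widths[idx]
    return CueTemplate(L, template.bin_size, cues)


def cue_threshold(
    rates: dict,
    template: CueTemplate,
    n_shuffles_per_cell: int = 100,
    percentile: float = 95.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ShuffleDistribution:
    """Pooled location-shuffle null for cue scores.

    Every cell is scored against ``n_shuffles_per_cell`` freshly shuffled
    templates; all finite shuffled scores are pooled and the threshold is
    the pooled ``percentile`` (linear interpolation).
    """
    if len(rates) == 0:
        raise ValueError("at least one cell is required")
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = []
    for _cell, rate in rates.items():
        for _ in range(n_shuffles_per_cell):
            st = shuffled_template(template, rng)
            res = cue_shift_and_score(rate, st)
            if np.isfinite(res.score):
                pool.append(res.score)
    if not pool:
        raise ValueError("all shuffled scores undefined")
    pool = np.asarray(pool)
    return ShuffleDistribution(pool, percentile, float(np.percentile(pool, percentile)))


def classify_cue_cells(rates: dict, template: CueTemplate, threshold: float):
    """Score each cell against the real template; flag = score > threshold.

    Returns (results, flags) keyed by cell id.
    """
    results = {cell: cue_shift_and_score(rate, template) for cell, rate in rates.items()}
    flags = {
        cell: bool(np.isfinite(res.score) and res.score > threshold)
        for cell, res in results.items()
    }
    return results, flags


def side_classify(
    rates: dict,
    left_template: CueTemplate,
    right_template: CueTemplate,
    thresholds: dict,
):
    """Assign cells to left/right cue classes.

    Unique passers take their side; cells passing both thresholds go to the
    side with the higher cue score (an exact tie leaves the cell without a
    side, with a warning).

    Returns a dict cell -> {'left': ..., 'right': ..., 'side': 'left'|'right'|None}.
    """
    out = {}
    for cell, rate in rates.items():
        lres = cue_shift_and_score(rate, left_template)
        rres = cue_shift_and_score(rate, right_template)
        lpass = np.isfinite(lres.score) and lres.score > thresholds["left"]
        rpass = np.isfinite(rres.score) and rres.score > thresholds["right"]
        side = None
        if lpass and rpass:
            if lres.score > rres.score:
                side = "left"
            elif rres.score > lres.score:
                side = "right"
            else:
                warnings.warn(f"cell {cell!r}: tied left/right cue scores; side unresolved")
        elif lpass:
            side = "left"
        elif rpass:
            side = "right"
        out[cell] = {"left": lres, "right": rres, "side": side}
    return out


def bilateral_score(
    rate: np.ndarray,
    left_template: CueTemplate,
    right_template: CueTemplate,
    preferred_side: str,
) -> float:
    """Left-minus-right cue score with both templates displaced by the
    preferred side's own best shift.

    Returns nan when the non-preferred side's local score is undefined.
    """
    if preferred_side not in ("left", "right"):
        raise ValueError("preferred_side must be 'left' or 'right'")
    pref = left_template if preferred_side == "left" else right_template
    other = right_template if preferred_side == "left" else left_template
    res = cue_shift_and_score(rate, pref)
    if not res.aligned:
        return np.nan
    other_score, _ = local_score_at_shift(rate, other, res.shift_cm)
    if not np.isfinite(other_score):
        return np.nan
    if preferred_side == "left":
        return float(res.score - other_score)
    return float(other_score - res.score)


def random_template_percentage_control(
    rates: dict,
    template: CueTemplate,
    n_random: int,
    seed: int | None = None,
    n_shuffles_per_cell: int = 100,
    percentile: float = 95.0,
):
    """Percentage of cells classified with the real template versus with
    location-shuffled templates (threshold recomputed per template).

    Returns (real_pct, np.ndarray of random pcts).
    """
    rng = np.random.default_rng(seed)

    def pct_for(tmpl):
        dist = cue_threshold(rates, tmpl, n_shuffles_per_cell, percentile, rng=rng)
        _, flags = classify_cue_cells(rates, tmpl, dist.threshold)
        return 100.0 * sum(flags.values()) / len(flags)

    real = pct_for(template)
    randoms = np.array([pct_for(shuffled_template(template, rng)) for _ in range(n_random)])
    return real, randoms
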