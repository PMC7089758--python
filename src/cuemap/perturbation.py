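"""With-cues versus missing-cues comparison over track regions.

A perturbation session pairs two tracks that are identical up to some
point (Region A) and differ afterwards (Region B, where cues were
removed). Two per-cell measures are compared across tracks within each
region: the lagged template correlation at the nearest-zero peak, and the
fraction of region bins carrying a firing field. Regions are configured as
bin intervals; run counts are equalised upstream by truncating the longer
block to the shorter one, earliest runs first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cue_scoring import lag_correlation, nearest_zero_peak, MIN_OVERLAP_BINS
from .fields import FieldMask
from .io_model import CueTemplate, TrackSession, slice_session

__all__ = [
    "region_template_correlation",
    "region_field_fraction",
    "paired_region_comparison",
    "equalize_runs",
    "RegionComparison",
]

MIN_REGION_BINS = 10


def equalize_runs(a: TrackSession, b: TrackSession):
    """Truncate both sessions to the same run count (earliest runs kept)."""
    n = min(a.run_ids.max() + 1 if a.n_samples else 0,
            b.run_ids.max() + 1 if b.n_samples else 0)

    def first_runs(s):
        keep = s.run_ids < n
        if keep.all():
            return s
        t_cut = s.sample_times[np.argmax(~keep)]
        return slice_session(s, s.sample_times[0], t_cut)

    return first_runs(a), first_runs(b)


def region_template_correlation(
    rate: np.ndarray,
    template: CueTemplate,
    region: tuple,
    max_shift_cm: float = 300.0,
) -> float:
    """Lagged rate-template correlation within a bin interval
    ``region = (first_bin, last_bin_exclusive)``: the correlation value at
    the lag peak nearest zero.

    Returns nan when the template is empty or the rate constant inside the
    region; a region shorter than 10 bins is an error.
    """
    b0, b1 = int(region[0]), int(region[1])
    if b1 - b0 < MIN_REGION_BINS:
        raise ValueError(f"region [{b0}, {b1}) shorter than {MIN_REGION_BINS} bins")
    r = np.asarray(rate, float)[b0:b1]
    t = np.asarray(template.values, float)[b0:b1]
    if t.max() == t.min():
        return np.nan
    max_lag = int(round(max_shift_cm / template.bin_size))
    lags, corr = lag_correlation(r, t, max_lag, MIN_OVERLAP_BINS)
    peak = nearest_zero_peak(lags, corr)
    if peak is None:
        return np.nan
    return float(corr[peak])


def region_field_fraction(mask: FieldMask, region: tuple) -> float:
    """Fraction of region bins flagged as field bins."""
    b0, b1 = int(region[0]), int(region[1])
    if b1 <= b0:
        raise ValueError("empty region")
    if b0 < 0 or b1 > mask.n_bins:
        raise ValueError("region outside track")
    return float(np.mean(mask.is_field[b0:b1]))


@dataclass
class RegionComparison:
    differences: np.ndarray  # per-cell (track A - track B)
    t_statistic: float
    p_value: float  # one-tailed, H1: mean(A) > mean(B)


def paired_region_comparison(values_a, values_b) -> RegionComparison:
    """Per-cell paired differences (A - B) with a one-tailed paired t-test
    of A > B. Requires at least 3 pairs."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    res = stats.ttest_rel(a[ok], b[ok], alternative="greater")
    return RegionComparison(a - b, float(res.statistic), float(res.pvalue))
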