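"""Slow, loop-based reference implementations used to cross-check the
vectorised analysis code. Deliberately written with plain Python loops and
no code shared with the package internals."""

import numpy as np
from scipy.ndimage import rotate as nd_rotate


def pearson_loop(x, y):
    n = len(x)
    if n < 2:
        return float("nan")
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx <= 1e-12 * n or syy <= 1e-12 * n:
        return float("nan")
    return sxy / (sxx * syy) ** 0.5


def lag_corr_oracle(rate, template, max_lag, min_overlap=10):
    n = len(rate)
    max_lag = min(max_lag, n - 1)
    lags = list(range(-max_lag, max_lag + 1))
    out = []
    for l in lags:
        if l >= 0:
            a, b = rate[l:], template[: n - l]
        else:
            a, b = rate[: n + l], template[-l:]
        out.append(float("nan") if len(a) < min_overlap else pearson_loop(list(a), list(b)))
    return np.array(lags), np.array(out)


def nearest_zero_peak_oracle(lags, corr):
    """Same peak rules, re-derived with explicit scans."""
    finite = np.isfinite(corr)
    if not finite.any():
        return None
    candidates = []
    segments = []
    start = None
    for i, f in enumerate(finite):
        if f and start is None:
            start = i
        if not f and start is not None:
            segments.append((start, i - 1))
            start = None
    if start is not None:
        segments.append((start, len(corr) - 1))
    for s, e in segments:
        i = s
        while i <= e:
            j = i
            while j < e and corr[j + 1] == corr[i]:
                j += 1
            left = (i == s) or (corr[i - 1] < corr[i])
            right = (j == e) or (corr[j + 1] < corr[i])
            if left and right and not (i == s and j == e):
                best = min(range(i, j + 1), key=lambda k: abs(lags[k]))
                candidates.append(best)
            i = j + 1
    if not candidates:
        best = None
        for i in range(len(corr)):
            if finite[i] and (best is None or corr[i] > corr[best]):
                best = i
        candidates = [best]
    return min(candidates, key=lambda c: (abs(int(lags[c])), -corr[c], int(lags[c])))


def cue_score_oracle(rate, template, max_shift_cm=300.0):
    """Exhaustive cue score: (score, shift_cm)."""
    bs = template.bin_size
    n = template.n_bins
    lags, corr = lag_corr_oracle(list(rate), list(template.values.astype(float)),
                                 int(round(max_shift_cm / bs)))
    peak = nearest_zero_peak_oracle(lags, corr)
    if peak is None:
        return float("nan"), float("nan")
    shift_bins = int(lags[peak])
    shifted = [0.0] * n
    for i in range(n):
        j = i - shift_bins
        if 0 <= j < n:
            shifted[i] = float(template.values[j])
    per_cue = []
    for start, end, *_ in template.cues:
        w = end - start
        lo = start + shift_bins * bs - w / 2.0
        hi = end + shift_bins * bs + w / 2.0
        b0 = max(int(np.floor(lo / bs + 1e-9)), 0)
        b1 = min(int(np.ceil(hi / bs - 1e-9)), n)
        if b1 - b0 < 3:
            continue
        r = pearson_loop(list(rate[b0:b1]), shifted[b0:b1])
        if np.isfinite(r):
            per_cue.append(r)
    score = sum(per_cue) / len(per_cue) if per_cue else float("nan")
    return score, shift_bins * bs


def autocorr_oracle(m, valid, min_overlap=20):
    ny, nx = m.shape
    out = np.full((2 * ny - 1, 2 * nx - 1), np.nan)
    for dy in range(-(ny - 1), ny):
        for dx in range(-(nx - 1), nx):
            xs, ys = [], []
            for i in range(ny):
                for j in range(nx):
                    i2, j2 = i + dy, j + dx
                    if 0 <= i2 < ny and 0 <= j2 < nx and valid[i, j] and valid[i2, j2]:
                        xs.append(m[i2, j2])
                        ys.append(m[i, j])
            if len(xs) >= min_overlap:
                out[dy + ny - 1, dx + nx - 1] = pearson_loop(xs, ys)
    return out


def grid_score_oracle(ac, bin_size_cm=2.5, min_overlap=20):
    n = ac.shape[0]
    c = (n - 1) / 2.0
    # radial mean
    rmax = int(np.floor(np.hypot(c, c)))
    sums = [[] for _ in range(rmax + 1)]
    for i in range(n):
        for j in range(n):
            if np.isfinite(ac[i, j]):
                r = int(round(np.hypot(i - c, j - c)))
                sums[r].append(ac[i, j])
    rad = [np.mean(s) if s else float("nan") for s in sums]
    first_min = None
    for r in range(1, len(rad) - 1):
        if (np.isfinite(rad[r - 1]) and np.isfinite(rad[r]) and np.isfinite(rad[r + 1])
                and rad[r] < rad[r - 1] and rad[r] <= rad[r + 1]):
            first_min = r
            break
    first_neg = None
    for r, v in enumerate(rad):
        if np.isfinite(v) and v < 0:
            first_neg = r
            break
    options = [x for x in (first_min, first_neg, max(1, int(round(10.0 / bin_size_cm))))
               if x is not None]
    inner = max(1, min(options))
    rots = {a: nd_rotate(ac, a, reshape=False, order=1, mode="constant", cval=np.nan)
            for a in (30, 60, 90, 120, 150)}
    best = float("nan")
    max_outer = int(np.floor(np.hypot(c, c))) - 4
    for outer in range(inner + 4, max_outer + 1):
        corrs = {}
        ok_all = True
        for ang, rot in rots.items():
            xs, ys = [], []
            for i in range(n):
                for j in range(n):
                    d = np.hypot(i - c, j - c)
                    if inner < d <= outer and np.isfinite(ac[i, j]) and np.isfinite(rot[i, j]):
                        xs.append(ac[i, j])
                        ys.append(rot[i, j])
            if len(xs) < min_overlap:
                ok_all = False
                break
            corrs[ang] = pearson_loop(xs, ys)
        if not ok_all or any(not np.isfinite(v) for v in corrs.values()):
            continue
        val = max(corrs[60], corrs[120]) - min(corrs[30], corrs[90], corrs[150])
        if not np.isfinite(best) or val > best:
            best = val
    return best


def ridge_background_oracle(rate, template, shift_cm,
                            near_cm=20.0, far_cm=30.0, ridge_bins=5):
    bs = template.bin_size
    n = template.n_bins
    cue_bin_sets = []
    for start, end, *_ in template.cues:
        lo = int(np.floor((start + shift_cm) / bs + 1e-9))
        hi = int(np.ceil((end + shift_cm) / bs - 1e-9))
        cue_bin_sets.append([b for b in range(max(lo, 0), min(hi, n))])
    all_cue = set(b for s in cue_bin_sets for b in s)
    ratios = []
    for (start, end, *_), bins in zip(template.cues, cue_bin_sets):
        if not bins:
            continue
        center = bins[(len(bins) - 1) // 2]
        ridge = [rate[b] for b in range(max(center - ridge_bins // 2, 0),
                                        min(center + ridge_bins // 2 + 1, n))]
        hw = (end - start) / 2.0
        c = (start + end) / 2.0 + shift_cm
        bg = []
        for b in range(n):
            d = abs((b + 0.5) * bs - c)
            if hw + near_cm < d <= hw + far_cm and b not in all_cue:
                bg.append(rate[b])
        if not bg or sum(bg) / len(bg) <= 0:
            continue
        ratios.append((sum(ridge) / len(ridge)) / (sum(bg) / len(bg)))
    return sum(ratios) / len(ratios) if ratios else float("nan")


def region_correlation_oracle(rate, template, region, max_shift_cm=300.0):
    b0, b1 = region
    r = list(rate[b0:b1])
    t = list(template.values.astype(float)[b0:b1])
    if max(t) == min(t):
        return float("nan")
    lags, corr = lag_corr_oracle(r, t, int(round(max_shift_cm / template.bin_size)))
    peak = nearest_zero_peak_oracle(lags, corr)
    return float("nan") if peak is None else corr[peak]
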