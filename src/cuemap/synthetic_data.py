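"""Synthetic sessions with known ground truth.

The generators emulate the recording conditions the analysis assumes:
unidirectional runs on an 8-18 m virtual track sampled at 50 Hz with
teleports back to the start and occasional sub-threshold pauses; random
foraging in a 0.5 x 0.5 m arena; spike trains drawn from an inhomogeneous
Poisson process (by thinning) under cue-locked, grid, border,
head-direction or untuned rate functions; and calcium traces obtained by
convolving spikes with a fast-rise/slow-decay kernel plus Gaussian noise.
Every simulated unit carries exactly one ground-truth class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import DffTrace
from .io_model import ArenaSession, CueTemplate, TrackSession

__all__ = [
    "GroundTruth",
    "simulate_track_trajectory",
    "simulate_arena_trajectory",
    "cue_rate_function",
    "grid_rate_function",
    "border_rate_function",
    "hd_rate_function",
    "poisson_spikes",
    "spikes_to_dff",
    "default_cue_template",
    "simulate_mixed_population",
]

DT_S = 0.02
DEFAULT_MEAN_SPEED = 20.0  # cm/s, typical sustained running speed on the treadmill
DEFAULT_SPEED_SD = 4.0
CUE_PEAK_HZ = 8.0
CUE_BASELINE_HZ = 0.5
CUE_FIELD_SIGMA_CM = 10.0


@dataclass
class GroundTruth:
    """Generative parameters of one simulated cell."""

    cell_id: object
    cell_class: str  # cue | grid | border | hd | untuned
    cue_shift_cm: float = np.nan
    cue_amplitudes: np.ndarray | None = None
    field_width_cm: float = np.nan
    peak_hz: float = np.nan
    baseline_hz: float = np.nan
    grid_spacing_cm: float = np.nan
    grid_orientation_deg: float = np.nan
    grid_phase: tuple = (np.nan, np.nan)
    hd_pref_deg: float = np.nan
    hd_kappa: float = np.nan


def simulate_track_trajectory(
    track_length: float = 800.0,
    n_runs: int = 40,
    mean_speed: float = DEFAULT_MEAN_SPEED,
    speed_sd: float = DEFAULT_SPEED_SD,
    dt: float = DT_S,
    pause_rate_hz: float = 0.02,
    pause_s: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TrackSession:
    """Unidirectional runs with teleports and occasional sub-threshold
    pauses (to exercise the velocity gate)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    times, positions, run_ids = [], [], []
    t = 0.0
    for run in range(n_runs):
        pos = 0.0
        base = max(mean_speed + rng.normal(0, speed_sd), 5.0)
        pause_left = 0.0
        while pos < track_length:
            if pause_left <= 0 and rng.random() < pause_rate_hz * dt:
                pause_left = pause_s * (0.5 + rng.random())
            if pause_left > 0:
                v = 0.3  # slow drift below the 1 cm/s gate
                pause_left -= dt
            else:
                v = max(base + rng.normal(0, speed_sd) * 0.5, 1.5)
            times.append(t)
            positions.append(pos)
            run_ids.append(run)
            pos += v * dt
            t += dt
    return TrackSession(
        sample_times=np.asarray(times),
        positions=np.clip(np.asarray(positions), 0, track_length),
        run_ids=np.asarray(run_ids, int),
        track_length=float(track_length),
    )


def simulate_arena_trajectory(
    arena_size: float = 50.0,
    duration_s: float = 1200.0,
    dt: float = DT_S,
    mean_speed: float = 12.0,
    heading_diffusion: float = 2.0,  # rad / sqrt(s)
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ArenaSession:
    """Smooth bounded random-walk foraging with heading carried as the
    head direction."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt))
    xy = np.empty((n, 2))
    hd = np.empty(n)
    pos = np.array([arena_size / 2, arena_size / 2])
    theta = rng.uniform(0, 2 * np.pi)
    speed = mean_speed
    for i in range(n):
        theta += heading_diffusion * np.sqrt(dt) * rng.normal()
        speed = np.clip(speed + rng.normal(0, 2.0) * np.sqrt(dt) * 4, 3.0, 30.0)
        step = speed * dt * np.array([np.cos(theta), np.sin(theta)])
        nxt = pos + step
        # reflect at the walls
        for k in (0, 1):
            if nxt[k] < 0 or nxt[k] > arena_size:
                nxt[k] = np.clip(2 * np.clip(nxt[k], 0, arena_size) - nxt[k], 0, arena_size)
                if k == 0:
                    theta = np.pi - theta
                else:
                    theta = -theta
        pos = nxt
        xy[i] = pos
        hd[i] = np.degrees(theta) % 360.0
    return ArenaSession(
        sample_times=np.arange(n) * dt,
        xy=xy,
        head_direction=hd,
        arena_size=float(arena_size),
    )


def default_cue_template(track_length: float = 800.0, bin_size: float = 5.0,
                         side: str = "both") -> CueTemplate:
    """Five 25 cm cues spaced non-uniformly along an 8 m track."""
    starts = np.array([120.0, 260.0, 430.0, 550.0, 700.0]) * (track_length / 800.0)
    cues = [(float(s), float(s + 25.0), side) for s in starts]
    return CueTemplate(track_length, bin_size, cues)


def cue_rate_function(
    template: CueTemplate,
    shift_cm: float = 0.0,
    field_width_cm: float = CUE_FIELD_SIGMA_CM,
    peak_hz: float = CUE_PEAK_HZ,
    baseline_hz: float = CUE_BASELINE_HZ,
    per_cue_jitter: float = 0.25,
    rng: np.random.Generator | None = None,
):
    """Cue-locked rate: baseline plus one Gaussian bump (sigma =
    ``field_width_cm``) per cue, centred ``shift_cm`` past each cue centre,
    with a per-cue amplitude factor drawn once.

    Returns (callable lambda(x), amplitude factors).
    """
    if rng is None:
        rng = np.random.default_rng()
    centers = np.array([(s + e) / 2.0 + shift_cm for s, e, *_ in template.cues])
    amps = np.clip(1.0 + per_cue_jitter * rng.standard_normal(len(centers)), 0.2, None)

    def rate(x):
        x = np.atleast_1d(np.asarray(x, float))
        bumps = amps * np.exp(-0.5 * ((x[:, None] - centers) / field_width_cm) ** 2)
        return baseline_hz + peak_hz * bumps.sum(axis=1)

    return rate, amps


def grid_rate_function(
    spacing_cm: float = 40.0,
    orientation_deg: float = 0.0,
    phase: tuple = (0.0, 0.0),
    peak_hz: float = 10.0,
    baseline_hz: float = 0.1,
):
    """Grid-cell rate over the arena: thresholded sum of three plane-wave
    cosines whose wave vectors are 60 degrees apart."""
    kmag = 4 * np.pi / (np.sqrt(3) * spacing_cm)
    angles = np.deg2rad(orientation_deg + np.array([0.0, 60.0, 120.0]))
    kvecs = kmag * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    phase = np.asarray(phase, float)

    def rate(x, y, hd=None):
        r = np.stack([np.atleast_1d(np.asarray(x, float)),
                      np.atleast_1d(np.asarray(y, float))], axis=1) - phase
        g = np.cos(r @ kvecs.T).sum(axis=1)
        return baseline_hz + peak_hz * np.maximum(g, 0.0) / 3.0

    return rate


def border_rate_function(
    wall: str = "west",
    peak_hz: float = 8.0,
    baseline_hz: float = 0.1,
    length_scale_cm: float = 4.0,
    arena_size: float = 50.0,
):
    """Border-cell rate decaying exponentially with distance to one wall."""

    def rate(x, y, hd=None):
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        d = {
            "west": x,
            "east": arena_size - x,
            "south": y,
            "north": arena_size - y,
        }[wall]
        return baseline_hz + peak_hz * np.exp(-d / length_scale_cm)

    return rate


def hd_rate_function(
    pref_deg: float = 0.0,
    kappa: float = 2.0,
    peak_hz: float = 10.0,
    baseline_hz: float = 0.0,
):
    """Head-direction rate: von Mises tuning (peak at the preferred angle)."""
    mu = np.deg2rad(pref_deg)

    def rate(x, y=None, hd=None):
        # accept (x, y, hd) arena state or a bare angle array
        ang = np.deg2rad(np.atleast_1d(np.asarray(hd if hd is not None else x, float)))
        return baseline_hz + peak_hz * np.exp(kappa * (np.cos(ang - mu) - 1.0))

    return rate


def poisson_spikes(
    rate_fn,
    times: np.ndarray,
    state,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning along a trajectory.

    ``state`` is the array (or tuple of arrays) of per-sample covariates
    consumed by ``rate_fn``; the rate between samples is interpolated
    linearly from the per-sample rate.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    times = np.asarray(times, float)
    if len(times) < 2:
        return np.zeros(0)
    if not isinstance(state, tuple):
        state = (state,)
    lam = np.asarray(rate_fn(*state), float)
    lam_max = lam.max()
    if lam_max <= 0:
        return np.zeros(0)
    t0, t1 = times[0], times[-1]
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    lam_at = np.interp(cand, times, lam)
    keep = rng.uniform(0, lam_max, size=n_cand) < lam_at
    return cand[keep]


def spikes_to_dff(
    spike_times: np.ndarray,
    duration_s: float,
    frame_rate: float = 30.0,
    amplitude: float = 1.0,
    rise_s: float = 0.05,
    decay_s: float = 0.4,
    noise_sd: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> DffTrace:
    """Spike train convolved with a difference-of-exponentials calcium
    kernel (peak-normalised) plus white Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * frame_rate))
    frames = np.arange(n) / frame_rate
    counts = np.bincount(
        np.clip((np.asarray(spike_times, float) * frame_rate).astype(int), 0, n - 1),
        minlength=n,
    ).astype(float)
    tk = np.arange(0, 5 * decay_s, 1.0 / frame_rate)
    kernel = np.exp(-tk / decay_s) - np.exp(-tk / rise_s)
    peak = kernel.max()
    if peak > 0:
        kernel = kernel / peak
    clean = np.convolve(counts * amplitude, kernel)[:n]
    dff = clean + rng.normal(0, noise_sd, size=n)
    return DffTrace(frames, dff, frame_rate)


_DEFAULT_FRACTIONS = {"cue": 0.30, "grid": 0.20, "border": 0.10, "hd": 0.20, "untuned": 0.20}


def simulate_mixed_population(
    n_cells: int = 60,
    fractions: dict | None = None,
    template: CueTemplate | None = None,
    track_n_runs: int = 40,
    arena_duration_s: float = 1800.0,
    untuned_rate_hz: float = 2.0,
    max_cue_shift_cm: float = 20.0,
    seed: int | None = None,
):
    """A mixed population recorded on the track and in the arena.

    Class fractions default to 30% cue (shifts uniform in +/-20 cm), 20%
    grid, 10% border, 20% head-direction and 20% untuned. Cue cells are
    untuned in the arena; grid cells see a fixed-y slice of their grid on
    the track; border and head-direction cells are untuned on the track.

    Returns (track_session, arena_session, ground_truth DataFrame).
    """
    rng = np.random.default_rng(seed)
    fractions = dict(_DEFAULT_FRACTIONS if fractions is None else fractions)
    if template is None:
        template = default_cue_template()
    counts = {c: int(round(f * n_cells)) for c, f in fractions.items()}
    while sum(counts.values()) < n_cells:
        counts["untuned"] += 1
    while sum(counts.values()) > n_cells:
        counts["untuned"] -= 1
    track = simulate_track_trajectory(
        track_length=template.track_length, n_runs=track_n_runs, rng=rng
    )
    arena = simulate_arena_trajectory(duration_s=arena_duration_s, rng=rng)
    tx = np.asarray(track.positions)
    ax, ay = arena.xy[:, 0], arena.xy[:, 1]
    ahd = arena.head_direction
    truth = []
    cid = 0
    for cls, k in counts.items():
        for _ in range(k):
            gt = GroundTruth(cell_id=cid, cell_class=cls)
            if cls == "cue":
                gt.cue_shift_cm = rng.uniform(-max_cue_shift_cm, max_cue_shift_cm)
                gt.field_width_cm = CUE_FIELD_SIGMA_CM
                gt.peak_hz, gt.baseline_hz = CUE_PEAK_HZ, CUE_BASELINE_HZ
                fn, amps = cue_rate_function(template, gt.cue_shift_cm, rng=rng)
                gt.cue_amplitudes = amps
                track_rate = fn
                arena_rate = lambda x, y, hd: np.full(np.shape(np.atleast_1d(x)), 2.0)
            elif cls == "grid":
                # spacings a 0.5 m arena can express: larger periods leave
                # no complete hexagonal ring in the autocorrelogram
                gt.grid_spacing_cm = rng.uniform(30.0, 50.0)
                gt.grid_orientation_deg = rng.uniform(0.0, 60.0)
                gt.grid_phase = tuple(rng.uniform(0.0, gt.grid_spacing_cm, 2))
                gt.peak_hz, gt.baseline_hz = 10.0, 0.1
                g = grid_rate_function(gt.grid_spacing_cm, gt.grid_orientation_deg,
                                       gt.grid_phase, gt.peak_hz, gt.baseline_hz)
                y0 = rng.uniform(0, 50.0)
                track_rate = lambda x, _g=g, _y=y0: _g(np.asarray(x) % 50.0, np.full(np.shape(np.atleast_1d(x)), _y))
                arena_rate = g
            elif cls == "border":
                wall = rng.choice(["west", "east", "south", "north"])
                gt.peak_hz, gt.baseline_hz = 8.0, 0.1
                arena_rate = border_rate_function(wall, gt.peak_hz, gt.baseline_hz)
                track_rate = lambda x: np.full(np.shape(np.atleast_1d(x)), 1.0)
            elif cls == "hd":
                gt.hd_pref_deg = rng.uniform(0.0, 360.0)
                gt.hd_kappa = rng.uniform(2.0, 4.0)
                gt.peak_hz = 10.0
                arena_rate = hd_rate_function(gt.hd_pref_deg, gt.hd_kappa, gt.peak_hz)
                track_rate = lambda x: np.full(np.shape(np.atleast_1d(x)), 1.0)
            else:
                r0 = untuned_rate_hz * rng.uniform(0.5, 1.5)
                track_rate = lambda x, _r=r0: np.full(np.shape(np.atleast_1d(x)), _r)
                arena_rate = lambda x, y, hd, _r=r0: np.full(np.shape(np.atleast_1d(x)), _r)
            track.spike_times_per_unit[cid] = poisson_spikes(
                track_rate, track.sample_times, tx, rng=rng
            )
            arena.spike_times_per_unit[cid] = poisson_spikes(
                arena_rate, arena.sample_times, (ax, ay, ahd), rng=rng
            )
            truth.append(gt)
            cid += 1
    gt_df = pd.DataFrame(
        {
            "cell_id": [g.cell_id for g in truth],
            "cell_class": [g.cell_class for g in truth],
            "cue_shift_cm": [g.cue_shift_cm for g in truth],
            "grid_spacing_cm": [g.grid_spacing_cm for g in truth],
            "hd_pref_deg": [g.hd_pref_deg for g in truth],
            "hd_kappa": [g.hd_kappa for g in truth],
        }
    )
    return track, arena, gt_df
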