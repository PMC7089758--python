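import numpy as np
import pytest

from cuemap import ratemaps as rm
from cuemap import synthetic_data as sd


@pytest.fixture
def template():
    return sd.default_cue_template()


@pytest.fixture(scope="session")
def track_with_cells():
    """20-run track session with a cue cell (shift +10 cm), a strongly
    tuned single-field cell, and an untuned cell."""
    rng = np.random.default_rng(11)
    tmpl = sd.default_cue_template()
    sess = sd.simulate_track_trajectory(n_runs=20, rng=rng)
    x = np.asarray(sess.positions)
    cue_fn, _ = sd.cue_rate_function(tmpl, shift_cm=10.0, rng=rng)
    sess.spike_times_per_unit["cue"] = sd.poisson_spikes(cue_fn, sess.sample_times, x, rng=rng)

    def single_field(pos):
        pos = np.atleast_1d(np.asarray(pos, float))
        return 0.5 + 10.0 * np.exp(-0.5 * ((pos - 400.0) / 10.0) ** 2)

    sess.spike_times_per_unit["field"] = sd.poisson_spikes(single_field, sess.sample_times, x, rng=rng)
    sess.spike_times_per_unit["null"] = sd.poisson_spikes(
        lambda p: np.full(np.shape(np.atleast_1d(p)), 2.0), sess.sample_times, x, rng=rng
    )
    return sess, tmpl


@pytest.fixture(scope="session")
def arena_with_cells():
    """15-minute arena session with grid, border, HD and untuned units."""
    rng = np.random.default_rng(23)
    arena = sd.simulate_arena_trajectory(duration_s=900.0, rng=rng)
    state = (arena.xy[:, 0], arena.xy[:, 1], arena.head_direction)
    arena.spike_times_per_unit["grid"] = sd.poisson_spikes(
        sd.grid_rate_function(40.0, 10.0, (5.0, 12.0)), arena.sample_times, state, rng=rng
    )
    arena.spike_times_per_unit["border"] = sd.poisson_spikes(
        sd.border_rate_function("west"), arena.sample_times, state, rng=rng
    )
    arena.spike_times_per_unit["hd"] = sd.poisson_spikes(
        sd.hd_rate_function(135.0, 3.0), arena.sample_times, state, rng=rng
    )
    arena.spike_times_per_unit["null"] = sd.poisson_spikes(
        lambda x, y, hd: np.full(np.shape(np.atleast_1d(x)), 2.0),
        arena.sample_times, state, rng=rng,
    )
    return arena


@pytest.fixture
def track_rate(track_with_cells):
    sess, tmpl = track_with_cells
    return {
        unit: rm.track_ratemap(sess, unit).rate_hz
        for unit in sess.spike_times_per_unit
    }
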