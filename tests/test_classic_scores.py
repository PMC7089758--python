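import numpy as np
import pytest
from scipy.ndimage import rotate as nd_rotate
from scipy.special import i0, i1

from cuemap import classic_scores as ccs
from cuemap import ratemaps as rm
from cuemap import synthetic_data as sd

from oracles import autocorr_oracle, grid_score_oracle


def _hex_map(n=20, bin_cm=2.5, spacing=30.0, orientation=10.0):
    fn = sd.grid_rate_function(spacing, orientation, (3.0, 7.0))
    xs = (np.arange(n) + 0.5) * bin_cm
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    return fn(xx.ravel(), yy.ravel()).reshape(n, n)


class TestAutocorr2d:
    def test_center_value_is_one(self):
        m = _hex_map()
        ac = ccs.autocorr2d(m, np.ones_like(m, bool))
        c = (ac.shape[0] - 1) // 2
        assert ac[c, c] == pytest.approx(1.0)

    def test_point_reflection_symmetry(self):
        m = _hex_map()
        ac = ccs.autocorr2d(m, np.ones_like(m, bool))
        flipped = ac[::-1, ::-1]
        ok = np.isfinite(ac) & np.isfinite(flipped)
        assert ac[ok] == pytest.approx(flipped[ok], abs=1e-10)

    def test_matches_loop_oracle_with_masked_bins(self):
        rng = np.random.default_rng(0)
        m = rng.random((12, 12))
        valid = rng.random((12, 12)) > 0.15
        ac = ccs.autocorr2d(m, valid, min_overlap=10)
        expected = autocorr_oracle(m, valid, min_overlap=10)
        ok = np.isfinite(expected)
        assert (np.isfinite(ac) == ok).all()
        assert ac[ok] == pytest.approx(expected[ok], abs=1e-10)


class TestGridScore:
    def test_hexagonal_map_scores_high_and_matches_oracle(self):
        m = _hex_map()
        ac = ccs.autocorr2d(m, np.ones_like(m, bool))
        got = ccs.grid_score(None, ac=ac)
        assert got > 0.5
        assert got == pytest.approx(grid_score_oracle(ac), abs=1e-10)

    def test_parallel_stripes_score_far_below_hexagonal(self):
        # per annulus the 60/120-degree rotations of a stripe pattern
        # anti-correlate; the max over annuli keeps stripes well below a
        # hexagonal pattern and below typical classification thresholds
        n, bin_cm = 20, 2.5
        xs = (np.arange(n) + 0.5) * bin_cm
        xx, _ = np.meshgrid(xs, xs, indexing="ij")
        stripes = 1.0 + np.cos(2 * np.pi * xx / 20.0)
        ac = ccs.autocorr2d(stripes, np.ones((n, n), bool))
        stripe_score = ccs.grid_score(None, ac=ac)
        hex_ac = ccs.autocorr2d(_hex_map(), np.ones((n, n), bool))
        assert stripe_score < 0.5
        assert stripe_score < ccs.grid_score(None, ac=hex_ac) - 0.3

    def test_radially_symmetric_map_near_zero(self):
        n = 20
        ii, jj = np.indices((n, n))
        d = np.hypot(ii - (n - 1) / 2, jj - (n - 1) / 2)
        m = np.exp(-0.5 * (d / 3.0) ** 2) + 0.2 * np.exp(-0.5 * ((d - 7) / 1.5) ** 2)
        ac = ccs.autocorr2d(m, np.ones((n, n), bool))
        assert abs(ccs.grid_score(None, ac=ac)) < 0.2

    def test_invariant_under_60_degree_rotation(self):
        m = _hex_map()
        ac = ccs.autocorr2d(m, np.ones_like(m, bool))
        m60 = nd_rotate(m, 60.0, reshape=False, order=1, mode="nearest")
        ac60 = ccs.autocorr2d(m60, np.ones_like(m, bool))
        assert ccs.grid_score(None, ac=ac60) == pytest.approx(
            ccs.grid_score(None, ac=ac), abs=0.15
        )


class TestHdScore:
    def test_single_bin_tuning_R_one(self):
        rate = np.zeros(120)
        rate[40] = 5.0
        R, ang = ccs.hd_score(rate)
        assert R == pytest.approx(1.0)
        assert ang == pytest.approx((40 + 0.5) * 3.0)

    def test_uniform_tuning_R_zero(self):
        R, _ = ccs.hd_score(np.full(120, 2.0))
        assert R == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_closed_form(self):
        kappa = 2.0
        centers = np.deg2rad((np.arange(120) + 0.5) * 3.0)
        rate = np.exp(kappa * np.cos(centers - np.pi / 3))
        R, ang = ccs.hd_score(rate)
        assert R == pytest.approx(i1(kappa) / i0(kappa), abs=1e-3)
        assert ang == pytest.approx(60.0, abs=1.6)

    def test_all_zero_undefined(self):
        R, ang = ccs.hd_score(np.zeros(120))
        assert np.isnan(R) and np.isnan(ang)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        rate = rng.random(120)
        R1, a1 = ccs.hd_score(rate)
        R2, a2 = ccs.hd_score(np.roll(rate, 10))
        assert R2 == pytest.approx(R1)
        assert (a2 - a1) % 360 == pytest.approx(30.0, abs=1e-9)


class TestBorderScore:
    def test_thin_wall_field_approaches_one_as_dM_vanishes(self):
        # one-bin-thick field on the whole wall: cM = 1, dM = 0 -> score 1
        # (area floor relaxed so the 125 cm^2 sliver qualifies)
        m = np.zeros((20, 20))
        m[0, :] = 5.0
        ones = np.ones((20, 20), bool)
        assert ccs.border_score(m, ones, min_field_area_cm2=100.0) == pytest.approx(1.0)
        # at the default 200 cm^2 floor a two-bin-thick wall field comes close
        m2 = np.zeros((20, 20))
        m2[:2, :] = 5.0
        assert ccs.border_score(m2, ones) > 0.85

    def test_compact_central_field_negative(self):
        ii, jj = np.indices((20, 20))
        m = 5.0 * (np.hypot(ii - 9.5, jj - 9.5) < 4)
        assert ccs.border_score(m, np.ones((20, 20), bool)) < 0

    def test_no_qualifying_field_undefined(self):
        m = np.zeros((20, 20))
        m[3, 3] = 1.0  # single bin: 6.25 cm^2 < 200 cm^2
        assert np.isnan(ccs.border_score(m, np.ones((20, 20), bool)))

    def test_synthetic_border_cell_beats_grid_cell(self, arena_with_cells):
        arena = arena_with_cells
        mb = rm.arena_ratemap(arena, "border")
        mg = rm.arena_ratemap(arena, "grid")
        assert ccs.border_score(mb) > 0.5
        assert ccs.border_score(mb) > ccs.border_score(mg)


class TestStability:
    def test_identical_deterministic_halves_score_one(self):
        rng = np.random.default_rng(2)
        half = sd.simulate_arena_trajectory(duration_s=300.0, seed=5)
        t, xy, hd = half.sample_times, half.xy, half.head_direction
        from cuemap.io_model import ArenaSession
        sess = ArenaSession(
            np.r_[t, t + t[-1] + 0.02], np.r_[xy, xy], np.r_[hd, hd], 50.0, {}
        )
        spikes = np.sort(rng.uniform(1, t[-1] - 1, 400))
        sess.spike_times_per_unit["u"] = np.sort(np.r_[spikes, spikes + t[-1] + 0.02])
        assert ccs.split_half_stability(sess, "u") == pytest.approx(1.0, abs=1e-9)

    def test_grid_cell_more_stable_than_poisson_null(self, arena_with_cells):
        arena = arena_with_cells
        s_grid = ccs.split_half_stability(arena, "grid")
        s_null = ccs.split_half_stability(arena, "null")
        assert s_grid > 0.5
        assert s_grid > s_null


class TestScoreShuffleThreshold:
    def test_permutation_preserves_spike_count_and_span(self, arena_with_cells):
        arena = arena_with_cells
        counts = []

        def count_fn(sess, unit):
            st = sess.spike_times_per_unit[unit]
            counts.append(len(st))
            assert st.min() >= sess.sample_times[0] - 1e-9
            assert st.max() <= sess.sample_times[-1] + 1e-9
            return 0.5

        ccs.score_shuffle_threshold([arena], ["grid"], count_fn, n_shuffles=5, seed=0)
        assert counts == [len(arena.spike_times_per_unit["grid"])] * 5

    def test_reproducible_under_fixed_seed(self, arena_with_cells):
        arena = arena_with_cells

        def fn(sess, unit):
            return ccs.hd_score(rm.hd_tuning(sess, unit))[0]

        d1 = ccs.score_shuffle_threshold([arena], ["hd"], fn, n_shuffles=10, seed=3)
        d2 = ccs.score_shuffle_threshold([arena], ["hd"], fn, n_shuffles=10, seed=3)
        assert d1.threshold == d2.threshold
        assert (d1.values == d2.values).all()

    def test_tuned_cells_exceed_threshold_nulls_do_not(self, arena_with_cells):
        arena = arena_with_cells

        def fn(sess, unit):
            return ccs.hd_score(rm.hd_tuning(sess, unit))[0]

        dist = ccs.score_shuffle_threshold(
            [arena, arena], ["hd", "null"], fn, n_shuffles=30, seed=4
        )
        assert fn(arena, "hd") > dist.threshold
        assert fn(arena, "null") < dist.threshold


class TestDeduplication:
    def _record(self, rng, n_spikes=500, rate=None):
        m = rng.random((20, 20)) if rate is None else rate
        return {
            "arena_map": m,
            "track_map": rng.random(160) if rate is None else np.tile(np.nanmean(m), 160),
            "spike_times": np.sort(rng.uniform(0, 600, n_spikes)),
            "arena_peak": float(np.nanmax(m)),
        }

    def test_identical_cluster_removed_larger_kept(self):
        rng = np.random.default_rng(6)
        a = self._record(rng, n_spikes=500)
        b = dict(a, spike_times=a["spike_times"][:400])
        kept = ccs.deduplicate_units({"a": a, "b": b}, [("a", "b")], mode="within_day")
        assert kept == ["a"]

    def test_independent_cells_both_kept(self):
        rng = np.random.default_rng(7)
        a, b = self._record(rng), self._record(rng)
        kept = ccs.deduplicate_units({"a": a, "b": b}, [("a", "b")], mode="within_day")
        assert kept == ["a", "b"]

    def test_cross_day_arena_correlation_rule(self):
        rng = np.random.default_rng(8)
        base = rng.random((20, 20))
        a = self._record(rng, rate=base)
        b = self._record(rng, rate=base + rng.normal(0, 0.1, (20, 20)))
        assert np.corrcoef(a["arena_map"].ravel(), b["arena_map"].ravel())[0, 1] >= 0.8
        kept = ccs.deduplicate_units({"a": a, "b": b}, [("a", "b")], mode="cross_day")
        assert len(kept) == 1

    @pytest.mark.parametrize(
        "n_spikes,rates,expected",
        [
            (50, [1.0], False),       # too few spikes
            (500, [20.0], False),     # rate minimum above 10 Hz
            (500, [0.0, 60.0], False),  # rate maximum above 50 Hz
            (500, [0.0, 5.0], True),
        ],
    )
    def test_inclusion_gates(self, n_spikes, rates, expected):
        assert ccs.passes_inclusion_gates(n_spikes, np.array(rates)) is expected
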