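import numpy as np
import pytest

from cuemap import cue_scoring as cs
from cuemap import synthetic_data as sd
from cuemap.io_model import CueTemplate

from oracles import cue_score_oracle


class TestCueShiftAndScore:
    def test_rate_equal_to_template_scores_one(self, template):
        res = cs.cue_shift_and_score(template.values.astype(float), template)
        assert res.shift_cm == 0.0
        assert res.score == pytest.approx(1.0)
        assert np.nanmin(res.per_cue_r) == pytest.approx(1.0)

    def test_displaced_rate_recovers_positive_shift(self, template):
        # rate = template displaced 2 bins toward larger positions
        rate = np.roll(template.values.astype(float), 2)
        res = cs.cue_shift_and_score(rate, template)
        assert res.shift_cm == 10.0
        assert res.score == pytest.approx(1.0)

    def test_negative_shift_sign_convention(self, template):
        rate = np.roll(template.values.astype(float), -3)
        res = cs.cue_shift_and_score(rate, template)
        assert res.shift_cm == -15.0

    def test_constant_rate_undefined(self, template):
        res = cs.cue_shift_and_score(np.full(template.n_bins, 2.0), template)
        assert np.isnan(res.score)
        assert not res.aligned

    def test_affine_invariance(self, template):
        rng = np.random.default_rng(0)
        rate = rng.random(template.n_bins) + template.values
        r1 = cs.cue_shift_and_score(rate, template)
        r2 = cs.cue_shift_and_score(3.7 * rate + 11.0, template)
        assert r2.shift_cm == r1.shift_cm
        assert r2.score == pytest.approx(r1.score, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_rates(self):
        rng = np.random.default_rng(42)
        tmpl = CueTemplate(250.0, 5.0, [(30.0, 55.0, "both"), (140.0, 165.0, "both")])
        for _ in range(25):
            rate = rng.gamma(2.0, 1.0, tmpl.n_bins)
            res = cs.cue_shift_and_score(rate, tmpl)
            o_score, o_shift = cue_score_oracle(rate, tmpl)
            assert res.shift_cm == o_shift
            assert res.score == pytest.approx(o_score, abs=1e-10, nan_ok=True)


class TestShuffledTemplate:
    def test_infeasible_when_cues_fill_track(self):
        tmpl = CueTemplate(100.0, 5.0, [(0.0, 100.0, "both")])
        with pytest.raises(ValueError):
            cs.shuffled_template(tmpl, np.random.default_rng(0))

    def test_single_cue_start_uniform_and_on_track(self):
        tmpl = CueTemplate(800.0, 5.0, [(100.0, 125.0, "both")])
        rng = np.random.default_rng(1)
        starts = [cs.shuffled_template(tmpl, rng).cues[0][0] for _ in range(500)]
        starts = np.asarray(starts)
        assert starts.min() >= 0 and starts.max() <= 775.0
        # uniform on [0, 775]: mean ~ 387.5, and both halves populated
        assert abs(starts.mean() - 387.5) < 40
        assert (starts < 387.5).mean() == pytest.approx(0.5, abs=0.1)

    def test_counts_widths_preserved_and_no_overlap(self, template):
        rng = np.random.default_rng(2)
        widths = sorted(template.cue_widths())
        for _ in range(200):
            st = cs.shuffled_template(template, rng)
            assert sorted(st.cue_widths()) == pytest.approx(widths)
            ordered = sorted((c[0], c[1]) for c in st.cues)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                assert e1 <= s2 + 1e-9
            assert ordered[0][0] >= 0 and ordered[-1][1] <= template.track_length


class TestThresholdAndClassification:
    def test_threshold_is_pooled_order_statistic(self, template):
        rng = np.random.default_rng(3)
        rates = {i: rng.random(template.n_bins) for i in range(4)}
        dist = cs.cue_threshold(rates, template, n_shuffles_per_cell=20, seed=0)
        assert dist.values.min() <= dist.threshold <= dist.values.max()
        assert dist.threshold == pytest.approx(np.percentile(dist.values, 95))

    def test_constant_shuffled_scores_give_that_threshold(self, monkeypatch, template):
        rng = np.random.default_rng(4)
        rates = {0: rng.random(template.n_bins)}
        monkeypatch.setattr(
            cs, "cue_shift_and_score",
            lambda rate, tmpl, *a, **k: cs.CueScoreResult(0.42, 0.0, np.array([0.42]), True),
        )
        dist = cs.cue_threshold(rates, template, n_shuffles_per_cell=10, seed=0)
        assert dist.threshold == pytest.approx(0.42)

    @pytest.mark.parametrize("score,flag", [(0.6, True), (0.4, False), (0.5, False)])
    def test_strictly_above_threshold_required(self, monkeypatch, template, score, flag):
        monkeypatch.setattr(
            cs, "cue_shift_and_score",
            lambda rate, tmpl, *a, **k: cs.CueScoreResult(score, 0.0, np.array([score]), True),
        )
        _, flags = cs.classify_cue_cells({0: np.zeros(template.n_bins)}, template, 0.5)
        assert flags[0] is flag


class TestSideClassification:
    def _templates(self):
        left = CueTemplate(800.0, 5.0, [(100.0, 125.0, "left"), (400.0, 425.0, "left")])
        right = CueTemplate(800.0, 5.0, [(250.0, 275.0, "right"), (600.0, 625.0, "right")])
        return left, right

    def test_unique_passer_gets_its_side(self):
        left, right = self._templates()
        rate = left.values.astype(float) + 0.01
        out = cs.side_classify({0: rate}, left, right, {"left": 0.5, "right": 0.5})
        assert out[0]["side"] == "left"

    def test_double_passer_goes_to_higher_score(self):
        left, right = self._templates()
        # left response smeared (imperfect match), right response exact
        smeared_left = np.convolve(left.values.astype(float), [0.4, 1.0, 0.4], mode="same")
        rate = smeared_left + 2.0 * right.values
        out = cs.side_classify({0: rate.astype(float)}, left, right,
                               {"left": -1.0, "right": -1.0})
        assert out[0]["left"].score is not None
        assert out[0]["side"] == "right"
        assert out[0]["right"].score > out[0]["left"].score

    def test_passes_neither_is_non_cue(self):
        left, right = self._templates()
        rng = np.random.default_rng(5)
        out = cs.side_classify({0: rng.random(160)}, left, right,
                               {"left": 2.0, "right": 2.0})
        assert out[0]["side"] is None


class TestBilateralScore:
    def _templates(self):
        left = CueTemplate(800.0, 5.0, [(100.0, 125.0, "left"), (400.0, 425.0, "left")])
        right = CueTemplate(800.0, 5.0, [(250.0, 275.0, "right"), (600.0, 625.0, "right")])
        return left, right

    def test_identical_templates_symmetric_rate_zero(self):
        tmpl = CueTemplate(800.0, 5.0, [(100.0, 125.0, "both"), (400.0, 425.0, "both")])
        rate = tmpl.values.astype(float) + 0.1
        assert cs.bilateral_score(rate, tmpl, tmpl, "left") == pytest.approx(0.0, abs=1e-12)

    def test_pure_left_responder_positive_matches_direct_recomputation(self):
        left, right = self._templates()
        rng = np.random.default_rng(6)
        rate = left.values + 0.02 * rng.random(160)
        got = cs.bilateral_score(rate, left, right, "left")
        res = cs.cue_shift_and_score(rate, left)
        other, _ = cs.local_score_at_shift(rate, right, res.shift_cm)
        assert got == pytest.approx(res.score - other, abs=1e-12)
        assert got > 0.5

    def test_pure_right_responder_negative(self):
        left, right = self._templates()
        rng = np.random.default_rng(7)
        rate = right.values + 0.02 * rng.random(160)
        assert cs.bilateral_score(rate, left, right, "right") < -0.5


class TestShiftRecovery:
    def test_imposed_shifts_recovered_within_one_bin(self):
        rng = np.random.default_rng(8)
        tmpl = sd.default_cue_template()
        sess = sd.simulate_track_trajectory(n_runs=25, rng=rng)
        from cuemap.ratemaps import track_ratemap, velocity_filter
        mask = velocity_filter(sess)
        shifts = np.arange(-20, 21, 5.0)
        ok = 0
        for i, s in enumerate(shifts):
            fn, _ = sd.cue_rate_function(tmpl, shift_cm=s, peak_hz=10.0, baseline_hz=0.5, rng=rng)
            sess.spike_times_per_unit[i] = sd.poisson_spikes(
                fn, sess.sample_times, np.asarray(sess.positions), rng=rng
            )
            rate = track_ratemap(sess, i, velocity_mask=mask).rate_hz
            res = cs.cue_shift_and_score(rate, tmpl)
            if abs(res.shift_cm - s) <= 5.0:
                ok += 1
        assert ok >= 0.9 * len(shifts)


def test_random_template_control_distinguishes_cue_population(template):
    rng = np.random.default_rng(9)
    rates = {}
    for i in range(6):
        bump = np.convolve(template.values.astype(float), np.ones(3) / 3, mode="same")
        rates[i] = 5.0 * bump + 0.05 * rng.random(template.n_bins)
    real, randoms = cs.random_template_percentage_control(
        rates, template, n_random=5, seed=0, n_shuffles_per_cell=20
    )
    assert real > max(randoms)


def test_random_template_control_zero_randoms(template):
    rng = np.random.default_rng(10)
    rates = {0: rng.random(template.n_bins)}
    real, randoms = cs.random_template_percentage_control(
        rates, template, n_random=0, seed=0, n_shuffles_per_cell=10
    )
    assert len(randoms) == 0
    assert 0.0 <= real <= 100.0
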