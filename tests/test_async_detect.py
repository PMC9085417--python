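"""Sliding-window detection, event rule, outcome taxonomy, IDR."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ernbci import async_detect as ad
from ernbci import synth_eeg as se
from ernbci.io_core import ValidationError


def _block(rng=None, n_ch=4, with_template=True, fs=250.0):
    """2700 ms synthetic block with the response at onset (sample 500)."""
    rng = rng or np.random.default_rng(0)
    data = rng.normal(0, 1.0, (n_ch, 675))
    if with_template:
        tpl = se.render_template(se.TemplateSpec(), "ERN", fs,
                                 window_ms=(0, 500))
        data[:, 500:625] += tpl
    return ad.EvaluationBlock(data, fs, onset_index=500)


class TestWindows:
    def test_111_windows_with_expected_stamps(self):
        windows, stamps = ad.slide_windows(_block())
        assert windows.shape == (111, 4, 125)
        assert stamps[0] == -1500.0
        assert stamps[-1] == 700.0
        np.testing.assert_allclose(np.diff(stamps), 20.0)

    def test_block_equal_to_window_gives_one_window(self):
        blk = ad.EvaluationBlock(np.zeros((2, 125)), 250.0, onset_index=0)
        windows, stamps = ad.slide_windows(blk)
        assert len(windows) == 1

    def test_step_equal_to_window_tiles(self):
        cfg = ad.DetectorConfig(window_ms=500.0, step_ms=500.0)
        windows, _ = ad.slide_windows(_block(), cfg)
        assert len(windows) == 675 // 125

    def test_short_block_rejected(self):
        blk = ad.EvaluationBlock(np.zeros((2, 50)), 250.0, onset_index=0)
        with pytest.raises(ValidationError):
            ad.slide_windows(blk)


class TestEventRule:
    def test_n1_single_prediction_fires(self):
        ev = ad.detect_events([False, False, True], [0., 20., 40.], n=1)
        np.testing.assert_allclose(ev, [40.0])

    def test_one_event_per_run_variant(self):
        labels = [False, True, True, True, False]
        stamps = [0., 20., 40., 60., 80.]
        ev = ad.detect_events(labels, stamps, n=2, retrigger=False)
        np.testing.assert_allclose(ev, [40.0])   # second window of the run

    def test_retrigger_emits_every_qualifying_window(self):
        labels = [False, True, True, True, False]
        stamps = [0., 20., 40., 60., 80.]
        ev = ad.detect_events(labels, stamps, n=2, retrigger=True)
        np.testing.assert_allclose(ev, [40.0, 60.0])

    def test_runs_shorter_than_n_emit_nothing(self):
        labels = [True, True, False, True, True]
        ev = ad.detect_events(labels, np.arange(5.0), n=3)
        assert len(ev) == 0

    def test_brute_force_run_enumerator_agreement(self, rng):
        """detect_events matches an independent run enumeration."""
        for _ in range(50):
            labels = rng.random(40) < 0.4
            stamps = np.arange(40.0)
            for n in (1, 2, 3):
                got = set(ad.detect_events(labels, stamps, n))
                # brute force: scan all maximal runs explicitly
                expected = set()
                i = 0
                while i < 40:
                    if labels[i]:
                        j = i
                        while j < 40 and labels[j]:
                            j += 1
                        if j - i >= n:
                            expected.update(stamps[i + n - 1:j])
                        i = j
                    else:
                        i += 1
                assert got == expected


class TestOutcomeTaxonomy:
    def test_single_event_inside_tolerance_is_correct(self):
        assert ad.classify_trial_outcome([100.0]) == "correct"

    def test_pre_onset_event_makes_incorrect(self):
        assert ad.classify_trial_outcome([-500.0, 100.0]) == "incorrect"

    def test_no_events_is_none(self):
        assert ad.classify_trial_outcome([]) == "none"

    def test_late_only_events_are_incorrect(self):
        assert ad.classify_trial_outcome([450.0]) == "incorrect"

    def test_decision_stamp_compensation(self):
        # decision at 550 ms for a 500 ms window = response onset at 50 ms
        assert ad.classify_trial_outcome([550.0], window_ms=500.0) == "correct"
        # decision before the onset is premature regardless of compensation
        assert ad.classify_trial_outcome([-20.0, 550.0],
                                         window_ms=500.0) == "incorrect"


class TestIdrMetric:
    def test_reference_rates_evaluate_to_4723(self):
        assert round(100 * ad.idr(0.3246, 0.0381, 0.6373), 2) == 47.23

    def test_boundary_identities(self):
        assert ad.idr(1.0, 0.0, 0.0) == 1.0
        assert ad.idr(0.0, 0.5, 0.5) == 0.0

    def test_natural_log_pins_the_convention(self):
        # base-10 logarithm would give ~0.382; only the natural log matches
        base10 = 0.3246 * (1 - 0.0381 + np.log10(1 + 0.6373))
        assert abs(base10 - 0.4723) > 0.05
        assert abs(ad.idr(0.3246, 0.0381, 0.6373) - 0.4723) < 5e-5

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_bounded_on_the_simplex(self, a, b):
        cd = a
        id_rate = (1 - a) * b
        nd = 1 - cd - id_rate
        if nd < 0:
            return
        val = ad.idr(cd, id_rate, max(nd, 0.0))
        assert -1e-12 <= val <= 1.0 + 1e-12

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValidationError):
            ad.idr(0.5, 0.5, 0.5)
        with pytest.raises(ValidationError):
            ad.idr(-0.1, 0.55, 0.55)


class _StubDetector:
    """Deterministic window-labeller for evaluation-logic tests."""

    def __init__(self, fire_at=(500.0,)):
        self.fire_at = set(fire_at)

    def predict_windows(self, block):
        _, stamps = ad.slide_windows(block)
        return np.isin(stamps, list(self.fire_at)), stamps


class TestLooBootstrap:
    def _blocks(self, k=12):
        rng = np.random.default_rng(3)
        return [_block(rng) for _ in range(k)]

    def test_perfect_detector_reaches_idr_1(self):
        blocks = self._blocks()
        reports = ad.loo_bootstrap_evaluate(
            blocks, n_boot=3, seed=0,
            detector_factory=lambda tb, cfg, rng: _StubDetector({500.0}))
        r = reports[1]
        assert r.cd == 1.0 and r.idr_value == 1.0
        assert r.ci99["CD"] == (1.0, 1.0)

    def test_never_firing_detector_scores_zero(self):
        blocks = self._blocks()
        reports = ad.loo_bootstrap_evaluate(
            blocks, n_boot=3, seed=0,
            detector_factory=lambda tb, cfg, rng: _StubDetector(set()))
        r = reports[1]
        assert r.nd == 1.0 and r.idr_value == 0.0

    def test_rates_always_sum_to_one(self):
        blocks = self._blocks()
        reports = ad.loo_bootstrap_evaluate(
            blocks, n_boot=2, seed=1,
            detector_factory=lambda tb, cfg, rng: _StubDetector({-800.0, 500.0}))
        for r in reports.values():
            assert r.cd + r.id_rate + r.nd == pytest.approx(1.0, abs=1e-12)

    def test_sensitivity_monotonicity_on_fixed_predictions(self):
        """For a fixed label stream, ND never decreases with n."""
        rng = np.random.default_rng(5)
        stamps = np.arange(-1500.0, 701.0, 20.0)
        nd_counts = {n: 0 for n in (1, 2, 3)}
        id_counts = {n: 0 for n in (1, 2, 3)}
        for _ in range(300):
            labels = rng.random(stamps.size) < 0.08
            for n in (1, 2, 3):
                events = ad.detect_events(labels, stamps, n)
                out = ad.classify_trial_outcome(events, window_ms=500.0)
                nd_counts[n] += out == "none"
                id_counts[n] += out == "incorrect"
        assert nd_counts[1] <= nd_counts[2] <= nd_counts[3]
        assert id_counts[1] >= id_counts[2] >= id_counts[3]

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValidationError):
            ad.loo_bootstrap_evaluate(self._blocks(5), n_boot=2)


class TestTrainingWindows:
    def test_background_sampled_from_pre_onset_region_only(self):
        blocks = [_block(np.random.default_rng(i)) for i in range(3)]
        cfg = ad.DetectorConfig()
        x, y = ad._training_windows(blocks, cfg, np.random.default_rng(0))
        assert list(y).count("ERN") == 3
        assert list(y).count("background") == 12
        # background windows must end at or before -500 ms:
        # starts were drawn from [0, onset - window - 500ms] of each block
        lo, hi = cfg.background_region_ms
        assert hi == -500.0

    def test_real_classifier_separates_noiseless_blocks(self):
        rng = np.random.default_rng(11)
        blocks = [_block(rng, n_ch=8) for _ in range(8)]
        det = ad.fit_async_classifier(blocks, rng=0)
        x, y = ad._training_windows(blocks, det.config,
                                    np.random.default_rng(0))
        pred = det.model.predict(det.chain.transform(x))
        assert np.mean(pred == y) == 1.0
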