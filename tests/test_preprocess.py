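"""Filtering, channel/epoch rejection, downsampling, epoching."""

import numpy as np
import pytest

from ernbci import io_core as io
from ernbci import preprocess as pp
from ernbci import synth_eeg as se


def _recording(data_1d, fs=500.0, n_ch=1):
    data = np.tile(np.asarray(data_1d, float)[:, None], (1, n_ch))
    return io.Recording(data, fs, io.CHANNELS_32[:n_ch])


def _sine(freq, seconds=60.0, fs=500.0, amp=10.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_zero_phase_impulse(self):
        x = np.zeros(40000)
        k = 20000
        x[k] = 1.0
        out = pp.bandpass_zero_phase(_recording(x)).data[:, 0]
        assert out.argmax() == k

    def test_passband_amplitude_preserved(self):
        rec = _recording(_sine(25.0))
        out = pp.bandpass_zero_phase(rec).data[20000:25000, 0]
        ref = rec.data[20000:25000, 0]
        assert np.isclose(out.std(), ref.std(), rtol=0.05)

    def test_slow_drift_removed(self):
        drift = np.linspace(0.0, 100.0, 30000)       # sub-0.01 Hz ramp
        out = pp.bandpass_zero_phase(_recording(drift)).data[:, 0]
        assert np.sqrt((out ** 2).mean()) <= np.sqrt((drift ** 2).mean()) / 10

    def test_band_outside_nyquist(self):
        with pytest.raises(io.ValidationError):
            pp.bandpass_zero_phase(_recording(np.zeros(1000)), (0.1, 300.0))


class TestNotch:
    def test_mains_attenuated_20db(self):
        rec = _recording(_sine(50.0, seconds=20.0))
        out = pp.notch_50(rec).data[2000:8000, 0]
        assert out.std() <= 0.1 * rec.data[2000:8000, 0].std()

    def test_nearby_band_preserved(self):
        rec = _recording(_sine(40.0, seconds=20.0))
        out = pp.notch_50(rec).data[2000:8000, 0]
        assert np.isclose(out.std(), rec.data[2000:8000, 0].std(), rtol=0.1)

    def test_zero_in_zero_out(self):
        out = pp.notch_50(_recording(np.zeros(5000)))
        assert np.allclose(out.data, 0.0)


class TestChannelRejection:
    def test_outlier_channel_flagged(self, rng):
        data = rng.normal(0, 10, (20000, 16))
        data[:, 7] *= 50.0
        rec = io.Recording(data, 500.0, io.CHANNELS_32[:16])
        _, bad = pp.reject_channels(rec)
        assert bad == [io.CHANNELS_32[7]]

    def test_homogeneous_noise_keeps_all(self, rng):
        data = rng.normal(0, 10, (20000, 16))
        rec = io.Recording(data, 500.0, io.CHANNELS_32[:16])
        reduced, bad = pp.reject_channels(rec)
        assert bad == []
        assert reduced.n_channels == 16

    def test_all_flat_is_data_quality_error(self):
        rec = io.Recording(np.zeros((1000, 8)), 500.0, io.CHANNELS_32[:8])
        with pytest.raises(io.DataQualityError):
            pp.reject_channels(rec)

    def test_mass_rejection_refused(self, rng):
        data = rng.normal(0, 1, (20000, 12))
        data[:, :4] *= 1000.0
        rec = io.Recording(data, 500.0, io.CHANNELS_32[:12])
        with pytest.raises(io.DataQualityError):
            pp.reject_channels(rec)


class TestDownsample:
    def test_halves_sample_count(self):
        rec = _recording(_sine(10.0, seconds=4.0))
        out = pp.downsample(rec, 250.0)
        assert out.fs == 250.0
        assert out.n_samples == rec.n_samples // 2

    def test_identity_when_target_equals_fs(self):
        rec = _recording(_sine(10.0, seconds=2.0))
        out = pp.downsample(rec, 500.0)
        assert np.array_equal(out.data, rec.data)

    def test_band_limited_content_preserved(self):
        rec = _recording(_sine(30.0, seconds=20.0))
        out = pp.downsample(rec, 250.0).data[1000:8000, 0]
        assert np.isclose(out.std(), rec.data[:, 0].std(), rtol=0.05)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(io.ValidationError):
            pp.downsample(_recording(np.zeros(1000)), 300.0)


class TestEpoching:
    def test_window_arithmetic_225_samples(self):
        rec, ev = se.assemble_subject(
            protocol=se.ProtocolSpec(seed=0), noise=se.NoiseSpec(rms_uv=0),
            subject=se.SubjectSpec(attrition_rate=0.0))
        rec250 = pp.downsample(rec, 250.0)
        ev250 = pp.rescale_events(ev, 500.0, 250.0)
        eps = pp.epoch(rec250, ev250, (-100, 800))
        assert eps.epochs.shape[2] == 225
        assert eps.n_epochs == 44          # 48 minus 4 catch trials

    def test_constant_channel_zero_after_demean(self):
        rec, ev = se.assemble_subject(
            protocol=se.ProtocolSpec(seed=0), noise=se.NoiseSpec(rms_uv=0),
            subject=se.SubjectSpec(attrition_rate=0.0))
        rec.data[:, 5] = 42.0              # constant-valued channel
        eps = pp.epoch(rec, ev, (-100, 800))
        assert np.allclose(eps.epochs[:, 5, :], 0.0)

    def test_edge_anchor_dropped_with_warning(self):
        rec, ev = se.assemble_subject(
            protocol=se.ProtocolSpec(seed=0), noise=se.NoiseSpec(rms_uv=0),
            subject=se.SubjectSpec(attrition_rate=0.0))
        short = rec.copy_with(data=rec.data[:int(ev.table["onset_sample"].max())])
        with pytest.warns(UserWarning, match="edge"):
            eps = pp.epoch(short, ev, (-100, 800))
        assert eps.n_epochs == 43


class TestEpochRejection:
    def _epochs(self, rng):
        eps = rng.normal(0, 10, (10, 4, 225))
        return io.EpochSet(eps, -100, 800, 250.0, np.array(["ERN"] * 10),
                           io.CHANNELS_32[:4])

    def test_clean_set_untouched(self, rng):
        eps = self._epochs(rng)
        assert pp.reject_epochs(eps, 100.0).n_epochs == 10

    def test_spike_epoch_removed(self, rng):
        eps = self._epochs(rng)
        eps.epochs[3, 2, 100] = 500.0
        out = pp.reject_epochs(eps, 100.0)
        assert out.n_epochs == 9

    def test_zero_threshold_rejected(self, rng):
        with pytest.raises(io.ValidationError):
            pp.reject_epochs(self._epochs(rng), 0.0)

    def test_threshold_removing_everything_errors(self, rng):
        eps = self._epochs(rng)
        with pytest.raises(io.DataQualityError):
            pp.reject_epochs(eps, 1e-6)


class TestInterpolation:
    def test_identical_channels_reproduced_exactly(self, rng):
        sig = rng.normal(0, 5, 2000)
        data = np.tile(sig[:, None], (1, 8))
        rec = io.Recording(data, 500.0, io.CHANNELS_32[:8])
        reduced = rec.copy_with(data=rec.data[:, 1:],
                                channels=rec.channels[1:])
        restored, marked = pp.interpolate_channels(reduced, [rec.channels[0]])
        assert marked == [rec.channels[0]]
        i = restored.channel_index(rec.channels[0])
        np.testing.assert_allclose(restored.data[:, i], sig, atol=1e-10)

    def test_linear_field_midpoint_within_10pct(self):
        """A potential linear in x is recovered at a removed electrode."""
        pos = io.standard_montage()
        channels = [c for c in io.CHANNELS_32 if c != "Cz"]
        field = np.array([pos[c][0] for c in channels])
        data = np.outer(np.ones(500), field) * 10.0
        rec = io.Recording(data, 500.0, channels)
        target = "C3"
        reduced = rec.copy_with(
            data=rec.data[:, [i for i, c in enumerate(channels) if c != target]],
            channels=[c for c in channels if c != target])
        restored, _ = pp.interpolate_channels(reduced, [target])
        got = restored.data[0, restored.channel_index(target)]
        expected = 10.0 * pos[target][0]
        assert abs(got - expected) <= 0.1 * abs(expected) + 0.2

    def test_empty_rejection_is_identity(self, rng):
        rec = io.Recording(rng.normal(size=(100, 8)), 500.0,
                           io.CHANNELS_32[:8])
        same, marked = pp.interpolate_channels(rec, [])
        assert marked == []
        assert same is rec


class TestComposedChain:
    def test_zero_phase_through_full_chain(self):
        """Template peak latencies shift < 1 sample through preprocessing."""
        rec, ev = se.assemble_subject(
            protocol=se.ProtocolSpec(seed=3), noise=se.NoiseSpec(rms_uv=0),
            subject=se.SubjectSpec(amplitude_scale=1.0,
                                   latency_jitter_sd_ms=0.0,
                                   attrition_rate=0.0))
        eps = pp.preprocess_subject(rec, ev)
        fz = eps.channel_index("Fz")
        ern = eps.epochs[eps.labels == "ERN"].mean(axis=0)[fz]
        t = eps.times_ms
        assert abs(t[ern.argmin()] - 208.0) <= 4.0
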