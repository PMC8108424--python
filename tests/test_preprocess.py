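import numpy as np
import pytest

from ppdbs.core_io import ChannelInfo, ChannelRole, TimeSeriesRecording
from ppdbs.preprocess import (
    CompositeEP,
    Epoch,
    PreprocessError,
    TemplateResponse,
    build_template,
    extract_epochs,
    fold_polarity,
    highpass,
    rereference,
    subtract_template,
)
from ppdbs.simulate import SimConfig, synthesize_session

from conftest import quiet_config

FS = 100_000.0


def recording_with(signals, roles, events=()):
    channels = [
        ChannelInfo(f"ch{i}", role, row=i) for i, role in enumerate(roles)
    ]
    return TimeSeriesRecording(FS, np.asarray(signals, float), channels, list(events))


def make_epoch(wave, isi=1.0, polarity=1, role="test", pair_id=0):
    n = len(wave)
    return Epoch(
        waveform=np.asarray(wave, float),
        times_ms=np.arange(n) / FS * 1000.0 - 5.0,
        sample_rate=FS,
        pair_id=pair_id,
        polarity=polarity,
        pulse_role=role,
        isi=isi,
    )


class TestRereference:
    def test_identical_rings_cancel(self):
        sig = np.random.default_rng(0).normal(size=1000)
        rec = recording_with(
            [np.zeros(1000), np.zeros(1000), sig, sig],
            [ChannelRole.STIM_ANODE, ChannelRole.STIM_CATHODE,
             ChannelRole.RING_RECORD, ChannelRole.RING_RECORD],
        )
        out = rereference(rec, "bipolar_rings")
        assert out.signals.shape[0] == 1
        np.testing.assert_allclose(out.signals[0], 0.0)
        assert out.channels[0].label == "ch2-ch3"

    def test_constant_segments_cancel_under_common_average(self):
        segs = [np.full(100, 7.5) for _ in range(6)]
        rec = recording_with(
            [np.zeros(100), np.zeros(100)] + segs,
            [ChannelRole.STIM_ANODE, ChannelRole.STIM_CATHODE]
            + [ChannelRole.SEGMENT_RECORD] * 6,
        )
        out = rereference(rec, "common_average_segments")
        assert out.signals.shape[0] == 6
        np.testing.assert_allclose(out.signals, 0.0)

    def test_common_average_subtracts_mean(self):
        segs = [np.full(100, float(v)) for v in range(1, 7)]
        rec = recording_with(
            [np.zeros(100), np.zeros(100)] + segs,
            [ChannelRole.STIM_ANODE, ChannelRole.STIM_CATHODE]
            + [ChannelRole.SEGMENT_RECORD] * 6,
        )
        out = rereference(rec, "common_average_segments")
        np.testing.assert_allclose(out.signals[:, 0], [-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])

    def test_too_few_recording_channels_rejected(self):
        rec = recording_with(
            [np.zeros(100), np.zeros(100), np.zeros(100)],
            [ChannelRole.STIM_ANODE, ChannelRole.STIM_CATHODE, ChannelRole.RING_RECORD],
        )
        with pytest.raises(PreprocessError, match="ring_record"):
            rereference(rec, "bipolar_rings")

    def test_unknown_montage_rejected(self):
        rec = recording_with([np.zeros(10)], [ChannelRole.RING_RECORD])
        with pytest.raises(PreprocessError, match="montage"):
            rereference(rec, "laplacian")


class TestExtractEpochs:
    def session(self):
        cfg = quiet_config(n_isi=10, n_template_isi=2)
        rec, _ = synthesize_session(cfg)
        return rereference(rec, "bipolar_rings")

    def test_epoch_count_equals_event_count(self):
        rec = self.session()
        epochs = extract_epochs(rec, channel=rec.channels[0].label)
        assert len(epochs) == len(rec.events) == 40

    def test_sample_boundary_alignment(self):
        rec = self.session()
        epochs = extract_epochs(rec, channel=rec.channels[0].label, baseline=None)
        ev = rec.events[0]
        ep = next(e for e in epochs if e.pair_id == ev.pair_id and e.pulse_role == ev.pulse_role)
        i0 = int(round(ev.time * FS))
        k0 = int(np.argmin(np.abs(ep.times_ms)))
        assert ep.times_ms[k0] == 0.0
        assert ep.waveform[k0] == rec.signals[0, i0]

    def test_conditioning_r1_peak_near_configured_latency(self):
        cfg = quiet_config(n_isi=4, n_template_isi=2, isi_short_range=(14.0, 16.0))
        rec, _ = synthesize_session(cfg)
        reref = rereference(rec, "bipolar_rings")
        epochs = extract_epochs(reref, channel=reref.channels[0].label)
        cond = next(e for e in epochs if e.pulse_role == "conditioning")
        m = (cond.times_ms > 0.1) & (cond.times_ms < 0.55)
        peak_t = cond.times_ms[m][cond.waveform[m].argmax()]
        assert abs(peak_t - cfg.r1_peak_lat) <= 1000.0 / FS + 1e-9

    def test_window_beyond_bounds_lists_pairs(self):
        rec = self.session()
        with pytest.raises(PreprocessError, match=r"pairs \["):
            extract_epochs(rec, window=(-10_000.0, 16.0), channel=rec.channels[0].label,
                           baseline=None)

    def test_window_must_contain_zero(self):
        rec = self.session()
        with pytest.raises(PreprocessError, match="t=0"):
            extract_epochs(rec, window=(1.0, 5.0), channel=rec.channels[0].label, baseline=None)


class TestFoldPolarity:
    def test_exact_algebra(self):
        rng = np.random.default_rng(1)
        artifact = rng.normal(size=2100)
        response = rng.normal(size=2100)
        pos = make_epoch(artifact + response, polarity=1)
        neg = make_epoch(-artifact + response, polarity=-1)
        (comp,) = fold_polarity([pos, neg])
        np.testing.assert_allclose(comp.waveform, 2 * response, rtol=0, atol=1e-12)
        assert comp.n_pairs_folded == 1

    def test_fold_mean_halves(self):
        rng = np.random.default_rng(2)
        response = rng.normal(size=500)
        pos = make_epoch(response, polarity=1)
        neg = make_epoch(response, polarity=-1)
        (comp,) = fold_polarity([pos, neg], fold="mean")
        np.testing.assert_allclose(comp.waveform, response)

    def test_arbitrary_antisymmetric_artifact_cancels(self):
        # cancellation holds for any artifact shape, not just the simulator's
        rng = np.random.default_rng(3)
        for _ in range(10):
            artifact = rng.normal(size=300) * rng.uniform(0.1, 50)
            response = rng.normal(size=300)
            pos = make_epoch(artifact + response, polarity=1)
            neg = make_epoch(-artifact + response, polarity=-1)
            (comp,) = fold_polarity([pos, neg])
            np.testing.assert_allclose(comp.waveform, 2 * response, atol=1e-10)

    def test_simulator_pure_artifact_cancels(self):
        cfg = quiet_config(
            n_isi=4, n_template_isi=2, r1_peak_amp=0.0, r1_trough_amp=0.0,
            erna_present=False,
        )
        rec, _ = synthesize_session(cfg)
        reref = rereference(rec, "bipolar_rings")
        epochs = extract_epochs(reref, channel=reref.channels[0].label)
        comps = fold_polarity(epochs)
        assert max(np.abs(c.waveform).max() for c in comps) < 1e-9

    def test_noisy_artifact_residual_within_noise_bound(self):
        cfg = SimConfig(
            seed=6, n_isi=8, n_template_isi=2, r1_peak_amp=0.0, r1_trough_amp=0.0,
            erna_present=False, beta_amp_per_channel=(0.0, 0.0), rest_duration=0.0,
            noise_sd=0.01,
        )
        rec, _ = synthesize_session(cfg)
        reref = rereference(rec, "bipolar_rings")
        epochs = extract_epochs(reref, channel=reref.channels[0].label)
        comps = fold_polarity(epochs)
        # bipolar doubles noise variance; fold of n=1 pair per polarity sums two
        # epoch means -> residual sd = noise_sd*sqrt(2)*sqrt(2); bound at 3x
        sigma = cfg.noise_sd * np.sqrt(2.0) * np.sqrt(2.0)
        for c in comps:
            m = (c.times_ms >= 0.0) & (c.times_ms <= 0.1)
            rms = np.sqrt(np.mean(c.waveform[m] ** 2))
            assert rms < 3.0 * sigma

    def test_unbalanced_polarity_names_isi(self):
        pos = make_epoch(np.zeros(100), isi=2.5, polarity=1)
        with pytest.raises(PreprocessError, match="2.5"):
            fold_polarity([pos])

    def test_linearity(self):
        rng = np.random.default_rng(4)
        a1, a2 = rng.normal(size=(2, 200))
        r1, r2 = rng.normal(size=(2, 200))
        def comp_of(a, r):
            (c,) = fold_polarity([make_epoch(a + r, polarity=1), make_epoch(-a + r, polarity=-1)])
            return c.waveform
        lhs = comp_of(a1 + a2, r1 + r2)
        rhs = comp_of(a1, r1) + comp_of(a2, r2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestTemplate:
    def test_pointwise_mean_and_count(self):
        rng = np.random.default_rng(5)
        waves = rng.normal(size=(4, 300))
        comps = [
            CompositeEP(w, np.arange(300) / FS * 1000 - 5, FS, isi, "conditioning", 1)
            for w, isi in zip(waves, [20.0, 22.0, 25.0, 30.0])
        ]
        tmpl = build_template(comps)
        np.testing.assert_allclose(tmpl.waveform, waves.mean(axis=0))
        assert tmpl.n_averaged == 4
        assert tmpl.source_isis == (20.0, 22.0, 25.0, 30.0)

    def test_short_isi_and_test_roles_excluded(self):
        times = np.arange(100) / FS * 1000 - 1
        keep = CompositeEP(np.ones(100), times, FS, 25.0, "conditioning", 1)
        drop1 = CompositeEP(np.full(100, 9.0), times, FS, 5.0, "conditioning", 1)
        drop2 = CompositeEP(np.full(100, 9.0), times, FS, 25.0, "test", 1)
        tmpl = build_template([keep, drop1, drop2])
        np.testing.assert_allclose(tmpl.waveform, 1.0)
        assert tmpl.n_averaged == 1

    def test_mean_residual_is_zero(self):
        rng = np.random.default_rng(6)
        waves = rng.normal(size=(3, 50))
        times = np.arange(50) / FS * 1000 - 0.5
        comps = [CompositeEP(w, times, FS, 20.0 + i, "conditioning", 1) for i, w in enumerate(waves)]
        tmpl = build_template(comps)
        residual = sum(w - tmpl.waveform for w in waves) / 3
        np.testing.assert_allclose(residual, 0.0, atol=1e-13)

    def test_no_qualifying_composite_rejected(self):
        times = np.arange(10) / FS * 1000 - 0.05
        comps = [CompositeEP(np.zeros(10), times, FS, 5.0, "conditioning", 1)]
        with pytest.raises(PreprocessError, match=">= 20"):
            build_template(comps)


class TestSubtractTemplate:
    def test_exact_recovery_of_added_signal(self):
        rng = np.random.default_rng(7)
        n = 2101  # (-5, 16) ms at 100 kHz
        times = np.arange(n) / FS * 1000 - 5.0
        tmpl_wave = rng.normal(size=n)
        template = TemplateResponse(tmpl_wave, times, FS, (20.0,), 1)
        isi = 4.0
        shift = int(round(isi * FS / 1000))
        x = rng.normal(size=n)
        comp_wave = x.copy()
        comp_wave[: n - shift] += tmpl_wave[shift:]  # template shifted to -isi
        comp = CompositeEP(comp_wave, times, FS, isi, "test", 1)
        out = subtract_template(comp, template)
        np.testing.assert_allclose(out.waveform, x, atol=1e-12)

    def test_large_isi_passthrough(self):
        n = 2101
        times = np.arange(n) / FS * 1000 - 5.0
        template = TemplateResponse(np.random.default_rng(8).normal(size=n), times, FS, (20.0,), 1)
        comp = CompositeEP(np.ones(n), times, FS, 30.0, "test", 1)
        out = subtract_template(comp, template)
        # template support ends 16 ms after its pulse = -14 ms in test time,
        # before the composite window start -> nothing to subtract... except the
        # overlap [-5, 16-30] is empty, so output == composite
        np.testing.assert_array_equal(out.waveform, comp.waveform)

    def test_insufficient_early_coverage_rejected(self):
        n = 500
        times_c = np.arange(n) / FS * 1000 - 5.0
        times_t = np.arange(n) / FS * 1000 - 1.0  # template starts too late
        template = TemplateResponse(np.zeros(n), times_t, FS, (20.0,), 1)
        comp = CompositeEP(np.zeros(n), times_c, FS, 2.0, "test", 1)
        with pytest.raises(PreprocessError, match="cover"):
            subtract_template(comp, template)

    def test_conditioning_erna_removed_in_simulation(self):
        cfg = quiet_config(seed=8)
        rec, _ = synthesize_session(cfg)
        reref = rereference(rec, "bipolar_rings")
        epochs = extract_epochs(reref, channel=reref.channels[0].label)
        comps = fold_polarity(epochs)
        template = build_template(comps)
        test = min(
            (c for c in comps if c.pulse_role == "test"), key=lambda c: abs(c.isi - 2.0)
        )
        sub = subtract_template(test, template)
        # region past the test R1 but before the test-evoked ERNA onset:
        # only conditioning-evoked energy lives here
        m = (test.times_ms >= 1.5) & (test.times_ms <= 3.0)
        before = np.sum(test.waveform[m] ** 2)
        after = np.sum(sub.waveform[m] ** 2)
        assert after < 0.01 * before

    def test_linearity(self):
        rng = np.random.default_rng(9)
        n = 400
        times = np.arange(n) / FS * 1000 - 2.0
        tw = rng.normal(size=n)
        template = TemplateResponse(tw, times, FS, (20.0,), 1)
        w1, w2 = rng.normal(size=(2, n))
        c = lambda w: CompositeEP(w, times, FS, 1.0, "test", 1)
        # affine linearity: subtract(w1+w2) = subtract(w1) + subtract(w2) + shifted_template
        lhs = subtract_template(c(w1 + w2), template).waveform
        rhs = (
            subtract_template(c(w1), template).waveform
            + subtract_template(c(w2), template).waveform
            + tw_shifted(tw, times, 1.0)
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def tw_shifted(tw, times, isi):
    fs = FS
    n = len(tw)
    offset = int(round((times[0] + isi - times[0]) * fs / 1000.0))
    shifted = np.zeros(n)
    hi = min(n, offset + n)
    shifted[: hi - offset] = tw[offset:hi]
    return shifted


class TestHighpass:
    def test_removes_slow_component(self):
        rng = np.random.default_rng(10)
        fs = 10_000.0
        t = np.arange(int(fs)) / fs
        slow = np.sin(2 * np.pi * 10 * t)
        fast = rng.normal(size=len(t)) * 0.1
        rec = recording_with([slow + fast], [ChannelRole.RING_RECORD])
        rec.sample_rate = fs
        out = highpass(rec, cutoff_hz=70.0)
        assert np.abs(out.signals[0] - fast).std() < 0.05 * slow.std()

    def test_bad_cutoff_rejected(self):
        rec = recording_with([np.zeros(100)], [ChannelRole.RING_RECORD])
        with pytest.raises(PreprocessError, match="Nyquist"):
            highpass(rec, cutoff_hz=1e6)
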