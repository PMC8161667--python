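"""Preprocessing: filtering, segmentation, artifacts, baseline, averaging."""

import numpy as np
import pandas as pd
import pytest

from erptrains.montage import Montage, default_montage
from erptrains.preprocess import (
    REASON_EDGE,
    REASON_TOO_MANY_BAD,
    REASON_UNINTERPOLABLE,
    ConditionERP,
    EpochSet,
    PreprocConfig,
    bandpass,
    baseline_and_rereference,
    detect_artifacts,
    interpolate_bad_channels,
    preprocess_recording,
    segment,
    truncate_and_average,
)
from erptrains.simulate import (
    NoiseSpec,
    ParadigmConfig,
    SimulatedRecording,
    default_effects,
    generate_subject_recording,
)

SR = 500.0


def make_epochset(epochs_by_cond, sample_rate=SR, ch_names=None):
    """Minimal EpochSet around raw trial tensors (already 'segmented')."""
    any_t = next(iter(epochs_by_cond.values()))
    n_samp = any_t.shape[2]
    times = (np.arange(n_samp) - n_samp // 9) * 1000.0 / sample_rate  # ~-100..800
    ch_names = ch_names or tuple(f"ch{i}" for i in range(any_t.shape[1]))
    return EpochSet(
        epochs={c: t.astype(float) for c, t in epochs_by_cond.items()},
        keep={c: np.ones(t.shape[0], dtype=bool) for c, t in epochs_by_cond.items()},
        reject_reason={c: [None] * t.shape[0] for c, t in epochs_by_cond.items()},
        bad_channels={c: [[] for _ in range(t.shape[0])] for c, t in epochs_by_cond.items()},
        times=times,
        ch_names=ch_names,
        sample_rate=sample_rate,
    )


class TestBandpass:
    def test_dc_is_blocked(self):
        out = bandpass(np.full(5000, 10.0), SR)
        assert np.abs(out[500:-500]).max() < 0.05

    def test_passband_and_stopband_response(self):
        t = np.arange(20_000) / SR
        in_band = bandpass(np.sin(2 * np.pi * 10 * t), SR)
        out_band = bandpass(np.sin(2 * np.pi * 60 * t), SR)
        mid = slice(5000, 15000)
        assert np.abs(in_band[mid]).max() == pytest.approx(1.0, abs=0.05)
        assert np.abs(out_band[mid]).max() < 0.1
        # >= 20 dB attenuation at twice the high corner
        assert np.abs(out_band[mid]).max() < 0.1 * 1.0

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass(np.zeros(10), SR)


def _recording(data, events, sr=SR):
    return SimulatedRecording(
        data=data, ch_names=tuple(f"ch{i}" for i in range(data.shape[0])),
        sample_rate=sr, events=events, subject_id="s", group="TD",
        age_months=5, seed=0,
    )


class TestSegment:
    def test_inclusive_451_sample_convention(self):
        data = np.arange(2 * 3000, dtype=float).reshape(2, 3000)
        ev = pd.DataFrame({"onset_sample": [1000], "onset_ms": [2000.0],
                           "label": ["S1"], "train_index": [0]})
        es = segment(_recording(data, ev), PreprocConfig())
        ep = es.epochs["S1"]
        assert ep.shape == (1, 2, 451)
        np.testing.assert_array_equal(ep[0], data[:, 950:1401])
        assert es.times[0] == -100.0 and es.times[-1] == 800.0
        assert es.times[50] == 0.0

    def test_zero_events_empty(self):
        ev = pd.DataFrame(columns=["onset_sample", "onset_ms", "label", "train_index"])
        es = segment(_recording(np.zeros((2, 1000)), ev), PreprocConfig())
        assert all(t.shape[0] == 0 for t in es.epochs.values())

    def test_edge_event_flagged_not_fatal(self):
        ev = pd.DataFrame({"onset_sample": [20, 500], "onset_ms": [40.0, 1000.0],
                           "label": ["S1", "S1"], "train_index": [0, 1]})
        es = segment(_recording(np.zeros((2, 1000)), ev), PreprocConfig())
        assert list(es.keep["S1"]) == [False, True]
        assert es.reject_reason["S1"][0] == REASON_EDGE

    def test_overlapping_epochs_contain_next_onset(self, montage):
        # 550 ms onset asynchrony < 800 ms epoch: S1 epoch holds S2 response
        cfg = ParadigmConfig(n_trains=1, isi_jitter_halfwidth=0.0)
        rec = generate_subject_recording(
            cfg, default_effects(), NoiseSpec(std=0.0), montage, seed=0
        )
        es = segment(rec, PreprocConfig())
        fz = rec.ch_names.index("Fz")
        tail = es.epochs["S1"][0, fz, es.times > 640.0]
        assert np.abs(tail).max() > 0.1  # S2's bump, onset 550+80 ms


class TestArtifacts:
    def _epochs_with_bad(self, n_bad, n_ch=30):
        tensor = np.zeros((1, n_ch, 451))
        tensor[0, :n_bad, 0] = 300.0  # 300 uV spike -> ptp over threshold
        return make_epochset({"S1": tensor})

    def test_more_than_limit_rejected(self):
        es = detect_artifacts(self._epochs_with_bad(26), PreprocConfig())
        assert not es.keep["S1"][0]
        assert es.reject_reason["S1"][0] == REASON_TOO_MANY_BAD

    def test_exactly_limit_retained(self):
        es = detect_artifacts(self._epochs_with_bad(25), PreprocConfig())
        assert es.keep["S1"][0]
        assert len(es.bad_channels["S1"][0]) == 25

    def test_clean_epoch_untouched(self):
        es = detect_artifacts(self._epochs_with_bad(0), PreprocConfig())
        assert es.keep["S1"][0]
        assert es.bad_channels["S1"][0] == []


class TestInterpolation:
    def test_constant_field_interpolates_exactly(self, montage):
        tensor = np.full((1, montage.n_channels, 11), 5.0)
        tensor[0, 0, :] = 500.0
        es = make_epochset({"S1": tensor}, ch_names=montage.ch_names)
        es.bad_channels["S1"][0] = [0]
        es = interpolate_bad_channels(es, montage, PreprocConfig())
        np.testing.assert_allclose(es.epochs["S1"][0, 0], 5.0, atol=1e-9)

    def test_no_bad_channels_identity(self, montage):
        tensor = np.random.default_rng(0).normal(size=(2, montage.n_channels, 11))
        es = make_epochset({"S1": tensor.copy()}, ch_names=montage.ch_names)
        es = interpolate_bad_channels(es, montage, PreprocConfig())
        np.testing.assert_array_equal(es.epochs["S1"], tensor)

    def test_linear_x_gradient_recovered_at_symmetric_channel(self, montage):
        # Cz sits at the montage's x-symmetry centre, so inverse-distance
        # weighting reproduces a pure x-gradient there exactly
        pos = montage.position_array()
        field = 1.0 + 2.0 * pos[:, 0]
        tensor = np.tile(field[None, :, None], (1, 1, 11))
        cz = montage.ch_names.index("Cz")
        truth = tensor[0, cz, 0]
        tensor[0, cz, :] = 999.0
        es = make_epochset({"S1": tensor}, ch_names=montage.ch_names)
        es.bad_channels["S1"][0] = [cz]
        es = interpolate_bad_channels(es, montage, PreprocConfig())
        np.testing.assert_allclose(es.epochs["S1"][0, cz], truth, atol=1e-9)

    def test_too_few_neighbours_rejects_epoch(self, montage):
        tensor = np.zeros((1, montage.n_channels, 11))
        es = make_epochset({"S1": tensor}, ch_names=montage.ch_names)
        es.bad_channels["S1"][0] = list(range(montage.n_channels - 1))
        es = interpolate_bad_channels(es, montage, PreprocConfig())
        assert not es.keep["S1"][0]
        assert es.reject_reason["S1"][0] == REASON_UNINTERPOLABLE


class TestBaselineReference:
    def _random_epochs(self):
        rng = np.random.default_rng(3)
        return make_epochset({"S1": rng.normal(2.0, 5.0, size=(4, 6, 451))})

    def test_baseline_mean_zero_and_channel_sum_zero(self):
        cfg = PreprocConfig()
        es = baseline_and_rereference(self._random_epochs(), cfg)
        mask = (es.times >= -100.0) & (es.times <= 0.0)
        base = es.epochs["S1"][:, :, mask].mean(axis=2)
        np.testing.assert_allclose(base, 0.0, atol=1e-9)
        np.testing.assert_allclose(es.epochs["S1"].sum(axis=1), 0.0, atol=1e-9)

    def test_idempotent(self):
        cfg = PreprocConfig()
        es = baseline_and_rereference(self._random_epochs(), cfg)
        before = es.epochs["S1"].copy()
        es = baseline_and_rereference(es, cfg)
        np.testing.assert_allclose(es.epochs["S1"], before, atol=1e-12)


class TestTruncateAverage:
    def test_caps_and_exclusion(self):
        s1 = np.arange(150, dtype=float)[:, None, None] * np.ones((150, 2, 11))
        dev = np.ones((9, 2, 11))
        es = make_epochset({"S1": s1, "DevVowel": dev})
        erp = truncate_and_average(es, PreprocConfig())
        assert erp.n_retained["S1"] == 120
        # mean of trial indices 0..119
        np.testing.assert_allclose(erp.data["S1"], np.mean(np.arange(120)))
        assert "DevVowel" in erp.excluded and "DevVowel" not in erp.data
        assert erp.n_retained["DevVowel"] == 9

    def test_identical_trials_average_to_value(self):
        es = make_epochset({"S2": np.full((20, 2, 11), 7.25)})
        erp = truncate_and_average(es, PreprocConfig())
        np.testing.assert_allclose(erp.data["S2"], 7.25)

    def test_deviant_cap_is_65(self):
        es = make_epochset({"DevPitch": np.zeros((80, 2, 11))})
        erp = truncate_and_average(es, PreprocConfig())
        assert erp.n_retained["DevPitch"] == 65


class TestEndToEnd:
    def test_retention_accounting(self, montage):
        cfg = ParadigmConfig(n_trains=20)
        rec = generate_subject_recording(
            cfg, default_effects(), NoiseSpec(std=20.0, artifact_rate=10.0),
            montage, seed=17,
        )
        pcfg = PreprocConfig()
        from erptrains.preprocess import bandpass_recording
        es = detect_artifacts(segment(bandpass_recording(rec, pcfg), pcfg), pcfg)
        summary = es.retention_summary()
        for cond, row in summary.items():
            assert row["presented"] == row["retained"] + row["rejected"]
            assert row["presented"] == (rec.events["label"] == cond).sum()

    def test_noiseless_contrast_recovery_within_filter_bound(
        self, noiseless_erp, effects, montage
    ):
        """Planted templates survive the full chain; the zero-phase IIR
        band-pass perturbs 0-500 ms contrast waveforms by < 0.02 uV."""
        from erptrains.features import build_contrasts
        cset = build_contrasts([noiseless_erp], montage)
        for contrast, (a, b) in (("S1", ("S1", None)), ("S1-S2", ("S1", "S2"))):
            _, w = cset.select(contrast, "frontal")
            expected = effects.condition_waveform(a, "frontal", cset.times)
            if b:
                expected = expected - effects.condition_waveform(b, "frontal", cset.times)
            assert np.abs(w[0] - expected).max() < 0.02

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocConfig(band=(30.0, 0.1))
        with pytest.raises(ValueError):
            PreprocConfig(baseline_window=(-200.0, 0.0))
        with pytest.raises(ValueError):
            PreprocConfig(cap_deviants=9, min_trials=10)
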