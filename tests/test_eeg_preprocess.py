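"""EEG ingestion, filtering chain, and state-epoch extraction."""

import numpy as np
import pytest
from scipy import signal

from anesrecov.eeg_preprocess import (
    STANDARD_21,
    EpochSelectionEvents,
    extract_state_epochs,
    preprocess_eeg,
    read_eeg,
    suppression_fraction,
    write_eeg,
)
from anesrecov.errors import (
    FormatError,
    MontageError,
    ParameterError,
    ReferenceError_,
    SamplingError,
)
from anesrecov.synthetic_data import SyntheticEEGSpec, iter_synthetic_eeg


class TestIO:
    def test_roundtrip_identity(self, tmp_path, make_recording, rng):
        rec = make_recording(rng.standard_normal((21, 5000)), fs=250.0)
        path = write_eeg(rec, tmp_path / "rec.csv")
        back = read_eeg(path)
        assert back.fs == rec.fs
        assert back.channel_labels == rec.channel_labels
        np.testing.assert_allclose(back.data, rec.data, atol=1e-5)

    def test_unreadable_and_undersized_inputs(self, tmp_path, make_recording, rng):
        with pytest.raises(FormatError):
            read_eeg(tmp_path / "nope.csv")
        rec = make_recording(rng.standard_normal((3, 100)))
        path = write_eeg(rec, tmp_path / "small.csv")
        with pytest.raises(MontageError):
            read_eeg(path)

    def test_sine_amplitude_preserved(self, tmp_path, make_recording):
        t = np.arange(5000) / 250.0
        data = np.tile(50.0 * np.sin(2 * np.pi * 10.0 * t), (21, 1))
        path = write_eeg(make_recording(data), tmp_path / "sine.csv")
        back = read_eeg(path)
        assert abs(back.data[0].max() - 50.0) < 0.5  # within 1% of 50 uV


class TestPreprocess:
    def _raw(self, make_recording, rng, fs=500.0, seconds=20.0):
        n = int(fs * seconds)
        return make_recording(rng.standard_normal((23, n)) * 20.0, fs=fs)

    def test_output_rate_and_montage(self, make_recording, rng):
        out = preprocess_eeg(self._raw(make_recording, rng))
        assert out.fs == 250.0
        assert out.channel_labels == list(STANDARD_21)
        assert out.n_channels == 21

    def test_too_low_sampling_rate_rejected(self, make_recording, rng):
        with pytest.raises(SamplingError):
            preprocess_eeg(self._raw(make_recording, rng, fs=50.0))

    def test_missing_mastoids_rejected(self, rng):
        from anesrecov.eeg_preprocess import EEGRecording

        rec = EEGRecording(
            "S", rng.standard_normal((21, 1000)), 250.0, list(STANDARD_21)
        )
        with pytest.raises(ReferenceError_):
            preprocess_eeg(rec)
        # declared substitute pair makes the same recording usable
        out = preprocess_eeg(rec, reference_pair=("Fp1", "Fp2"))
        assert out.n_channels == 21

    def test_dc_channel_rejected_by_highpass(self, make_recording, rng):
        rec = self._raw(make_recording, rng, fs=250.0)
        rec.data[0, :] = 1000.0  # DC on one channel
        rec.data[21:, :] = 0.0  # silent mastoids so the reference adds nothing
        out = preprocess_eeg(rec)
        trim = 500  # discard filter edges
        assert np.abs(out.data[0, trim:-trim]).max() < 1e-6 * 1000.0

    def test_50hz_attenuated_beyond_20db(self, make_recording):
        # oracle: squared (two-pass) Butterworth magnitude response at 50 Hz
        sos = signal.butter(4, (0.5, 30.0), btype="bandpass", fs=250.0, output="sos")
        _, h = signal.sosfreqz(sos, worN=[50.0], fs=250.0)
        expected_db = 20.0 * np.log10(np.abs(h[0]) ** 2)
        assert expected_db < -20.0

        t = np.arange(int(250.0 * 20)) / 250.0
        # silent mastoids: the linked-mastoid reference must not cancel the
        # 50 Hz content before it reaches the filter
        data = np.tile(30.0 * np.sin(2 * np.pi * 50.0 * t), (23, 1))
        data[21:] = 0.0
        out = preprocess_eeg(make_recording(data, fs=250.0))
        trim = 500
        rms_in = np.sqrt(np.mean(data[0] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, trim:-trim] ** 2))
        atten_db = 20.0 * np.log10(rms_out / rms_in)
        assert atten_db < -20.0
        # residual output is dominated by window leakage, so the measured
        # attenuation can only fall short of the pure-tone oracle
        assert atten_db <= expected_db + 10.0

    def test_zero_phase_no_lag(self, make_recording, rng):
        # band-limited input: cross-correlation peak between input and output
        # sits at lag zero
        sos = signal.butter(4, (2.0, 20.0), btype="bandpass", fs=250.0, output="sos")
        x = signal.sosfilt(sos, rng.standard_normal(5000)) * 20.0
        data = np.vstack([np.tile(x, (21, 1)), np.zeros((2, x.size))])
        out = preprocess_eeg(make_recording(data, fs=250.0))
        a = x[500:-500]
        b = out.data[0, 500:-500]
        lags = signal.correlation_lags(a.size, b.size)
        xc = signal.correlate(a, b)
        assert lags[np.argmax(xc)] == 0

    def test_idempotent_on_clean_data(self, make_recording, rng):
        # content well inside the 0.5-30 Hz passband: re-running the chain
        # must change it only through filter edge effects
        sos = signal.butter(4, (2.0, 20.0), btype="bandpass", fs=250.0, output="sos")
        data = signal.sosfilt(sos, rng.standard_normal((23, 15000)), axis=1) * 20.0
        ref = ("Fp1", "Fp2")
        once = preprocess_eeg(make_recording(data, fs=250.0), reference_pair=ref)
        again = preprocess_eeg(once, reference_pair=ref)
        trim = 1000
        r1 = np.sqrt(np.mean(once.data[:, trim:-trim] ** 2))
        r2 = np.sqrt(np.mean(again.data[:, trim:-trim] ** 2))
        assert abs(r2 - r1) / r1 < 0.01


class TestSuppression:
    def test_sine_above_threshold_never_suppressed(self, make_epoch):
        t = np.arange(250 * 10) / 250.0
        ep = make_epoch(np.tile(30.0 * np.sin(2 * np.pi * 10 * t), (21, 1)))
        assert suppression_fraction(ep, amp_threshold=5.0) == 0.0

    def test_all_zero_fully_suppressed(self, make_epoch):
        ep = make_epoch(np.zeros((21, 2500)))
        assert suppression_fraction(ep) == 1.0

    def test_burst_suppression_fraction(self, make_epoch):
        fs = 250.0
        t = np.arange(int(fs * 120)) / fs
        x = 30.0 * np.sin(2 * np.pi * 10 * t)
        gate = (t % 5.0) < 3.0  # 3 s bursts, 2 s silence
        ep = make_epoch(np.tile(x * gate, (21, 1)), fs=fs)
        assert suppression_fraction(ep) == pytest.approx(0.4, abs=0.02)

    def test_nonpositive_threshold_rejected(self, make_epoch):
        ep = make_epoch(np.zeros((21, 2500)))
        with pytest.raises(ParameterError):
            suppression_fraction(ep, amp_threshold=0.0)


@pytest.fixture(scope="module")
def subjects():
    spec = SyntheticEEGSpec(n_subjects=1, burst_suppression_frac=0.0)
    return {
        group: (rec, ev) for rec, ev, group in iter_synthetic_eeg(spec, seed=42)
    }


class TestEpochExtraction:
    def test_anesthesia_yields_ten_epochs(self, subjects):
        rec, ev = subjects["anesthesia"]
        clean = preprocess_eeg(rec)
        epochs, missing = extract_state_epochs(clean, ev, "anesthesia")
        assert [e.state for e in epochs] == [
            "EC1", "LOC", "Maintenance", "PreROC",
            "EC2", "EC3", "EC4", "EC5", "EC6", "EC7",
        ]
        assert not missing
        assert all(e.data.shape == (21, 30000) for e in epochs)  # 120 s x 250 Hz

    def test_control_yields_seven_epochs(self, subjects):
        rec, ev = subjects["control"]
        clean = preprocess_eeg(rec)
        epochs, missing = extract_state_epochs(clean, ev, "control")
        assert [e.state for e in epochs] == [f"EC{i}" for i in range(1, 8)]
        assert not missing

    def test_epochs_avoid_artifact_mask(self, subjects):
        rec, ev = subjects["anesthesia"]
        clean = preprocess_eeg(rec)
        # mask the first 30 s of the nominal EC1 window: the epoch must shift
        fs = clean.fs
        t0 = ev.resting_session_starts[0]
        clean.artifact_mask[int(t0 * fs) : int((t0 + 30) * fs)] = True
        epochs, missing = extract_state_epochs(clean, ev, "anesthesia")
        ec1 = next(e for e in epochs if e.state == "EC1")
        i0 = int(ec1.start_s * fs)
        assert not clean.artifact_mask[i0 : i0 + ec1.data.shape[1]].any()
        assert ec1.start_s >= t0 + 30

    def test_unplaceable_epoch_reported_not_fabricated(self, subjects):
        rec, ev = subjects["anesthesia"]
        clean = preprocess_eeg(rec)
        fs = clean.fs
        # mask the entire PreROC search region
        clean.artifact_mask[int((ev.roc_time - 500) * fs) : int(ev.roc_time * fs)] = True
        epochs, missing = extract_state_epochs(clean, ev, "anesthesia")
        assert "PreROC" not in {e.state for e in epochs}
        assert {m.state for m in missing} == {"PreROC"}

    def test_burst_suppression_fallback(self):
        spec = SyntheticEEGSpec(n_subjects=1, burst_suppression_frac=1.0)
        rec, ev, _ = next(iter(iter_synthetic_eeg(spec, seed=7, groups=("anesthesia",))))
        clean = preprocess_eeg(rec)
        epochs, missing = extract_state_epochs(clean, ev, "anesthesia")
        maint = next(e for e in epochs if e.state == "Maintenance")
        # the selected epoch is suppression-free and therefore ends before
        # the contaminated nominal (last 2 min) window
        assert suppression_fraction(maint) == 0.0
        assert maint.start_s + maint.duration <= ev.iso_off_time - 60.0


class TestEvents:
    def test_event_ordering_enforced(self):
        with pytest.raises(ParameterError):
            EpochSelectionEvents(
                resting_session_starts=[0.0, 100.0],
                loc_time=500.0, iso_off_time=400.0, roc_time=600.0,
            )
        with pytest.raises(ParameterError):
            EpochSelectionEvents(resting_session_starts=[100.0, 100.0])
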