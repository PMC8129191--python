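"""Closed-form and hand-computed checks for every preprocessing stage."""

import numpy as np
import pytest

import seegdecode as sd
from seegdecode.datatypes import BANDS, ContactInfo, EventTable, RecordingSession
from seegdecode.preprocess import (
    band_power,
    comb_notch,
    epoch_and_zscore,
    laplacian_reference,
    reject_artifact_contacts,
    screen_line_noise_contacts,
    smooth_gaussian,
)


def make_session(signals, fs=1000.0, onsets=(1500, 4000), labels=("own", "other"),
                 shafts=None):
    signals = np.asarray(signals, dtype=float)
    n = signals.shape[0]
    if shafts is None:
        shafts = [("A", i + 1) for i in range(n)]
    contacts = [
        ContactInfo(contact_id=f"{s}-{k}", shaft_id=s, index_on_shaft=k)
        for s, k in shafts
    ]
    events = EventTable.from_arrays(list(onsets), list(labels), "auditory")
    return RecordingSession(
        signals=signals, fs=fs, contacts=contacts, events=events,
        session_meta={"stimulus_ms": 1000.0},
    )


def _contiguous_shafts(counts):
    out = []
    for si, k in enumerate(counts):
        out.extend((f"S{si}", j + 1) for j in range(k))
    return out


class TestLineScreen:
    def test_identical_line_power_none_removed(self):
        rng = np.random.default_rng(0)
        t = np.arange(8000) / 1000.0
        line = np.sin(2 * np.pi * 50 * t)
        signals = np.array([line + 0.01 * rng.standard_normal(8000) for _ in range(5)])
        session = make_session(signals, shafts=_contiguous_shafts([5]))
        kept, removed, _ = screen_line_noise_contacts(session)
        # near-identical line power: MAD is the (small) estimate noise,
        # threshold sits just above the median
        assert len(removed) == 0

    def test_single_noisy_contact_removed(self):
        rng = np.random.default_rng(1)
        t = np.arange(20000) / 1000.0
        signals = rng.standard_normal((10, 20000))
        signals[4] += 100 * np.sin(2 * np.pi * 50 * t)
        session = make_session(signals, shafts=_contiguous_shafts([10]))
        kept, removed, power = screen_line_noise_contacts(session)
        assert list(removed) == [4]
        assert session.contacts[4].excluded
        assert session.contacts[4].exclusion_reason == "line_noise"
        # hand check: the other nine powers bracket the median, contact 4
        # exceeds median + 10*MAD
        med = np.median(power)
        mad = np.median(np.abs(power - med))
        assert power[4] > med + 10 * mad

    def test_clean_session_none_removed(self):
        rng = np.random.default_rng(2)
        session = make_session(rng.standard_normal((6, 20000)),
                               shafts=_contiguous_shafts([6]))
        _, removed, _ = screen_line_noise_contacts(session)
        assert len(removed) == 0

    def test_too_few_contacts_rejected(self):
        session = make_session(np.zeros((2, 8000)), shafts=_contiguous_shafts([2]))
        with pytest.raises(ValueError, match="3 contacts"):
            screen_line_noise_contacts(session)


class TestCombNotch:
    def test_attenuates_50hz(self):
        t = np.arange(8000) / 1000.0
        x = np.sin(2 * np.pi * 50 * t)
        session = make_session(np.tile(x, (3, 1)), shafts=_contiguous_shafts([3]))
        out = comb_notch(session)
        interior = slice(1000, 7000)
        assert np.sqrt(np.mean(out.signals[0, interior] ** 2)) <= 0.03 * np.sqrt(
            np.mean(x[interior] ** 2)
        )

    def test_attenuates_harmonics(self):
        t = np.arange(8000) / 1000.0
        for f in (100.0, 150.0):
            x = np.sin(2 * np.pi * f * t)
            session = make_session(np.tile(x, (3, 1)), shafts=_contiguous_shafts([3]))
            out = comb_notch(session)
            interior = slice(1000, 7000)
            assert np.sqrt(np.mean(out.signals[0, interior] ** 2)) <= 0.05

    def test_passband_preserved_at_80hz(self):
        t = np.arange(8000) / 1000.0
        x = np.sin(2 * np.pi * 80 * t)
        session = make_session(np.tile(x, (3, 1)), shafts=_contiguous_shafts([3]))
        out = comb_notch(session)
        interior = slice(1000, 7000)
        rms_ratio = np.sqrt(np.mean(out.signals[0, interior] ** 2)) / np.sqrt(
            np.mean(x[interior] ** 2)
        )
        assert abs(rms_ratio - 1.0) < 0.1

    def test_zero_signal_unchanged(self):
        session = make_session(np.zeros((3, 8000)), shafts=_contiguous_shafts([3]))
        out = comb_notch(session)
        np.testing.assert_allclose(out.signals, 0.0, atol=1e-12)


class TestLaplacian:
    def test_common_mode_interior_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5000)
        session = make_session(np.tile(x, (4, 1)), shafts=_contiguous_shafts([4]))
        out = laplacian_reference(session)
        np.testing.assert_allclose(out.signals[1], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.signals[2], 0.0, atol=1e-12)

    def test_hand_computed_three_contact_shaft(self):
        signals = np.array([[1.0] * 100, [2.0] * 100, [3.0] * 100])
        session = make_session(signals, shafts=_contiguous_shafts([3]))
        out = laplacian_reference(session)
        np.testing.assert_allclose(out.signals[1], 0.0)  # 2 - (1+3)/2
        np.testing.assert_allclose(out.signals[0], -1.0)  # 1 - 2
        np.testing.assert_allclose(out.signals[2], 1.0)  # 3 - 2

    def test_end_contact_uses_single_neighbor(self):
        rng = np.random.default_rng(1)
        signals = rng.standard_normal((3, 500))
        session = make_session(signals, shafts=_contiguous_shafts([3]))
        out = laplacian_reference(session)
        np.testing.assert_allclose(out.signals[0], signals[0] - signals[1])

    def test_excluded_neighbor_skipped(self):
        signals = np.array([[1.0] * 50, [5.0] * 50, [3.0] * 50])
        session = make_session(signals, shafts=_contiguous_shafts([3]))
        session.contacts[1].excluded = True
        out = laplacian_reference(session)
        # contacts 0 and 2 now neighbor each other
        np.testing.assert_allclose(out.signals[0], 1.0 - 3.0)
        np.testing.assert_allclose(out.signals[2], 3.0 - 1.0)

    def test_single_contact_shaft_excluded_with_warning(self):
        signals = np.zeros((3, 100))
        shafts = [("A", 1), ("A", 2), ("B", 1)]
        session = make_session(signals, shafts=shafts)
        with pytest.warns(UserWarning, match="no Laplacian neighbor"):
            out = laplacian_reference(session)
        assert out.contacts[2].excluded
        assert out.contacts[2].exclusion_reason == "no_neighbor"


class TestBandPower:
    def test_in_band_sinusoid_power_one(self):
        t = np.arange(8000) / 1000.0
        x = np.sin(2 * np.pi * 100 * t)
        session = make_session(np.tile(x, (2, 1)), shafts=_contiguous_shafts([2]))
        power = band_power(session, BANDS["high_gamma"])
        interior = power[0, 2000:6000]
        assert np.all(np.abs(interior - 1.0) < 0.02)

    def test_out_of_band_sinusoid_power_zero(self):
        t = np.arange(8000) / 1000.0
        x = np.sin(2 * np.pi * 5 * t)
        session = make_session(np.tile(x, (2, 1)), shafts=_contiguous_shafts([2]))
        power = band_power(session, BANDS["alpha"])
        assert np.max(power[0, 2000:6000]) < 1e-3

    def test_zero_signal_zero_power(self):
        session = make_session(np.zeros((2, 4000)), shafts=_contiguous_shafts([2]))
        power = band_power(session, BANDS["beta"])
        np.testing.assert_allclose(power, 0.0, atol=1e-20)

    def test_band_outside_nyquist_rejected(self):
        session = make_session(np.zeros((2, 4000)), fs=200.0,
                               shafts=_contiguous_shafts([2]))
        with pytest.raises(ValueError, match="outside"):
            band_power(session, BANDS["high_gamma"])


class TestEpochZscore:
    def _power_session(self, power):
        session = make_session(np.zeros_like(power), shafts=_contiguous_shafts([1]))
        return session

    def test_zscore_arithmetic(self):
        rng = np.random.default_rng(0)
        power = np.empty((1, 6000))
        power[0] = rng.normal(2.0, 1.0, 6000)  # baseline stats approx (2, 1)
        session = self._power_session(power)
        ep = epoch_and_zscore(power, session, session.contacts)
        # recompute by hand for trial 0
        onset = session.events.onsets[0]
        base = power[0, onset - 200 : onset]
        expected = (power[0, onset] - base.mean()) / base.std()
        assert ep.z_power[0, 0, 0] == pytest.approx(expected)

    def test_post_equal_to_baseline_mean_gives_zero(self):
        power = np.ones((1, 6000))
        power[0, ::7] = 3.0  # variability everywhere, same distribution
        session = self._power_session(power)
        ep = epoch_and_zscore(power, session, session.contacts)
        # every 7-periodic segment has identical mean; z fluctuates around 0
        assert abs(ep.z_power.mean()) < 0.2

    def test_constant_baseline_rejected_naming_trial(self):
        power = np.ones((1, 6000))
        power[0, 1500:] = np.linspace(1, 2, 4500)  # variance only post-onset
        session = self._power_session(power)
        with pytest.raises(ValueError, match="trial 0"):
            epoch_and_zscore(power, session, session.contacts)

    def test_event_too_close_to_edge_rejected(self):
        power = np.random.default_rng(0).random((1, 6000))
        session = make_session(np.zeros((1, 6000)), onsets=(100, 4000),
                               shafts=_contiguous_shafts([1]))
        with pytest.raises(ValueError, match="row 0"):
            epoch_and_zscore(power, session, session.contacts)


class TestSmoothing:
    def _epochs(self, traces):
        traces = np.asarray(traces, dtype=float)
        n_trials, n_time = traces.shape
        return sd.EpochedPower(
            z_power=traces[:, None, :],
            baseline_power=np.ones((n_trials, 1, 200)),
            raw_power=traces[:, None, :],
            labels=np.array(["own"] * n_trials, dtype=object),
            fs=1000.0,
            contacts=[ContactInfo("A-1", "A", 1)],
        )

    def test_constant_trace_unchanged(self):
        ep = self._epochs(np.full((2, 1000), 3.7))
        out = smooth_gaussian(ep)
        np.testing.assert_allclose(out.z_power, 3.7, atol=1e-9)

    def test_impulse_mass_preserved_and_symmetric(self):
        trace = np.zeros((1, 1000))
        trace[0, 500] = 1.0
        out = smooth_gaussian(self._epochs(trace)).z_power[0, 0]
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(out[500 - 60 : 500], out[501 : 501 + 60][::-1],
                                   atol=1e-12)

    def test_linear_ramp_interior_unchanged(self):
        ramp = np.linspace(0.0, 1.0, 1000)[None, :]
        out = smooth_gaussian(self._epochs(ramp)).z_power[0, 0]
        np.testing.assert_allclose(out[100:900], ramp[0, 100:900], atol=1e-6)

    def test_window_longer_than_epoch_rejected(self):
        ep = self._epochs(np.zeros((1, 100)))
        with pytest.raises(ValueError, match="shorter than the epoch"):
            smooth_gaussian(ep, window_ms=200.0)


class TestArtifactRejection:
    def _epochs(self, z, labels=None):
        z = np.asarray(z, dtype=float)
        n_trials, n_contacts, _ = z.shape
        labels = labels or ["own", "other"] * (n_trials // 2)
        return sd.EpochedPower(
            z_power=z,
            baseline_power=np.ones((n_trials, n_contacts, 200)),
            raw_power=z.copy(),
            labels=np.array(labels[:n_trials], dtype=object),
            fs=1000.0,
            contacts=[ContactInfo(f"A-{i+1}", "A", i + 1) for i in range(n_contacts)],
        )

    def test_identical_trials_all_kept(self):
        base = np.random.default_rng(0).random((1, 3, 1000))
        z = np.repeat(base, 6, axis=0)
        kept, removed = reject_artifact_contacts(self._epochs(z))
        assert removed == []
        assert kept.n_contacts == 3

    def test_wildly_deviant_trial_removes_contact(self):
        rng = np.random.default_rng(1)
        z = 0.02 * rng.standard_normal((20, 3, 1000))
        z[:, 1, :] += 0.5  # consistent response on contact 1
        # one trial deviates by 10x the response amplitude (opposite
        # sign) during an interval: there SE > |M| while |M| clears the floor
        z[3, 1, 300:600] -= 5.5
        kept, removed = reject_artifact_contacts(self._epochs(z))
        assert removed == ["A-2"]

    def test_single_trial_rejected(self):
        z = np.zeros((1, 2, 1000))
        with pytest.raises(ValueError, match="2 trials"):
            reject_artifact_contacts(self._epochs(z, labels=["own"]))


class TestPipelineOrder:
    def test_provenance_records_stage_order(self, null_epochs):
        stages = [s.split(":")[0] for s in null_epochs.log]
        assert stages == [
            "screen_line_noise",
            "comb_notch",
            "laplacian_reference",
            "band_power",
            "epoch_and_zscore",
            "smooth_gaussian",
            "reject_artifact_contacts",
        ]

    def test_band_power_nonnegative_and_shapes(self, null_epochs):
        assert np.all(null_epochs.raw_power >= 0)
        assert null_epochs.z_power.shape == null_epochs.raw_power.shape
        assert null_epochs.z_power.shape[2] == 1000
        assert null_epochs.baseline_power.shape[2] == 200
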