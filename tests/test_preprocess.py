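"""Channel rejection, bipolar montage, artifact replacement, filtering,
and epoching."""

import numpy as np
import pytest

from spesnet.preprocess import (
    bipolar_rereference,
    epoch,
    lowpass_filter,
    remove_stim_artifact,
    reject_noisy_channels,
)
from spesnet.types import Recording, StimBlock

from conftest import make_contact


def _rec(samples, fs=1000.0, montage="referential"):
    ids = [f"c{i}" for i in range(np.atleast_2d(samples).shape[0])]
    return Recording(samples=np.atleast_2d(np.asarray(samples, dtype=float)),
                     sampling_rate=fs, channel_ids=ids, montage=montage)


class TestChannelRejection:
    def test_uniform_noise_keeps_everything(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal((4, 2000)))
        kept, report = reject_noisy_channels(rec)
        assert kept == rec.channel_ids and report == []

    def test_noisy_channel_is_the_only_rejection(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 2000))
        x[3] *= 100.0
        kept, report = reject_noisy_channels(_rec(x), sd_multiplier=5.0)
        assert [r["channel_id"] for r in report] == ["c3"]
        assert report[0]["reason"] == "excessive_noise"
        # oracle: direct robust-SD computation agrees with the decision
        from spesnet.preprocess import robust_sd

        sds = robust_sd(x, axis=1)
        assert sds[3] > 5.0 * np.median(sds)

    def test_flat_channel_rejected_as_flat(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 1000))
        x[1] = 4.2
        kept, report = reject_noisy_channels(_rec(x))
        assert report == [{"channel_id": "c1", "reason": "flat", "robust_sd": 0.0}]

    def test_all_rejected_is_an_error(self):
        with pytest.raises(ValueError, match="all channels"):
            reject_noisy_channels(_rec(np.zeros((2, 100))))


class TestBipolarRereference:
    def test_common_mode_cancels(self):
        x = np.vstack([np.sin(np.arange(500) / 10.0)] * 2)
        contacts = [make_contact("c0", index=0), make_contact("c1", index=1)]
        rec = _rec(x)
        derived, dcontacts = bipolar_rereference(rec, contacts)
        assert derived.n_channels == 1
        assert np.allclose(derived.samples, 0.0)
        assert dcontacts[0].contact_id == "c0-c1"

    def test_three_contact_shank_yields_two_channels(self):
        rng = np.random.default_rng(0)
        contacts = [make_contact(f"c{i}", index=i) for i in range(3)]
        derived, _ = bipolar_rereference(_rec(rng.standard_normal((3, 100))), contacts)
        assert derived.n_channels == 2

    def test_label_inheritance_and_boundary_flag(self):
        rng = np.random.default_rng(0)
        contacts = [
            make_contact("c0", "hippocampus", index=0),
            make_contact("c1", "hippocampus", index=1),
            make_contact("c2", "other", index=2),
        ]
        _, dcontacts = bipolar_rereference(_rec(rng.standard_normal((3, 100))), contacts)
        assert dcontacts[0].structure == "hippocampus" and not dcontacts[0].boundary
        assert dcontacts[1].structure == "hippocampus" and dcontacts[1].boundary

    def test_cross_shank_pairs_never_formed(self):
        rng = np.random.default_rng(0)
        contacts = [
            make_contact("c0", index=0, shank="s1"),
            make_contact("c1", index=1, shank="s1"),
            make_contact("c2", index=2, shank="s2"),
            make_contact("c3", index=3, shank="s2"),
        ]
        derived, dcontacts = bipolar_rereference(_rec(rng.standard_normal((4, 100))), contacts)
        assert [c.contact_id for c in dcontacts] == ["c0-c1", "c2-c3"]

    def test_singleton_shank_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        contacts = [
            make_contact("c0", index=0, shank="s1"),
            make_contact("c1", index=1, shank="s1"),
            make_contact("c2", index=2, shank="lonely"),
        ]
        with pytest.warns(UserWarning, match="lonely"):
            derived, _ = bipolar_rereference(_rec(rng.standard_normal((3, 100))), contacts)
        assert derived.n_channels == 1


class TestArtifactRemoval:
    def test_constant_signal_unchanged(self):
        rec = _rec(np.full((2, 5000), 3.7))
        out = remove_stim_artifact(rec, np.array([1000, 2000]))
        assert np.array_equal(out.samples, rec.samples)

    def test_locality_outside_window(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal((2, 5000)))
        onsets = np.array([1000, 2500])
        out = remove_stim_artifact(rec, onsets)
        mask = np.ones(5000, dtype=bool)
        for o in onsets:
            mask[o - 5 : o + 11] = False
        assert np.array_equal(out.samples[:, mask], rec.samples[:, mask])
        assert not np.array_equal(out.samples, rec.samples)

    def test_idempotent_on_cleaned_data(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((1, 4000)))
        onsets = np.array([1500])
        once = remove_stim_artifact(rec, onsets)
        twice = remove_stim_artifact(once, onsets)
        assert np.allclose(once.samples, twice.samples)

    def test_splice_continuity(self):
        rng = np.random.default_rng(2)
        t = np.arange(4000) / 1000.0
        rec = _rec(10 * np.sin(2 * np.pi * 8 * t) + 500 * rng.standard_normal(4000) * 0)
        x = rec.samples.copy()
        x[0, 1495:1511] += 500.0  # square artifact
        out = remove_stim_artifact(_rec(x[0]), np.array([1500]))
        d = np.abs(np.diff(out.samples[0, 1480:1530]))
        assert d.max() < 5 * np.abs(np.diff(rec.samples[0])).max()

    def test_spectrum_preserved_against_clean_oracle(self):
        from spesnet.evaluation import artifact_preservation_experiment

        res = artifact_preservation_experiment(seed=0)
        assert res["locality_max_abs_dev"] == 0.0
        assert res["band_amplitude_rel_dev"] < 0.05
        assert res["peak_amplitude_rel_dev"] < 0.05

    def test_edge_onset_skipped_with_warning(self):
        rec = _rec(np.random.default_rng(0).standard_normal((1, 200)))
        with pytest.warns(UserWarning, match="edge"):
            out = remove_stim_artifact(rec, np.array([5]))
        assert np.array_equal(out.samples, rec.samples)


class TestLowpass:
    def test_passband_amplitude_preserved(self):
        t = np.arange(10000) / 1000.0
        rec = _rec(np.sin(2 * np.pi * 10 * t))
        out = lowpass_filter(rec)
        assert abs(np.abs(out.samples[0, 2000:8000]).max() - 1.0) < 0.01

    def test_stopband_attenuation(self):
        t = np.arange(10000) / 1000.0
        rec = _rec(np.sin(2 * np.pi * 200 * t))
        out = lowpass_filter(rec)
        assert np.abs(out.samples[0, 2000:8000]).max() < 1.0 / 100.0

    def test_zero_phase_symmetric_impulse_response(self):
        x = np.zeros((1, 2001))
        x[0, 1000] = 1.0
        out = lowpass_filter(_rec(x)).samples[0]
        assert np.argmax(np.abs(out)) == 1000
        assert np.allclose(out[1000 - 200 : 1000], out[1001 : 1201][::-1], atol=1e-10)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(_rec(np.zeros((1, 100))), cutoff_hz=500.0)

    def test_order_of_artifact_removal_and_filtering_matters(self):
        """Filtering first smears the broadband artifact beyond the window."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 6000))
        x[0, 1995:2011] += 800.0
        onsets = np.array([2000])
        clean_first = lowpass_filter(remove_stim_artifact(_rec(x[0]), onsets))
        filter_first = remove_stim_artifact(lowpass_filter(_rec(x[0])), onsets)
        assert not np.allclose(clean_first.samples, filter_first.samples, atol=1e-3)
        # residual artifact energy just outside the window is larger when
        # filtering happens first
        seg = slice(2011, 2060)
        assert (
            np.abs(filter_first.samples[0, seg]).max()
            > np.abs(clean_first.samples[0, seg]).max()
        )


class TestEpoching:
    def _block(self, onsets, isi=1.0):
        return StimBlock("a", "b", np.asarray(onsets), 4.0, isi)

    def test_two_second_isi_window(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal((2, 120000)))
        onsets = 1000 + np.arange(50) * 2000
        es = epoch(rec, self._block(onsets, isi=2.0))
        assert es.data.shape == (2, 50, 2001)
        assert es.window_ms == (-500.0, 1500.0)
        assert es.baseline_ms == (-500.0, -10.0)

    def test_one_second_isi_window(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal((1, 60000)))
        onsets = 500 + np.arange(50) * 1000
        es = epoch(rec, self._block(onsets))
        assert es.data.shape[2] == 1001
        assert es.baseline_ms == (-250.0, -10.0)

    def test_edge_trial_dropped_and_counted(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal((1, 3000)))
        es = epoch(rec, self._block([100, 1500]))
        assert es.n_trials == 1 and es.n_dropped_trials == 1

    def test_no_usable_trials_is_an_error(self):
        rec = _rec(np.zeros((1, 500)) + np.arange(500))
        with pytest.raises(ValueError, match="usable"):
            epoch(rec, self._block([100]))

    def test_epochs_recover_original_samples(self):
        rng = np.random.default_rng(4)
        rec = _rec(rng.standard_normal((1, 5000)))
        onsets = np.array([1000, 3000])
        es = epoch(rec, self._block(onsets, isi=2.0))
        for k, o in enumerate(onsets):
            assert np.array_equal(es.data[0, k], rec.samples[0, o - 500 : o + 1501])
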