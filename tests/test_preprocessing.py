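"""Filtering, ocular ICA, epoching, artifact rejection, wavelets, z-scoring."""

import numpy as np
import pandas as pd
import pytest

from eventseg import preprocessing as pp
from tests.conftest import make_epochs

SF = 250.0


@pytest.fixture(scope="module")
def filtered_tones():
    n = int(120 * SF)
    t = np.arange(n) / SF
    x = np.vstack(
        [np.sin(2 * np.pi * 60 * t), np.sin(2 * np.pi * 10 * t), np.full(n, 7.0)]
    )
    with pytest.warns(UserWarning, match="Nyquist"):
        y = pp.filter_continuous(x, SF)
    core = slice(int(10 * SF), int(110 * SF))
    return x[:, core], y[:, core]


class TestFilter:
    def test_line_noise_attenuated(self, filtered_tones):
        x, y = filtered_tones
        assert y[0].std() / x[0].std() < 0.10

    def test_passband_preserved(self, filtered_tones):
        x, y = filtered_tones
        assert y[1].std() / x[1].std() == pytest.approx(1.0, abs=0.05)

    def test_dc_removed(self, filtered_tones):
        _, y = filtered_tones
        assert np.abs(y[2]).mean() < 0.05


class TestOcularRemoval:
    def _mixing_setup(self, coupled: bool, seed=0):
        """16 scalp + 2 EOG channels from known sources; one blink source.

        At least ~11 components are needed for a single outlying
        EOG-correlation to be able to reach |z| > 3 within its distribution.
        """
        rng = np.random.default_rng(seed)
        n = 20_000
        sources = rng.laplace(size=(16, n))
        blink = np.zeros(n)
        for s0 in range(500, n - 200, 1500):
            blink[s0 : s0 + 75] += np.hanning(75)
        if coupled:
            sources[0] = blink * 8 + 0.05 * rng.standard_normal(n)
        A = rng.standard_normal((16, 16))
        scalp = A @ sources
        eog = np.vstack(
            [blink * 50 + rng.standard_normal(n), blink * 45 + rng.standard_normal(n)]
        )
        data = np.vstack([scalp, eog])
        names = [f"ch{i}" for i in range(16)] + ["VEOG1", "VEOG2"]
        return data, names, blink

    def test_planted_blink_component_removed(self):
        data, names, blink = self._mixing_setup(coupled=True)
        clean, info = pp.remove_ocular_components(
            data, names, ["VEOG1", "VEOG2"], seed=1
        )
        assert len(info["excluded"]) >= 1
        for ch in range(16):
            r = np.corrcoef(clean[ch], blink)[0, 1]
            assert abs(r) < 0.1

    def test_no_coupling_reconstruction_close(self):
        data, names, _ = self._mixing_setup(coupled=False, seed=2)
        clean, info = pp.remove_ocular_components(
            data, names, ["VEOG1", "VEOG2"], seed=1
        )
        if len(info["excluded"]) == 0:
            scale = np.abs(data[:16]).max()
            assert np.abs(clean[:16] - data[:16]).max() < 1e-6 * scale

    def test_exactly_one_outlying_component_removed(self):
        data, names, _ = self._mixing_setup(coupled=True, seed=3)
        _, info = pp.remove_ocular_components(data, names, ["VEOG1", "VEOG2"], seed=4)
        # the planted blink source is the single strong EOG correlate
        strong = (np.abs(info["correlations"]) > 0.5).any(axis=1)
        assert strong.sum() == 1
        assert len(info["excluded"]) == 1

    def test_requires_two_eog_channels(self):
        data = np.random.default_rng(0).standard_normal((4, 1000))
        with pytest.raises(ValueError):
            pp.remove_ocular_components(data, ["a", "b", "c", "E"], ["E"])


class TestEpoching:
    def test_constant_channel_becomes_zero(self):
        data = np.full((2, 3000), 7.0)
        ep = pp.epoch_and_baseline(data, SF, [500, 1200], ["a", "b"])
        assert np.allclose(ep.data, 0.0)

    def test_step_function_hand_computed(self):
        data = np.zeros((1, 2000))
        onset = 1000
        data[0, onset:] = 10.0
        ep = pp.epoch_and_baseline(data, SF, [onset], ["a"])
        pre = ep.data[0, 0, ep.times < 0]
        post = ep.data[0, 0, ep.times >= 0]
        assert np.allclose(pre, 0.0)
        assert np.allclose(post, 10.0)

    def test_time_axis_inclusive(self):
        data = np.zeros((1, 2000))
        ep = pp.epoch_and_baseline(data, SF, [1000], ["a"])
        assert ep.times[0] == pytest.approx(-0.1)
        assert ep.times[-1] == pytest.approx(1.0)
        assert ep.data.shape[2] == int(1.1 * SF) + 1

    def test_edge_onsets_dropped(self):
        data = np.zeros((1, 1000))
        meta = pd.DataFrame({"k": [0, 1, 2]})
        ep = pp.epoch_and_baseline(data, SF, [5, 500, 990], ["a"], metadata=meta)
        assert ep.n_epochs == 1
        assert ep.metadata["k"].tolist() == [1]

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((3, 4000))
        k = 17
        shifted = np.concatenate([np.zeros((3, k)), data], axis=1)
        a = pp.epoch_and_baseline(data, SF, [1000, 2000], ["x", "y", "z"])
        b = pp.epoch_and_baseline(shifted, SF, [1000 + k, 2000 + k], ["x", "y", "z"])
        assert np.allclose(a.data, b.data)


class TestRejection:
    @staticmethod
    def brute_force_mask(data, sfreq, threshold=250.0, win_s=0.2, step_s=0.05):
        """Independent O(n*w) oracle over every window and channel."""
        n_ep, n_ch, n_t = data.shape
        win = int(round(win_s * sfreq))
        step = int(round(step_s * sfreq))
        mask = np.zeros(n_ep, bool)
        for e in range(n_ep):
            for s in range(0, n_t, step):
                length = min(win, n_t - s)
                if length < win and 2 * length < win:
                    continue
                for c in range(n_ch):
                    seg = data[e, c, s : s + length]
                    if seg.max() - seg.min() > threshold:
                        mask[e] = True
        return mask

    def test_flat_epochs_not_rejected(self):
        ep = make_epochs(np.zeros((5, 3, 276)))
        assert not pp.reject_artifacts(ep).any()

    def test_single_large_spike_rejected(self):
        data = np.zeros((2, 2, 276))
        data[1, 0, 100] = 300.0
        ep = make_epochs(data)
        assert pp.reject_artifacts(ep).tolist() == [False, True]

    def test_spike_in_tail_partial_window_detected(self):
        data = np.zeros((1, 1, 276))
        data[0, 0, -3] = 300.0  # inside the final partial window
        ep = make_epochs(data)
        assert pp.reject_artifacts(ep).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mask_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((100, 4, 276)) * 35
        data[rng.random(100) < 0.3] *= 2.5  # push some epochs over threshold
        ep = make_epochs(data)
        got = pp.reject_artifacts(ep)
        want = self.brute_force_mask(data, SF)
        assert (got == want).all()
        assert want.any() and not want.all()


class TestSpectral:
    def test_frequency_axis(self):
        f = pp.DEFAULT_FREQS
        assert len(f) == 30
        assert f[0] == pytest.approx(4.0)
        assert f[-1] == pytest.approx(100.0)
        assert np.allclose(np.diff(np.log(f)), np.diff(np.log(f))[0])

    def test_pure_tone_peaks_at_nearest_axis_frequency(self):
        times = np.arange(int(1.1 * SF) + 1) / SF
        tone = np.sin(2 * np.pi * 10.0 * times)
        ep = make_epochs(np.tile(tone, (2, 1, 1)))
        pw = pp.spectral_power(ep, average_time=True)
        peak = pw.freqs[pw.power[0, 0].argmax()]
        nearest = pw.freqs[np.abs(pw.freqs - 10.0).argmin()]
        assert peak == nearest

    def test_amplitude_doubling_adds_log10_four(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1, 276))
        a = pp.spectral_power(make_epochs(x), average_time=False)
        b = pp.spectral_power(make_epochs(2 * x), average_time=False)
        assert np.allclose(b.power - a.power, np.log10(4.0), atol=1e-4)

    def test_above_nyquist_rejected(self):
        ep = make_epochs(np.zeros((2, 1, 276)), sfreq=150.0)
        with pytest.raises(ValueError, match="Nyquist"):
            pp.spectral_power(ep)

    def test_mirror_buffer_close_to_true_context_at_center(self):
        """Power at epoch center barely changes when real data replace mirrors."""
        rng = np.random.default_rng(3)
        n_t = 276
        long = rng.standard_normal((1, 3 * n_t))
        center = make_epochs(long[None, :, n_t : 2 * n_t])
        mirrored = pp.spectral_power(center, average_time=False)
        # same wavelets on the true surrounding samples
        import mne

        tfr = mne.time_frequency.tfr_array_morlet(
            long[None], sfreq=SF, freqs=pp.DEFAULT_FREQS, n_cycles=4.0,
            output="power", verbose="error",
        )
        true_core = np.log10(tfr[:, :, :, n_t : 2 * n_t])
        mid = slice(n_t // 2 - 10, n_t // 2 + 10)
        a = mirrored.power[0, 0, :, mid]
        b = true_core[0, 0, :, mid]
        rel = np.abs(a - b) / np.abs(b)
        assert rel.max() < 0.01


class TestZScore:
    def test_mean_zero_sd_one_to_tolerance(self, small_epochs):
        retained = small_epochs.retained()
        pw = pp.spectral_power(
            retained, freqs=np.logspace(np.log10(4), np.log10(40), 8),
            average_time=True, channel_chunk=34,
        )
        z = pp.zscore_features(pw)
        assert np.abs(z.power.mean(axis=0)).max() < 1e-10
        assert np.abs(z.power.std(axis=0) - 1).max() < 1e-10

    def test_three_epoch_toy_hand_computed(self):
        vals = np.array([1.0, 2.0, 6.0])
        pw = pp.SpectralPower(
            power=vals.reshape(3, 1, 1), freqs=np.array([10.0]),
            ch_names=["a"], metadata=pd.DataFrame({"epoch": range(3)}),
        )
        z = pp.zscore_features(pw)
        mu, sd = 3.0, np.sqrt(((vals - 3.0) ** 2).mean())
        assert np.allclose(z.power.ravel(), (vals - mu) / sd)

    def test_epoch_permutation_permutes_rows(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((20, 3, 4))
        pw = lambda arr: pp.SpectralPower(
            power=arr, freqs=np.arange(4.0, 8.0), ch_names=["a", "b", "c"],
            metadata=pd.DataFrame({"epoch": range(20)}),
        )
        perm = rng.permutation(20)
        z1 = pp.zscore_features(pw(x)).power
        z2 = pp.zscore_features(pw(x[perm])).power
        assert np.allclose(z1[perm], z2)

    def test_zero_variance_feature_named(self):
        x = np.random.default_rng(0).standard_normal((5, 2, 2))
        x[:, 1, 0] = 3.14
        pw = pp.SpectralPower(
            power=x, freqs=np.array([4.0, 8.0]), ch_names=["good", "flat"],
            metadata=pd.DataFrame({"epoch": range(5)}),
        )
        with pytest.raises(ValueError, match="flat"):
            pp.zscore_features(pw)

    def test_single_epoch_rejected(self):
        pw = pp.SpectralPower(
            power=np.ones((1, 2, 2)), freqs=np.array([4.0, 8.0]),
            ch_names=["a", "b"], metadata=pd.DataFrame({"epoch": [0]}),
        )
        with pytest.raises(ValueError):
            pp.zscore_features(pw)

    def test_time_resolved_uses_epoch_level_statistics(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((10, 2, 3, 50)).astype(np.float64)
        pw = pp.SpectralPower(
            power=x, freqs=np.arange(3.0, 6.0), ch_names=["a", "b"],
            metadata=pd.DataFrame({"epoch": range(10)}),
            times=np.arange(50) / 250.0, sfreq=250.0,
        )
        z = pp.zscore_features(pw)
        # epoch-averaged z values are standardized...
        em = z.power.mean(axis=3)
        assert np.abs(em.mean(axis=0)).max() < 1e-10
        # ...but per-sample SD is not forced to 1 (dynamics preserved)
        assert not np.allclose(z.power.std(axis=0), 1.0, atol=1e-3)


class TestInvariantsAfterRejection:
    def test_zscore_on_retained_subset(self, small_epochs):
        sub = small_epochs.retained()
        freqs = np.logspace(np.log10(5), np.log10(20), 4)
        pw = pp.spectral_power(sub, freqs=freqs, average_time=True, channel_chunk=34)
        # rejecting an arbitrary further subset and recomputing still yields
        # exact standardization on the survivors
        pw.power = pw.power[5:]
        pw.metadata = pw.metadata.iloc[5:].reset_index(drop=True)
        z = pp.zscore_features(pw)
        assert np.abs(z.power.mean(axis=0)).max() < 1e-10
        assert np.abs(z.power.std(axis=0) - 1).max() < 1e-10


def test_features_matrix_layout():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((6, 2, 3))
    pw = pp.SpectralPower(
        power=x, freqs=np.array([4.0, 8.0, 16.0]), ch_names=["A", "B"],
        metadata=pd.DataFrame({"epoch": range(6)}),
    )
    X, index = pp.features_matrix(pw)
    assert X.shape == (6, 6)
    assert index[0] == ("A", 4.0)
    assert index[3] == ("B", 4.0)
    assert np.allclose(X[:, 4], x[:, 1, 1])
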