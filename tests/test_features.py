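import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pcgnet as pn
from pcgnet.features import LOG_FLOOR, MfccConfig, mel_filterbank


class TestFrameCount:
    @pytest.mark.parametrize(
        "fs,sec,winlength,winstep,expected",
        [
            (8000, 1.4, 1600, 800, 13),
            (2000, 1.4, 400, 200, 13),
            (8000, 0.2, 1600, 800, 1),
        ],
    )
    def test_known_values(self, fs, sec, winlength, winstep, expected):
        assert pn.frame_count(fs, sec, winlength, winstep) == expected

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError):
            pn.frame_count(8000, 0.1, 1600, 800)

    @settings(max_examples=50, deadline=None)
    @given(
        n_extra=st.integers(0, 20000),
        fs=st.sampled_from([2000, 8000]),
    )
    def test_matches_actual_framing(self, n_extra, fs):
        """The formula always agrees with the number of frames the extractor
        actually produces."""
        cfg = MfccConfig()
        winlength = cfg.winlength(fs)
        n = winlength + n_extra
        rec = pn.AudioRecording(np.random.default_rng(0).normal(size=n), fs=fs)
        fm = pn.extract_mfcc(rec, cfg)
        assert fm.frames == pn.frame_count(fs, n / fs, winlength, cfg.winstep(fs))


class TestPreEmphasize:
    def test_alpha_zero_identity(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_array_equal(pn.pre_emphasize(x, 0.0), x)

    def test_constant_signal(self):
        y = pn.pre_emphasize(np.ones(10), 0.97)
        assert y[0] == 1.0
        np.testing.assert_allclose(y[1:], 0.03)

    def test_alternating_signal(self):
        x = np.array([1.0, -1.0] * 5)
        y = pn.pre_emphasize(x, 0.97)
        np.testing.assert_allclose(np.abs(y[1:]), 1.97)


def _naive_mfcc(samples, fs, cfg):
    """Independent loop-based reference: explicit framing, window, triangle
    filters and the DCT-II cosine formula (orthonormal scaling)."""
    x = np.asarray(samples, dtype=float).copy()
    for i in range(x.size - 1, 0, -1):
        x[i] = x[i] - cfg.pre_emphasis * x[i - 1]
    wl, ws = cfg.winlength(fs), cfg.winstep(fs)
    n_frames = (x.size - wl) // ws + 1
    ham = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(wl) / (wl - 1))

    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10 ** (m / 2595.0) - 1.0)

    edges = imel(np.linspace(mel(0), mel(fs / 2), cfg.n_mels + 2))
    nbins = cfg.n_fft // 2 + 1
    out = np.zeros((cfg.n_static, n_frames))
    for t in range(n_frames):
        frame = x[t * ws : t * ws + wl] * ham
        spec = np.fft.rfft(frame, n=cfg.n_fft)
        power = (spec * spec.conj()).real
        logeng = np.zeros(cfg.n_mels)
        for m in range(cfg.n_mels):
            e = 0.0
            for b in range(nbins):
                f = b * fs / cfg.n_fft
                if edges[m] <= f <= edges[m + 1]:
                    w = (f - edges[m]) / (edges[m + 1] - edges[m])
                elif edges[m + 1] < f <= edges[m + 2]:
                    w = (edges[m + 2] - f) / (edges[m + 2] - edges[m + 1])
                else:
                    w = 0.0
                e += w * power[b]
            logeng[m] = np.log(max(e, LOG_FLOOR))
        for k in range(cfg.n_static):
            scale = np.sqrt(1.0 / cfg.n_mels) if k == 0 else np.sqrt(2.0 / cfg.n_mels)
            out[k, t] = scale * np.sum(
                logeng * np.cos(np.pi * k * (2 * np.arange(cfg.n_mels) + 1) / (2 * cfg.n_mels))
            )
    return out


class TestExtractMfcc:
    @pytest.mark.parametrize("fs", [2000, 8000])
    def test_default_geometry_17x13(self, fs):
        rec = pn.AudioRecording(
            np.random.default_rng(0).normal(size=round(1.4 * fs)), fs=fs
        )
        fm = pn.extract_mfcc(rec)
        assert (fm.dims, fm.frames) == (17, 13)

    def test_silence_finite_and_columns_identical(self):
        rec = pn.AudioRecording(np.zeros(11200), fs=8000)
        fm = pn.extract_mfcc(rec)
        assert np.all(np.isfinite(fm.values))
        np.testing.assert_allclose(fm.values, np.tile(fm.values[:, :1], (1, fm.frames)))

    def test_polarity_flip_invariance(self, rng):
        x = rng.normal(size=2800)
        cfg = MfccConfig()
        a = pn.extract_mfcc(pn.AudioRecording(x, fs=2000), cfg)
        b = pn.extract_mfcc(pn.AudioRecording(-x, fs=2000), cfg)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_amplitude_scaling_shifts_only_energy_coefficient(self, rng):
        x = rng.normal(size=2800)
        cfg = MfccConfig()
        a = pn.extract_mfcc(pn.AudioRecording(x, fs=2000), cfg)
        b = pn.extract_mfcc(pn.AudioRecording(7.0 * x, fs=2000), cfg)
        # log power scales by 2*ln(7) in every mel band -> only DCT
        # coefficient 0 moves
        np.testing.assert_allclose(a.values[1:], b.values[1:], atol=1e-8)
        shift = b.values[0] - a.values[0]
        np.testing.assert_allclose(shift, shift[0], atol=1e-8)
        assert shift[0] > 0

    @pytest.mark.parametrize("kind", ["noise", "tone"])
    def test_agrees_with_naive_reference(self, rng, kind):
        """Vectorized extraction matches an independent loop-based reference
        on both broadband and mel-band-centered tonal inputs."""
        fs = 2000
        cfg = MfccConfig(n_fft=512, n_mels=12, n_static=8)
        if kind == "noise":
            x = rng.normal(size=1000)
        else:
            fb = mel_filterbank(cfg.n_mels, cfg.n_fft, fs)
            f_tone = fb[6].argmax() * fs / cfg.n_fft  # center of mel band 6
            x = np.sin(2 * np.pi * f_tone * np.arange(1000) / fs)
        fast = pn.extract_mfcc(pn.AudioRecording(x, fs=fs), cfg).values
        slow = _naive_mfcc(x, fs, cfg)
        np.testing.assert_allclose(fast, slow, rtol=1e-8, atol=1e-8)

    def test_window_longer_than_nfft_rejected(self):
        rec = pn.AudioRecording(np.zeros(11200), fs=8000)
        with pytest.raises(ValueError):
            pn.extract_mfcc(rec, MfccConfig(n_fft=1024))


class TestComputeDeltas:
    def test_constant_map_zero_deltas(self):
        fm = pn.FeatureMap(np.tile(np.arange(13.0)[:, None], (1, 13)))
        out = pn.compute_deltas(fm)
        assert out.dims == 39
        np.testing.assert_allclose(out.values[13:], 0.0, atol=1e-12)

    def test_linear_ramp_delta_equals_slope(self):
        c = 0.7
        base = np.arange(13.0)[None, :] * c
        out = pn.compute_deltas(pn.FeatureMap(np.tile(base, (3, 1))))
        # interior frames of the delta rows equal the per-frame increment
        np.testing.assert_allclose(out.values[3:6, 2:-2], c, atol=1e-12)

    def test_17_static_rows_give_51(self):
        fm = pn.FeatureMap(np.random.default_rng(0).normal(size=(17, 13)))
        assert pn.compute_deltas(fm).dims == 51

    def test_13_static_rows_give_39(self):
        fm = pn.FeatureMap(np.random.default_rng(0).normal(size=(13, 13)))
        assert pn.compute_deltas(fm).dims == 39

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            pn.compute_deltas(pn.FeatureMap(np.zeros((13, 2))))


class TestMFCCTransformer:
    def test_transform_stacks_standardized_maps(self):
        recs = [
            pn.AudioRecording(np.random.default_rng(i).normal(size=n), fs=8000)
            for i, n in enumerate([8000, 11200, 30000])
        ]
        X = pn.MFCCTransformer().fit_transform(recs)
        assert X.shape == (3, 17, 13)

    def test_delta_mode_uses_13_static_rows(self):
        recs = [pn.AudioRecording(np.random.default_rng(0).normal(size=11200), fs=8000)]
        X = pn.MFCCTransformer(n_static=13, include_deltas=True).fit_transform(recs)
        assert X.shape == (1, 39, 13)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        tr = pn.MFCCTransformer(n_static=15)
        assert clone(tr).get_params()["n_static"] == 15
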