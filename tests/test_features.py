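"""Frame measures, the 102-feature grid, and the design matrix."""

import numpy as np
import pytest

from usvkit import (
    FEATURE_NAMES,
    DesignMatrix,
    build_design_matrix,
    call_features,
    frame_measures,
)
from usvkit.detection import DetectionParams, detect_elements
from usvkit.spectral import SpectrogramConfig, compute_spectrogram, highpass_filter
from usvkit.synth import CallSpec, Segment, Waveform, synthesize_waveform

CFG = SpectrogramConfig()
BIN_HZ = 488.28125


def test_feature_grid_shape_and_names():
    assert len(FEATURE_NAMES) == 102
    assert len(set(FEATURE_NAMES)) == 102
    for name in (
        "peak freq (stddeventire)",
        "quart 50 (start)",
        "bandw (start)",
        "fundamental (max)",
        "entropy (mean)",
        "min freq (meanentire)",
        "quart 75 (stddeventire)",
        "entropy (maxentire)",
        "bandw (maxentire)",
        "duration",
        "peaktopeak",
    ):
        assert name in FEATURE_NAMES


def _tone_frame(freq_hz: float = 70_000.0):
    """A Hamming-tapered pure-tone frame's magnitude spectrum."""
    t = np.arange(512) / 250_000
    frame = np.sin(2 * np.pi * freq_hz * t) * np.hamming(512)
    mag = np.abs(np.fft.rfft(frame))
    freqs = np.fft.rfftfreq(512, d=1 / 250_000)
    return mag, freqs


def test_pure_tone_frame_measures():
    mag, freqs = _tone_frame(70_000.0)
    fm = frame_measures(mag, freqs)
    assert abs(fm.peak_freq_hz - 70_000.0) <= BIN_HZ
    assert abs(fm.quart50_hz - 70_000.0) <= BIN_HZ
    assert abs(fm.fundamental_hz - 70_000.0) <= BIN_HZ
    assert fm.entropy < 0.3


def test_uniform_spectrum_measures():
    # flat magnitude over the 30-120 kHz band: median = band midpoint
    freqs = np.arange(30_000.0, 120_000.0 + 1, BIN_HZ)
    mag = np.ones_like(freqs)
    fm = frame_measures(mag, freqs)
    assert abs(fm.quart50_hz - 75_000.0) <= BIN_HZ
    assert fm.entropy > 0.95
    assert abs(fm.quart25_hz - 52_500.0) <= 2 * BIN_HZ
    assert abs(fm.quart75_hz - 97_500.0) <= 2 * BIN_HZ


def test_frame_measures_scale_equivariance():
    mag, freqs = _tone_frame()
    a = frame_measures(mag, freqs)
    b = frame_measures(10.0 * mag, freqs)
    assert b.peak_ampl == pytest.approx(10.0 * a.peak_ampl)
    for attr in (
        "peak_freq_hz",
        "min_freq_hz",
        "max_freq_hz",
        "bandwidth_hz",
        "quart25_hz",
        "quart50_hz",
        "quart75_hz",
        "entropy",
        "fundamental_hz",
    ):
        assert getattr(b, attr) == pytest.approx(getattr(a, attr))


def test_frame_measures_ordering_chain(rng):
    for _ in range(100):
        mag, freqs = _tone_frame(rng.uniform(40_000, 110_000))
        mag = mag + rng.uniform(0, 0.1 * mag.max(), size=mag.shape)
        fm = frame_measures(mag, freqs)
        assert (
            fm.min_freq_hz
            <= fm.quart25_hz
            <= fm.quart50_hz
            <= fm.quart75_hz
            <= fm.max_freq_hz
        )
        assert 0.0 <= fm.entropy <= 1.0
        assert fm.bandwidth_hz >= 0.0


def test_noise_entropy_exceeds_tone_entropy(rng):
    freqs = np.fft.rfftfreq(512, d=1 / 250_000)
    for _ in range(100):
        tone_mag, _ = _tone_frame(rng.uniform(40_000, 110_000))
        noise = np.abs(np.fft.rfft(rng.normal(size=512) * np.hamming(512)))
        assert frame_measures(noise, freqs).entropy > frame_measures(tone_mag, freqs).entropy


def test_all_zero_frame_rejected():
    freqs = np.fft.rfftfreq(512, d=1 / 250_000)
    with pytest.raises(ValueError, match="silent"):
        frame_measures(np.zeros_like(freqs), freqs)


def test_no_passband_bins_rejected():
    freqs = np.linspace(0, 20_000, 50)
    with pytest.raises(ValueError, match="high-pass"):
        frame_measures(np.ones(50), freqs)


# --- call-level features ---------------------------------------------------

def _featurize(spec: CallSpec, gain: float = 1.0):
    w = synthesize_waveform(spec)
    w = Waveform(samples=gain * w.samples, fs_hz=w.fs_hz)
    hp = highpass_filter(w, CFG.highpass_hz)
    sg = compute_spectrogram(hp, CFG)
    elements = detect_elements(sg, DetectionParams())
    assert elements
    return call_features(elements, sg, w), elements, sg


def test_constant_call_positional_features():
    spec = CallSpec("flat", 40.0, [[Segment(0.0, 40.0, 70.0, 70.0)]], snr_db=40.0, seed=3)
    values, _, _ = _featurize(spec)
    names = list(FEATURE_NAMES)
    std = values[names.index("peak freq (stddeventire)")]
    start = values[names.index("peak freq (start)")]
    end = values[names.index("peak freq (end)")]
    assert std < BIN_HZ
    assert abs(start - end) <= BIN_HZ


def test_duration_identity():
    spec = CallSpec("flat", 40.0, [[Segment(0.0, 40.0, 70.0, 70.0)]], snr_db=20.0, seed=5)
    values, elements, sg = _featurize(spec)
    first = min(e.frame_start for e in elements)
    last = max(e.frame_end for e in elements)
    dur = values[list(FEATURE_NAMES).index("duration")]
    assert dur == pytest.approx((last - first + 1) * sg.config.hop_ms)


def test_upward_call_positional_rise():
    spec = CallSpec("upward", 40.0, [[Segment(0.0, 40.0, 50.0, 65.0)]], snr_db=40.0, seed=2)
    values, _, _ = _featurize(spec)
    names = list(FEATURE_NAMES)
    rise = values[names.index("peak freq (end)")] - values[names.index("peak freq (start)")]
    assert rise >= 12_500.0 - 2 * BIN_HZ


def test_gain_equivariance():
    spec = CallSpec("flat", 40.0, [[Segment(0.0, 40.0, 70.0, 70.0)]], snr_db=30.0, seed=9)
    base, _, _ = _featurize(spec, gain=1.0)
    names = list(FEATURE_NAMES)
    scaled_cols = [
        i
        for i, n in enumerate(names)
        if n.startswith("peak ampl") or n == "peaktopeak"
    ]
    invariant_cols = [i for i in range(len(names)) if i not in scaled_cols]
    for gain in (0.1, 10.0):
        v, _, _ = _featurize(spec, gain=gain)
        assert np.allclose(v[scaled_cols], gain * base[scaled_cols], rtol=1e-6)
        assert np.allclose(v[invariant_cols], base[invariant_cols], rtol=1e-6)


def test_empty_element_list_rejected():
    spec = CallSpec("flat", 40.0, [[Segment(0.0, 40.0, 70.0, 70.0)]], snr_db=40.0, seed=1)
    w = synthesize_waveform(spec)
    sg = compute_spectrogram(highpass_filter(w, CFG.highpass_hz), CFG)
    with pytest.raises(ValueError, match="element"):
        call_features([], sg, w)


# --- design matrix ---------------------------------------------------------

def test_small_design_matrix_shape(small_dm):
    assert small_dm.shape == (27, 102)
    assert not np.isnan(small_dm.X).any()
    assert small_dm.feature_names == FEATURE_NAMES


def test_design_matrix_determinism(small_corpus, small_dm):
    again = build_design_matrix(small_corpus)
    assert np.array_equal(again.X, small_dm.X)
    assert again.y == small_dm.y


def test_design_matrix_rejects_nan():
    with pytest.raises(ValueError, match="missing"):
        DesignMatrix(
            X=np.array([[1.0, np.nan]]),
            y=["flat"],
            feature_names=("a", "b"),
            call_ids=["c0"],
        )


def test_design_matrix_csv_round_trip(tmp_path, small_dm):
    path = tmp_path / "features.csv"
    small_dm.to_csv(path)
    back = DesignMatrix.from_csv(path)
    assert back.shape == small_dm.shape
    assert back.y == small_dm.y
    assert back.call_ids == small_dm.call_ids
    assert np.allclose(back.X, small_dm.X)


def test_class_discriminative_sanity(full_dm):
    names = list(full_dm.feature_names)
    y = np.asarray(full_dm.y)
    dur = full_dm.X[:, names.index("duration")]
    short_mean = dur[y == "short"].mean()
    for c in set(y) - {"short"}:
        assert short_mean < dur[y == c].mean()
    # flat has the least peak-frequency spread among the longer
    # single-component classes (short spans too few frames to compete)
    std = full_dm.X[:, names.index("peak freq (stddeventire)")]
    flat_mean = std[y == "flat"].mean()
    for c in ("upward", "downward", "chevron", "complex", "frequency step"):
        assert flat_mean < std[y == c].mean()
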