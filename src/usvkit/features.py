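"""The 102-measure acoustic feature set.

Ten frame-wise spectral measures (peak frequency and amplitude, -20 dB
minimum/maximum frequency, bandwidth, the 25/50/75 % spectral-energy
quartile frequencies, Wiener entropy, and the fundamental) are aggregated
ten ways: at the start/centre/end of the principal element, as
mean/min/max over the principal element, and as mean/min/max/standard
deviation over all signal frames of all elements ("entire" variants).
Together with the call duration and the waveform peak-to-peak amplitude
this yields 102 measures per call, assembled into a design matrix of one
row per call.

All spectral measures are computed on the high-passed band only (bins at or
above the 30 kHz cutoff by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import CallElement, default_detection_params, detect_elements
from .spectral import Spectrogram, SpectrogramConfig, compute_spectrogram, highpass_filter
from .synth import LabeledCorpus, Waveform

MEASURES = (
    "peak freq",
    "peak ampl",
    "min freq",
    "max freq",
    "bandw",
    "quart 25",
    "quart 50",
    "quart 75",
    "entropy",
    "fundamental",
)

AGGREGATIONS = (
    "start",
    "centre",
    "end",
    "mean",
    "min",
    "max",
    "meanentire",
    "minentire",
    "maxentire",
    "stddeventire",
)

#: Canonical order of the 102 feature names.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{m} ({a})" for m in MEASURES for a in AGGREGATIONS
) + ("duration", "peaktopeak")

#: Relative floor (dB below the frame peak) bounding the min/max frequency
#: and fundamental measurements against noise bins.
REL_FLOOR_DB = -20.0


@dataclass
class FrameMeasures:
    peak_freq_hz: float
    peak_ampl: float
    min_freq_hz: float
    max_freq_hz: float
    bandwidth_hz: float
    quart25_hz: float
    quart50_hz: float
    quart75_hz: float
    entropy: float
    fundamental_hz: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.peak_freq_hz,
                self.peak_ampl,
                self.min_freq_hz,
                self.max_freq_hz,
                self.bandwidth_hz,
                self.quart25_hz,
                self.quart50_hz,
                self.quart75_hz,
                self.entropy,
                self.fundamental_hz,
            ]
        )


def frame_measures(
    spec_column: np.ndarray,
    freqs_hz: np.ndarray,
    highpass_hz: float = 30_000.0,
) -> FrameMeasures:
    """Spectral measures of a single spectrogram frame.

    Operates only on bins at or above ``highpass_hz``.  The frame must carry
    signal: an all-zero frame has no defined measures and is rejected.
    """
    band = freqs_hz >= highpass_hz
    mag = np.asarray(spec_column, dtype=float)[band]
    f = freqs_hz[band]
    if len(mag) == 0:
        raise ValueError("no spectrogram bins above the high-pass cutoff")
    peak_i = int(np.argmax(mag))
    peak = mag[peak_i]
    if peak <= 0:
        raise ValueError("all-zero frame: measures undefined; exclude silent frames")

    floor = peak * 10.0 ** (REL_FLOOR_DB / 20.0)
    above = np.flatnonzero(mag >= floor)
    min_freq = f[above[0]]
    max_freq = f[above[-1]]

    # energy quartiles within the [min_freq, max_freq] band, so the ordering
    # chain min <= q25 <= q50 <= q75 <= max holds on noisy frames too
    lo, hi = above[0], above[-1]
    cum = np.cumsum(mag[lo : hi + 1] ** 2)
    quarts = [
        f[lo + int(np.searchsorted(cum, q * cum[-1]))] for q in (0.25, 0.5, 0.75)
    ]

    # Wiener entropy: geometric / arithmetic mean of the magnitude spectrum
    logmag = np.log(np.maximum(mag, 1e-300))
    entropy = float(np.exp(logmag.mean()) / mag.mean())

    # fundamental: lowest local spectral peak within the relative floor
    interior = np.zeros(len(mag), dtype=bool)
    if len(mag) >= 3:
        interior[1:-1] = (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:])
    interior[0] = len(mag) >= 2 and mag[0] >= mag[1]
    interior[-1] = len(mag) >= 2 and mag[-1] >= mag[-2]
    candidates = np.flatnonzero(interior & (mag >= floor))
    fundamental = f[candidates[0]] if len(candidates) else f[peak_i]

    return FrameMeasures(
        peak_freq_hz=float(f[peak_i]),
        peak_ampl=float(peak),
        min_freq_hz=float(min_freq),
        max_freq_hz=float(max_freq),
        bandwidth_hz=float(max_freq - min_freq),
        quart25_hz=float(quarts[0]),
        quart50_hz=float(quarts[1]),
        quart75_hz=float(quarts[2]),
        entropy=entropy,
        fundamental_hz=float(fundamental),
    )


def call_features(
    elements: list[CallElement],
    spec: Spectrogram,
    wave: Waveform,
) -> np.ndarray:
    """The 102-value feature vector of one call (order :data:`FEATURE_NAMES`).

    Positional aggregations (start/centre/end) and the mean/min/max
    statistics use the signal frames of the principal (longest) element;
    the "entire" variants pool the signal frames of every element.
    """
    if not elements:
        raise ValueError("call_features requires at least one detected element")
    cfg = spec.config

    def element_frames(e: CallElement) -> np.ndarray:
        return np.arange(e.frame_start, e.frame_end + 1)[e.signal_mask]

    principal = max(elements, key=lambda e: e.n_signal_frames)
    pframes = element_frames(principal)
    all_frames = np.concatenate([element_frames(e) for e in elements])

    cache: dict[int, np.ndarray] = {}

    def meas(i: int) -> np.ndarray:
        if i not in cache:
            cache[i] = frame_measures(
                spec.magnitudes[i], spec.freqs_hz, cfg.highpass_hz
            ).as_array()
        return cache[i]

    pmat = np.stack([meas(i) for i in pframes])  # n_frames x 10
    amat = np.stack([meas(i) for i in all_frames])

    centre_target = (principal.frame_start + principal.frame_end) // 2
    centre_i = pframes[np.argmin(np.abs(pframes - centre_target))]

    values = np.empty(len(FEATURE_NAMES))
    k = 0
    for m in range(len(MEASURES)):
        col_p = pmat[:, m]
        col_a = amat[:, m]
        row = {
            "start": meas(pframes[0])[m],
            "centre": meas(centre_i)[m],
            "end": meas(pframes[-1])[m],
            "mean": col_p.mean(),
            "min": col_p.min(),
            "max": col_p.max(),
            "meanentire": col_a.mean(),
            "minentire": col_a.min(),
            "maxentire": col_a.max(),
            "stddeventire": col_a.std(ddof=0),
        }
        for a in AGGREGATIONS:
            values[k] = row[a]
            k += 1

    first = min(e.frame_start for e in elements)
    last = max(e.frame_end for e in elements)
    values[k] = (last - first + 1) * cfg.hop_ms  # duration
    k += 1
    s0 = first * cfg.hop
    s1 = min(last * cfg.hop + cfg.fft_len, len(wave.samples))
    seg = wave.samples[s0:s1]
    values[k] = float(seg.max() - seg.min())  # peaktopeak
    return values


@dataclass
class DesignMatrix:
    """n_calls x 102 feature table with call-type labels."""

    X: np.ndarray
    y: list[str]
    feature_names: tuple[str, ...]
    call_ids: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y):
            raise ValueError("rows of X must match the number of labels")
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "call_id", self.call_ids)
        df.insert(1, "label", self.y)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DesignMatrix":
        df = pd.read_csv(path)
        names = tuple(c for c in df.columns if c not in ("call_id", "label"))
        return cls(
            X=df[list(names)].to_numpy(dtype=float),
            y=df["label"].tolist(),
            feature_names=names,
            call_ids=df["call_id"].astype(str).tolist(),
        )


def build_design_matrix(
    corpus: LabeledCorpus,
    cfg: SpectrogramConfig | None = None,
    params_by_category: dict | None = None,
) -> DesignMatrix:
    """Detect and featurise every call of a labeled corpus.

    Detection settings default to the per-category table
    (:data:`usvkit.detection.CATEGORY_DETECTION`).  Fails loudly, listing the
    offending call ids, if any call yields no detected element.
    """
    if len(corpus.records) == 0:
        raise ValueError("corpus is empty")
    if cfg is None:
        cfg = SpectrogramConfig()
    rows, labels, ids, failed = [], [], [], []
    for rec in corpus.records:
        w = highpass_filter(rec.waveform, cfg.highpass_hz)
        spec = compute_spectrogram(w, cfg)
        if params_by_category and rec.category in params_by_category:
            params = params_by_category[rec.category]
        else:
            params = default_detection_params(rec.category)
        elements = detect_elements(spec, params)
        if not elements:
            failed.append(rec.call_id)
            continue
        rows.append(call_features(elements, spec, rec.waveform))
        labels.append(rec.category)
        ids.append(rec.call_id)
    if failed:
        raise RuntimeError(
            f"detection produced no elements for {len(failed)} call(s): {failed}"
        )
    return DesignMatrix(
        X=np.vstack(rows), y=labels, feature_names=FEATURE_NAMES, call_ids=ids
    )
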