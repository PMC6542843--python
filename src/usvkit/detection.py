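"""Call-element detection on spectrograms.

Implements the three automatic detection modes used in USV parameter
measurement: whistle tracking (ridge following under a frequency-continuity
bound), and two- or three-threshold amplitude hysteresis, followed by
hold-time merging of elements separated by short pauses and a minimum
duration filter.  Thresholds are expressed in dB relative to the file's peak
frame amplitude (the strongest passband bin of any frame), which gains the
STFT's processing margin over broadband noise and keeps the default
hysteresis pair robust down to ~10 dB SNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .spectral import Spectrogram

logger = logging.getLogger(__name__)

MODES = ("whistle_tracking", "two_thresholds", "three_thresholds")


@dataclass(frozen=True)
class DetectionParams:
    mode: str = "whistle_tracking"
    hold_ms: float = 0.0
    min_duration_ms: float = 0.0
    start_rel_db: float = -20.0
    stop_rel_db: float = -30.0
    rearm_rel_db: float = -25.0  # three-threshold intermediate re-arm level
    max_jump_hz: float | None = None  # default: 3 x frequency resolution

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown detection mode {self.mode!r}")
        if self.stop_rel_db > self.start_rel_db:
            raise ValueError("stop_rel_db must be <= start_rel_db")
        if self.hold_ms < 0 or self.min_duration_ms < 0:
            raise ValueError("hold_ms and min_duration_ms must be >= 0")


def _load_category_table() -> dict[str, DetectionParams]:
    path = Path(__file__).parent / "data" / "detection_table.yaml"
    table = yaml.safe_load(path.read_text())
    return {cat: DetectionParams(**params) for cat, params in table.items()}


#: Per-category detection settings for the nine call types: mode, hold time
#: for multi-part calls, and a minimum duration for very brief calls.
#: Shipped as ``data/detection_table.yaml`` inside the package.
CATEGORY_DETECTION: dict[str, DetectionParams] = _load_category_table()

#: Fallback when the call type is unknown ahead of detection.
DEFAULT_DETECTION = DetectionParams(mode="whistle_tracking", hold_ms=25.0)


def default_detection_params(category: str | None = None) -> DetectionParams:
    """Detection settings for a known call type, or the generic default."""
    if category is None:
        return DEFAULT_DETECTION
    try:
        return CATEGORY_DETECTION[category]
    except KeyError:
        raise ValueError(f"no detection settings for category {category!r}") from None


@dataclass
class CallElement:
    """A detected call segment: inclusive frame span with a peak-freq track.

    ``signal_mask`` flags frames carrying signal; frames bridged into the
    element by hold-time merging are masked out and excluded from frame-wise
    feature statistics.
    """

    frame_start: int
    frame_end: int
    peak_track_hz: np.ndarray
    element_index: int = 0
    signal_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame_start > self.frame_end:
            raise ValueError("frame_start must be <= frame_end")
        n = self.frame_end - self.frame_start + 1
        if len(self.peak_track_hz) != n:
            raise ValueError("track length must equal the frame span")
        if self.signal_mask is None:
            self.signal_mask = np.ones(n, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.frame_end - self.frame_start + 1

    @property
    def n_signal_frames(self) -> int:
        return int(self.signal_mask.sum())


def _frame_levels_db(spec: Spectrogram) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame peak passband bin magnitude in dB re file peak, and argmax bin."""
    band = spec.passband
    mags = spec.magnitudes[:, band]
    peak_idx = np.argmax(mags, axis=1)
    peaks = mags[np.arange(len(mags)), peak_idx]
    ref = peaks.max()
    if ref <= 0:
        return np.full(len(mags), -np.inf), peak_idx
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(peaks / ref)
    return db, peak_idx


def detect_elements(spec: Spectrogram, params: DetectionParams) -> list[CallElement]:
    """Segment call elements from a spectrogram.

    Whistle tracking follows the per-frame spectral-peak ridge: an element
    opens when the peak rises above ``start_rel_db`` and continues while it
    stays above ``stop_rel_db`` and moves by at most ``max_jump_hz`` between
    frames.  Threshold modes use frame-amplitude hysteresis (open above
    start, close below stop); the three-threshold mode additionally re-arms
    follow-on elements at the intermediate ``rearm_rel_db`` level.  Elements
    are then merged across gaps shorter than ``hold_ms`` and filtered by
    ``min_duration_ms``.
    """
    db, peak_idx = _frame_levels_db(spec)
    if not np.isfinite(db).any():
        return []
    band_freqs = spec.freqs_hz[spec.passband]
    track_hz_all = band_freqs[peak_idx]
    hop_ms = spec.config.hop_ms
    max_jump = (
        params.max_jump_hz
        if params.max_jump_hz is not None
        else 3.0 * spec.config.freq_resolution_hz
    )

    spans: list[tuple[int, int]] = []
    if params.mode == "whistle_tracking":
        open_ = False
        s = 0
        for i in range(spec.n_frames):
            if not open_:
                if db[i] >= params.start_rel_db:
                    open_, s = True, i
            else:
                if db[i] < params.stop_rel_db or (
                    abs(track_hz_all[i] - track_hz_all[i - 1]) > max_jump
                ):
                    spans.append((s, i - 1))
                    open_ = db[i] >= params.start_rel_db
                    s = i
        if open_:
            spans.append((s, spec.n_frames - 1))
    else:
        rearm = params.mode == "three_thresholds"
        open_ = False
        opened_once = False
        s = 0
        for i in range(spec.n_frames):
            if not open_:
                level = (
                    params.rearm_rel_db if (rearm and opened_once) else params.start_rel_db
                )
                if db[i] >= level:
                    open_, s = True, i
                    opened_once = True
            else:
                if db[i] < params.stop_rel_db:
                    spans.append((s, i - 1))
                    open_ = False
        if open_:
            spans.append((s, spec.n_frames - 1))

    elements = [
        CallElement(
            frame_start=a,
            frame_end=b,
            peak_track_hz=track_hz_all[a : b + 1].copy(),
            element_index=k,
        )
        for k, (a, b) in enumerate(spans)
    ]
    elements = merge_elements(elements, params.hold_ms, hop_ms=hop_ms)
    if params.min_duration_ms > 0:
        elements = [
            e for e in elements if e.n_frames * hop_ms >= params.min_duration_ms
        ]
        for k, e in enumerate(elements):
            e.element_index = k
    return elements


def merge_elements(
    elements: list[CallElement],
    hold_ms: float,
    hop_ms: float = 0.512,
) -> list[CallElement]:
    """Merge adjacent elements whose silent gap is shorter than ``hold_ms``.

    Gap frames are included in the merged span but masked out of
    ``signal_mask``.  Idempotent; ``hold_ms = 0`` is the identity.
    """
    if hold_ms <= 0 or len(elements) < 2:
        return elements
    merged: list[CallElement] = []
    cur = elements[0]
    for nxt in elements[1:]:
        gap_frames = nxt.frame_start - cur.frame_end - 1
        if gap_frames < 0:
            raise ValueError("elements must be sorted and non-overlapping")
        if gap_frames * hop_ms < hold_ms:
            track = np.concatenate(
                [
                    cur.peak_track_hz,
                    np.full(gap_frames, cur.peak_track_hz[-1]),
                    nxt.peak_track_hz,
                ]
            )
            mask = np.concatenate(
                [cur.signal_mask, np.zeros(gap_frames, dtype=bool), nxt.signal_mask]
            )
            cur = CallElement(
                frame_start=cur.frame_start,
                frame_end=nxt.frame_end,
                peak_track_hz=track,
                signal_mask=mask,
            )
        else:
            merged.append(cur)
            cur = nxt
    merged.append(cur)
    for k, e in enumerate(merged):
        e.element_index = k
    return merged


# ---------------------------------------------------------------------------
# Peak-track extraction for rule-based labeling
# ---------------------------------------------------------------------------

def extract_peak_tracks(
    spec: Spectrogram,
    floor_rel_db: float = -25.0,
    secondary_rel_db: float = -15.0,
    min_sep_bins: int = 10,
    simultaneity_frac: float = 0.6,
    bridge_frames: int = 2,
) -> tuple[list[tuple[int, np.ndarray]], float]:
    """Extract per-frame peak-frequency track(s) in kHz from a spectrogram.

    Voiced frames (peak within ``floor_rel_db`` of the file peak) are grouped
    into runs, bridging dropouts of up to ``bridge_frames``.  Within a run, a
    persistent secondary spectral peak (present in >= ``simultaneity_frac``
    of frames, >= ``min_sep_bins`` away from the primary and within
    ``secondary_rel_db`` of the frame peak) splits the run into two
    simultaneous tracks, as produced by composite calls.

    Returns ``(tracks, duration_ms)`` in the form consumed by
    :func:`usvkit.synth.rule_oracle_label`.
    """
    db, peak_idx = _frame_levels_db(spec)
    band = spec.passband
    mags = spec.magnitudes[:, band]
    band_freqs = spec.freqs_hz[band]
    active = db >= floor_rel_db
    if not active.any():
        return [], 0.0

    # runs of voiced frames, bridging tiny dropouts
    idx = np.flatnonzero(active)
    runs: list[tuple[int, int]] = []
    s = p = idx[0]
    for i in idx[1:]:
        if i - p <= bridge_frames + 1:
            p = i
        else:
            runs.append((s, p))
            s = p = i
    runs.append((s, p))

    tracks: list[tuple[int, np.ndarray]] = []
    for a, b in runs:
        prim = peak_idx[a : b + 1]
        n = b - a + 1
        sec = np.full(n, -1, dtype=int)
        for j in range(n):
            row = mags[a + j]
            p0 = prim[j]
            lo = max(0, p0 - min_sep_bins)
            hi = min(len(row), p0 + min_sep_bins + 1)
            masked = row.copy()
            masked[lo:hi] = 0.0
            cand = int(np.argmax(masked))
            if masked[cand] >= row[p0] * 10.0 ** (secondary_rel_db / 20.0):
                sec[j] = cand
        if np.mean(sec >= 0) >= simultaneity_frac:
            both = np.stack(
                [
                    band_freqs[prim],
                    np.where(sec >= 0, band_freqs[np.maximum(sec, 0)], np.nan),
                ]
            )
            low = np.nanmin(both, axis=0)
            high = np.nanmax(both, axis=0)
            # frames with a single peak contribute it to the nearer track
            single = sec < 0
            if single.any():
                med_low, med_high = np.nanmedian(low), np.nanmedian(high)
                f = band_freqs[prim[single]]
                to_low = np.abs(f - med_low) <= np.abs(f - med_high)
                low[single] = np.where(to_low, f, med_low)
                high[single] = np.where(to_low, med_high, f)
            tracks.append((a, low / 1000.0))
            tracks.append((a, high / 1000.0))
        else:
            tracks.append((a, band_freqs[prim] / 1000.0))

    first = min(s for s, _ in tracks)
    last = max(s + len(t) - 1 for s, t in tracks)
    # correct the frame span for temporal smearing by the analysis window:
    # every frame whose window overlaps the call can be voiced, inflating the
    # span by roughly (fft_len - hop) samples
    smear_ms = 1000.0 * (spec.config.fft_len - spec.config.hop) / spec.config.fs_hz
    duration_ms = max(spec.config.hop_ms, (last - first + 1) * spec.config.hop_ms - smear_ms)
    return tracks, duration_ms
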