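"""Synthetic mouse ultrasonic vocalizations.

Generates labeled waveforms for the nine expert call categories used in
pup-USV phenotyping (complex, two-components, upward, downward, chevron,
short, composite, frequency step, flat).  Each category is realised as a
piecewise-linear frequency trajectory satisfying the category's quantitative
rule with margin, rendered by phase-integration FM synthesis at 250 kHz with
additive white Gaussian background noise at a controlled SNR.

A rule oracle (`rule_oracle_label`) applies the printed category definitions
to peak-frequency tracks, providing ground-truth labels independent of the
generator's bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

#: Canonical call-type labels, in the conventional order of the taxonomy.
CATEGORIES: tuple[str, ...] = (
    "complex",
    "two-components",
    "upward",
    "downward",
    "chevron",
    "short",
    "composite",
    "frequency step",
    "flat",
)

#: Quantum of a "directional change" in frequency (kHz).
DIRECTION_CHANGE_KHZ = 6.25
#: Minimum beginning-to-end excursion for upward/downward calls (kHz).
MONOTONE_EXCURSION_KHZ = 12.5
#: Maximum duration of a "short" call (ms).
SHORT_MAX_MS = 5.0
#: Maximum total frequency change of a "flat" call (kHz).
FLAT_MAX_KHZ = 3.0

#: Admissible band for synthetic trajectories: above the 30 kHz high-pass,
#: below Nyquist at 250 kHz sampling.
FREQ_LO_KHZ = 30.0
FREQ_HI_KHZ = 125.0

DEFAULT_FS_HZ = 250_000
DEFAULT_SNR_DB = 20.0
DEFAULT_PAD_MS = 15.0


@dataclass(frozen=True)
class Segment:
    """One linear piece of a frequency trajectory (times in ms, freqs in kHz)."""

    t0_ms: float
    t1_ms: float
    f0_khz: float
    f1_khz: float

    def freq_at(self, t_ms: float) -> float:
        if self.t1_ms == self.t0_ms:
            return self.f0_khz
        a = (t_ms - self.t0_ms) / (self.t1_ms - self.t0_ms)
        return self.f0_khz + a * (self.f1_khz - self.f0_khz)


@dataclass
class CallSpec:
    """Parametric description of one synthetic USV.

    ``components`` is a list of trajectories, each a list of contiguous-in-
    frequency-or-stepped :class:`Segment` pieces; two overlapping components
    model a composite call, two sequential components separated by a silent
    gap model a two-components call.
    """

    category: str
    duration_ms: float
    components: list[list[Segment]]
    amplitude_envelope: float = 0.1
    snr_db: float = DEFAULT_SNR_DB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown call category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        for comp in self.components:
            for seg in comp:
                for f in (seg.f0_khz, seg.f1_khz):
                    if not (FREQ_LO_KHZ < f < FREQ_HI_KHZ):
                        raise ValueError(
                            f"trajectory frequency {f} kHz outside the "
                            f"admissible ({FREQ_LO_KHZ}, {FREQ_HI_KHZ}) kHz band"
                        )

    @property
    def trajectory(self) -> list[Segment]:
        """The principal (first) component's trajectory."""
        return self.components[0]

    @property
    def max_freq_khz(self) -> float:
        return max(
            max(seg.f0_khz, seg.f1_khz) for comp in self.components for seg in comp
        )

    def ideal_tracks(self, frame_ms: float = 0.512) -> list[tuple[int, np.ndarray]]:
        """Noise-free peak-frequency tracks sampled on a frame grid.

        Returns one ``(start_frame, track_khz)`` pair per component, the form
        consumed by :func:`rule_oracle_label`.
        """
        tracks = []
        for comp in self.components:
            c0 = comp[0].t0_ms
            c1 = comp[-1].t1_ms
            start = int(np.floor(c0 / frame_ms))
            centers = []
            i = start
            while (i + 0.5) * frame_ms < c1 or not centers:
                t = min(max((i + 0.5) * frame_ms, c0), c1)
                centers.append(t)
                i += 1
            f = np.array([_freq_on_component(comp, t) for t in centers])
            tracks.append((start, f))
        return tracks

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "duration_ms": self.duration_ms,
            "components": [
                [[s.t0_ms, s.t1_ms, s.f0_khz, s.f1_khz] for s in comp]
                for comp in self.components
            ],
            "amplitude_envelope": self.amplitude_envelope,
            "snr_db": self.snr_db,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CallSpec":
        comps = [[Segment(*s) for s in comp] for comp in d["components"]]
        return cls(
            category=d["category"],
            duration_ms=d["duration_ms"],
            components=comps,
            amplitude_envelope=d["amplitude_envelope"],
            snr_db=d["snr_db"],
            seed=d["seed"],
        )


def _freq_on_component(comp: list[Segment], t_ms: float) -> float:
    for seg in comp:
        if seg.t0_ms <= t_ms <= seg.t1_ms:
            return seg.freq_at(t_ms)
    # clamp to nearest end
    if t_ms < comp[0].t0_ms:
        return comp[0].f0_khz
    return comp[-1].f1_khz


@dataclass
class Waveform:
    """Sampled audio, amplitude-normalised to [-1, 1]."""

    samples: np.ndarray
    fs_hz: int = DEFAULT_FS_HZ


@dataclass
class CorpusRecord:
    call_id: str
    category: str
    spec: CallSpec
    waveform: Waveform


@dataclass
class LabeledCorpus:
    records: list[CorpusRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Category-specific trajectory construction
# ---------------------------------------------------------------------------

def _u(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def _flat_segments(rng, dur, f0=None, max_drift=2.0):
    if f0 is None:
        f0 = _u(rng, 50.0, 90.0)
    drift = _u(rng, -max_drift, max_drift)
    return [Segment(0.0, dur, f0, f0 + drift)]


def _make_components(category: str, rng: np.random.Generator):
    """Draw (duration_ms, components) for one call of the given category."""
    if category == "flat":
        dur = _u(rng, 15.0, 60.0)
        return dur, [_flat_segments(rng, dur)]

    if category == "short":
        dur = _u(rng, 1.5, SHORT_MAX_MS)
        return dur, [_flat_segments(rng, dur, max_drift=1.0)]

    if category == "upward":
        dur = _u(rng, 15.0, 60.0)
        f0 = _u(rng, 50.0, 75.0)
        rise = _u(rng, 14.0, min(25.0, 105.0 - f0))
        return dur, [[Segment(0.0, dur, f0, f0 + rise)]]

    if category == "downward":
        dur = _u(rng, 15.0, 60.0)
        f0 = _u(rng, 65.0, 90.0)
        fall = _u(rng, 14.0, min(25.0, f0 - 38.0))
        return dur, [[Segment(0.0, dur, f0, f0 - fall)]]

    if category == "chevron":
        # inverted-U; arms kept gentle enough that the whistle tracker follows
        dur = _u(rng, 20.0, 60.0)
        f0 = _u(rng, 55.0, 78.0)
        up = _u(rng, 8.0, 16.0)
        down = _u(rng, 8.0, 16.0)
        tm = dur * _u(rng, 0.4, 0.6)
        peak = f0 + up
        return dur, [[Segment(0.0, tm, f0, peak), Segment(tm, dur, peak, peak - down)]]

    if category == "complex":
        # three monotone runs -> two directional changes, each >= 6.25 kHz
        dur = _u(rng, 30.0, 60.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        f0 = _u(rng, 60.0, 78.0)
        exc = [_u(rng, 8.0, 15.0) for _ in range(3)]
        t1 = dur * _u(rng, 0.28, 0.38)
        t2 = dur * _u(rng, 0.6, 0.72)
        fa = f0 + sign * exc[0]
        fb = fa - sign * exc[1]
        fc = fb + sign * exc[2]
        return dur, [
            [
                Segment(0.0, t1, f0, fa),
                Segment(t1, t2, fa, fb),
                Segment(t2, dur, fb, fc),
            ]
        ]

    if category == "frequency step":
        # flat-ish plateaus joined by instantaneous jumps, no time gap
        dur = _u(rng, 20.0, 60.0)
        n_steps = int(rng.integers(1, 3))  # 1 or 2 jumps
        bounds = np.sort(rng.uniform(0.25, 0.75, size=n_steps)) * dur
        ts = [0.0, *bounds.tolist(), dur]
        f = _u(rng, 50.0, 80.0)
        segs = []
        for i in range(n_steps + 1):
            drift = _u(rng, -1.0, 1.0)
            segs.append(Segment(ts[i], ts[i + 1], f, f + drift))
            if i < n_steps:
                jump = _u(rng, 8.0, 20.0)
                if f + drift + jump > 105.0:
                    jump = -jump
                elif f + drift - jump > 45.0 and rng.random() < 0.5:
                    jump = -jump
                f = f + drift + jump
        return dur, [segs]

    if category == "two-components":
        # main flat-or-downward call, silent gap, shorter second component
        main_dur = _u(rng, 20.0, 45.0)
        gap = _u(rng, 3.0, 15.0)
        dur2 = _u(rng, 5.0, 12.0)
        if rng.random() < 0.5:
            main = _flat_segments(rng, main_dur, f0=_u(rng, 55.0, 80.0))
        else:
            f0 = _u(rng, 68.0, 88.0)
            fall = _u(rng, 14.0, min(22.0, f0 - 40.0))
            main = [Segment(0.0, main_dur, f0, f0 - fall)]
        f_end = main[-1].f1_khz
        off = _u(rng, 10.0, 20.0)
        f2 = f_end + off if f_end + off < 105.0 else f_end - off
        t0 = main_dur + gap
        second = [Segment(t0, t0 + dur2, f2, f2 + _u(rng, -1.0, 1.0))]
        return t0 + dur2, [main, second]

    if category == "composite":
        # two harmonically independent simultaneous components
        dur = _u(rng, 20.0, 60.0)
        lo = _flat_segments(rng, dur, f0=_u(rng, 45.0, 60.0))
        hi = _flat_segments(rng, dur, f0=_u(rng, 78.0, 95.0))
        return dur, [lo, hi]

    raise ValueError(
        f"unknown call category {category!r}; expected one of {CATEGORIES}"
    )


def make_call_spec(
    category: str,
    rng: np.random.Generator,
    noise_level: float = DEFAULT_SNR_DB,
) -> CallSpec:
    """Draw a random :class:`CallSpec` satisfying the category's rule.

    Parameters
    ----------
    category : one of :data:`CATEGORIES`
    rng : seeded numpy Generator driving all random draws
    noise_level : signal-to-noise ratio in dB for later synthesis
    """
    if category not in CATEGORIES:
        raise ValueError(
            f"unknown call category {category!r}; expected one of {CATEGORIES}"
        )
    dur, comps = _make_components(category, rng)
    seed = int(rng.integers(0, 2**31 - 1))
    return CallSpec(
        category=category,
        duration_ms=dur,
        components=comps,
        snr_db=noise_level,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# FM synthesis
# ---------------------------------------------------------------------------

def synthesize_waveform(
    spec: CallSpec,
    fs_hz: int = DEFAULT_FS_HZ,
    pad_ms: float = DEFAULT_PAD_MS,
) -> Waveform:
    """Render a :class:`CallSpec` to audio by phase-integration FM synthesis.

    Each component is a unit-amplitude tone whose instantaneous frequency
    follows its trajectory (phase is the cumulative sum of the frequency, so
    a stepped trajectory yields a continuous waveform with an instantaneous
    frequency jump).  A raised-cosine onset/offset ramp is applied per
    component, components are summed, and white Gaussian noise is added at
    ``spec.snr_db`` over the whole record, including ``pad_ms`` of background
    on either side of the call.
    """
    if spec.duration_ms <= 0:
        raise ValueError("cannot synthesize a zero-duration call")
    fmax = spec.max_freq_khz * 1000.0
    if fs_hz < 2 * fmax:
        raise ValueError(
            f"sampling rate {fs_hz} Hz violates Nyquist for trajectory "
            f"frequency {fmax:.0f} Hz"
        )
    pad_n = int(round(pad_ms * 1e-3 * fs_hz))
    n_call = int(round(spec.duration_ms * 1e-3 * fs_hz))
    n_total = n_call + 2 * pad_n
    sig = np.zeros(n_total)

    for comp in spec.components:
        c0, c1 = comp[0].t0_ms, comp[-1].t1_ms
        i0 = pad_n + int(round(c0 * 1e-3 * fs_hz))
        n = int(round((c1 - c0) * 1e-3 * fs_hz))
        if n <= 0:
            continue
        t_ms = c0 + np.arange(n) / fs_hz * 1e3
        f_hz = np.empty(n)
        # piecewise-linear instantaneous frequency
        edges = np.array([s.t0_ms for s in comp] + [comp[-1].t1_ms])
        idx = np.clip(np.searchsorted(edges, t_ms, side="right") - 1, 0, len(comp) - 1)
        for k, seg in enumerate(comp):
            m = idx == k
            if not m.any():
                continue
            span = seg.t1_ms - seg.t0_ms
            a = (t_ms[m] - seg.t0_ms) / span if span > 0 else 0.0
            f_hz[m] = (seg.f0_khz + a * (seg.f1_khz - seg.f0_khz)) * 1000.0
        phase = 2.0 * np.pi * np.cumsum(f_hz) / fs_hz
        tone = np.sin(phase)
        tone *= _raised_cosine_envelope(n, spec.amplitude_envelope)
        sig[i0 : i0 + n] += tone

    # normalise the clean signal, then add background noise at the target SNR
    peak = np.max(np.abs(sig))
    if peak > 0:
        sig *= 0.5 / peak
    active = sig != 0.0
    p_sig = float(np.mean(sig[active] ** 2)) if active.any() else 0.0
    if np.isfinite(spec.snr_db) and p_sig > 0:
        noise_rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(p_sig / 10.0 ** (spec.snr_db / 10.0))
        sig = sig + noise_rng.normal(0.0, sigma, size=n_total)
    peak = np.max(np.abs(sig))
    if peak > 1.0:
        sig /= peak
    return Waveform(samples=sig, fs_hz=fs_hz)


def _raised_cosine_envelope(n: int, ramp_frac: float) -> np.ndarray:
    env = np.ones(n)
    r = int(round(n * ramp_frac))
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(
    n_per_class: int,
    master_seed: int,
    snr_db: float = DEFAULT_SNR_DB,
    fs_hz: int = DEFAULT_FS_HZ,
    pad_ms: float = DEFAULT_PAD_MS,
) -> LabeledCorpus:
    """Generate ``n_per_class`` labeled calls of each of the nine categories.

    All randomness derives deterministically from ``master_seed``; the same
    seed reproduces bit-identical waveforms.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = np.random.SeedSequence(master_seed)
    children = master.spawn(len(CATEGORIES) * n_per_class)
    records = []
    k = 0
    for cat in CATEGORIES:
        for i in range(n_per_class):
            rng = np.random.default_rng(children[k])
            spec = make_call_spec(cat, rng, noise_level=snr_db)
            wave = synthesize_waveform(spec, fs_hz=fs_hz, pad_ms=pad_ms)
            call_id = f"{cat.replace(' ', '_')}_{i:03d}"
            records.append(CorpusRecord(call_id, cat, spec, wave))
            k += 1
    prov = {
        "n_per_class": n_per_class,
        "master_seed": master_seed,
        "snr_db": snr_db,
        "fs_hz": fs_hz,
        "pad_ms": pad_ms,
    }
    return LabeledCorpus(records=records, provenance=prov)


def write_corpus(corpus: LabeledCorpus, out_dir: str | Path) -> Path:
    """Write one 16-bit PCM WAV per call plus a JSON manifest; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"provenance": corpus.provenance, "calls": []}
    for rec in corpus.records:
        w = rec.waveform
        pcm = np.clip(w.samples, -1.0, 1.0)
        wavfile.write(out / f"{rec.call_id}.wav", w.fs_hz, (pcm * 32767).astype(np.int16))
        manifest["calls"].append(
            {"call_id": rec.call_id, "category": rec.category, "spec": rec.spec.to_dict()}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_corpus(in_dir: str | Path) -> LabeledCorpus:
    """Read a corpus written by :func:`write_corpus`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    records = []
    for entry in manifest["calls"]:
        fs, pcm = wavfile.read(in_dir / f"{entry['call_id']}.wav")
        samples = pcm.astype(np.float64) / 32767.0
        records.append(
            CorpusRecord(
                call_id=entry["call_id"],
                category=entry["category"],
                spec=CallSpec.from_dict(entry["spec"]),
                waveform=Waveform(samples=samples, fs_hz=int(fs)),
            )
        )
    return LabeledCorpus(records=records, provenance=manifest["provenance"])


# ---------------------------------------------------------------------------
# Rule oracle
# ---------------------------------------------------------------------------

def _significant_extremes(track: np.ndarray, thresh: float) -> np.ndarray:
    """Indices of turning points whose adjacent monotone runs are >= thresh.

    Small reversals (below ``thresh``) are treated as jitter and absorbed
    into the surrounding run, so the returned extremes partition the track
    into monotone runs each with excursion >= thresh (end runs may be
    smaller).
    """
    n = len(track)
    if n < 3:
        return np.array([0, n - 1], dtype=int)
    extremes = [0]
    imin = imax = 0
    direction = 0  # +1 rising, -1 falling, 0 undetermined
    cand = 0  # candidate extreme index
    start = 1
    for i in range(1, n):
        if track[i] >= track[imax]:
            imax = i
        if track[i] <= track[imin]:
            imin = i
        if track[imax] - track[imin] >= thresh:
            direction = 1 if imax >= imin else -1
            cand = imax if direction == 1 else imin
            start = i + 1
            break
    for i in range(start, n):
        if direction == 1:
            if track[i] > track[cand]:
                cand = i
            elif track[cand] - track[i] >= thresh:
                extremes.append(cand)
                direction = -1
                cand = i
        elif direction == -1:
            if track[i] < track[cand]:
                cand = i
            elif track[i] - track[cand] >= thresh:
                extremes.append(cand)
                direction = 1
                cand = i
    extremes.append(n - 1)
    return np.unique(np.array(extremes, dtype=int))


def _median3(track: np.ndarray) -> np.ndarray:
    if len(track) < 3:
        return track
    out = track.copy()
    out[1:-1] = np.median(
        np.stack([track[:-2], track[1:-1], track[2:]]), axis=0
    )
    return out


def rule_oracle_label(
    tracks: np.ndarray | list[tuple[int, np.ndarray]],
    duration_ms: float,
    frame_ms: float = 0.512,
) -> str:
    """Classify peak-frequency track(s) by the nine printed category rules.

    Parameters
    ----------
    tracks : either a single 1-D track (kHz per frame) or a list of
        ``(start_frame, track_khz)`` pairs for multi-component calls.
    duration_ms : total call duration (first to last voiced frame).
    frame_ms : frame hop in ms, used to relate start offsets to time.

    Rules are applied in a fixed precedence: composite, frequency step,
    two-components, short, complex, chevron, upward, downward, and flat as
    the residual class, so exactly one label is always returned.
    """
    if isinstance(tracks, np.ndarray):
        tracks = [(0, tracks)]
    tracks = [(int(s), np.asarray(t, dtype=float)) for s, t in tracks if len(t) > 0]
    if not tracks:
        raise ValueError("rule oracle requires at least one non-empty track")

    # composite: two or more tracks overlapping in time
    if len(tracks) >= 2:
        spans = [(s, s + len(t) - 1) for s, t in tracks]
        spans.sort()
        overlap = any(
            spans[i + 1][0] <= spans[i][1] for i in range(len(spans) - 1)
        )
        if overlap:
            return "composite"

    # frequency step: instantaneous jump >= 6.25 kHz with no interruption
    for _, t in tracks:
        if len(t) >= 2 and np.max(np.abs(np.diff(t))) >= DIRECTION_CHANGE_KHZ:
            return "frequency step"

    # two-components: sequential tracks separated by a silent gap
    if len(tracks) >= 2:
        return "two-components"

    if duration_ms <= SHORT_MAX_MS:
        return "short"

    track = _median3(tracks[0][1])
    ext = _significant_extremes(track, DIRECTION_CHANGE_KHZ)
    runs = np.diff(track[ext])
    interior = ext[1:-1]
    n_changes = sum(
        1
        for j in range(len(interior))
        if abs(runs[j]) >= DIRECTION_CHANGE_KHZ and abs(runs[j + 1]) >= DIRECTION_CHANGE_KHZ
    )
    if n_changes >= 2:
        return "complex"
    if (
        n_changes == 1
        and len(runs) >= 2
        and runs[0] >= DIRECTION_CHANGE_KHZ
        and runs[1] <= -DIRECTION_CHANGE_KHZ
    ):
        return "chevron"
    net = track[-1] - track[0]
    if net >= MONOTONE_EXCURSION_KHZ:
        return "upward"
    if net <= -MONOTONE_EXCURSION_KHZ:
        return "downward"
    return "flat"
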