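"""Schematic audio rendering of BDAT items.

The psychometric layer only ever looks at :class:`~bdat.item_bank.ItemSpec`;
audio exists so that a full test session can actually be played.  Each clip
is rendered schematically with sample-accurate onsets:

* an isochronous grid click on every beat of bars 1-3, bar-4 beat 1 and
  bars 5-6 (the "musical material"),
* a sustained drone with no amplitude periodicity filling the beat-drop
  window (bar 4, beats 2-4), so the gap is not silent but carries no
  rhythmic cue,
* the probe: a 120 ms decaying tone pitched at F2 (87.31 Hz), placed on
  or off the internally continued beat.

Both stereo channels carry identical content.  ``verify_onsets`` is a
self-check that energy-rise onset detection on the rendered buffer
recovers every planned event to within +-1 ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.io import wavfile

from .item_bank import (BARS, BEATS_PER_BAR, BEAT_DROP_BAR, BEAT_DROP_BEATS,
                        Condition, ItemSpec, TimingPlan, probe_timing)

__all__ = [
    "AudioRenderSpec",
    "RenderedStimulus",
    "render_stimulus",
    "verify_onsets",
    "write_wav",
    "read_wav",
]

F2_HZ = 87.31  # equal temperament, A4 = 440 Hz


@dataclass(frozen=True)
class AudioRenderSpec:
    sample_rate: int = 44100
    bit_depth: int = 16
    channels: int = 2
    click_freq: float = F2_HZ          # probe pitch
    click_duration: float = 0.120      # probe length, seconds
    click_level: float = 0.85
    beat_click_freq: float = 1108.73   # grid click pitch (C#6), distinct from probe
    beat_click_duration: float = 0.030
    beat_click_level: float = 0.60
    drone_freq: float = 110.0
    drone_level: float = 0.05

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.click_duration <= 0:
            raise ValueError("sample_rate and click_duration must be positive")


@dataclass
class RenderedStimulus:
    samples: np.ndarray            # mono float64 buffer in [-1, 1]
    planned_onsets: list[tuple[str, float]]
    item_id: str
    sample_rate: int
    plan: TimingPlan | None = None

    @property
    def stereo(self) -> np.ndarray:
        """Two identical channels, shape (n, 2)."""
        return np.stack([self.samples, self.samples], axis=1)


def _decaying_tone(freq: float, duration: float, sr: int, level: float,
                   tau: float) -> np.ndarray:
    """Exponentially decaying sine burst with an instantaneous attack."""
    n = round(duration * sr)
    t = np.arange(n) / sr
    return level * np.exp(-t / tau) * np.sin(2 * np.pi * freq * t)


def _grid_beats(plan: TimingPlan) -> list[tuple[str, float]]:
    """Grid-click events: every beat outside the beat-drop window."""
    lo, hi = BEAT_DROP_BEATS
    events = []
    for bar in range(1, BARS + 1):
        for beat in range(1, BEATS_PER_BAR + 1):
            if bar == BEAT_DROP_BAR and lo <= beat <= hi:
                continue
            events.append((f"beat_b{bar}k{beat}", plan.beat_time(bar, beat)))
    return events


def render_stimulus(item: ItemSpec, spec: AudioRenderSpec = AudioRenderSpec()
                    ) -> RenderedStimulus:
    """Render one item to a sample-accurate schematic clip.

    The probe's onset sample is ``round(probe_onset * sample_rate)``; grid
    clicks are placed the same way.  The drone spans the drop window with a
    slow 30 ms fade-in and constant amplitude thereafter: it is background,
    not an event, and produces no energy rise the onset detector can see.
    """
    plan = probe_timing(item)
    n = round(plan.clip_duration * spec.sample_rate)
    buf = np.zeros(n)
    sr = spec.sample_rate

    def add(sig: np.ndarray, t: float) -> None:
        i = round(t * sr)
        if not (0 <= i < n):
            raise RuntimeError(f"onset {t:.4f}s outside clip")
        j = min(n, i + len(sig))
        buf[i:j] += sig[: j - i]

    onsets: list[tuple[str, float]] = []
    click = _decaying_tone(spec.beat_click_freq, spec.beat_click_duration, sr,
                           spec.beat_click_level, tau=0.008)
    for label, t in _grid_beats(plan):
        add(click, t)
        onsets.append((label, t))

    # drone across the drop window: slow attack and release so it carries
    # no detectable onset, constant level in between (no beat-rate periodicity)
    d0, d1 = plan.drop_window
    nd = round((d1 - d0) * sr)
    t = np.arange(nd) / sr
    env = np.minimum(1.0, t / 0.030)
    rel = round(0.030 * sr)
    env[-rel:] *= np.linspace(1.0, 0.0, rel)
    drone = spec.drone_level * env * np.sin(2 * np.pi * spec.drone_freq * t)
    add(drone, d0)

    probe = _decaying_tone(spec.click_freq, spec.click_duration, sr,
                           spec.click_level, tau=0.040)
    add(probe, plan.probe_onset)
    onsets.append(("probe", plan.probe_onset))

    peak = np.max(np.abs(buf))
    if peak > 1.0:
        buf /= peak
    onsets.sort(key=lambda e: e[1])
    return RenderedStimulus(samples=buf, planned_onsets=onsets,
                            item_id=item.item_id, sample_rate=sr, plan=plan)


def detect_onsets(samples: np.ndarray, sample_rate: int,
                  rise: float = 0.12, lag_ms: float = 1.0,
                  refractory_ms: float = 25.0) -> list[float]:
    """Energy-rise onset detection.

    Tracks a short moving-maximum amplitude envelope and reports times
    where it rises by more than ``rise`` over a ``lag_ms`` lag, with a
    refractory period to suppress duplicates.  Adequate for the schematic
    clips rendered here, which have near-instantaneous attacks.
    """
    # window must span a half-period of the lowest rendered frequency (F2)
    # or the envelope dips at zero crossings and re-triggers
    win = max(1, round(0.007 * sample_rate))
    env = np.abs(samples)
    # moving max via stride tricks on a padded array
    pad = np.concatenate([np.zeros(win - 1), env])
    from numpy.lib.stride_tricks import sliding_window_view
    env = sliding_window_view(pad, win).max(axis=1)
    lag = max(1, round(lag_ms / 1000 * sample_rate))
    jump = env[lag:] - env[:-lag]
    hot = np.flatnonzero(jump > rise) + lag
    refr = round(refractory_ms / 1000 * sample_rate)
    out: list[float] = []
    last = -refr
    for i in hot:
        if i - last >= refr:
            # refine to the first sample of the rise
            start = i - lag
            seg = np.flatnonzero(np.abs(samples[start:i + 1])
                                 > np.abs(samples[start]) + rise / 2)
            onset = start + (seg[0] if len(seg) else lag)
            out.append(onset / sample_rate)
            last = i
    return out


def verify_onsets(stimulus: RenderedStimulus,
                  spec: AudioRenderSpec = AudioRenderSpec(),
                  tol_ms: float = 1.0) -> list[float]:
    """Check that detected onsets match the plan to within ``tol_ms``.

    Returns the detected onset times; raises ``RuntimeError`` listing any
    planned onset without a detection (or any spurious detection) within
    tolerance.
    """
    detected = detect_onsets(stimulus.samples, stimulus.sample_rate)
    tol = tol_ms / 1000.0
    planned = [t for _, t in stimulus.planned_onsets]
    # planned events closer than the detector's refractory period merge
    # (e.g. an ON probe exactly on a grid beat)
    merged: list[float] = []
    for t in sorted(planned):
        if not merged or t - merged[-1] > 0.020:
            merged.append(t)
    problems = []
    for t in merged:
        if not any(abs(t - d) <= tol for d in detected):
            problems.append(f"missed planned onset at {t:.4f}s")
    for d in detected:
        if not any(abs(t - d) <= tol for t in merged):
            problems.append(f"spurious onset at {d:.4f}s")
    if problems:
        raise RuntimeError("; ".join(problems))
    return detected


def write_wav(path, stimulus: RenderedStimulus,
              spec: AudioRenderSpec = AudioRenderSpec(),
              sidecar: bool = True) -> None:
    """Write PCM-16 stereo WAV plus a JSON sidecar with planned onsets."""
    pcm = np.clip(stimulus.stereo, -1.0, 1.0)
    pcm = (pcm * 32767).astype(np.int16)
    wavfile.write(path, stimulus.sample_rate, pcm)
    if sidecar:
        meta = {
            "item_id": stimulus.item_id,
            "sample_rate": stimulus.sample_rate,
            "planned_onsets": stimulus.planned_onsets,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a WAV written by :func:`write_wav`; returns (rate, float array)."""
    rate, data = wavfile.read(path)
    return rate, data.astype(np.float64) / 32767.0
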