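"""Quantized transition matrix (qTM) of the overnight magnitude envelope.

The absolute magnitude envelope is quantized into silence / low / high
levels; silence runs lasting 20-60 s are relabeled as apnea candidates
(shorter or longer runs stay silence), giving four levels. The qTM is the
row-stochastic matrix of transition probabilities between consecutive
frame levels over the whole night.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sdbsound.io_audio import AudioRecording

LEVELS = ("SILENCE", "LOW", "HIGH", "APNEA")
SILENCE, LOW, HIGH, APNEA = range(4)

QTM_FEATURE_NAMES = tuple(f"qtm_{a}_{b}" for a in LEVELS for b in LEVELS)


@dataclass
class LevelSequence:
    """Per-frame quantized magnitude levels (integer codes into LEVELS)."""

    levels: np.ndarray
    frame_seconds: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.size == 0:
            raise ValueError("level sequence is empty")
        if self.frame_seconds <= 0:
            raise ValueError("frame_seconds must be positive")
        if self.levels.min() < 0 or self.levels.max() > 3:
            raise ValueError("level codes must be in 0..3")

    def __len__(self) -> int:
        return self.levels.size

    def occupancy(self, level: int) -> float:
        """Fraction of frames at the given level."""
        return float(np.mean(self.levels == level))


@dataclass
class QTM:
    """4x4 transition-probability matrix over (SILENCE, LOW, HIGH, APNEA).

    ``probs[m, n]`` is P(level n at the next frame | level m now); rows with
    no occurrences are all-zero and flagged in ``row_occupied``.
    """

    counts: np.ndarray
    probs: np.ndarray
    row_occupied: np.ndarray

    def to_dict(self) -> dict:
        return {
            "levels": list(LEVELS),
            "counts": self.counts.tolist(),
            "probs": self.probs.tolist(),
            "row_occupied": self.row_occupied.tolist(),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def quantize_levels(
    rec: AudioRecording,
    frame_seconds: float = 1.0,
    silence_thresh: float = 0.15,
    high_thresh: float = 0.85,
    absolute: bool = False,
    noise_floor: float = 0.0,
) -> LevelSequence:
    """Quantize the frame-RMS magnitude envelope into SILENCE/LOW/HIGH.

    With ``absolute=False`` the thresholds are quantiles of the whole-night
    frame magnitude distribution (recordings are uncalibrated, so per-subject
    adaptive thresholds are the default); with ``absolute=True`` they are raw
    magnitudes. ``noise_floor`` lower-bounds the silence threshold.
    """
    if silence_thresh >= high_thresh:
        raise ValueError("silence threshold must be below the high threshold")
    frame_len = round(frame_seconds * rec.rate)
    n_frames = rec.samples.size // frame_len
    if n_frames == 0:
        raise ValueError("recording shorter than one quantization frame")
    mags = np.sqrt(
        (rec.samples[: n_frames * frame_len].reshape(n_frames, frame_len) ** 2).mean(axis=1)
    )
    if absolute:
        t_sil, t_high = silence_thresh, high_thresh
    else:
        t_sil = np.quantile(mags, silence_thresh)
        t_high = np.quantile(mags, high_thresh)
    t_sil = max(t_sil, noise_floor)
    levels = np.full(n_frames, LOW, dtype=np.int64)
    levels[mags <= t_sil] = SILENCE
    levels[mags >= max(t_high, t_sil)] = HIGH
    return LevelSequence(levels=levels, frame_seconds=frame_seconds)


def _runs(mask: np.ndarray):
    """Yield (start, stop) of maximal True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return zip(edges[::2], edges[1::2])


def mark_apnea_candidates(
    seq: LevelSequence, min_s: float = 20.0, max_s: float = 60.0
) -> LevelSequence:
    """Relabel silence runs lasting min_s..max_s (inclusive) as APNEA.

    Shorter runs (quiet breathing) and longer runs stay SILENCE. Idempotent:
    already-relabeled frames are APNEA, not SILENCE, so a second pass is a
    no-op.
    """
    if not min_s < max_s:
        raise ValueError("min_s must be below max_s")
    levels = seq.levels.copy()
    for start, stop in _runs(levels == SILENCE):
        duration = (stop - start) * seq.frame_seconds
        if min_s <= duration <= max_s:
            levels[start:stop] = APNEA
    return LevelSequence(levels=levels, frame_seconds=seq.frame_seconds)


def transition_matrix(seq: LevelSequence) -> QTM:
    """Count adjacent-frame level transitions and row-normalize."""
    if len(seq) < 2:
        raise ValueError("need at least two frames to count transitions")
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (seq.levels[:-1], seq.levels[1:]), 1)
    row_sums = counts.sum(axis=1)
    occupied = row_sums > 0
    probs = np.zeros((4, 4))
    probs[occupied] = counts[occupied] / row_sums[occupied, None]
    return QTM(counts=counts, probs=probs, row_occupied=occupied)


def qtm_features(q: QTM) -> dict[str, float]:
    """Flatten the qTM row-major into named per-subject features."""
    flat = q.probs.ravel()
    return {name: float(v) for name, v in zip(QTM_FEATURE_NAMES, flat)}


def estimate_noise_floor(
    rec: AudioRecording, frame_seconds: float = 1.0, quantile: float = 0.05, margin: float = 1.3
) -> float:
    """Noise-floor magnitude estimate: margin x the low-quantile frame RMS.

    Used to lower-bound the adaptive silence threshold so that stationary
    background noise inside true breathing gaps still reads as silence.
    """
    frame_len = round(frame_seconds * rec.rate)
    n_frames = rec.samples.size // frame_len
    if n_frames == 0:
        raise ValueError("recording shorter than one quantization frame")
    mags = np.sqrt(
        (rec.samples[: n_frames * frame_len].reshape(n_frames, frame_len) ** 2).mean(axis=1)
    )
    return float(margin * np.quantile(mags, quantile))


def extract_qtm(
    rec: AudioRecording,
    frame_seconds: float = 1.0,
    silence_quantile: float = 0.15,
    high_quantile: float = 0.85,
    noise_floor: float | str = "auto",
    apnea_min_s: float = 20.0,
    apnea_max_s: float = 60.0,
) -> tuple[QTM, LevelSequence]:
    """Full qTM pipeline: quantize, mark apnea candidates, count transitions.

    The silence threshold is the larger of the silence quantile and the
    noise-floor estimate (``noise_floor="auto"`` estimates it from the
    quietest frames; recordings are uncalibrated, so thresholds adapt per
    subject).
    """
    if noise_floor == "auto":
        noise_floor = estimate_noise_floor(rec, frame_seconds)
    seq = quantize_levels(
        rec,
        frame_seconds=frame_seconds,
        silence_thresh=silence_quantile,
        high_thresh=high_quantile,
        noise_floor=float(noise_floor),
    )
    seq = mark_apnea_candidates(seq, apnea_min_s, apnea_max_s)
    return transition_matrix(seq), seq
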