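"""Two-stage cleanup of overnight recordings.

Stage one removes stationary background noise by magnitude spectral
subtraction; stage two keeps only the sleep-stage epochs (by default N2/N3)
in which breathing is stable, concatenating the retained audio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from sdbsound.io_audio import AudioRecording

STAGES = ("W", "N1", "N2", "N3", "REM")

_STAGE_SYNONYMS = {
    "W": "W",
    "WAKE": "W",
    "0": "W",
    "N1": "N1",
    "1": "N1",
    "N2": "N2",
    "2": "N2",
    "N3": "N3",
    "3": "N3",
    "N4": "N3",
    "4": "N3",
    "REM": "REM",
    "R": "REM",
    "5": "REM",
}


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels; epoch k covers [k*epoch_seconds, (k+1)*epoch_seconds)."""

    stages: list[str]
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if not self.stages:
            raise ValueError("hypnogram has no epochs")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages: {sorted(bad)}")

    @property
    def duration_seconds(self) -> float:
        return len(self.stages) * self.epoch_seconds


@dataclass
class NoiseProfile:
    """Per-bin noise magnitude estimate tied to a fixed STFT configuration."""

    magnitude: np.ndarray
    fft_size: int
    hop: int
    rate: int

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        if self.magnitude.ndim != 1 or self.magnitude.size != self.fft_size // 2 + 1:
            raise ValueError("noise profile must have fft_size/2 + 1 bins")
        if np.any(self.magnitude < 0):
            raise ValueError("noise magnitudes must be non-negative")


def normalize_stage(label: str) -> str:
    try:
        return _STAGE_SYNONYMS[label.strip().upper()]
    except KeyError:
        raise ValueError(f"unrecognized sleep stage label: {label!r}") from None


def read_hypnogram(path: str | Path, epoch_seconds: float = 30.0) -> Hypnogram:
    """Read a hypnogram TSV with columns ``epoch_index<TAB>stage``."""
    stages: dict[int, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 'epoch_index<TAB>stage'")
            stages[int(parts[0])] = normalize_stage(parts[1])
    if not stages:
        raise ValueError(f"{path}: no epochs found")
    n = max(stages) + 1
    if set(stages) != set(range(n)):
        raise ValueError(f"{path}: epoch indices are not contiguous from 0")
    return Hypnogram(stages=[stages[k] for k in range(n)], epoch_seconds=epoch_seconds)


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    with open(path, "w") as fh:
        for k, stage in enumerate(hyp.stages):
            fh.write(f"{k}\t{stage}\n")


def _stft_params(rate: int, fft_ms: float, hop_ms: float) -> tuple[int, int]:
    nperseg = round(rate * fft_ms / 1000.0)
    hop = round(rate * hop_ms / 1000.0)
    return nperseg, hop


def _stft(samples: np.ndarray, rate: int, nperseg: int, hop: int):
    return signal.stft(
        samples, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg - hop, padded=True
    )


def estimate_noise_profile(
    rec: AudioRecording,
    frac_quietest: float = 0.1,
    fft_ms: float = 32.0,
    hop_ms: float = 16.0,
) -> NoiseProfile:
    """Estimate the stationary noise spectrum from the quietest STFT frames.

    The per-bin noise magnitude is the mean magnitude over the
    ``frac_quietest`` fraction of frames with the lowest total energy.
    """
    if not 0 < frac_quietest <= 1:
        raise ValueError("frac_quietest must be in (0, 1]")
    nperseg, hop = _stft_params(rec.rate, fft_ms, hop_ms)
    if rec.samples.size < nperseg:
        raise ValueError("recording shorter than one analysis frame")
    _, _, spec = _stft(rec.samples, rec.rate, nperseg, hop)
    mag = np.abs(spec)  # (bins, frames)
    energy = np.sum(mag**2, axis=0)
    n_keep = max(1, int(round(frac_quietest * energy.size)))
    quiet = np.argsort(energy, kind="stable")[:n_keep]
    return NoiseProfile(
        magnitude=mag[:, quiet].mean(axis=1), fft_size=nperseg, hop=hop, rate=rec.rate
    )


def spectral_subtract(
    rec: AudioRecording,
    noise: NoiseProfile,
    oversubtraction: float = 2.0,
    floor: float = 0.02,
) -> AudioRecording:
    """Magnitude spectral subtraction with a spectral floor and overlap-add resynthesis.

    Per STFT frame the output magnitude is
    ``max(|X| - oversubtraction * noise, floor * |X|)``; the noisy phase is
    reused. Output length and rate match the input.
    """
    nperseg, hop = noise.fft_size, noise.hop
    if noise.rate != rec.rate:
        raise ValueError("noise profile sampling rate does not match the recording")
    if rec.samples.size < nperseg:
        raise ValueError("recording shorter than one analysis frame")
    _, _, spec = _stft(rec.samples, rec.rate, nperseg, hop)
    mag = np.abs(spec)
    cleaned = np.maximum(mag - oversubtraction * noise.magnitude[:, None], floor * mag)
    phase = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 1.0)
    _, out = signal.istft(
        cleaned * phase,
        fs=rec.rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - hop,
    )
    if out.size < rec.samples.size:
        out = np.pad(out, (0, rec.samples.size - out.size))
    return AudioRecording(
        samples=out[: rec.samples.size], rate=rec.rate, subject_id=rec.subject_id
    )


def denoise(
    rec: AudioRecording,
    frac_quietest: float = 0.1,
    fft_ms: float = 32.0,
    hop_ms: float = 16.0,
    oversubtraction: float = 2.0,
    floor: float = 0.02,
) -> AudioRecording:
    """Convenience wrapper: estimate the noise profile, then subtract it."""
    profile = estimate_noise_profile(rec, frac_quietest, fft_ms, hop_ms)
    return spectral_subtract(rec, profile, oversubtraction, floor)


def stage_filter(
    rec: AudioRecording,
    hyp: Hypnogram | None,
    keep: set[str] | frozenset[str] = frozenset({"N2", "N3"}),
) -> AudioRecording:
    """Keep only the audio of epochs whose stage is in ``keep``, concatenated in time order.

    The hypnogram must cover at least the recording duration (excess epochs
    are ignored). With ``hyp=None`` filtering is skipped with a warning, for
    screening-only use without staging.
    """
    if hyp is None:
        warnings.warn("no hypnogram supplied; sleep-stage filtering skipped", stacklevel=2)
        return rec
    if not keep:
        raise ValueError("keep set must not be empty")
    bad = set(keep) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages in keep set: {sorted(bad)}")
    if hyp.duration_seconds < rec.duration_seconds - 1e-9:
        raise ValueError(
            f"hypnogram covers {hyp.duration_seconds:.0f} s but the recording "
            f"lasts {rec.duration_seconds:.3f} s"
        )
    epoch_len = hyp.epoch_seconds * rec.rate
    pieces = []
    for k, stage in enumerate(hyp.stages):
        if stage not in keep:
            continue
        lo = round(k * epoch_len)
        if lo >= rec.samples.size:
            break
        pieces.append(rec.samples[lo : min(round((k + 1) * epoch_len), rec.samples.size)])
    if not pieces:
        warnings.warn("no epochs matched the keep set; output recording is empty", stacklevel=2)
        return AudioRecording(samples=np.zeros(0), rate=rec.rate, subject_id=rec.subject_id)
    return AudioRecording(
        samples=np.concatenate(pieces), rate=rec.rate, subject_id=rec.subject_id
    )
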