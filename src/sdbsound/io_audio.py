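"""Audio and roster I/O plus fixed-length windowing of recordings."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

SEVERITY_GROUPS = ("normal", "mild", "moderate", "severe")

#: AHI cut-offs between severity groups (events/hour).
AHI_CUTOFFS = (5.0, 15.0, 30.0)


class AudioFormatError(ValueError):
    """Raised when a file cannot be decoded as PCM WAV audio."""


@dataclass
class AudioRecording:
    """A single-channel recording: float samples in [-1, 1] plus sampling rate."""

    samples: np.ndarray
    rate: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.dtype not in (np.float32, np.float64):
            # float32 is preserved so whole cohorts fit in memory
            self.samples = self.samples.astype(np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        # empty recordings are representable (stage filtering can drop every
        # epoch); readers and feature extractors reject them at their boundary
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_seconds(self) -> float:
        return self.samples.size / self.rate


@dataclass
class WindowSequence:
    """Contiguous non-overlapping equal-length sample blocks from one recording.

    ``windows`` is a 2-D array of shape (n_windows, samples_per_window); a
    trailing partial window is discarded, never zero-padded.
    """

    windows: np.ndarray
    window_seconds: float
    rate: int

    def __len__(self) -> int:
        return self.windows.shape[0]

    def __iter__(self):
        return iter(self.windows)

    @property
    def samples_per_window(self) -> int:
        return self.windows.shape[1] if self.windows.size else round(self.window_seconds * self.rate)


def _pcm_to_float(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1]; float data is passed through."""
    if data.dtype == np.int16:
        return data / 32768.0
    if data.dtype == np.int32:
        return data / 2147483648.0
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        return (data.astype(np.float64) - 128.0) / 128.0
    if data.dtype.kind == "f":
        return data.astype(np.float64)
    raise AudioFormatError(f"unsupported WAV sample format: {data.dtype}")


def read_wav(path: str | Path, subject_id: str | None = None) -> AudioRecording:
    """Read a PCM RIFF/WAVE file; multichannel files use channel 0.

    Samples are scaled to [-1, 1] by the full-scale integer range of the
    stored format; the header sampling rate is preserved.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError for bad RIFF
        raise AudioFormatError(f"cannot decode {path} as PCM WAV: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"{path} contains no audio samples")
    if data.ndim > 1:
        data = data[:, 0]
    return AudioRecording(
        samples=_pcm_to_float(data),
        rate=int(rate),
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_wav(path: str | Path, rec: AudioRecording) -> None:
    """Write a recording as 16-bit PCM WAV (clipping to full scale)."""
    clipped = np.clip(rec.samples, -1.0, 32767.0 / 32768.0)
    wavfile.write(Path(path), rec.rate, np.round(clipped * 32768.0).astype(np.int16))


def segment_windows(rec: AudioRecording, window_seconds: float = 5.0) -> WindowSequence:
    """Split a recording into contiguous non-overlapping windows.

    The window count is floor(duration / window_seconds); the trailing
    partial window is dropped. An 8 h recording at 5 s windows therefore
    yields 5760 windows.
    """
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    samples_per_window = round(window_seconds * rec.rate)
    n_windows = rec.samples.size // samples_per_window
    if n_windows == 0:
        warnings.warn(
            f"window of {window_seconds} s is longer than the "
            f"{rec.duration_seconds:.3f} s recording; no windows produced",
            stacklevel=2,
        )
        windows = np.empty((0, samples_per_window))
    else:
        windows = rec.samples[: n_windows * samples_per_window].reshape(
            n_windows, samples_per_window
        )
    return WindowSequence(windows=windows, window_seconds=window_seconds, rate=rec.rate)


def severity_from_ahi(ahi: float) -> str:
    """Map an AHI value to its severity group: <5 normal, 5-15 mild, 15-30 moderate, >=30 severe."""
    if ahi < 0 or not np.isfinite(ahi):
        raise ValueError(f"AHI must be a non-negative finite number, got {ahi}")
    if ahi < AHI_CUTOFFS[0]:
        return "normal"
    if ahi < AHI_CUTOFFS[1]:
        return "mild"
    if ahi < AHI_CUTOFFS[2]:
        return "moderate"
    return "severe"


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read a subject roster CSV with columns ``subject_id,ahi``.

    The severity group is derived from the AHI, never trusted from the file.
    """
    roster = pd.read_csv(path, dtype={"subject_id": str})
    missing = {"subject_id", "ahi"} - set(roster.columns)
    if missing:
        raise ValueError(f"roster is missing columns: {sorted(missing)}")
    roster = roster[["subject_id", "ahi"]].copy()
    roster["ahi"] = roster["ahi"].astype(float)
    roster["severity_group"] = roster["ahi"].map(severity_from_ahi)
    if roster["subject_id"].duplicated().any():
        raise ValueError("roster contains duplicate subject ids")
    return roster


def write_roster(path: str | Path, roster: pd.DataFrame) -> None:
    roster[["subject_id", "ahi"]].to_csv(path, index=False)
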