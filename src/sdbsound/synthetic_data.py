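"""Seeded synthetic overnight recordings, hypnograms, and cohorts.

The generator plants the statistical structure the pipeline is meant to
recover: breathing-cycle amplitude modulation, snore-like harmonic bursts
whose gain grows with severity, silence gaps whose hourly rate follows a
target AHI (10-60 s long, so both the below-20 s "stays silence" branch and
the 20-60 s apnea-candidate branch are exercised), and stationary
background noise. Acoustic realism is a non-goal; ground truth is returned
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from sdbsound.io_audio import AudioRecording, severity_from_ahi
from sdbsound.preprocessing import Hypnogram

#: Severity-dependent snore gain (strong planted group effect).
GROUP_SNORE_GAIN = {"normal": 0.06, "mild": 0.18, "moderate": 0.42, "severe": 0.85}

#: AHI sampling range per group, matching the severity definition.
GROUP_AHI_RANGE = {
    "normal": (0.0, 5.0),
    "mild": (5.0, 15.0),
    "moderate": (15.0, 30.0),
    "severe": (30.0, 80.0),
}


@dataclass
class SynthSubjectSpec:
    """Parameters of one synthetic subject's overnight recording."""

    target_ahi: float
    duration_s: float
    rate: int = 8000
    breathing_period_s: float = 4.0
    snore_intensity: float = 0.3
    apnea_duration_range_s: tuple[float, float] = (10.0, 60.0)
    noise_floor: float = 0.003
    seed: int = 0
    subject_id: str = "synth"

    def __post_init__(self) -> None:
        if self.target_ahi < 0:
            raise ValueError("target_ahi must be non-negative")
        lo, hi = self.apnea_duration_range_s
        if lo <= 0 or hi <= lo:
            raise ValueError("apnea duration range must be positive and increasing")
        if self.duration_s < 10 * self.breathing_period_s:
            raise ValueError("recording must cover at least ten breathing cycles")


def _bandpass_noise(rng: np.random.Generator, n: int, rate: int, lo: float, hi: float) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / max(np.sqrt(np.mean(x**2)), 1e-12)


def synth_breathing_audio(spec: SynthSubjectSpec):
    """Generate one synthetic overnight recording plus its planted gap list.

    Returns ``(AudioRecording, events)`` where events is a list of
    ``{"start_s", "duration_s"}`` dicts for the planted breathing gaps. Gap
    counts follow a Poisson process at ``target_ahi`` per hour; gaps are
    placed non-overlapping with >= 2 s spacing and their total time is
    capped at half the recording.
    """
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration_s * spec.rate)
    t = np.arange(n) / spec.rate

    # breathing: band-limited noise under a raised-cosine cyclic envelope;
    # band edges clamp below Nyquist so low-rate test fixtures stay valid
    band_hi = min(1200.0, 0.45 * spec.rate)
    band_lo = min(150.0, band_hi / 3.0)
    carrier = _bandpass_noise(rng, n, spec.rate, band_lo, band_hi)
    phase = 2.0 * np.pi * t / spec.breathing_period_s
    # raised-cosine cyclic envelope; the 0.15 base keeps breathing troughs
    # well above the noise floor so only planted gaps read as silence
    breath_env = 0.15 + 0.85 * (0.5 * (1.0 - np.cos(phase))) ** 2
    audio = 0.12 * carrier * breath_env

    # snore bursts: harmonic stack on a subset of breath cycles
    n_cycles = int(spec.duration_s / spec.breathing_period_s)
    snore_prob = min(0.9, 0.15 + 0.6 * spec.snore_intensity)
    f0 = rng.uniform(90.0, 160.0)
    for cycle in range(n_cycles):
        if rng.random() >= snore_prob:
            continue
        start = round(cycle * spec.breathing_period_s * spec.rate)
        length = round(0.4 * spec.breathing_period_s * spec.rate)
        stop = min(start + length, n)
        if stop <= start:
            continue
        tt = t[start:stop] - t[start]
        burst = np.zeros(stop - start)
        for h in range(1, 6):
            burst += np.sin(2.0 * np.pi * f0 * h * tt + rng.uniform(0, 2 * np.pi)) / h
        burst *= np.hanning(burst.size)
        audio[start:stop] += spec.snore_intensity * 0.25 * burst

    # silence gaps: Poisson count at target_ahi per hour, uniform durations;
    # total gap time is capped at half the recording (short recordings with
    # extreme AHI would otherwise be all gap), keeping occupancy monotone in
    # the target rate up to saturation
    hours = spec.duration_s / 3600.0
    n_gaps = int(rng.poisson(spec.target_ahi * hours))
    lo, hi = spec.apnea_duration_range_s
    if lo >= spec.duration_s:
        raise ValueError("a single planted gap would exceed the recording")
    durations = list(rng.uniform(lo, hi, size=n_gaps))
    min_space = 2.0  # seconds of breathing between gaps
    while durations and (
        sum(durations) > 0.5 * spec.duration_s
        or sum(durations) + (len(durations) + 1) * min_space > spec.duration_s
    ):
        durations.pop()
    events: list[dict] = []
    gap_mask = np.zeros(n, dtype=bool)
    if durations:
        slack = spec.duration_s - sum(durations) - (len(durations) + 1) * min_space
        spacings = min_space + rng.dirichlet(np.ones(len(durations) + 1)) * slack
        cursor = 0.0
        for dur, space in zip(durations, spacings):
            start_s = cursor + space
            gap_mask[round(start_s * spec.rate) : round((start_s + dur) * spec.rate)] = True
            events.append({"start_s": float(start_s), "duration_s": float(dur)})
            cursor = start_s + dur
    audio[gap_mask] = 0.0

    audio += spec.noise_floor * rng.standard_normal(n)
    peak = np.max(np.abs(audio))
    if peak > 1.0:
        audio /= 1.01 * peak
    rec = AudioRecording(
        samples=audio.astype(np.float32), rate=spec.rate, subject_id=spec.subject_id
    )
    events.sort(key=lambda e: e["start_s"])
    return rec, events


# stage transition structure: N2-dominant with occasional N3/REM/W excursions
_STAGE_ORDER = ("W", "N1", "N2", "N3", "REM")
_STAGE_TRANSITIONS = np.array(
    [
        [0.60, 0.30, 0.08, 0.01, 0.01],  # W
        [0.05, 0.40, 0.50, 0.02, 0.03],  # N1
        [0.01, 0.03, 0.85, 0.08, 0.03],  # N2
        [0.00, 0.01, 0.14, 0.80, 0.05],  # N3
        [0.02, 0.05, 0.13, 0.00, 0.80],  # REM
    ]
)


def synth_hypnogram(duration_s: float, epoch_s: float = 30.0, seed: int = 0) -> Hypnogram:
    """Markov-chain hypnogram with N2-dominant dwell, covering duration_s."""
    if duration_s < epoch_s:
        raise ValueError("duration must cover at least one epoch")
    rng = np.random.default_rng(seed)
    n_epochs = int(np.ceil(duration_s / epoch_s))
    stages = []
    state = 0  # start awake
    for _ in range(n_epochs):
        state = rng.choice(5, p=_STAGE_TRANSITIONS[state])
        stages.append(_STAGE_ORDER[state])
    return Hypnogram(stages=stages, epoch_seconds=epoch_s)


def stationary_n23_fraction() -> float:
    """N2+N3 occupancy of the stage chain's stationary distribution."""
    vals, vecs = np.linalg.eig(_STAGE_TRANSITIONS.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    pi /= pi.sum()
    return float(pi[2] + pi[3])


def synth_cohort(
    n_per_group: int,
    duration_s: float,
    seed: int = 0,
    rate: int = 8000,
):
    """Generate a balanced four-group cohort with AHI-controlled recordings.

    Returns ``(roster, recordings, hypnograms, ground_truth)``: a roster
    DataFrame (subject_id, ahi, severity_group), dicts of recordings and
    hypnograms keyed by subject id, and per-subject ground truth (planted
    gap events and generator spec).
    """
    if n_per_group < 2:
        raise ValueError("need at least two subjects per group")
    rng = np.random.default_rng(seed)
    rows = []
    recordings: dict[str, AudioRecording] = {}
    hypnograms: dict[str, Hypnogram] = {}
    ground_truth: dict[str, dict] = {}
    for group in ("normal", "mild", "moderate", "severe"):
        lo, hi = GROUP_AHI_RANGE[group]
        for k in range(n_per_group):
            subject_id = f"{group}_{k:02d}"
            ahi = float(rng.uniform(lo, hi))
            assert severity_from_ahi(ahi) == group
            spec = SynthSubjectSpec(
                target_ahi=ahi,
                duration_s=duration_s,
                rate=rate,
                snore_intensity=GROUP_SNORE_GAIN[group] * float(rng.uniform(0.85, 1.15)),
                seed=int(rng.integers(0, 2**31)),
                subject_id=subject_id,
            )
            rec, events = synth_breathing_audio(spec)
            recordings[subject_id] = rec
            hypnograms[subject_id] = synth_hypnogram(
                duration_s, seed=int(rng.integers(0, 2**31))
            )
            ground_truth[subject_id] = {
                "events": events,
                "target_ahi": ahi,
                "snore_intensity": spec.snore_intensity,
                "seed": spec.seed,
            }
            rows.append({"subject_id": subject_id, "ahi": ahi, "severity_group": group})
    roster = pd.DataFrame(rows)
    return roster, recordings, hypnograms, ground_truth
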