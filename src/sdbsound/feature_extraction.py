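"""Per-window audio features and their per-subject aggregation.

Each 5-s analysis window yields ~100 named values: classical music-
information-retrieval descriptors (spectral shape, MFCC family, LPC,
beat-histogram and area-moment statistics), the amplitudes of the first
three spectral-envelope peaks (F1-F3), gammatone sub-band energies over
eight 500 Hz bands, and A/C/unweighted sound pressure levels. Subject
vectors hold mean/SD of every windowed descriptor and of its first
difference, plus max/min/mean/SD of the formant, sub-band and SPL series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sdbsound import dsp
from sdbsound.io_audio import AudioRecording, segment_windows

_LOG_EPS = 1e-10

# Windowed descriptors aggregated as mean/SD of the raw and first-difference
# series ("Table-1 family").
TABLE1_FEATURES: tuple[str, ...] = (
    "SC",
    "SR",
    "SF",
    "Compactness",
    "SV",
    "RMS",
    "FLEW",
    "ZC",
    "SB",
    "BS",
    "SSB",
    "SF_ZC",
    "SF_SC",
    "SF_FFT",
    *[f"MFCC_{k}" for k in range(13)],
    *[f"CQMFCC_{k}" for k in range(13)],
    *[f"LPC_{k}" for k in range(10)],
    *[f"MM_{k}" for k in range(5)],
    "RDF",
    *[f"AMoM_{k}" for k in range(10)],
    *[f"AMoM_MFCC_{k}" for k in range(10)],
    *[f"AMoM_CQMFCC_{k}" for k in range(10)],
    *[f"AMoM_LCQT_{k}" for k in range(10)],
)

# Descriptors aggregated as max/min/mean/SD of the raw series.
EXTRA_FEATURES: tuple[str, ...] = (
    "F1",
    "F2",
    "F3",
    *[f"sb{k}" for k in range(1, 9)],
    "dBA",
    "dBC",
    "dB",
    "peak_dBA",
    "peak_dBC",
    "peak_dB",
)

TABLE1_STATS = ("mean", "sd")
EXTRA_STATS = ("max", "min", "mean", "sd")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable extraction parameters; defaults follow the pipeline defaults."""

    window_s: float = 5.0
    frame_ms: float = 32.0
    hop_ratio: float = 0.5
    n_mels: int = 26
    n_mfcc: int = 13
    lpc_order: int = 10
    cq_fmin: float = 32.7
    cq_bins_per_octave: int = 12
    amom_patch_frames: int = 10
    n_gammatone: int = 32
    rolloff_fraction: float = 0.85
    flew_subwindow_ms: float = 100.0
    bpm_min: float = 10.0
    bpm_max: float = 240.0
    spl_floor_db: float = -120.0
    calibration_offset: float = 0.0


def feature_schema(config: FeatureConfig | None = None, include_qtm: bool = True) -> list[str]:
    """Ordered list of per-subject feature names (identical across subjects)."""
    names = []
    for feat in TABLE1_FEATURES:
        for stat in TABLE1_STATS:
            names.append(f"{feat}_{stat}")
        for stat in TABLE1_STATS:
            names.append(f"{feat}_d1_{stat}")
    for feat in EXTRA_FEATURES:
        for stat in EXTRA_STATS:
            names.append(f"{feat}_{stat}")
    if include_qtm:
        from sdbsound.qtm import QTM_FEATURE_NAMES

        names.extend(QTM_FEATURE_NAMES)
    return names


class _Analyzer:
    """Kernel cache for a fixed (rate, window length, config)."""

    def __init__(self, rate: int, window_len: int, config: FeatureConfig):
        self.rate = rate
        self.window_len = window_len
        self.config = config
        self.frame_len = round(rate * config.frame_ms / 1000.0)
        self.hop = max(1, round(self.frame_len * config.hop_ratio))
        self.window = np.hanning(self.frame_len)
        self.freqs = np.fft.rfftfreq(self.frame_len, 1.0 / rate)
        self.bin_width = rate / self.frame_len
        self.mel_fb = dsp.mel_filterbank(config.n_mels, self.frame_len, rate)
        self.cq_k, self.cq_centers = dsp.cq_kernel(
            self.frame_len, rate, fmin=config.cq_fmin, bins_per_octave=config.cq_bins_per_octave
        )
        # window-length spectra for sub-bands and SPL
        self.wfreqs = np.fft.rfftfreq(window_len, 1.0 / rate)
        gt_lo, gt_hi = 60.0, min(3950.0, 0.99 * rate / 2.0)
        self.gt_centers = dsp.erb_space(gt_lo, gt_hi, config.n_gammatone)
        self.gt_power = dsp.gammatone_power_response(self.wfreqs, self.gt_centers)
        self.a_gain2 = 10.0 ** (dsp.a_weighting_db(self.wfreqs) / 10.0)
        self.c_gain2 = 10.0 ** (dsp.c_weighting_db(self.wfreqs) / 10.0)


_ANALYZERS: dict[tuple, _Analyzer] = {}


def _get_analyzer(rate: int, window_len: int, config: FeatureConfig) -> _Analyzer:
    key = (rate, window_len, config)
    if key not in _ANALYZERS:
        _ANALYZERS[key] = _Analyzer(rate, window_len, config)
    return _ANALYZERS[key]


def _area_moments(matrix: np.ndarray, patch: int) -> np.ndarray:
    """Mean 2-D area moments over consecutive ``patch``-column blocks of |matrix|.

    Ten values per patch: total mass, then raw moments E[x^i y^j] up to
    combined order three, with x (time) and y (row) normalized to [0, 1].
    """
    m = np.abs(matrix)
    rows, cols = m.shape
    n_patches = cols // patch
    if n_patches == 0:
        n_patches, patch = 1, cols
    m = m[:, : n_patches * patch].reshape(rows, n_patches, patch)
    mass = m.sum(axis=(0, 2))
    y = np.linspace(0.0, 1.0, rows)[:, None, None] if rows > 1 else np.zeros((1, 1, 1))
    x = np.linspace(0.0, 1.0, patch)[None, None, :] if patch > 1 else np.zeros((1, 1, 1))
    safe = np.where(mass > 0, mass, 1.0)
    p = m / safe[None, :, None]
    out = np.empty((10, n_patches))
    out[0] = mass
    k = 1
    for i, j in ((1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)):
        out[k] = (p * (x**i) * (y**j)).sum(axis=(0, 2))
        k += 1
    out[:, mass <= 0] = 0.0
    return out.mean(axis=1)


def _beat_histogram(env: np.ndarray, frame_rate: float, bpm_min: float, bpm_max: float):
    """Strongest beat (BPM), beat sum, and relative strongest-beat strength
    from the autocorrelation of the frame-RMS envelope."""
    n = env.size
    if n < 4 or not np.any(env > 0):
        return 0.0, 0.0, 0.0
    centered = env - env.mean()
    ac = np.correlate(centered, centered, mode="full")[n - 1 :]
    lag_lo = max(1, int(np.floor(frame_rate * 60.0 / bpm_max)))
    lag_hi = min(n - 1, int(np.ceil(frame_rate * 60.0 / bpm_min)))
    if lag_hi <= lag_lo:
        return 0.0, 0.0, 0.0
    hist = np.clip(ac[lag_lo : lag_hi + 1], 0.0, None)
    total = hist.sum()
    if total <= 0:
        return 0.0, 0.0, 0.0
    peak = int(np.argmax(hist))
    strongest_bpm = 60.0 * frame_rate / (lag_lo + peak)
    return strongest_bpm, float(total), float(hist[peak] / total)


def extract_window_features(
    window: np.ndarray, rate: int, config: FeatureConfig | None = None
) -> dict[str, float]:
    """Compute the windowed (Table-1 family) descriptors for one sample block.

    Deterministic, and total: degenerate all-zero windows produce finite
    floor-valued features, never NaN.
    """
    config = config or FeatureConfig()
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 1 or window.size == 0:
        raise ValueError("window must be a non-empty 1-D sample block")
    if rate <= 0:
        raise ValueError("rate must be positive")
    an = _get_analyzer(rate, window.size, config)
    if window.size < an.frame_len:
        raise ValueError("window shorter than one internal analysis frame")

    frames = dsp.frame_signal(window, an.frame_len, an.hop)
    n_frames = frames.shape[0]
    spec = np.abs(np.fft.rfft(frames * an.window, axis=1))  # (frames, bins)
    power = spec**2
    spec_sum = spec.sum(axis=1)
    pow_sum = power.sum(axis=1)
    nonzero = spec_sum > 0
    out: dict[str, float] = {}

    bins = np.arange(spec.shape[1])
    sc_bins = np.where(nonzero, (spec @ bins) / np.where(nonzero, spec_sum, 1.0), 0.0)
    out["SC"] = float(sc_bins.mean())

    cum = np.cumsum(power, axis=1)
    thresh = config.rolloff_fraction * pow_sum[:, None]
    roll_idx = np.argmax(cum >= thresh, axis=1)
    out["SR"] = float(np.where(nonzero, an.freqs[roll_idx], 0.0).mean())

    flux = ((spec[1:] - spec[:-1]) ** 2).sum(axis=1)
    out["SF"] = float(flux.mean()) if flux.size else 0.0

    log_spec = 20.0 * np.log10(spec + _LOG_EPS)
    neigh = (log_spec[:, :-2] + log_spec[:, 1:-1] + log_spec[:, 2:]) / 3.0
    out["Compactness"] = float(np.abs(log_spec[:, 1:-1] - neigh).sum(axis=1).mean())

    out["SV"] = float(spec.std(axis=1).mean())

    rms_env = np.sqrt((frames**2).mean(axis=1))
    out["RMS"] = float(rms_env.mean())

    sub_len = max(1, round(rate * config.flew_subwindow_ms / 1000.0))
    n_sub = window.size // sub_len
    sub_rms = np.sqrt(
        (window[: n_sub * sub_len].reshape(n_sub, sub_len) ** 2).mean(axis=1)
    )
    out["FLEW"] = float((sub_rms < sub_rms.mean()).mean()) if n_sub else 0.0

    sign = np.signbit(window)
    zc = int(np.count_nonzero(sign[1:] != sign[:-1]))
    out["ZC"] = float(zc)

    frame_rate = rate / an.hop
    sb, bs, ssb = _beat_histogram(rms_env, frame_rate, config.bpm_min, config.bpm_max)
    out["SB"], out["BS"], out["SSB"] = sb, bs, ssb

    duration = window.size / rate
    out["SF_ZC"] = zc / (2.0 * duration)
    out["SF_SC"] = out["SC"] * an.bin_width
    out["SF_FFT"] = float(np.where(nonzero, an.freqs[np.argmax(power, axis=1)], 0.0).mean())

    mel_e = an.mel_fb @ power.T  # (mels, frames)
    log_mel = np.log10(mel_e + _LOG_EPS)
    mfcc = dsp.dct_ii(log_mel, config.n_mfcc, axis=0)
    for k in range(config.n_mfcc):
        out[f"MFCC_{k}"] = float(mfcc[k].mean())

    cq = an.cq_k @ spec.T  # (cq bins, frames)
    lcqt = np.log10(cq + _LOG_EPS)
    cqmfcc = dsp.dct_ii(lcqt, config.n_mfcc, axis=0)
    for k in range(config.n_mfcc):
        out[f"CQMFCC_{k}"] = float(cqmfcc[k].mean())

    ac = dsp.autocorrelation(frames, config.lpc_order)
    lpc = dsp.levinson(ac, config.lpc_order)  # (frames, order)
    lpc_mean = lpc.mean(axis=0)
    for k in range(config.lpc_order):
        out[f"LPC_{k}"] = float(lpc_mean[k])

    safe_sum = np.where(nonzero, spec_sum, 1.0)
    w = spec / safe_sum[:, None]
    mu = w @ bins
    var = (w * (bins[None, :] - mu[:, None]) ** 2).sum(axis=1)
    sd = np.sqrt(var)
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (bins[None, :] - mu[:, None]) / safe_sd[:, None]
    skew = np.where(sd > 0, (w * z**3).sum(axis=1), 0.0)
    kurt = np.where(sd > 0, (w * z**4).sum(axis=1), 0.0)
    for k, series in enumerate((spec_sum, mu, sd, skew, kurt)):
        out[f"MM_{k}"] = float(np.where(nonzero, series, 0.0).mean())

    d_rms = np.abs(np.diff(rms_env))
    out["RDF"] = float(np.log10(d_rms + _LOG_EPS).mean()) if d_rms.size else np.log10(_LOG_EPS)

    patch = config.amom_patch_frames
    for prefix, matrix in (
        ("AMoM", spec.T),
        ("AMoM_MFCC", mfcc),
        ("AMoM_CQMFCC", cqmfcc),
        ("AMoM_LCQT", lcqt),
    ):
        moments = _area_moments(matrix, patch)
        for k in range(10):
            out[f"{prefix}_{k}"] = float(moments[k])

    assert len(out) == len(TABLE1_FEATURES)
    return out


def extract_formants(
    window: np.ndarray,
    rate: int,
    n_peaks: int = 3,
    config: FeatureConfig | None = None,
    return_frequencies: bool = False,
):
    """Amplitudes (dB) of the first ``n_peaks`` peaks of the LPC spectral envelope.

    Peaks are local maxima of the gain-scaled order-10 LPC envelope, in
    ascending frequency. If fewer peaks exist (flat envelopes), missing
    entries are filled with the envelope level at the upper band edge.
    With ``return_frequencies`` the peak frequencies (Hz) are returned too.
    """
    config = config or FeatureConfig()
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("window must be non-empty")
    an = _get_analyzer(rate, window.size, config)
    if window.size < an.frame_len:
        raise ValueError("window shorter than one internal analysis frame")
    frames = dsp.frame_signal(window, an.frame_len, an.hop)
    ac = dsp.autocorrelation(frames, config.lpc_order).mean(axis=0)
    coeffs, err = dsp.levinson(ac[None, :], config.lpc_order, return_error=True)
    coeffs, err = coeffs[0], float(err[0])
    n_grid = 512
    omega = np.pi * np.arange(n_grid) / n_grid
    a_poly = np.concatenate(([1.0], -coeffs))
    denom = np.abs(np.exp(-1j * np.outer(omega, np.arange(a_poly.size))) @ a_poly)
    env = np.sqrt(max(err, 0.0)) / np.maximum(denom, 1e-12)
    env_db = 20.0 * np.log10(env + _LOG_EPS)
    interior = (env_db[1:-1] > env_db[:-2]) & (env_db[1:-1] >= env_db[2:])
    peaks = np.flatnonzero(interior) + 1
    grid_hz = omega / (2.0 * np.pi) * rate
    amplitudes = list(env_db[peaks[:n_peaks]])
    frequencies = list(grid_hz[peaks[:n_peaks]])
    if len(amplitudes) < n_peaks:
        warnings.warn(
            f"only {len(amplitudes)} spectral-envelope peaks found; "
            "padding with the band-edge level",
            stacklevel=2,
        )
        amplitudes.extend([float(env_db[-1])] * (n_peaks - len(amplitudes)))
        frequencies.extend([float(grid_hz[-1])] * (n_peaks - len(frequencies)))
    amps = np.array(amplitudes[:n_peaks])
    if return_frequencies:
        return amps, np.array(frequencies[:n_peaks])
    return amps


def extract_subband_energies(
    window: np.ndarray, rate: int, config: FeatureConfig | None = None
) -> np.ndarray:
    """Gammatone-filterbank energy per 500 Hz sub-band (sb1..sb8, 0-4000 Hz).

    The filterbank is evaluated in the frequency domain; each filter's output
    energy is assigned to the 500 Hz band containing its centre frequency.
    """
    config = config or FeatureConfig()
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("window must be non-empty")
    an = _get_analyzer(rate, window.size, config)
    power = np.abs(np.fft.rfft(window)) ** 2
    filt_energy = an.gt_power @ power
    bands = np.zeros(8)
    band_idx = np.minimum((an.gt_centers // 500.0).astype(int), 7)
    np.add.at(bands, band_idx, filt_energy)
    if rate < 8000:
        nyq_band = int(rate / 2.0 // 500.0)
        if nyq_band < 8:
            warnings.warn(
                f"rate {rate} Hz cannot populate sub-bands above {nyq_band + 1}; zero-filled",
                stacklevel=2,
            )
            bands[np.flatnonzero(np.arange(8) * 500.0 >= rate / 2.0)] = 0.0
    return bands


def extract_weighted_spl(
    window: np.ndarray,
    rate: int,
    calibration_offset: float = 0.0,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """A-, C- and un-weighted RMS and peak levels of a window, in dB.

    Levels are relative to digital full scale plus ``calibration_offset``;
    silent windows clamp at the configured floor instead of -inf.
    """
    config = config or FeatureConfig()
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("window must be non-empty")
    an = _get_analyzer(rate, window.size, config)
    floor = config.spl_floor_db

    def level(x: np.ndarray, peak: bool) -> float:
        v = np.max(np.abs(x)) if peak else np.sqrt(np.mean(x**2))
        if v <= 0:
            return floor
        return max(20.0 * np.log10(v) + calibration_offset, floor)

    spectrum = np.fft.rfft(window)
    n = window.size
    out = {"dB": level(window, False), "peak_dB": level(window, True)}
    for name, gain2 in (("dBA", an.a_gain2), ("dBC", an.c_gain2)):
        weighted = np.fft.irfft(spectrum * np.sqrt(gain2), n=n)
        out[name] = level(weighted, False)
        out[f"peak_{name}"] = level(weighted, True)
    return out


def first_derivative(series: np.ndarray) -> np.ndarray:
    """First difference: output[k] = series[k+1] - series[k] (length N-1)."""
    series = np.asarray(series, dtype=np.float64)
    if series.size < 2:
        raise ValueError("need at least two values to differentiate")
    return np.diff(series)


def aggregate_subject(frames: list[dict[str, float]] | pd.DataFrame) -> dict[str, float]:
    """Aggregate per-window feature frames to one per-subject vector.

    Windowed descriptors contribute mean/SD of the raw and first-difference
    series; formant/sub-band/SPL descriptors contribute max/min/mean/SD.
    Sample SD (n-1 denominator) is used throughout, so at least two frames
    are required.
    """
    table = pd.DataFrame(frames) if not isinstance(frames, pd.DataFrame) else frames
    if len(table) < 2:
        raise ValueError("at least two window frames are required (SD undefined otherwise)")
    out: dict[str, float] = {}
    for feat in TABLE1_FEATURES:
        series = table[feat].to_numpy(dtype=np.float64)
        d1 = np.diff(series)
        out[f"{feat}_mean"] = float(series.mean())
        out[f"{feat}_sd"] = float(series.std(ddof=1))
        out[f"{feat}_d1_mean"] = float(d1.mean())
        out[f"{feat}_d1_sd"] = float(d1.std(ddof=1)) if d1.size > 1 else 0.0
    for feat in EXTRA_FEATURES:
        series = table[feat].to_numpy(dtype=np.float64)
        out[f"{feat}_max"] = float(series.max())
        out[f"{feat}_min"] = float(series.min())
        out[f"{feat}_mean"] = float(series.mean())
        out[f"{feat}_sd"] = float(series.std(ddof=1))
    return out


def extract_window_frame(
    window: np.ndarray, rate: int, config: FeatureConfig | None = None
) -> dict[str, float]:
    """All per-window descriptors (windowed family + formants, sub-bands, SPLs)."""
    config = config or FeatureConfig()
    frame = extract_window_features(window, rate, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f123 = extract_formants(window, rate, config=config)
    frame["F1"], frame["F2"], frame["F3"] = map(float, f123)
    sb = extract_subband_energies(window, rate, config)
    for k in range(8):
        frame[f"sb{k + 1}"] = float(sb[k])
    frame.update(extract_weighted_spl(window, rate, config.calibration_offset, config))
    return frame


def extract_subject_features(
    rec: AudioRecording,
    config: FeatureConfig | None = None,
    return_frames: bool = False,
):
    """Segment a recording into windows and aggregate all window descriptors.

    Returns the per-subject feature dict, or ``(vector, frames_dataframe)``
    with ``return_frames``.
    """
    config = config or FeatureConfig()
    seq = segment_windows(rec, config.window_s)
    if len(seq) < 2:
        raise ValueError(
            f"recording of {rec.duration_seconds:.1f} s yields fewer than two "
            f"{config.window_s} s windows"
        )
    frames = [extract_window_frame(w, rec.rate, config) for w in seq.windows]
    table = pd.DataFrame(frames)
    vector = aggregate_subject(table)
    if return_frames:
        return vector, table
    return vector
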