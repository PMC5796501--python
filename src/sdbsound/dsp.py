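"""Signal-processing primitives shared by the feature extractors.

Everything here is plain numpy/scipy: short-time framing, mel and
constant-Q analysis kernels, a gammatone filterbank evaluated in the
frequency domain, IEC 61672 A/C weighting curves, and a batched
Levinson-Durbin recursion for LPC.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Slice ``x`` into overlapping frames of ``frame_len`` samples (rows)."""
    if x.size < frame_len:
        raise ValueError("signal shorter than one frame")
    return sliding_window_view(x, frame_len)[::hop]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, rate: float, fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank matrix of shape (n_mels, n_fft//2 + 1)."""
    if fmax is None:
        fmax = rate / 2.0
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    edges = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    fb = np.zeros((n_mels, freqs.size))
    for m in range(n_mels):
        lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def cq_kernel(
    n_fft: int,
    rate: float,
    fmin: float = 32.7,
    bins_per_octave: int = 12,
    fmax: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Constant-Q analysis kernel mapping an rFFT magnitude spectrum to CQ bins.

    Each CQ bin is a unit-sum triangular aggregation of FFT bins centred at a
    geometrically spaced frequency with constant-Q bandwidth. Returns
    ``(kernel, center_freqs)`` with kernel shape (n_cq, n_fft//2 + 1).
    """
    if fmax is None:
        fmax = rate / 2.0
    n_bins = int(np.floor(bins_per_octave * np.log2(fmax / fmin))) + 1
    centers = fmin * 2.0 ** (np.arange(n_bins) / bins_per_octave)
    q_bw = centers * (2.0 ** (1.0 / bins_per_octave) - 1.0)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    bin_width = rate / n_fft
    # bandwidth never narrower than one FFT bin, otherwise low bins vanish
    half = np.maximum(q_bw, bin_width)
    resp = np.clip(1.0 - np.abs(freqs[None, :] - centers[:, None]) / half[:, None], 0.0, None)
    resp /= np.maximum(resp.sum(axis=1, keepdims=True), 1e-12)
    return resp, centers


def erb_bandwidth(fc):
    """Equivalent rectangular bandwidth of the human auditory filter at fc (Hz)."""
    fc = np.asarray(fc, dtype=np.float64)
    return 24.7 * (4.37 * fc / 1000.0 + 1.0)


def erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """``n`` centre frequencies uniformly spaced on the ERB-number scale."""
    def to_erb(f):
        return 21.4 * np.log10(1.0 + 0.00437 * f)

    def from_erb(e):
        return (10.0 ** (e / 21.4) - 1.0) / 0.00437

    return from_erb(np.linspace(to_erb(fmin), to_erb(fmax), n))


def gammatone_power_response(freqs: np.ndarray, centers: np.ndarray, order: int = 4) -> np.ndarray:
    """Squared magnitude response of a gammatone filterbank on a frequency grid.

    Uses the standard all-pole approximation
    ``|H(f)|^2 = (1 + ((f - fc) / b)^2)^(-order)`` with ``b = 1.019 ERB(fc)``;
    rows are filters, columns frequency bins.
    """
    b = 1.019 * erb_bandwidth(centers)
    x = (freqs[None, :] - centers[:, None]) / b[:, None]
    return (1.0 + x**2) ** (-float(order))


def a_weighting_db(freqs) -> np.ndarray:
    """IEC 61672 A-weighting in dB (0 dB at 1 kHz)."""
    f2 = np.asarray(freqs, dtype=np.float64) ** 2
    num = (12194.0**2) * f2**2
    den = (f2 + 20.6**2) * np.sqrt((f2 + 107.7**2) * (f2 + 737.9**2)) * (f2 + 12194.0**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ra = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        db = 20.0 * np.log10(np.where(ra > 0, ra, 1e-30)) + 2.0
    return db


def c_weighting_db(freqs) -> np.ndarray:
    """IEC 61672 C-weighting in dB (0 dB at 1 kHz)."""
    f2 = np.asarray(freqs, dtype=np.float64) ** 2
    num = (12194.0**2) * f2
    den = (f2 + 20.6**2) * (f2 + 12194.0**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rc = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        db = 20.0 * np.log10(np.where(rc > 0, rc, 1e-30)) + 0.06
    return db


def levinson(r: np.ndarray, order: int, return_error: bool = False):
    """Batched Levinson-Durbin: autocorrelations ``r[..., :order+1]`` -> LPC coefficients.

    Returns the prediction coefficients a_1..a_order (sign convention:
    x[t] ~= sum_k a_k x[t-k]) with shape ``r.shape[:-1] + (order,)``.
    Degenerate rows (r0 == 0) yield all-zero coefficients. With
    ``return_error`` the final prediction-error power is returned as well.
    """
    r = np.asarray(r, dtype=np.float64)
    batch = r.shape[:-1]
    a = np.zeros(batch + (order + 1,))
    a[..., 0] = 1.0
    err = r[..., 0].copy()
    dead = err <= 0
    err = np.where(dead, 1.0, err)
    for i in range(1, order + 1):
        acc = np.einsum("...j,...j->...", a[..., :i], r[..., i:0:-1][..., -i:])
        k = -acc / err
        k = np.where(dead, 0.0, k)
        # a_new[j] = a[j] + k * a[i - j]
        a[..., 1 : i + 1] = a[..., 1 : i + 1] + k[..., None] * a[..., i - 1 :: -1][..., :i]
        err = err * (1.0 - k**2)
        err = np.where(err <= 1e-300, 1e-300, err)
    coeffs = -a[..., 1:]
    if return_error:
        return coeffs, np.where(dead, 0.0, err)
    return coeffs


def autocorrelation(frames: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocorrelation of each row up to ``max_lag`` (inclusive), via FFT."""
    n = frames.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frames, n=nfft, axis=-1)
    ac = np.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=-1)[..., : max_lag + 1]
    return ac


def dct_ii(x: np.ndarray, n_out: int, axis: int = 0) -> np.ndarray:
    """Orthonormal DCT-II truncated to the first ``n_out`` coefficients."""
    return np.take(dct(x, type=2, norm="ortho", axis=axis), np.arange(n_out), axis=axis)
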