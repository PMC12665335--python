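"""Per-motif sonic time series: f0, Δf0, loudness, spectral centroid.

The conditioning order is fixed: pitch tracking → gap interpolation →
Gaussian smoothing → Δf0.  Loudness and spectral centroid come from a
short-time Fourier transform of the raw audio and are smoothed with the
same Gaussian.  All four series live on one frame grid (default 100 Hz).

Loudness is decibels relative to the maximum frame power of a reference
extent, L_t = 10·log10(P_t / ref) with ref = max_t P_t, so the loudest
frame is 0 dB; a −80 dB floor is applied.  Δf0 is the Keogh–Pazzani
estimated derivative

    D_i = ((q_i − q_{i−1}) + (q_{i+1} − q_{i−1}) / 2) / 2

with endpoints replicating the nearest interior value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

__all__ = [
    "SonicFeatures",
    "estimate_f0",
    "interpolate_gaps",
    "smooth_gaussian",
    "delta_f0",
    "loudness",
    "spectral_centroid",
    "compute_sonic_features",
]

DEFAULT_FRAME_RATE_HZ = 100.0
DEFAULT_SIGMA_SAMPLES = 2.5
MAX_GAP_S = 0.350
LOUDNESS_FLOOR_DB = -80.0
STFT_WINDOW_S = 0.046


@dataclass
class SonicFeatures:
    """The four per-motif sonic series on a shared time base."""

    f0: np.ndarray
    delta_f0: np.ndarray
    loudness: np.ndarray
    spectral_centroid: np.ndarray
    rate: float
    voiced_mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.f0)
        for name in ("delta_f0", "loudness", "spectral_centroid", "voiced_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"sonic series {name!r} length differs from f0")
        if np.any(self.loudness > 1e-9):
            raise ValueError("loudness must be <= 0 dB (max-referenced)")
        if np.any(self.f0[self.voiced_mask] <= 0):
            raise ValueError("voiced f0 must be positive")

    def __len__(self) -> int:
        return len(self.f0)


def _frame_grid(n_samples: int, sample_rate: float, frame_rate: float) -> int:
    return max(1, int(np.floor(n_samples / sample_rate * frame_rate)))


def estimate_f0(
    waveform: np.ndarray,
    sample_rate: float,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    fmin: float = 65.0,
    fmax: float = 1000.0,
    voicing_threshold: float = 0.5,
    silence_db: float = -50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise autocorrelation pitch tracker.

    For each analysis frame the normalized autocorrelation is searched for
    its highest peak in the candidate lag range; the lag is refined by
    parabolic interpolation.  A frame is voiced when the peak correlation
    exceeds ``voicing_threshold`` and the frame RMS is above ``silence_db``
    relative to the loudest frame.  Unvoiced frames carry f0 = NaN.
    """
    x = np.asarray(waveform, dtype=np.float64)
    n_frames = _frame_grid(len(x), sample_rate, frame_rate)
    hop = sample_rate / frame_rate
    win = int(round(sample_rate * 0.05))
    lag_min = max(2, int(np.floor(sample_rate / fmax)))
    lag_max = int(np.ceil(sample_rate / fmin))
    f0 = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    rms = np.zeros(n_frames)
    frames = []
    for k in range(n_frames):
        c = int(round(k * hop))
        seg = x[max(0, c - win // 2): c + win // 2]
        if len(seg) < lag_max + 2:
            seg = np.pad(seg, (0, lag_max + 2 - len(seg)))
        seg = seg - seg.mean()
        frames.append(seg)
        rms[k] = np.sqrt(np.mean(seg**2))
    peak_rms = rms.max() if rms.size else 0.0
    if peak_rms <= 0:
        warnings.warn("silent input: no voiced frames", stacklevel=2)
        return f0, voiced
    floor = peak_rms * 10 ** (silence_db / 20)
    for k, seg in enumerate(frames):
        if rms[k] <= floor:
            continue
        # autocorrelation via FFT
        nfft = int(2 ** np.ceil(np.log2(2 * len(seg))))
        spec = np.fft.rfft(seg, nfft)
        ac = np.fft.irfft(spec * np.conj(spec))[: lag_max + 2]
        if ac[0] <= 0:
            continue
        ac = ac / ac[0]
        search = ac[lag_min: lag_max + 1]
        peak = int(np.argmax(search)) + lag_min
        if ac[peak] < voicing_threshold:
            continue
        # parabolic refinement around the integer-lag peak
        if 1 <= peak < len(ac) - 1:
            y0, y1, y2 = ac[peak - 1], ac[peak], ac[peak + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f0[k] = sample_rate / (peak + delta)
        voiced[k] = True
    if not voiced.any():
        warnings.warn("no voiced frames detected", stacklevel=2)
    return f0, voiced


def interpolate_gaps(
    f0: np.ndarray,
    voiced_mask: np.ndarray,
    rate: float,
    max_gap_s: float = MAX_GAP_S,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Linearly fill interior unvoiced runs of at most ``max_gap_s``.

    Runs bounded by voiced frames on both sides and no longer than the
    threshold are filled by linear interpolation between the flanking
    voiced values and marked voiced.  Longer interior runs are left
    untouched and flagged: the returned ``ok`` is False if any interior
    gap above the threshold remains (such a motif is excluded from the
    distance table downstream, never silently included).  Leading and
    trailing unvoiced frames are not interior gaps.
    """
    f0 = np.asarray(f0, dtype=np.float64).copy()
    voiced = np.asarray(voiced_mask, dtype=bool).copy()
    max_len = int(np.floor(max_gap_s * rate + 1e-9))
    ok = True
    n = len(f0)
    i = 0
    while i < n:
        if voiced[i]:
            i += 1
            continue
        j = i
        while j < n and not voiced[j]:
            j += 1
        interior = i > 0 and j < n
        if interior:
            if j - i <= max_len:
                span = j - i + 1
                fill = np.linspace(f0[i - 1], f0[j], span + 1)[1:-1]
                f0[i:j] = fill
                voiced[i:j] = True
            else:
                ok = False
        i = j
    return f0, voiced, ok


def smooth_gaussian(series: np.ndarray, sigma_samples: float = DEFAULT_SIGMA_SAMPLES) -> np.ndarray:
    """Truncated discrete Gaussian smoothing (radius 4σ, reflected edges)."""
    series = np.asarray(series, dtype=np.float64)
    if series.size == 0:
        raise ValueError("cannot smooth an empty series")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    return gaussian_filter1d(series, sigma_samples, mode="reflect", truncate=4.0)


def delta_f0(f0: np.ndarray) -> np.ndarray:
    """Keogh–Pazzani estimated first derivative of a (smoothed) f0 curve."""
    q = np.asarray(f0, dtype=np.float64)
    if len(q) < 3:
        raise ValueError("delta_f0 needs at least 3 frames")
    d = np.empty_like(q)
    d[1:-1] = ((q[1:-1] - q[:-2]) + (q[2:] - q[:-2]) / 2.0) / 2.0
    d[0] = d[1]
    d[-1] = d[-2]
    return d


def _stft_mag(waveform: np.ndarray, sample_rate: float, frame_rate: float):
    x = np.asarray(waveform, dtype=np.float64)
    win_len = max(8, int(round(sample_rate * STFT_WINDOW_S)))
    hop = max(1, int(round(sample_rate / frame_rate)))
    stft = ShortTimeFFT(hann(win_len, sym=False), hop=hop, fs=sample_rate)
    X = stft.stft(x)
    n_frames = _frame_grid(len(x), sample_rate, frame_rate)
    mags = np.abs(X)
    # ShortTimeFFT frame p is centred on sample p*hop, matching our grid
    mags = mags[:, :n_frames] if mags.shape[1] >= n_frames else np.pad(
        mags, ((0, 0), (0, n_frames - mags.shape[1]))
    )
    freqs = stft.f
    return mags, freqs


def loudness(
    waveform: np.ndarray,
    sample_rate: float,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    ref_power: float | None = None,
    floor_db: float = LOUDNESS_FLOOR_DB,
) -> tuple[np.ndarray, float]:
    """Frame loudness in dB relative to the maximum frame power.

    Returns ``(loudness_db, ref)`` where ``ref`` is the reference power
    actually used: ``ref_power`` when given (e.g. the parent performance's
    maximum, keeping motifs comparable within a performance), else the
    maximum frame power of this waveform.
    """
    mags, _ = _stft_mag(waveform, sample_rate, frame_rate)
    power = np.sum(mags**2, axis=0)
    ref = float(ref_power) if ref_power is not None else float(power.max())
    if ref <= 0:
        warnings.warn("all-zero audio: loudness at floor", stacklevel=2)
        return np.full(power.shape, floor_db), 0.0
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power / ref)
    db = np.maximum(db, floor_db)
    db = np.minimum(db, 0.0)
    return db, ref


def spectral_centroid(
    waveform: np.ndarray,
    sample_rate: float,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-weighted mean frequency per frame, Σ f·|X(f)| / Σ |X(f)|.

    Silent frames have no defined centroid; they carry the previous frame's
    value (the first frames, if silent, carry the first defined value) and
    are flagged False in the returned mask.
    """
    mags, freqs = _stft_mag(waveform, sample_rate, frame_rate)
    total = mags.sum(axis=0)
    defined = total > 1e-12 * max(1.0, float(total.max()))
    cent = np.zeros_like(total)
    cent[defined] = (freqs[:, None] * mags).sum(axis=0)[defined] / total[defined]
    if defined.any():
        # forward-fill undefined frames; back-fill a silent head
        last = np.nan
        for k in range(len(cent)):
            if defined[k]:
                last = cent[k]
            elif not np.isnan(last):
                cent[k] = last
        first = cent[defined][0]
        for k in range(len(cent)):
            if defined[k]:
                break
            cent[k] = first
    return cent, defined


def compute_sonic_features(
    waveform: np.ndarray | None,
    sample_rate: float | None,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    sigma_samples: float = DEFAULT_SIGMA_SAMPLES,
    max_gap_s: float = MAX_GAP_S,
    ref_power: float | None = None,
    f0_track: np.ndarray | None = None,
    loudness_track: np.ndarray | None = None,
    centroid_track: np.ndarray | None = None,
) -> tuple[SonicFeatures, bool]:
    """Full sonic pipeline for one motif: f0 → gaps → smoothing → Δf0.

    Either raw audio (``waveform`` + ``sample_rate``) or precomputed tracks
    on the frame grid may be supplied; precomputed tracks take precedence.
    Returns the features and the gap flag ``ok`` (False when an interior
    pitch gap longer than ``max_gap_s`` survives interpolation).
    """
    if f0_track is not None:
        f0 = np.asarray(f0_track, dtype=np.float64)
        voiced = np.isfinite(f0) & (f0 > 0)
    else:
        if waveform is None or sample_rate is None:
            raise ValueError("need audio or a precomputed f0 track")
        f0, voiced = estimate_f0(waveform, sample_rate, frame_rate)

    f0, voiced, ok = interpolate_gaps(f0, voiced, frame_rate, max_gap_s)
    # trim unvoiced edges off the common time base
    idx = np.flatnonzero(voiced)
    if idx.size == 0:
        raise ValueError("motif has no voiced frames")
    lo, hi = int(idx[0]), int(idx[-1]) + 1

    if loudness_track is not None:
        loud = np.asarray(loudness_track, dtype=np.float64)
    else:
        if waveform is None or sample_rate is None:
            raise ValueError("need audio or a precomputed loudness track")
        loud, _ = loudness(waveform, sample_rate, frame_rate, ref_power=ref_power)
    if centroid_track is not None:
        cent = np.asarray(centroid_track, dtype=np.float64)
    else:
        cent, _ = spectral_centroid(waveform, sample_rate, frame_rate)

    n = min(len(f0), len(loud), len(cent))
    lo, hi = min(lo, n), min(hi, n)
    if hi - lo < 3:
        raise ValueError("motif too short after edge trimming")
    f0_s = smooth_gaussian(np.where(voiced[:n], f0[:n], np.interp(
        np.arange(n), np.flatnonzero(voiced[:n]), f0[:n][voiced[:n]]))[lo:hi], sigma_samples)
    loud_s = np.minimum(smooth_gaussian(loud[lo:hi], sigma_samples), 0.0)
    cent_s = smooth_gaussian(cent[lo:hi], sigma_samples)
    feats = SonicFeatures(
        f0=f0_s,
        delta_f0=delta_f0(f0_s),
        loudness=loud_s,
        spectral_centroid=cent_s,
        rate=frame_rate,
        voiced_mask=voiced[lo:hi],
    )
    return feats, ok
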