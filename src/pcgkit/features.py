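"""Per-cycle feature extraction: 10 time-domain statistics, 4 spectral
features, and 13 MFCCs — 27 values per heart cycle in a fixed canonical
order.

Conventions that matter for reproducibility:

* standard deviation uses the n-1 denominator; skewness and kurtosis are
  the third/fourth central moments over N divided by s^3 / s^4 (with that
  same n-1 s), kurtosis reported as excess (-3);
* Shannon entropy is computed on a fixed-count amplitude histogram
  (32 bins over the cycle's min-max), log base 2;
* spectral entropy is the Shannon entropy of the normalized power spectrum
  divided by log2(N_freqs), so it lies in [0, 1];
* MFCCs use pre-emphasis x[n] - 0.95 x[n-1], short-time frames (25 ms,
  10 ms hop, Hamming), a 26-triangle mel filterbank over 20-600 Hz,
  log energies, orthonormal DCT-II; coefficients 1-13 (the 0th excluded)
  averaged across frames;
* moments of a constant cycle are defined as 0 rather than NaN so
  downstream classifiers never see non-finite values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft, rfftfreq

#: Canonical feature order. Column order everywhere in the package.
FEATURE_NAMES = (
    "mean", "median", "std", "mad", "p25", "p75", "iqr",
    "skewness", "kurtosis", "shannon_entropy",
    "spectral_entropy", "f_max", "mag_at_fmax", "energy_ratio",
) + tuple(f"mfcc_{i}" for i in range(1, 14))

N_FEATURES = len(FEATURE_NAMES)  # 27


@dataclass
class FeatureConfig:
    entropy_bins: int = 32
    delta_f_hz: float = 10.0          # half-window for the energy ratio
    mfcc_n_coeffs: int = 13
    mfcc_preemphasis: float = 0.95
    mfcc_n_mel_filters: int = 26
    mfcc_fmin_hz: float = 20.0
    mfcc_fmax_hz: float = 600.0
    mfcc_frame_s: float = 0.025
    mfcc_hop_s: float = 0.010
    mfcc_whole_cycle: bool = False    # single-frame analysis of the whole cycle
    log_floor: float = 1e-12

    def __post_init__(self):
        if self.mfcc_n_coeffs > self.mfcc_n_mel_filters:
            raise ValueError("mfcc_n_coeffs must be <= mfcc_n_mel_filters")
        if self.delta_f_hz <= 0:
            raise ValueError("delta_f_hz must be positive")


@dataclass
class FeatureVector:
    """Ordered, named feature values for one heart cycle."""

    values: np.ndarray
    names: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.size != len(self.names):
            raise ValueError("values and names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def __len__(self):
        return self.values.size

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def _cycle_samples(cycle) -> np.ndarray:
    return np.asarray(getattr(cycle, "samples", cycle), float)


def time_features(cycle, config: FeatureConfig | None = None) -> np.ndarray:
    """The ten time-domain statistics, in canonical order."""
    config = config or FeatureConfig()
    x = _cycle_samples(cycle)
    n = x.size
    if n < 4:
        raise ValueError("cycle must have at least 4 samples")
    xbar = np.sum(x) / n
    med = np.median(x)
    s = np.sqrt(np.sum((x - xbar) ** 2) / (n - 1))
    mad = np.sum(np.abs(x - xbar)) / n  # mean absolute deviation
    p25, p75 = np.percentile(x, [25, 75])  # linear interpolation rule
    iqr = p75 - p25
    if np.max(x) == np.min(x):  # degenerate constant cycle
        s = 0.0
        skew = kurt = 0.0
    else:
        skew = np.sum((x - xbar) ** 3) / n / s ** 3
        kurt = np.sum((x - xbar) ** 4) / n / s ** 4 - 3.0
    entropy = _amplitude_entropy(x, config.entropy_bins)
    return np.array([xbar, med, s, mad, p25, p75, iqr, skew, kurt, entropy])


def _amplitude_entropy(x: np.ndarray, bins: int) -> float:
    if np.max(x) == np.min(x):
        return 0.0
    counts, _edges = np.histogram(x, bins=bins)
    p = counts / x.size
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def freq_features(cycle, config: FeatureConfig | None = None,
                  sample_rate_hz: int | None = None) -> np.ndarray:
    """Spectral entropy, peak frequency, magnitude at the peak, and the
    energy ratio in ``f_max`` +/- ``delta_f`` over the whole spectrum."""
    config = config or FeatureConfig()
    x = _cycle_samples(cycle)
    fs = sample_rate_hz or getattr(cycle, "sample_rate_hz", 2000)
    if x.size < 8:
        raise ValueError("cycle must have at least 8 samples")
    if not np.any(x):
        raise ValueError("zero cycle has no spectrum")
    X = rfft(x)
    power = np.abs(X) ** 2
    freqs = rfftfreq(x.size, d=1.0 / fs)
    total = np.sum(power)
    p = power / total
    p_nz = p[p > 0]
    n_freqs = power.size
    sen = float(-np.sum(p_nz * np.log2(p_nz)) / np.log2(n_freqs))
    k = 1 + int(np.argmax(power[1:]))  # DC excluded from the peak search
    f_max = float(freqs[k])
    mag = float(np.abs(X[k]))
    band = np.abs(freqs - f_max) <= config.delta_f_hz
    ratio = float(np.sum(power[band]) / total)
    return np.array([sen, f_max, mag, ratio])


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, fs: float,
                   fmin: float, fmax: float) -> np.ndarray:
    """Triangular mel filterbank, shape (n_filters, nfft//2 + 1)."""
    pts = _mel_inv(np.linspace(_mel(fmin), _mel(fmax), n_filters + 2))
    bin_freqs = rfftfreq(nfft, d=1.0 / fs)
    fb = np.zeros((n_filters, bin_freqs.size))
    for m in range(n_filters):
        lo, ctr, hi = pts[m], pts[m + 1], pts[m + 2]
        up = (bin_freqs - lo) / (ctr - lo)
        down = (hi - bin_freqs) / (hi - ctr)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def preemphasize(x: np.ndarray, alpha: float = 0.95) -> np.ndarray:
    """y[n] = x[n] - alpha * x[n-1], with x[-1] = 0."""
    x = np.asarray(x, float)
    y = x.copy()
    y[1:] -= alpha * x[:-1]
    return y


def mfcc_features(cycle, config: FeatureConfig | None = None,
                  sample_rate_hz: int | None = None) -> np.ndarray:
    """Thirteen mel-frequency cepstral coefficients for one cycle.

    Short-time frames are analyzed independently and the retained
    coefficients (1..13, 0th excluded) are averaged across frames. A cycle
    shorter than one frame falls back to single-frame analysis.
    """
    config = config or FeatureConfig()
    x = _cycle_samples(cycle)
    fs = sample_rate_hz or getattr(cycle, "sample_rate_hz", 2000)
    if x.size < 32:
        raise ValueError("cycle must have at least 32 samples for MFCC analysis")
    x = preemphasize(x, config.mfcc_preemphasis)
    frame = int(round(config.mfcc_frame_s * fs))
    hop = max(1, int(round(config.mfcc_hop_s * fs)))
    if config.mfcc_whole_cycle or x.size < frame:
        frames = [x]
    else:
        n_frames = 1 + (x.size - frame) // hop
        frames = [x[i * hop:i * hop + frame] for i in range(n_frames)]
    nfft = 256
    fb = mel_filterbank(config.mfcc_n_mel_filters, nfft, fs,
                        config.mfcc_fmin_hz, config.mfcc_fmax_hz)
    coefs = np.zeros((len(frames), config.mfcc_n_coeffs))
    for i, fr in enumerate(frames):
        w = fr * np.hamming(fr.size)
        spec = np.abs(rfft(w, n=nfft)) ** 2
        energies = fb @ spec
        log_e = np.log(np.maximum(energies, config.log_floor))
        cep = dct(log_e, type=2, norm="ortho")
        coefs[i] = cep[1:config.mfcc_n_coeffs + 1]
    return coefs.mean(axis=0)


def extract_features(cycle, config: FeatureConfig | None = None,
                     sample_rate_hz: int | None = None) -> FeatureVector:
    """Concatenate the time, spectral and MFCC blocks: the full 27-vector."""
    config = config or FeatureConfig()
    try:
        values = np.concatenate([
            time_features(cycle, config),
            freq_features(cycle, config, sample_rate_hz),
            mfcc_features(cycle, config, sample_rate_hz),
        ])
    except ValueError as exc:
        cid = getattr(cycle, "s1_index", "?")
        raise ValueError(f"feature extraction failed for cycle at s1={cid}: {exc}") from exc
    return FeatureVector(values, FEATURE_NAMES)
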