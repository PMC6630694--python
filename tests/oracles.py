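"""Independent straight-line reference implementations used only by tests.

Everything here is written with explicit loops and textbook formulas,
deliberately avoiding the package's own code paths (and, for the DCT and
filterbank, avoiding scipy's transforms) so that agreement is meaningful.
"""

import math

import numpy as np


# -- time-domain statistics ------------------------------------------------

def mean(x):
    return sum(x) / len(x)


def std_n_minus_1(x):
    m = mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def mean_abs_dev(x):
    m = mean(x)
    return sum(abs(v - m) for v in x) / len(x)


def percentile_linear(x, q):
    """Linear interpolation between order statistics (the numpy default)."""
    s = sorted(x)
    pos = (len(s) - 1) * q / 100.0
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def skewness(x):
    m = mean(x)
    s = std_n_minus_1(x)
    n = len(x)
    return sum((v - m) ** 3 for v in x) / n / s ** 3


def excess_kurtosis(x):
    m = mean(x)
    s = std_n_minus_1(x)
    n = len(x)
    return sum((v - m) ** 4 for v in x) / n / s ** 4 - 3.0


def shannon_entropy_hist(x, bins):
    lo, hi = min(x), max(x)
    counts = [0] * bins
    for v in x:
        k = int((v - lo) / (hi - lo) * bins)
        if k == bins:  # right edge closed
            k = bins - 1
        counts[k] += 1
    h = 0.0
    for c in counts:
        if c:
            p = c / len(x)
            h -= p * math.log2(p)
    return h


# -- spectral features -----------------------------------------------------

def power_spectrum(x):
    """One-sided |rfft|^2 (np.fft is a shared primitive, not the code under test)."""
    return np.abs(np.fft.rfft(x)) ** 2


def spectral_entropy(x):
    p = power_spectrum(x)
    p = p / p.sum()
    h = 0.0
    for v in p:
        if v > 0:
            h -= v * math.log2(v)
    return h / math.log2(len(p))


def f_max(x, fs):
    p = power_spectrum(x)
    k = 1 + int(np.argmax(p[1:]))
    return k * fs / len(x)


def energy_ratio(x, fs, delta_f):
    p = power_spectrum(x)
    fmax = f_max(x, fs)
    num = 0.0
    for k in range(len(p)):
        if abs(k * fs / len(x) - fmax) <= delta_f:
            num += p[k]
    return num / p.sum()


# -- MFCC ------------------------------------------------------------------

def mel(f):
    return 2595.0 * math.log10(1.0 + f / 700.0)


def mel_inv(m):
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mfcc_single_frame(frame, fs, n_filters, fmin, fmax, nfft, n_coeffs,
                      log_floor):
    """MFCCs of one pre-emphasized frame with explicit filter/cosine loops."""
    w = [frame[i] * (0.54 - 0.46 * math.cos(2 * math.pi * i / (len(frame) - 1)))
         for i in range(len(frame))]
    spec = np.abs(np.fft.rfft(w, n=nfft)) ** 2
    pts = [mel_inv(mel(fmin) + (mel(fmax) - mel(fmin)) * i / (n_filters + 1))
           for i in range(n_filters + 2)]
    energies = []
    for m in range(n_filters):
        lo, ctr, hi = pts[m], pts[m + 1], pts[m + 2]
        e = 0.0
        for k in range(len(spec)):
            f = k * fs / nfft
            if lo <= f <= ctr and ctr > lo:
                e += spec[k] * (f - lo) / (ctr - lo)
            elif ctr < f <= hi and hi > ctr:
                e += spec[k] * (hi - f) / (hi - ctr)
        energies.append(math.log(max(e, log_floor)))
    # orthonormal DCT-II by explicit cosine sums
    n = n_filters
    coefs = []
    for k in range(1, n_coeffs + 1):
        c = 0.0
        for i in range(n):
            c += energies[i] * math.cos(math.pi * k * (2 * i + 1) / (2 * n))
        coefs.append(c * math.sqrt(2.0 / n))
    return coefs


# -- classification and metrics -------------------------------------------

def knn_neighbors(train_X, query, k, metric="euclidean"):
    """Indices of the k nearest training rows by exhaustive all-pairs sort."""
    dists = []
    for i, row in enumerate(train_X):
        if metric == "euclidean":
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(row, query)))
        elif metric == "cityblock":
            d = sum(abs(a - b) for a, b in zip(row, query))
        elif metric == "chebyshev":
            d = max(abs(a - b) for a, b in zip(row, query))
        elif metric == "cosine":
            num = sum(a * b for a, b in zip(row, query))
            na = math.sqrt(sum(a * a for a in row))
            nb = math.sqrt(sum(b * b for b in query))
            d = 1.0 - num / (na * nb)
        else:
            raise ValueError(metric)
        dists.append((d, i))
    dists.sort()
    return [i for _d, i in dists[:k]]


def metrics_by_hand(tp, fn, fp, tn):
    p = tp + fn
    n = fp + tn
    recall = tp / (tp + fn)
    specificity = tn / (tn + fp)
    fpr = fp / (tn + fp)
    precision = tp / (tp + fp)
    f_score = 2 * recall * precision / (recall + precision)
    acc = (tp + tn) / (p + n)
    error = 1 - acc
    mcc = (tp * tn - fp * fn) / ((tp + fp) * p * n * (tn + fn)) ** 0.5
    return {"sensitivity": recall, "specificity": specificity, "fpr": fpr,
            "precision": precision, "f_score": f_score, "accuracy": acc,
            "error": error, "mcc": mcc}


def band_power(x, fs, f_lo, f_hi):
    """Total one-sided spectral power inside [f_lo, f_hi]."""
    p = power_spectrum(x)
    total = 0.0
    for k in range(len(p)):
        f = k * fs / len(x)
        if f_lo <= f <= f_hi:
            total += p[k]
    return total
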