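"""S1-anchored heart-cycle segmentation.

S1 is the most dominant peak of the phonocardiogram; we locate S1 peaks on
a normalized average Shannon-energy envelope and cut the record into
S1-to-S1 cycles, each shifted back by a small pre-offset so the cycle
captures the onset of S1 and, at its far end, the tail of S2.

Coordinates are 0-based sample indices with half-open [start, end)
intervals; times are in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import PCGRecord


@dataclass
class HeartCycle:
    """One S1-to-S1 segment of a parent record."""

    samples: np.ndarray
    start_index: int
    end_index: int
    s1_index: int
    sample_rate_hz: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if not (self.start_index <= self.s1_index < self.end_index):
            raise ValueError("need start <= s1_index < end")
        if self.samples.size != self.end_index - self.start_index:
            raise ValueError("samples length inconsistent with [start, end)")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


def shannon_energy_envelope(record: PCGRecord, frame_s: float = 0.02,
                            hop_s: float = 0.005) -> np.ndarray:
    """Normalized average Shannon energy envelope.

    Per frame: SE = -mean(x^2 * ln(x^2)) of the amplitude-normalized signal,
    lightly smoothed and scaled to max 1. Length = number of hops; frame i
    is centered at ``i * hop_s + frame_s / 2`` seconds.
    """
    if frame_s < 0.01:
        raise ValueError("frame must be at least 10 ms")
    fs = record.sample_rate_hz
    frame = int(round(frame_s * fs))
    hop = max(1, int(round(hop_s * fs)))
    x = np.asarray(record.samples, float)
    if x.size < frame:
        raise ValueError("record shorter than one frame")
    peak = np.max(np.abs(x))
    if peak == 0:
        n_hops = 1 + (x.size - frame) // hop
        return np.zeros(n_hops)
    x = x / peak
    x2 = x ** 2
    logx2 = np.zeros_like(x2)
    np.log(x2, out=logx2, where=x2 > 0)
    se = -x2 * logx2
    n_hops = 1 + (x.size - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_hops)[:, None]
    env = se[idx].mean(axis=1)
    if env.size >= 3:  # 3-point smoothing
        env = np.convolve(env, np.ones(3) / 3.0, mode="same")
    m = env.max()
    return env / m if m > 0 else env


def detect_s1_peaks(record: PCGRecord, hr_bounds_bpm=(40.0, 180.0),
                    frame_s: float = 0.02, hop_s: float = 0.005,
                    min_height_frac: float = 0.15) -> np.ndarray:
    """Detect S1 peaks as sample indices, strictly increasing.

    Candidate peaks come from the Shannon-energy envelope; dominance under
    the refractory spacing of ``60 / hr_max`` seconds is then judged on the
    plain smoothed signal energy, where S1 amplitude dominance over S2 is
    unambiguous (the Shannon transform itself de-emphasizes the largest
    amplitudes). Peak positions are refined to the local maximum of the
    smoothed instantaneous energy.
    """
    hr_min, hr_max = hr_bounds_bpm
    if not (0 < hr_min < hr_max):
        raise ValueError("invalid heart-rate bounds")
    fs = record.sample_rate_hz
    x = np.asarray(record.samples, float)
    if np.max(np.abs(x)) == 0:
        return np.array([], dtype=int)
    env = shannon_energy_envelope(record, frame_s, hop_s)
    hop = max(1, int(round(hop_s * fs)))
    cand, _props = find_peaks(env, height=min_height_frac * env.max(),
                              distance=max(1, int(round(0.05 / hop_s))))
    if cand.size == 0:
        return np.array([], dtype=int)

    # refine each candidate to the local argmax of 20 ms moving-average energy
    frame = int(round(frame_s * fs))
    energy = np.convolve(x ** 2, np.ones(frame) / frame, mode="same")
    half = int(round(0.03 * fs))
    refined = []
    for c in cand:
        center = int(c * hop + frame // 2)
        lo, hi = max(0, center - half), min(x.size, center + half + 1)
        refined.append(lo + int(np.argmax(energy[lo:hi])))
    refined = np.array(sorted(set(refined)), dtype=int)

    # greedy keep-largest-energy under the refractory spacing
    min_gap = int(round((60.0 / hr_max) * fs))
    order = refined[np.argsort(energy[refined])[::-1]]
    kept: list = []
    for p in order:
        if all(abs(p - k) >= min_gap for k in kept):
            kept.append(p)
    peaks = np.array(sorted(kept), dtype=int)
    if peaks.size < 2:
        warnings.warn("fewer than 2 S1 peaks detected; no cycles derivable")
    return peaks


def segment_cycles(record: PCGRecord, s1_indices, pre_offset_s: float = 0.05,
                   min_dur_s: float = 0.3, max_dur_s: float = 2.0) -> list:
    """Cut the record into S1-to-S1 cycles.

    Cycle i spans ``[s1_i - pre_offset, s1_{i+1} - pre_offset)``. Cycles
    outside the duration bounds are dropped with a warning; a start pushed
    below 0 is clamped.
    """
    s1_indices = np.asarray(s1_indices, dtype=int)
    if s1_indices.size < 2:
        raise ValueError("need at least 2 S1 indices to form a cycle")
    fs = record.sample_rate_hz
    off = int(round(pre_offset_s * fs))
    cycles = []
    n_dropped = 0
    for s1, s1_next in zip(s1_indices[:-1], s1_indices[1:]):
        start = s1 - off
        if start < 0:
            start = 0
        end = min(s1_next - off, record.samples.size)
        dur = (end - start) / fs
        if not (min_dur_s <= dur <= max_dur_s):
            n_dropped += 1
            continue
        cycles.append(HeartCycle(record.samples[start:end], int(start), int(end),
                                 int(s1), fs))
    if n_dropped:
        warnings.warn(f"{record.record_id}: dropped {n_dropped} cycles "
                      f"outside [{min_dur_s}, {max_dur_s}] s")
    return cycles


def average_cycles(cycles: list) -> np.ndarray:
    """Pointwise mean of cycles after linear resampling to the median length."""
    if not cycles:
        raise ValueError("cannot average an empty list of cycles")
    lengths = [c.samples.size for c in cycles]
    target = int(np.median(lengths))
    grid = np.linspace(0.0, 1.0, target)
    stack = np.vstack([
        np.interp(grid, np.linspace(0.0, 1.0, c.samples.size), c.samples)
        for c in cycles])
    return stack.mean(axis=0)
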