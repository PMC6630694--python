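"""Digital pre-processing: band-limiting, spike removal, baseline correction.

The main filter is a sixth-order Butterworth band-pass (20-600 Hz at
2000 Hz sampling), applied zero-phase (forward-backward) so S1/S2 timing is
not distorted before segmentation. "Sixth-order" means total band-pass
order 6, i.e. 3rd-order low/high prototypes.

The pipeline composition is fixed: spike removal -> baseline correction ->
band-pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import PCGRecord


@dataclass
class FilterSpec:
    order: int = 6
    low_cut_hz: float = 20.0
    high_cut_hz: float = 600.0
    sample_rate_hz: int = 2000
    family: str = "iir_butterworth"

    def __post_init__(self):
        if not (0 < self.low_cut_hz < self.high_cut_hz < self.sample_rate_hz / 2):
            raise ValueError("need 0 < low_cut < high_cut < sample_rate/2")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be even and >= 2")
        if self.family != "iir_butterworth":
            raise ValueError(f"unsupported filter family {self.family!r}")


def design_bandpass(spec: FilterSpec) -> np.ndarray:
    """Design the band-pass as second-order sections; verify stability."""
    sos = signal.butter(spec.order // 2, [spec.low_cut_hz, spec.high_cut_hz],
                        btype="bandpass", fs=spec.sample_rate_hz, output="sos")
    # poles of each biquad must be inside the unit circle
    for section in sos:
        poles = np.roots(section[3:])
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(
                "unstable band-pass design; try cascaded second-order sections "
                "with a lower order")
    return sos


def bandpass_filter(record: PCGRecord, spec: FilterSpec | None = None) -> PCGRecord:
    """Zero-phase band-pass filtering; length-preserving."""
    spec = spec or FilterSpec()
    if record.sample_rate_hz != spec.sample_rate_hz:
        raise ValueError(
            f"record rate {record.sample_rate_hz} != filter rate {spec.sample_rate_hz}")
    sos = design_bandpass(spec)
    y = signal.sosfiltfilt(sos, record.samples)
    return record.replace_samples(
        y, f"bandpass {spec.low_cut_hz}-{spec.high_cut_hz} Hz (order {spec.order})")


def remove_spikes(record: PCGRecord, threshold_mads: float = 8.0,
                  max_spike_width_s: float = 0.010,
                  merge_gap_s: float = 0.025) -> PCGRecord:
    """Replace impulsive spikes by linear interpolation of flanking samples.

    A sample is a spike candidate when it deviates more than
    ``threshold_mads`` median absolute deviations from the median. Because
    a phonocardiogram is quiet most of the time, genuine heart-sound bursts
    also exceed an amplitude threshold; what distinguishes an artifact is
    its brevity. Above-threshold runs closer than ``merge_gap_s`` are first
    merged (the crests of an oscillatory burst belong together), and only
    merged runs shorter than ``max_spike_width_s`` (default 10 ms, well
    below the ~50 ms S1 burst) are treated as spikes. A constant signal
    (MAD = 0) is returned unchanged.
    """
    x = np.asarray(record.samples, float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return record.replace_samples(x, "spike removal (no-op: MAD=0)")
    over = np.abs(x - med) > threshold_mads * mad
    max_w = max(1, int(round(max_spike_width_s * record.sample_rate_hz)))
    gap = max(1, int(round(merge_gap_s * record.sample_rate_hz)))
    edges = np.flatnonzero(np.diff(np.concatenate([[False], over, [False]])))
    runs = list(zip(edges[::2], edges[1::2]))
    merged = []
    for lo, hi in runs:
        if merged and lo - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    spikes = np.zeros_like(over)
    for lo, hi in merged:
        if hi - lo <= max_w:
            spikes[lo:hi] = True
    if not spikes.any():
        return record.replace_samples(x, "spike removal (none found)")
    good = np.flatnonzero(~spikes)
    if good.size == 0:
        return record.replace_samples(np.full_like(x, med), "spike removal (all spikes)")
    y = x.copy()
    y[spikes] = np.interp(np.flatnonzero(spikes), good, x[good])
    return record.replace_samples(y, f"spike removal ({int(spikes.sum())} samples)")


def correct_baseline(record: PCGRecord, cutoff_hz: float = 2.0) -> PCGRecord:
    """Remove baseline drift with a zero-phase 2nd-order high-pass below the
    main band edge."""
    if cutoff_hz >= record.sample_rate_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(2, cutoff_hz, btype="highpass",
                        fs=record.sample_rate_hz, output="sos")
    y = signal.sosfiltfilt(sos, record.samples)
    return record.replace_samples(y, f"baseline correction (HP {cutoff_hz} Hz)")


def preprocess_record(record: PCGRecord, spec: FilterSpec | None = None,
                      spike_mads: float = 8.0,
                      baseline_cutoff_hz: float = 2.0) -> PCGRecord:
    """Fixed composition: spike removal -> baseline correction -> band-pass."""
    rec = remove_spikes(record, spike_mads)
    rec = correct_baseline(rec, baseline_cutoff_hz)
    return bandpass_filter(rec, spec)
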