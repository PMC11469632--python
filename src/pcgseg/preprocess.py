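"""Preprocessing: resample to 4 kHz, bandpass 40-500 Hz, normalize to [-1, 1].

The bandpass is a 4th-order Butterworth applied forward-backward (zero phase)
so that sound onsets are not shifted by group delay. Resampling is polyphase
rational resampling with built-in anti-alias filtering.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .io import PCGRecording

TARGET_RATE = 4000.0
BAND_LOW_HZ = 40.0
BAND_HIGH_HZ = 500.0
_FILTER_ORDER = 4


def resample_to_4khz(rec: PCGRecording) -> PCGRecording:
    """Resample to exactly 4000 Hz, preserving duration within one sample.

    Rates below 80 Hz cannot carry the 40 Hz band and are rejected.
    """
    if rec.rate < 2 * BAND_LOW_HZ:
        raise ValueError(f"rate {rec.rate} Hz cannot carry the {BAND_LOW_HZ:g} Hz band")
    if rec.rate == TARGET_RATE:
        return rec
    frac = Fraction(int(round(TARGET_RATE * 1000)), int(round(rec.rate * 1000)))
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.samples, up, down)
    return PCGRecording(out, TARGET_RATE, rec.source_id)


def bandpass(
    rec: PCGRecording, low: float = BAND_LOW_HZ, high: float = BAND_HIGH_HZ
) -> PCGRecording:
    """Zero-phase Butterworth bandpass keeping the 40-500 Hz heart sound band."""
    if not (0 < low < high < rec.rate / 2):
        raise ValueError(f"need 0 < {low} < {high} < rate/2 = {rec.rate / 2}")
    sos = signal.butter(_FILTER_ORDER, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    # sosfiltfilt default padlen for this sos; require enough signal to pad.
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if rec.samples.size <= padlen:
        raise ValueError(f"signal too short for filtering ({rec.samples.size} <= {padlen} samples)")
    out = signal.sosfiltfilt(sos, rec.samples)
    return rec.with_samples(out)


def normalize(rec: PCGRecording) -> PCGRecording:
    """Scale the waveform so max |sample| = 1; errors on an all-zero signal."""
    peak = float(np.max(np.abs(rec.samples))) if rec.samples.size else 0.0
    if peak == 0.0:
        raise ValueError("cannot normalize a silent (all-zero) recording")
    return rec.with_samples(rec.samples / peak)


def preprocess(rec: PCGRecording) -> PCGRecording:
    """Full preprocessing chain: resample -> bandpass -> normalize."""
    return normalize(bandpass(resample_to_4khz(rec)))
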