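"""Denoising of skeleton streams and signal-to-noise accounting.

The pipeline is median filtering first (kills isolated spike samples
from tracking glitches) followed by a zero-phase low-pass Butterworth
stage.  A 30 Hz cutoff is the nominal default, but body-tracking streams
commonly run at 30 fps where that exceeds Nyquist; the effective cutoff
is therefore min(cutoff, 0.45 * sample_rate) and the clamp is reported
on the spec object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import ndimage, signal

from .skeleton import SkeletonFrame

__all__ = ["FilterSpec", "median_filter", "lowpass_filter", "snr_db",
           "filter_stream", "stream_snr_table"]


@dataclass(frozen=True)
class FilterSpec:
    """Median window (odd samples) + Butterworth order/cutoff at a rate."""

    median_window: int = 5
    butter_order: int = 6
    cutoff_hz: float = 30.0
    sample_rate_hz: float = 30.0

    def __post_init__(self):
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 3")
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def effective_cutoff_hz(self) -> float:
        """Cutoff clamped below Nyquist: min(cutoff, 0.45 * fs)."""
        return min(self.cutoff_hz, 0.45 * self.sample_rate_hz)

    def validate_strict(self) -> None:
        """Raise if the *configured* cutoff breaks Nyquist (CLI guard)."""
        nyq = self.sample_rate_hz / 2.0
        if self.cutoff_hz >= nyq:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz >= Nyquist {nyq} Hz at "
                f"sample rate {self.sample_rate_hz} Hz")


def median_filter(series: np.ndarray, window: int) -> np.ndarray:
    """Running median with reflected edges; output length equals input."""
    x = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("median window must be odd")
    if window > x.shape[0]:
        raise ValueError("median window exceeds series length")
    return ndimage.median_filter(x, size=window, mode="reflect")


def lowpass_filter(series: np.ndarray, spec: FilterSpec,
                   strict: bool = False) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward, DC gain 1)."""
    x = np.asarray(series, dtype=float)
    if strict:
        spec.validate_strict()
    fc = spec.effective_cutoff_hz
    nyq = spec.sample_rate_hz / 2.0
    if fc >= nyq:
        raise ValueError(
            f"effective cutoff {fc} Hz >= Nyquist {nyq} Hz at sample rate "
            f"{spec.sample_rate_hz} Hz")
    sos = signal.butter(spec.butter_order, fc, btype="low",
                        fs=spec.sample_rate_hz, output="sos")
    padlen = min(x.shape[0] - 1, 3 * (spec.butter_order + 1))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def snr_db(raw: np.ndarray, reference: np.ndarray) -> float:
    """10*log10(var(reference) / var(raw - reference)), decibels.

    The reference is treated as the signal and the residual between raw
    and reference as noise; identical inputs return +inf.
    """
    raw = np.asarray(raw, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if raw.shape != reference.shape:
        raise ValueError("series must have equal lengths")
    noise_var = float(np.var(raw - reference))
    sig_var = float(np.var(reference))
    if noise_var == 0.0:
        return float("inf")
    if sig_var == 0.0:
        return float("-inf")
    return 10.0 * np.log10(sig_var / noise_var)


def filter_stream(frames: Sequence[SkeletonFrame],
                  spec: FilterSpec) -> List[SkeletonFrame]:
    """Median-then-Butterworth per joint per axis across a stream.

    Confidences are carried over unchanged; the filters run on the raw
    coordinate tracks including any occlusion sentinels, which the
    median stage is specifically there to suppress.
    """
    if not frames:
        raise ValueError("empty stream")
    names = list(frames[0].joints)
    tracks = {n: np.stack([f.position(n) for f in frames]) for n in names}
    for n, x in tracks.items():
        for ax in range(3):
            y = median_filter(x[:, ax], min(spec.median_window,
                                            _odd_floor(len(frames))))
            tracks[n][:, ax] = lowpass_filter(y, spec)
    out = []
    for i, f in enumerate(frames):
        out.append(SkeletonFrame(
            timestamp=f.timestamp,
            joints={n: tracks[n][i] for n in names},
            confidence=dict(f.confidence)))
    return out


def _odd_floor(n: int) -> int:
    return n if n % 2 == 1 else n - 1


def stream_snr_table(raw: Sequence[SkeletonFrame],
                     reference: Sequence[SkeletonFrame]) -> List[Dict]:
    """Per joint, per axis SNR rows: {joint, axis, snr_db}."""
    if len(raw) != len(reference):
        raise ValueError("streams must have equal lengths")
    rows = []
    names = [n for n in raw[0].joints if n in reference[0].joints]
    for n in names:
        r = np.stack([f.position(n) for f in raw])
        c = np.stack([f.position(n) for f in reference])
        for ax, label in enumerate("xyz"):
            rows.append({"joint": n, "axis": label,
                         "snr_db": snr_db(r[:, ax], c[:, ax])})
    return rows
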