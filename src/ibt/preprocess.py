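"""Depth-stack preprocessing: sliding-window binning, SNR, drift registration.

Sliding-window binning sums ``n`` consecutive depth slices, advancing one
slice at a time, so the SNR of each transformed image improves while the
axial sampling of the series is preserved (the output is only ``n - 1``
slices shorter than the input).

SNR is reported in dB as 20*log10(mu_signal / rms(background)), where
rms(background) is the root-mean-square deviation of the background pixels
from their mean.  NOTE: the source formula for this metric is sometimes
written without the square on the deviation term, which would make the
radicand identically zero; the RMS reading implemented here is the only one
that produces finite dB values.

Drift registration estimates a per-slice lateral offset of a fiducial
channel against slice 0 by cross-correlation with sub-pixel (upsampled DFT)
peak refinement, and applies the negated trace to every channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .simulate import DriftTrace
from .stack import IonStack

__all__ = [
    "SnrMeasurement", "SnrUndefinedError",
    "sliding_window_sum", "snr_db", "estimate_drift", "apply_correction",
]


class SnrUndefinedError(ValueError):
    """Background has zero deviation; the SNR is undefined (not infinite)."""


@dataclass(frozen=True)
class SnrMeasurement:
    """SNR in dB with the components used, kept for audit."""
    mu_signal: float
    mu_background: float
    n_background: int
    background_rms: float
    snr_db: float


def sliding_window_sum(stack: IonStack, n: int) -> IonStack:
    """Sum each run of ``n`` consecutive slices; output slice t covers input
    slices t .. t+n-1, so the output length is L - n + 1.

    Channel-wise independent; integer inputs are summed in exact integer
    arithmetic (accumulated at 64 bits).
    """
    L = stack.n_slices
    if not (1 <= n <= L):
        raise ValueError(f"window n={n} must be in [1, {L}]")
    c = stack.counts
    dtype = np.int64 if np.issubdtype(c.dtype, np.integer) else np.float64
    csum = np.cumsum(np.concatenate([np.zeros_like(c[:1], dtype=dtype),
                                     c.astype(dtype)], axis=0), axis=0)
    out = csum[n:] - csum[:-n]
    return stack.replace_counts(out, f"sliding_window_sum(n={n})")


def snr_db(image: np.ndarray, signal_mask: np.ndarray,
           background_mask: np.ndarray) -> SnrMeasurement:
    """SNR(dB) = 20 log10(mu_signal / RMS deviation of background)."""
    image = np.asarray(image, dtype=float)
    signal_mask = np.asarray(signal_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not signal_mask.any() or not background_mask.any():
        raise ValueError("signal and background masks must be non-empty")
    if np.any(signal_mask & background_mask):
        raise ValueError("signal and background masks must be disjoint")
    bg = image[background_mask]
    if bg.size < 2:
        raise ValueError("background must contain at least 2 pixels")
    mu_signal = float(image[signal_mask].mean())
    mu_bg = float(bg.mean())
    rms = float(np.sqrt(np.mean((bg - mu_bg) ** 2)))
    if rms == 0.0:
        raise SnrUndefinedError("background deviation is zero; SNR undefined")
    return SnrMeasurement(mu_signal=mu_signal, mu_background=mu_bg,
                          n_background=int(bg.size), background_rms=rms,
                          snr_db=float(20.0 * np.log10(mu_signal / rms)))


def estimate_drift(stack: IonStack, fiducial_channel: str | int,
                   upsample_factor: int = 50,
                   integer_only: bool = False,
                   chain_previous: bool = False) -> DriftTrace:
    """Per-slice (dx, dy) offsets of the fiducial channel vs slice 0.

    Offsets are estimated by maximizing the cross-correlation against the
    reference slice with sub-pixel refinement (``integer_only`` disables
    it).  ``chain_previous`` registers each slice against its predecessor
    and accumulates, instead of using the fixed slice-0 reference.
    Slices with a flat fiducial image get offsets interpolated from their
    neighbors and are flagged in provenance.
    """
    if isinstance(fiducial_channel, str):
        cube = stack.channel(fiducial_channel)
    else:
        cube = stack.counts[:, fiducial_channel]
    n = cube.shape[0]
    offsets = np.zeros((n, 2))
    flat = np.array([np.ptp(cube[z]) == 0 for z in range(n)])
    factor = 1 if integer_only else upsample_factor
    prev_known = 0
    for z in range(1, n):
        if flat[z]:
            continue
        ref_idx = prev_known if chain_previous else 0
        ref = cube[ref_idx]
        if np.ptp(ref) == 0:
            continue
        # phase_cross_correlation returns the (row, col) shift that maps the
        # moving image onto the reference; negate for the applied offset
        shift, _, _ = phase_cross_correlation(ref, cube[z],
                                              upsample_factor=factor,
                                              normalization=None)
        dy, dx = -shift
        if chain_previous:
            offsets[z] = offsets[prev_known] + (dx, dy)
        else:
            offsets[z] = (dx, dy)
        prev_known = z
    if flat.any():
        # interpolate flat-slice offsets from the nearest estimated neighbors
        good = np.flatnonzero(~flat)
        bad = np.flatnonzero(flat)
        if good.size >= 2:
            for col in range(2):
                offsets[bad, col] = np.interp(bad, good, offsets[good, col])
        stack.log(f"estimate_drift: {bad.size} flat fiducial slice(s) interpolated")
    if integer_only:
        offsets = np.round(offsets)
    offsets[0] = (0.0, 0.0)
    return DriftTrace(offsets)


def apply_correction(stack: IonStack, trace: DriftTrace,
                     interpolation_order: int = 1) -> IonStack:
    """Shift every channel of every slice by the negated trace.

    The same trace is applied to all channels (registration is
    channel-consistent).  Out-of-field pixels are zero-filled.
    """
    if len(trace) != stack.n_slices:
        raise ValueError("trace length must match the number of slices")
    out = np.empty_like(stack.counts, dtype=float)
    for z in range(stack.n_slices):
        dx, dy = trace.offsets[z]
        for c in range(stack.n_channels):
            out[z, c] = ndimage.shift(stack.counts[z, c], shift=(-dy, -dx),
                                      order=interpolation_order,
                                      mode="constant", cval=0.0)
    out = np.clip(out, 0.0, None)
    return stack.replace_counts(
        out, f"apply_correction(max_offset={np.abs(trace.offsets).max():.3f}px)")
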