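"""Complex-valued preprocessing: slice-wise homodyne filtering, then per-voxel
polynomial detrending and z-scoring.

Homodyne filtering removes large-scale background phase (field inhomogeneity
and its wraps) by dividing each complex slice by its own low-pass-filtered
version.  The variant here is phase-only: the output keeps the input
magnitude exactly and only the phase is corrected, since the filter's job is
to fix phase wrap, not to touch magnitude statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_signal import detrend_poly, zscore
from .errors import ConfigurationError, DegenerateVarianceError
from .vein_phantom import ComplexVolumeSeries, wrap_phase

__all__ = ["homodyne_filter", "preprocess_series", "PreprocessResult"]


def _lowpass_window(shape: tuple[int, int], kernel_fraction: float) -> np.ndarray:
    """Separable centered k-space window of side kernel_fraction x matrix size
    with a Hann taper, returned in fftshifted (DC-centered) layout."""
    wins = []
    for n in shape:
        half = max(int(round(kernel_fraction * n)), 2)
        taper = np.hanning(half + 2)[1:-1]      # strictly positive Hann lobe
        w = np.zeros(n)
        start = (n - half) // 2
        w[start:start + half] = taper
        wins.append(w)
    return np.outer(wins[0], wins[1])


def homodyne_filter(complex_slice: np.ndarray, kernel_fraction: float = 0.25
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Phase-only homodyne filter of one 2D complex slice.

    Returns ``(filtered, zero_mask)`` where ``filtered`` has the input
    magnitude and phase equal to the input phase minus the phase of the
    low-pass-filtered slice, and ``zero_mask`` flags zero-magnitude pixels
    (their phase is set to 0).
    """
    sl = np.asarray(complex_slice, complex)
    if sl.ndim != 2 or min(sl.shape) < 4:
        raise ConfigurationError("expected a non-degenerate 2D complex slice")
    if not (0.0 < kernel_fraction < 1.0):
        raise ConfigurationError("kernel_fraction must lie in (0, 1)")

    win = np.fft.ifftshift(_lowpass_window(sl.shape, kernel_fraction))
    low = np.fft.ifft2(np.fft.fft2(sl) * win)

    mag = np.abs(sl)
    zero_mask = mag == 0.0
    low_phase = np.angle(np.where(np.abs(low) > 0, low, 1.0))
    phase = wrap_phase(np.angle(sl) - low_phase)
    phase[zero_mask] = 0.0
    return mag * np.exp(1j * phase), zero_mask


@dataclass
class PreprocessResult:
    """Preprocessed series plus the degenerate-voxel mask."""

    series: ComplexVolumeSeries
    degenerate_mask: np.ndarray     # 3D bool, True where z-scoring failed
    zero_pixel_mask: np.ndarray     # 3D bool, any zero-magnitude pixel flagged


def preprocess_series(series: ComplexVolumeSeries, kernel_fraction: float = 0.25,
                      degree: int = 3) -> PreprocessResult:
    """Homodyne-filter each slice of each timepoint, then detrend (cubic by
    default) and z-score every voxel's magnitude and phase series.

    Voxels whose magnitude or phase is constant cannot be z-scored; they are
    zero-filled, masked, and reported rather than raised on.
    """
    nx, ny, nz, nt = series.shape
    phase_f = np.empty_like(series.phase)
    zero_any = np.zeros((nx, ny, nz), bool)
    for t in range(nt):
        for z in range(nz):
            sl = series.magnitude[:, :, z, t] * np.exp(1j * series.phase[:, :, z, t])
            filt, zmask = homodyne_filter(sl, kernel_fraction)
            phase_f[:, :, z, t] = np.angle(filt)
            zero_any[:, :, z] |= zmask

    mag_out = np.zeros_like(series.magnitude)
    phase_out = np.zeros_like(series.phase)
    degenerate = np.zeros((nx, ny, nz), bool)
    for idx in np.ndindex(nx, ny, nz):
        m = series.magnitude[idx]
        p = phase_f[idx]
        # a constant channel leaves only rounding noise after detrending;
        # flag it up front instead of z-scoring that noise
        if np.ptp(m) == 0.0 or np.ptp(p) == 0.0:
            degenerate[idx] = True
            continue
        try:
            mag_out[idx] = zscore(detrend_poly(m, degree))
            phase_out[idx] = zscore(detrend_poly(p, degree))
        except DegenerateVarianceError:
            degenerate[idx] = True

    out = ComplexVolumeSeries(mag_out, phase_out, series.voxel_size,
                              series.sample_interval)
    return PreprocessResult(out, degenerate, zero_any)
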