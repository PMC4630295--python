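"""NIfTI pair I/O for complex-valued series.

Complex data are stored acquisition-style as separate magnitude and phase
volumes (``*_mag.nii.gz`` / ``*_phase.nii.gz``), not real/imaginary;
converters between the two conventions are provided.  Phase files whose
values span a scaled-integer convention (e.g. +/-4096) are auto-detected and
rescaled to (-pi, pi].
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DataError
from .vein_phantom import ComplexVolumeSeries, wrap_phase

__all__ = ["read_complex_series", "write_complex_series",
           "to_real_imag", "from_real_imag"]

log = logging.getLogger("phasereg")


def _load(path):
    img = nib.load(str(path))
    return img, np.asarray(img.dataobj, dtype=float)


def read_complex_series(mag_path, phase_path,
                        sample_interval: float | None = None) -> ComplexVolumeSeries:
    """Load a magnitude/phase 4D NIfTI pair into a ComplexVolumeSeries.

    Validates matching shapes and affines and the phase value convention:
    radians in [-pi, pi] pass through, symmetric integer-scaled conventions
    are rescaled (logged), anything else is rejected.
    """
    mag_img, mag = _load(mag_path)
    phase_img, phase = _load(phase_path)
    if mag.shape != phase.shape:
        raise DataError(f"shape mismatch: {mag.shape} vs {phase.shape}")
    if not np.allclose(mag_img.affine, phase_img.affine, atol=1e-4):
        raise DataError("affine mismatch between magnitude and phase volumes")
    if mag.ndim != 4:
        raise DataError("expected 4D volumes")

    pmax = np.abs(phase).max()
    if pmax <= np.pi + 1e-6:
        pass  # radians already
    elif pmax <= 2 * np.pi + 1e-6:
        # 0..2pi convention
        log.info("phase in [0, 2pi): rewrapping to (-pi, pi]")
        phase = wrap_phase(phase)
    elif 1000 <= pmax <= 65536:
        scale = np.pi / pmax
        log.info("integer-scaled phase detected (max |value| %.0f): "
                 "rescaling by pi/%.0f", pmax, pmax)
        phase = phase * scale
    else:
        raise DataError(f"phase range (+/-{pmax:.3g}) matches no known convention")

    zooms = mag_img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    if sample_interval is None:
        sample_interval = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return ComplexVolumeSeries(mag, wrap_phase(phase), voxel_size, sample_interval)


def write_complex_series(series: ComplexVolumeSeries, out_dir, stem: str,
                         sidecar: dict | None = None) -> tuple[Path, Path]:
    """Write ``<stem>_mag.nii.gz`` and ``<stem>_phase.nii.gz`` (+ JSON sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(series.voxel_size) + [1.0])
    paths = []
    for name, data in (("mag", series.magnitude), ("phase", series.phase)):
        img = nib.Nifti1Image(np.asarray(data, np.float64), affine)
        img.header.set_zooms(tuple(series.voxel_size) + (series.sample_interval,))
        p = out_dir / f"{stem}_{name}.nii.gz"
        nib.save(img, str(p))
        paths.append(p)
    if sidecar is not None:
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return tuple(paths)


def to_real_imag(series: ComplexVolumeSeries) -> tuple[np.ndarray, np.ndarray]:
    z = series.magnitude * np.exp(1j * series.phase)
    return z.real, z.imag


def from_real_imag(real: np.ndarray, imag: np.ndarray, voxel_size,
                   sample_interval: float) -> ComplexVolumeSeries:
    z = np.asarray(real, float) + 1j * np.asarray(imag, float)
    return ComplexVolumeSeries(np.abs(z), wrap_phase(np.angle(z)),
                               tuple(voxel_size), sample_interval)
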