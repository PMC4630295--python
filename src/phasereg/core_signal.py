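"""Core time-series types and statistics for block-design BOLD analysis.

The functional SNR (fSNR) statistic used throughout is

    fSNR = (mean(S_on) - mean(S_off)) / (std(S_on)/2 + std(S_off)/2)

i.e. the on/off mean difference over the average of the within-condition
standard deviations.  For block designs this is the quantity reported as a
"t-value" in the single-voxel simulations; the volumetric ROI analysis uses a
conventional pooled-variance two-sample t instead (see
:mod:`phasereg.roi_metrics`) and the two are deliberately kept distinct.

Conventions (applied uniformly package-wide):

* standard deviations are *sample* standard deviations (ddof=1), both in the
  fSNR denominator and in z-scoring;
* hemodynamic delay is applied as a backward shift of the condition labels by
  ``round(delay / sample_interval)`` samples, discarding the unlabeled leading
  samples;
* preprocessing order is always detrend -> z-score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .errors import DegenerateVarianceError, InsufficientDataError

__all__ = [
    "BlockDesign",
    "VoxelTimecourse",
    "FsnrSpec",
    "realized_fsnr",
    "zscore",
    "detrend_poly",
]


@dataclass(frozen=True)
class BlockDesign:
    """An alternating on/off block design.

    Parameters
    ----------
    n_blocks:
        Total number of blocks (on and off together).  The reference design is
        14 alternating 16 s blocks.
    block_duration:
        Duration of one block in seconds.
    sample_interval:
        Sampling interval in seconds (1 s for single-voxel simulation, TR = 2 s
        for volume series).
    hemodynamic_delay:
        Lag in seconds between stimulus and vascular response; rounded to an
        integer number of samples and applied as a backward label shift.
    condition_order:
        Cycle of condition labels; blocks take labels from this cycle in turn.
        Defaults to ("off", "on"), i.e. alternation starting with "off".
    """

    n_blocks: int = 14
    block_duration: float = 16.0
    sample_interval: float = 1.0
    hemodynamic_delay: float = 0.0
    condition_order: tuple[str, ...] = ("off", "on")

    def __post_init__(self):
        if self.n_blocks < 2:
            raise ValueError("need at least two blocks (one per condition)")
        if self.hemodynamic_delay < 0:
            raise ValueError("hemodynamic_delay must be non-negative")
        spb = self.block_duration / self.sample_interval
        if abs(spb - round(spb)) > 1e-9:
            raise ValueError("block_duration must be a multiple of sample_interval")

    @property
    def samples_per_block(self) -> int:
        return int(round(self.block_duration / self.sample_interval))

    @property
    def n_timepoints(self) -> int:
        return self.n_blocks * self.samples_per_block

    @property
    def delay_samples(self) -> int:
        return int(round(self.hemodynamic_delay / self.sample_interval))

    def labels(self) -> np.ndarray:
        """Per-timepoint condition label, *without* the hemodynamic shift."""
        order = [self.condition_order[b % len(self.condition_order)]
                 for b in range(self.n_blocks)]
        return np.repeat(np.asarray(order, dtype=object), self.samples_per_block)

    def shifted_labels(self) -> tuple[np.ndarray, int]:
        """Labels shifted backward by the hemodynamic delay.

        Returns ``(labels, d)`` where ``labels`` has length ``n_timepoints - d``
        and aligns with the data after dropping its first ``d`` samples: the
        response at scan time t is attributed to the stimulus at t - delay.
        """
        d = self.delay_samples
        lab = self.labels()
        if d == 0:
            return lab, 0
        return lab[:-d], d

    def boxcar(self, on_label: str = "on") -> np.ndarray:
        """0/1 indicator of the given condition, unshifted (unit-impulse HRF)."""
        return (self.labels() == on_label).astype(float)

    # -- plain-text serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "block_duration": self.block_duration,
            "sample_interval": self.sample_interval,
            "hemodynamic_delay": self.hemodynamic_delay,
            "condition_order": list(self.condition_order),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockDesign":
        d = dict(d)
        if "condition_order" in d:
            d["condition_order"] = tuple(d["condition_order"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_file(cls, path) -> "BlockDesign":
        text = open(path).read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            d = yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class VoxelTimecourse:
    """Paired magnitude and phase time series for one voxel."""

    magnitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase must have equal length")

    def zscored(self) -> "VoxelTimecourse":
        return VoxelTimecourse(zscore(self.magnitude), zscore(self.phase))


@dataclass(frozen=True)
class FsnrSpec:
    """Expected fSNR specification: (mu_on - mu_off) / sigma_noise."""

    mu_on: float
    mu_off: float
    sigma_noise: float

    def __post_init__(self):
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")

    @property
    def expected_fsnr(self) -> float:
        return (self.mu_on - self.mu_off) / self.sigma_noise


def _condition_split(x: np.ndarray, design: BlockDesign,
                     on_label: str = "on", off_label: str = "off"):
    x = np.asarray(x, dtype=float)
    lab, d = design.shifted_labels()
    if x.shape[0] != design.n_timepoints:
        raise ValueError(
            f"series length {x.shape[0]} != design timepoints {design.n_timepoints}"
        )
    xs = x[d:]
    return xs[lab == on_label], xs[lab == off_label]


def realized_fsnr(tc: Sequence[float], design: BlockDesign,
                  on_label: str = "on", off_label: str = "off") -> float:
    """Realized fSNR of a series under a block design.

    ``(mean(on) - mean(off)) / (std(on)/2 + std(off)/2)`` with sample (ddof=1)
    standard deviations, after applying the design's hemodynamic-delay shift.
    """
    on, off = _condition_split(np.asarray(tc, float), design, on_label, off_label)
    if on.size < 2 or off.size < 2:
        raise InsufficientDataError("need >= 2 samples in each condition")
    denom = (on.std(ddof=1) + off.std(ddof=1)) / 2.0
    if denom == 0.0:
        raise DegenerateVarianceError("both condition sets are constant")
    return float((on.mean() - off.mean()) / denom)


def zscore(x: Sequence[float]) -> np.ndarray:
    """Normalize to mean 0, sample standard deviation (ddof=1) 1."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need length >= 2 to z-score")
    s = x.std(ddof=1)
    if s == 0.0:
        raise DegenerateVarianceError("cannot z-score a constant series")
    return (x - x.mean()) / s


def detrend_poly(x: Sequence[float], degree: int = 3) -> np.ndarray:
    """Remove the least-squares polynomial fit of the given degree.

    The residual is orthogonal to all polynomials up to ``degree``. The cubic
    default matches standard slow-drift removal for run-length fMRI series.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= degree + 1:
        raise InsufficientDataError(
            f"need more than {degree + 1} samples for degree-{degree} detrending"
        )
    t = np.arange(x.size, dtype=float)
    # Polynomial.fit uses a scaled/shifted domain for conditioning.
    fit = np.polynomial.Polynomial.fit(t, x, deg=degree)
    return x - fit(t)


def detrend_zscore(x: Sequence[float], degree: int = 3) -> np.ndarray:
    """The package-wide preprocessing order: detrend, then z-score."""
    return zscore(detrend_poly(x, degree=degree))
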