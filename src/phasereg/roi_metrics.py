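"""Contrast t-maps, threshold-and-cluster ROI definition, and vein-contribution
and laterality statistics.

The volumetric "t" here is a conventional pooled-variance two-sample t over
delay-shifted condition volumes (distinct from the realized-fSNR statistic
used for single-voxel simulations; see :mod:`phasereg.core_signal`).  ROIs are
the largest contiguous cluster of supra-threshold voxels per hemisphere, with
6-connectivity (face adjacency) chosen for consistency with the sPR
neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_signal import BlockDesign
from .errors import ConfigurationError

__all__ = [
    "RoiResult",
    "VeinContribution",
    "LateralityIndex",
    "contrast_tmap",
    "define_roi",
    "vein_contribution",
    "laterality",
    "paired_t",
    "anova_f",
    "pearson_r",
]


@dataclass
class RoiResult:
    """A thresholded, connected ROI in one hemisphere."""

    voxel_indices: tuple          # tuple of (x, y, z) tuples
    t_values: np.ndarray
    hemisphere: str = ""
    label: str = ""

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    @property
    def mean_t(self) -> float:
        if self.n_voxels == 0:
            return float("nan")
        return float(np.mean(self.t_values))


@dataclass
class VeinContribution:
    """Vein-contribution statistics from ROIs with and without suppression.

    ``n_norm = N_sPR / N_mag``; ``percent_vein = (1 - n_norm) * 100`` is the
    percentage of ROI voxels predominantly reflecting large-vein signal.
    Metric 1 is the ROI size difference (voxels) without vs. with suppression;
    metric 2 the mean-ROI-t difference, each mean taken over its own ROI's
    voxels.
    """

    n_norm: float
    percent_vein: float
    metric1: int
    metric2: float
    anomalous: bool = False       # True when N_sPR > N_mag


@dataclass
class LateralityIndex:
    """(right - left)/(right + left) of ROI size and of mean ROI t.

    Positive values indicate right-hemisphere lateralization.  Undefined
    ratios (zero denominators) are flagged, not raised.
    """

    size_lat: float
    fsnr_lat: float
    size_defined: bool = True
    fsnr_defined: bool = True


def contrast_tmap(series_4d: np.ndarray, design: BlockDesign,
                  cond_a: str = "on", cond_b: str = "off",
                  delay: float | None = None) -> np.ndarray:
    """Per-voxel pooled-variance two-sample t between two conditions.

    ``delay`` (seconds) overrides the design's hemodynamic delay; condition
    labels are shifted backward and the unlabeled leading volumes dropped.
    Degenerate voxels (zero pooled variance) give NaN.
    """
    x = np.asarray(series_4d, float)
    if delay is not None:
        from dataclasses import replace
        design = replace(design, hemodynamic_delay=delay)
    lab, d = design.shifted_labels()
    present = set(lab.tolist())
    if cond_a not in present or cond_b not in present:
        raise ConfigurationError(f"conditions {cond_a!r}/{cond_b!r} not in design")
    xs = x[..., d:]
    a = xs[..., lab == cond_a]
    b = xs[..., lab == cond_b]
    na, nb = a.shape[-1], b.shape[-1]
    va = a.var(-1, ddof=1)
    vb = b.var(-1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(-1) - b.mean(-1)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[sp2 == 0.0] = np.nan
    return t


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)   # 6-connectivity


def _largest_cluster(tmap: np.ndarray, region: np.ndarray,
                     threshold: float) -> tuple:
    """Largest 6-connected cluster of t > threshold within ``region``.

    Ties on size break by highest mean t, then lowest linear index.
    """
    above = region & np.isfinite(tmap) & (tmap > threshold)
    labels, n = ndimage.label(above, structure=_FACE_STRUCT)
    if n == 0:
        return ()
    best, best_key = None, None
    for lab_id in range(1, n + 1):
        idx = np.nonzero(labels == lab_id)
        size = len(idx[0])
        mean_t = float(tmap[idx].mean())
        first_linear = int(np.ravel_multi_index((idx[0][0], idx[1][0], idx[2][0]),
                                                tmap.shape))
        key = (size, mean_t, -first_linear)
        if best_key is None or key > best_key:
            best, best_key = idx, key
    return tuple(zip(best[0].tolist(), best[1].tolist(), best[2].tolist()))


def define_roi(tmap: np.ndarray, threshold: float = 3.0,
               mask: np.ndarray | None = None,
               hemisphere_split: int | None = None,
               label: str = "") -> dict[str, RoiResult]:
    """Largest supra-threshold cluster per hemisphere.

    ``hemisphere_split`` is the x index of the mid-sagittal plane: voxels with
    x < split are "left", x >= split are "right" (defaults to the middle of
    the volume).  An empty ROI is a valid outcome.
    """
    tmap = np.asarray(tmap, float)
    if mask is None:
        mask = np.ones(tmap.shape, bool)
    if hemisphere_split is None:
        hemisphere_split = tmap.shape[0] // 2
    xs = np.arange(tmap.shape[0])[:, None, None]
    out = {}
    for hemi, region in (("left", xs < hemisphere_split),
                         ("right", xs >= hemisphere_split)):
        vox = _largest_cluster(tmap, mask & np.broadcast_to(region, tmap.shape),
                               threshold)
        tvals = np.array([tmap[i] for i in vox]) if vox else np.empty(0)
        out[hemi] = RoiResult(vox, tvals, hemisphere=hemi, label=label)
    return out


def vein_contribution(roi_mag: RoiResult, roi_spr: RoiResult) -> VeinContribution:
    """Quantify the large-vein contribution from paired ROIs.

    ``roi_mag`` is defined on the unsuppressed magnitude t-map, ``roi_spr`` on
    the suppressed one.  Requires a non-empty magnitude ROI.
    """
    if roi_mag.n_voxels == 0:
        raise ZeroDivisionError("empty magnitude ROI: n_norm undefined")
    n_norm = roi_spr.n_voxels / roi_mag.n_voxels
    metric2 = roi_mag.mean_t - (roi_spr.mean_t if roi_spr.n_voxels else 0.0)
    return VeinContribution(
        n_norm=n_norm,
        percent_vein=(1.0 - n_norm) * 100.0,
        metric1=roi_mag.n_voxels - roi_spr.n_voxels,
        metric2=metric2,
        anomalous=roi_spr.n_voxels > roi_mag.n_voxels,
    )


def laterality(right: RoiResult, left: RoiResult) -> LateralityIndex:
    """Size and fSNR laterality indices; positive = right-lateralized."""
    nr, nl = right.n_voxels, left.n_voxels
    size_defined = (nr + nl) > 0
    size_lat = (nr - nl) / (nr + nl) if size_defined else float("nan")
    tr = right.mean_t if nr else 0.0
    tl = left.mean_t if nl else 0.0
    fsnr_defined = (tr + tl) != 0.0 and not np.isnan(tr + tl)
    fsnr_lat = (tr - tl) / (tr + tl) if fsnr_defined else float("nan")
    return LateralityIndex(size_lat, fsnr_lat, size_defined, fsnr_defined)


# ------------------------------------------------ group-level generic utilities
# Thin wrappers for tables of VeinContribution-style measurements; these are
# ordinary inferential helpers, not part of the phantom validation surface.

def paired_t(a, b):
    """Paired two-sided t-test; returns (t, p)."""
    from scipy import stats
    res = stats.ttest_rel(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def anova_f(*groups):
    """One-way ANOVA F-test across groups; returns (F, p)."""
    from scipy import stats
    res = stats.f_oneway(*[np.asarray(g, float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y):
    """Pearson correlation with its two-sided p-value; returns (r, p)."""
    from scipy import stats
    res = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)
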