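"""Frozen, seed-pinned fixture definitions used by tests, examples and the CLI.

The phantom parameterizations below were calibrated once to realize the
magnitude/phase fSNR taxonomy around a voxel-sized vein (vein voxel: high
magnitude / low phase fSNR; adjacent voxel: the converse) and then frozen.
All fixture data are generated programmatically; ``make_fixtures`` writes
them to disk for inspection or CLI use.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np

from .block_simulator import run_grid
from .core_signal import BlockDesign
from .vein_phantom import (ComplexVolumeSeries, ParenchymaRegion, VeinModel,
                           VolumeGrid, noiseless_states, synthesize_phantom)

__all__ = [
    "single_vein_model",
    "single_vein_grid",
    "single_vein_design",
    "SINGLE_VEIN_NOISE_SD",
    "VEIN_VOXEL",
    "ADJACENT_VOXEL",
    "FAR_VOXEL",
    "make_single_vein_phantom",
    "laterality_models",
    "laterality_parenchyma",
    "make_laterality_phantom",
    "venogram_grid",
    "venogram_volume",
    "pr_fixture_pair",
    "make_fixtures",
]

# ---------------------------------------------------------------- single vein
# Vein along x, tilted to the magic angle (zero intravascular shift -- the
# low-phase-fSNR vein regime the neighborhood source exists for), radius
# 0.3 mm.  Calibrated once against the voxel taxonomy (vein voxel: magnitude
# fSNR > 3, phase < 1.5; one voxel lateral: the converse) and frozen:
# Y 0.54 -> 0.70, complex noise sd 0.0033.

SINGLE_VEIN_NOISE_SD = 0.0033
MAGIC_ANGLE = math.acos(math.sqrt(1.0 / 3.0))

VEIN_VOXEL = (5, 5, 2)        # grid voxel containing the vein axis
ADJACENT_VOXEL = (5, 6, 2)    # one voxel lateral (y), single-polarity field lobe
FAR_VOXEL = (5, 10, 2)        # far from the axis: noise only


def single_vein_grid() -> VolumeGrid:
    return VolumeGrid(shape=(12, 12, 6), voxel_size=(2.25, 2.25, 2.5))


def single_vein_design() -> BlockDesign:
    # 14 x 16 s blocks at TR 2 s -> 112 volumes; the phantom generator applies
    # the oxygenation state directly, so no hemodynamic delay.
    return BlockDesign(n_blocks=14, block_duration=16.0, sample_interval=2.0)


def single_vein_model() -> VeinModel:
    grid = single_vein_grid()
    # The axis runs along x (tilted toward z by the magic angle) and threads
    # VEIN_VOXEL off its exact center; the slight offset lets the symmetric
    # near-field lobes cancel in the voxel average (calibrated, frozen).
    cx, cy, cz = grid.centers()
    return VeinModel(
        radius=0.30,
        tilt=MAGIC_ANGLE, azimuth=0.0,
        center=(0.0, float(cy[VEIN_VOXEL[1]]), float(cz[VEIN_VOXEL[2]])),
        oxygenation_rest=0.54, oxygenation_active=0.70,
    )


def make_single_vein_phantom(seed: int = 0, subvoxel: int = 15) -> ComplexVolumeSeries:
    return synthesize_phantom(single_vein_grid(), single_vein_model(),
                              single_vein_design(), SINGLE_VEIN_NOISE_SD,
                              seed, subvoxel=subvoxel)


# ------------------------------------------------------------- two-vein (lat.)
# "Right" hemisphere (x >= 6): large vein; "left" (x < 6): small vein; one
# identical parenchymal activation disk per side, centered on each vein so the
# thresholded cluster is connected.  Both veins run along y (magic-angle tilt
# toward z), staying within their hemisphere.  Pre-suppression the right
# cluster is vein-inflated; sPR removes the right vein's contribution (its
# vein-adjacent voxels carry usable phase) but only weakly the small left
# vein's, so size laterality decreases.


def laterality_models(phase_gain: float = 1.0) -> list[VeinModel]:
    """Two veins of unequal caliber; ``phase_gain`` scales the task-related
    oxygenation change (1.0 = frozen fixture) for sensitivity sweeps."""
    grid = single_vein_grid()
    cx, cy, cz = grid.centers()
    y_rest = 0.54
    y_act = min(0.54 + 0.16 * phase_gain, 0.95)
    big = VeinModel(radius=0.40, tilt=MAGIC_ANGLE, azimuth=math.pi / 2,
                    center=(float(cx[8]), 0.0, float(cz[2])),
                    oxygenation_rest=y_rest, oxygenation_active=y_act)
    small = VeinModel(radius=0.20, tilt=MAGIC_ANGLE, azimuth=math.pi / 2,
                      center=(float(cx[3]), 0.0, float(cz[2])),
                      oxygenation_rest=y_rest, oxygenation_active=y_act)
    return [big, small]


def laterality_parenchyma() -> list[ParenchymaRegion]:
    # one activation strip per hemisphere, two voxel columns away from the
    # vein so no strip voxel face-touches a vein-adjacent phase source
    grid = single_vein_grid()
    cx, cy, cz = grid.centers()
    z0 = float(cz[2])
    out = []
    for xc in (float(cx[11]), float(cx[0])):
        for y0 in (float(cy[3]), float(cy[5]), float(cy[7])):
            out.append(ParenchymaRegion(center=(xc, y0, z0),
                                        radius=2.0, rel_amplitude=0.02))
    return out


def make_laterality_phantom(seed: int = 0, subvoxel: int = 15,
                            phase_gain: float = 1.0) -> ComplexVolumeSeries:
    return synthesize_phantom(single_vein_grid(), laterality_models(phase_gain),
                              single_vein_design(), SINGLE_VEIN_NOISE_SD,
                              seed, subvoxel=subvoxel,
                              parenchyma=laterality_parenchyma())


# ------------------------------------------------------------------- venogram


def venogram_grid() -> VolumeGrid:
    # susceptibility-weighted scan resolution: 1 mm isotropic
    return VolumeGrid(shape=(16, 16, 9), voxel_size=(1.0, 1.0, 1.0))


def venogram_volume(subvoxel: int = 9) -> np.ndarray:
    """Noiseless resting-state magnitude volume of a perpendicular vein at the
    venogram echo time (26 ms): the short-T2* blood and strong intravoxel
    dephasing render the vein dark, as in susceptibility-weighted imaging."""
    grid = venogram_grid()
    cy, cz = grid.centers()[1:]
    m = VeinModel(radius=0.5, tilt=math.pi / 2, azimuth=0.0,
                  center=(0.0, float(cy[8]), float(cz[4])),
                  echo_time=0.026)
    s_rest, _ = noiseless_states(grid, m, subvoxel=subvoxel)
    return np.abs(s_rest)


# ------------------------------------------------------------------ PR fixture


def pr_fixture_pair(n: int = 50, seed: int = 1234) -> tuple[np.ndarray, np.ndarray]:
    """Frozen pseudo-random z-scored 50-point (Sm, Sp) pair for fit tests."""
    from .core_signal import zscore
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(n)
    Sm = zscore(base + 0.3 * rng.standard_normal(n))
    Sp = zscore(0.8 * base + 0.6 * rng.standard_normal(n))
    return Sm, Sp


# --------------------------------------------------------------- make_fixtures


def make_fixtures(out_dir, seed: int = 0) -> Path:
    """Write the frozen fixtures (phantoms, PR pair, reduced grid) plus a
    manifest with content hashes; byte-identical for identical seeds."""
    from .io import write_complex_series

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = single_vein_design()

    files = []

    single = make_single_vein_phantom(seed)
    files += write_complex_series(
        single, out, "single_vein",
        sidecar={"design": design.to_dict(), "seed": seed,
                 "noise_sd": SINGLE_VEIN_NOISE_SD,
                 "vein_voxel": VEIN_VOXEL, "adjacent_voxel": ADJACENT_VOXEL})
    files.append(out / "single_vein.json")

    lat = make_laterality_phantom(seed)
    files += write_complex_series(
        lat, out, "two_vein",
        sidecar={"design": design.to_dict(), "seed": seed,
                 "noise_sd": SINGLE_VEIN_NOISE_SD})
    files.append(out / "two_vein.json")

    Sm, Sp = pr_fixture_pair()
    pr_path = out / "pr_fixture_pair.csv"
    np.savetxt(pr_path, np.column_stack([Sm, Sp]), delimiter=",",
               header="Sm,Sp", comments="", fmt="%.17g")
    files.append(pr_path)

    for method in ("pr", "spr"):
        g = run_grid(method, BlockDesign(), step=1.0, seed=seed)
        gp = out / f"grid11_{method}.csv"
        g.to_dataframe().to_csv(gp, float_format="%.10g")
        files.append(gp)

    manifest = {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(files)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
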