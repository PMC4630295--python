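"""Susceptibility vein phantom: field model, voxel taxonomy and venogram.

Builds the frozen single-vein phantom (infinite-cylinder dipole field at 4 T,
TE 28 ms, blood oxygenation 0.54 -> 0.70 on stimulus-on blocks, subvoxel
integration with T2*-weighted blood/tissue compartments) and shows the
magnitude/phase fSNR taxonomy that motivates neighborhood-based suppression,
plus a minimum-intensity-projection venogram of a perpendicular vein.
"""

import numpy as np

from phasereg import offres_field, realized_fsnr, venogram_mip
from phasereg.fixtures import (ADJACENT_VOXEL, FAR_VOXEL, VEIN_VOXEL,
                               make_single_vein_phantom, single_vein_design,
                               single_vein_model, venogram_volume)

model = single_vein_model()
print("cylinder field checks:")
print(f"  inside shift at the magic angle: "
      f"{offres_field([0.1, model.center[1], model.center[2]], model):.2e} Hz")
point = (model.center[0], model.center[1] + 2 * model.radius, model.center[2])
print(f"  outside shift 2R lateral to the axis: "
      f"{offres_field(list(point), model):+.2f} Hz\n")

design = single_vein_design()
phantom = make_single_vein_phantom(seed=0)
print(f"phantom series: shape {phantom.shape}, voxel {phantom.voxel_size} mm\n")
print(f"{'voxel':12s} {'mag fSNR':>9s} {'phase fSNR':>11s}")
for name, vx in (("vein", VEIN_VOXEL), ("adjacent", ADJACENT_VOXEL),
                 ("far", FAR_VOXEL)):
    m = realized_fsnr(phantom.magnitude[vx], design)
    p = realized_fsnr(phantom.phase[vx], design)
    print(f"{name:12s} {m:9.2f} {p:11.2f}")

vol = venogram_volume()
mip = venogram_mip(vol, slab=3)
print(f"\nvenogram mIP: tissue median {np.median(mip):.3f}, "
      f"vein minimum {mip.min():.3f}")
print("""
The vein-containing voxel responds in magnitude but not phase (the
symmetric field cancels); the adjacent voxel shows the converse (a
single-polarity field lobe shifts its phase).  The short-T2* vein survives
the minimum projection as a dark tube, as in susceptibility-weighted
venography.""")
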