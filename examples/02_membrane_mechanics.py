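"""RBC membrane mechanics: resting shapes and the Skalak/Helfrich
elastic forces, with their invariants.

Run:  python examples/02_membrane_mechanics.py
"""

import numpy as np

from hemonet import (MembraneParams, bending_forces, cell_length,
                     make_biconcave, make_cell_contour_2d, skalak_forces)
from hemonet.membrane import MembraneMesh

# the default resting cell: biconcave discocyte, 7.8 um end to end,
# 5120 triangular elements
mesh = make_biconcave()
print(f"biconcave mesh: {len(mesh.faces)} triangles, "
      f"end-to-end {cell_length(mesh):.2f} um, "
      f"surface area {mesh.surface_area():.1f} um^2")

params = MembraneParams()           # G_s = 5e-6 N/m, normal cells
stiff = MembraneParams.stiffer()    # 10x G_s, everything else identical
print(f"shear moduli: normal {params.G_s:.1e} N/m, "
      f"stiffer {stiff.G_s:.1e} N/m (ratio "
      f"{stiff.G_s / params.G_s:.0f})")
print(f"viscosities: hemoglobin {params.mu_interior} Pa s, "
      f"plasma {params.mu_plasma} Pa s (ratio {params.lambda_visc:.0f})")

# elastic response to a small uniform inflation: energy grows, net
# force and torque stay identically zero (translation/rotation
# invariance of the discrete energies)
deformed = MembraneMesh(mesh.vertices * 1.02, mesh.faces, mesh.ref_vertices)
el = skalak_forces(deformed, params)
bd = bending_forces(deformed, params)
print(f"\n2% inflation: Skalak energy {el.energy:.3g} Pa um^3, "
      f"bending energy {bd.energy:.3g} Pa um^3")
print(f"net force magnitude / max nodal force: "
      f"{np.abs(el.net_force).max() / np.abs(el.forces).max():.1e} "
      f"(zero to roundoff)")

# the 2D contour analog used by the flow core
contour = make_cell_contour_2d(7.8, 64)
print(f"\n2D contour: {contour.n_vertices} nodes, max chord "
      f"{cell_length(contour):.2f} um, enclosed area "
      f"{abs(contour.enclosed_area()):.1f} um^2")
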