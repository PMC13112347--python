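"""Interface energetics: residue-pair Lennard-Jones, coarse-grained
Coulomb, and surface hydropathy.

All three quantities feed the Monte Carlo cost function; here they are
computed once for a static toy complex.
"""

import numpy as np

import zernipep as zp
from zernipep.fixtures import ToyDimerSpec, make_toy_dimer

complex_ = zp.assign_parameters(make_toy_dimer(ToyDimerSpec(n_residues=8, separation=6.0)))

matrix = zp.interface_lj_matrix(complex_, "A", "B")
print(f"residue-pair LJ matrix {matrix.values.shape}, "
      f"total {matrix.total():.3f} kcal/mol")
share = zp.per_residue_vdw_share(matrix, 4)
print(f"residue 4 carries {100 * share:.1f}% of the interface LJ energy")

cg_a = zp.coarse_grain(complex_, "A")
cg_b = zp.coarse_grain(complex_, "B")
e_c = zp.coulomb_energy_cg(cg_a, cg_b, dielectric=1.0)
print(f"2-bead CG models: {len(cg_a.beads)} + {len(cg_b.beads)} beads, "
      f"Coulomb energy {e_c:.4f} kcal/mol (poly-ALA is neutral)")

cloud = zp.compute_sas_points(complex_, 5.0, 1.4)
patch = zp.extract_patch(cloud, cloud.points[0], 9.0)
h = zp.patch_hydropathy(patch, complex_)
print(f"patch hydropathy {h.value:.2f} over {h.n_surface_points} points "
      f"({len(h.contributing_residues)} residues) — Kyte-Doolittle ALA = 1.8")
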