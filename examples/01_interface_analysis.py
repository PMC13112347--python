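"""Interface statistics on a synthetic trajectory.

Builds a toy two-chain complex, simulates 100 frames in which residues
3-6 of chain A touch chain B 90% of the time (5% background elsewhere),
and recovers the contact profile, the peptide-template segment, its share
of the interface van der Waals energy, and its edge-to-edge extension.
"""

import numpy as np

import zernipep as zp
from zernipep.fixtures import ContactSchedule, ToyDimerSpec, make_synthetic_trajectory, make_toy_dimer

dimer = zp.assign_parameters(make_toy_dimer(ToyDimerSpec(n_residues=8, separation=6.0)))
occ = np.array([0.05, 0.05, 0.9, 0.9, 0.9, 0.9, 0.05, 0.05])
traj = make_synthetic_trajectory(dimer, ContactSchedule(occ, n_frames=100, seed=1))

profile = zp.contact_occurrence(traj, "A", "B", cutoff=8.0)
print("contact occurrence per residue:", profile.occurrence)

segment = zp.select_peptide_segment(profile, threshold=0.25)
print(f"peptide template: residues {segment.start}-{segment.end} "
      f"(length {segment.length}, mean occurrence {segment.mean_occurrence:.2f})")

matrix = zp.interface_lj_matrix(dimer, "A", "B")
frac = zp.segment_vdw_fraction(matrix, segment)
print(f"segment carries {100 * frac:.1f}% of the inter-chain LJ energy "
      f"(total {matrix.total():.2f} kcal/mol)")

d = zp.edge_to_edge(dimer, segment, "A")
# extension statistics over frames with thermal-scale positional noise
rng = np.random.default_rng(0)
series = [d + rng.normal(0.0, 0.4) for _ in range(1000)]
iv = zp.extension_interval(series, k_sigma=2.0)
print(f"edge-to-edge extension {d:.2f} Å; mean±2sd band "
      f"[{iv.low:.2f}, {iv.high:.2f}] Å holds {100 * iv.occupancy:.1f}% of frames")
# A high in-band occupancy means the segment keeps a consistent extension,
# the behaviour wanted of a peptide template excised from an interface.
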