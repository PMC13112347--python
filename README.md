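# zernipep

Design of interface-mimetic inhibitory peptides from protein–protein
complexes.

Aggregation-prone proteins — the driving example is an amyloidogenic
antibody light chain, whose misfolded variable domains pair into a
pathogenic homodimer that seeds fibril formation — can in principle be
neutralized by a peptide that mimics one side of the pathological
interface and outcompetes it. `zernipep` implements that design protocol
as a library:

1. **Interface characterization.** Given trajectory frames of a two-chain
   complex (multi-model PDB), residues are flagged as interface members
   when a Cα of the partner chain lies within 8 Å, and each residue's
   *contact occurrence* (fraction of frames at the interface) is
   tabulated. Residue-pair van der Waals energies
   `E_ij = Σ_l Σ_m ε_lm[(R_lm/r_lm)¹² − 2(R_lm/r_lm)⁶]`
   (CHARMM-style per-atom ε and Rmin/2, combined as ε_lm = √(ε_l ε_m),
   R_lm = Rmin/2_l + Rmin/2_m) quantify how much of the binding energy the
   candidate segment carries.
2. **Template extraction.** The peptide template is the longest contiguous
   run of residues whose occurrence exceeds 25%, with ties broken by mean
   occurrence. Its extension is monitored as the Cα–Cα distance of its
   termini, summarized by the mean ± 2σ band and its frame occupancy.
3. **Shape descriptors.** Solvent-accessible surfaces are sampled as point
   clouds with outward normals (5 points/Å², 1.4 Å probe). A patch (9 Å
   ball around a surface point) is reoriented so its mean normal is the
   z-axis, viewed from the on-axis apex C chosen so the widest secant
   angle is 45°, and binned onto a unit-disk image of mean secant lengths.
   The image is expanded in 2D Zernike polynomials
   `f(r,ϕ) = Σ c_nm R_nm(r) e^{imϕ}` up to order N = 20 (121
   coefficients); the moduli z_nm = |c_nm| are rotation-invariant shape
   descriptors, and two facing patches (one projected with normals up,
   the other flipped) are compared by the Euclidean distance
   `Z_d = √Σ (z_k − z'_k)²` — small distance means complementary shape.
4. **Monte Carlo mutagenesis.** The peptide sequence is optimized by a
   Metropolis chain: each step mutates one random position to a random
   residue, rebuilds the side chain (naive ideal-geometry placer, or a
   Scwrl4 adapter), rescores, and accepts with probability 1 if the cost
   change `ΔC_f = A·ΔZ + B·ΔE_c + C·ΔH + D·(M_new−M_old)·M_new²` is
   negative, else `e^{−βΔC_f}`. Here E_c is the Coulomb energy of a
   2-bead-per-residue coarse-grained model (backbone and side-chain beads
   at mean atom positions, summed partial charges), H the surface-patch
   hydropathy mismatch, and M the mutation count versus the original
   sequence. Default weights A = 10, B = 0.04, C = 32.1, D = 0.5 put the
   terms on a common scale. Accepted sequences from all chains are
   pooled, capped at 5 mutations, deduplicated and ranked by the
   physicochemical cost alone.

A synthetic-fixtures module generates toy dimers, trajectories with
prescribed contact occupancy, and analytic disk images, so the whole
pipeline runs and is tested without any external data.

## Worked example

```python
import numpy as np
import zernipep as zp
from zernipep.fixtures import (ContactSchedule, ToyDimerSpec,
                               make_synthetic_trajectory, make_toy_dimer)

dimer = zp.assign_parameters(make_toy_dimer(ToyDimerSpec(n_residues=8, separation=6.0)))
occ = np.array([0.05, 0.05, 0.9, 0.9, 0.9, 0.9, 0.05, 0.05])
traj = make_synthetic_trajectory(dimer, ContactSchedule(occ, n_frames=100, seed=1))

profile = zp.contact_occurrence(traj, "A", "B", cutoff=8.0)
segment = zp.select_peptide_segment(profile, threshold=0.25)
matrix = zp.interface_lj_matrix(dimer, "A", "B")
print(segment.start, segment.end, zp.segment_vdw_fraction(matrix, segment))
```

Running `python examples/01_interface_analysis.py` (this workflow plus
extension statistics) prints:

```
contact occurrence per residue: [0.05 0.05 0.9  0.9  0.9  0.9  0.05 0.05]
peptide template: residues 3-6 (length 4, mean occurrence 0.90)
segment carries 55.8% of the inter-chain LJ energy (total -12.08 kcal/mol)
edge-to-edge extension 11.40 Å; mean±2sd band [10.59, 12.16] Å holds 95.8% of frames
```

The occurrence vector reproduces the occupancies planted in the synthetic
trajectory; the 25% rule picks exactly the planted block (residues 3–6);
that block carries over half of the interface van der Waals energy, the
signature of a good template; and its extension stays inside the 2σ band
for ~95% of frames, as expected for Gaussian fluctuations.

`python examples/04_optimize_peptide.py` runs three short Monte Carlo
chains on a 6-residue peptide and prints the ranked candidates:

```
run 0: 150 proposals, 12 accepted (8%)
initial physicochemical cost 0.63
  AIIVIA  M=4  Z_d=0.428  E_c=0.0  H_d=-2.575  cost=-78.38
```

The best candidate lowers the composite cost far below the initial
sequence, here mainly by raising the peptide-side hydropathy (negative
H_d) at preserved shape complementarity.

The other examples cover surface descriptors (`02`), static energetics
(`03`) and MSA position frequencies (`05`). A thin CLI exposes the same
stages (`zernipep surface | zernike | analyze-interface | extract-peptide
| optimize | filter-candidates | msa-freqs | fixtures`); run
`zernipep --help`.

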