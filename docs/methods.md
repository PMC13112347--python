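# Methods

This note documents the models, numerical choices and limitations behind
`zernipep`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic tests do and do not establish.

## Structure model and parameterization

Structures are parsed from PDB text into a minimal chain → residue → atom
hierarchy; author residue numbering and insertion codes are preserved, and
multi-model files become trajectories after a strict topology check (every
model must list the same residues and atom names). Coordinates are Å
throughout.

Nonbonded parameters come from a shipped plain-text table keyed by
(residue, atom name): Lennard-Jones well depth ε (kcal/mol), Rmin/2 (Å)
and partial charge (e), CHARMM-style values for the heavy atoms of the 20
standard amino acids. Because the package operates on heavy-atom
structures, hydrogen partial charges are absorbed into their bonded heavy
atom; this keeps per-residue net charges integral (−1 for ASP/GLU, +1 for
LYS/ARG, 0 otherwise), which the coarse-grained electrostatics relies on.
If a PQR file is supplied its charges override the table (the route to
use protonation-state-aware charges from PDB2PQR-like tools). Atoms with
no table entry are reported together in a single lookup error. Hydrogens,
when present in the input, are deliberately not covered by the shipped
table: energy and surface calculations here are defined on heavy atoms,
and a user wanting explicit hydrogens must supply a matching table.

The backbone atom set is {N, CA, C, O, OXT, H, HA (+ terminal H1–H3)};
everything else is side chain. Coarse graining emits one backbone bead
and one side-chain bead per residue — positions are unweighted means of
the constituent atoms, charges their sums, so total charge is conserved
exactly; glycine, having no side-chain heavy atoms, yields a single
backbone bead carrying the whole residue charge.

## Surfaces and the disk projection

The solvent-accessible surface is a point cloud with outward unit
normals: each atom sphere of radius (Rmin/2 + probe) is sampled on a
deterministic golden-angle spiral lattice at the requested density
(default 5 points/Å², probe 1.4 Å) and points inside any neighbouring
atom's inflated sphere are removed. This is a drop-in equivalent of
external molecular-surface tools; a reader for point-plus-normal files is
provided so an externally computed surface can be substituted.

Sampling happens in a molecule-intrinsic frame (principal axes of the
atom covariance, eigenvalue-ordered, signs fixed by the third moment of
the projections, right-handed). The sampled cloud therefore co-rotates
rigidly with the structure, making all downstream descriptors invariant
under rigid motion to machine precision. The frame is ill-defined for
structures with (near-)degenerate principal axes or vanishing skewness on
an axis — exactly symmetric synthetic shapes may flip sign under motion;
real proteins are far from these degeneracies.

A patch is the set of cloud points within a Euclidean ball (default 9 Å,
the scale of a residue-centred binding site) around a chosen surface
point. For projection the patch is centred on its centroid and rotated so
its mean normal is +z (or −z for the partner patch of a complementarity
pair, followed by a z-mirror, so both patches are viewed "from outside"
and interlocking shapes produce similar images). The remaining azimuthal
freedom is fixed by rotating the dominant principal axis of the projected
points to +x (again skew-sign-fixed), which removes pixel-binning noise
between differently oriented copies of the same patch.

The apex point C = (0, 0, h) is found by bisection on h so that the
largest angle between the z-axis and a secant from C to any patch point
equals 45°; the maximum secant angle is strictly decreasing in h, so
bisection is valid (tolerance 1e-6 relative). Each point is then mapped
to the unit disk at radius sin α / sin 45° (α the secant's polar angle,
azimuth preserved) and binned onto a square grid (default 64×64); a pixel
holds the mean secant length r of its points. Interior pixels that
received no point are filled once from the mean of their valid
8-neighbourhood (else the patch mean), so the expansion integrand is
defined on the whole disk. Pixel values are then shifted to zero mean and
scaled to unit maximum absolute value within the disk, making descriptor
distances comparable across patches of different absolute size.

## 2D Zernike descriptors

The basis is Z_nm = R_nm(r) e^{imϕ} with the standard radial polynomials;
only m ≥ 0 with n − m even is stored (for real images the ±m moduli
coincide), giving 121 coefficients at the default maximum order N = 20.
Coefficients are computed as the least-squares projection of the pixel
values onto the basis sampled at pixel centres. In the continuum limit
this equals the (n+1)/π inner-product integral; at finite resolution it
has the advantage of representing band-limited images exactly (round-trip
reconstruction error at machine precision) where a raw midpoint
quadrature leaves percent-level leakage between modes. The quadrature
itself is validated separately: the Gram matrix of the sampled basis on a
256² grid (each pixel integrated with a 5×5 midpoint subrule clipped to
the disk) matches π/(n+1)·δ·δ to better than 4×10⁻⁴ relative for
n ≤ 10.

Descriptors are the coefficient moduli in lexicographic (n, m) order;
they are rotation-invariant by construction, and patch pairs are compared
by the plain Euclidean distance of their descriptor vectors. No
additional normalization by z_00 is applied; the image normalization
above already removes the overall scale.

## Energetics

Residue-pair van der Waals energies are the double sum of 12–6
Lennard-Jones terms over the atoms of two residues on opposite chains,
with CHARMM combination rules ε_lm = √(ε_l ε_m) and
R_lm = Rmin/2_l + Rmin/2_m (each atom stores Rmin/2, so the sum is the
pair's minimum-energy distance). A strict-literal mode (product of ε's,
sum of full Rmin) exists behind a flag for comparison, but the
combination-rule form is the default because the parameters are
CHARMM-convention values. No distance cutoff is applied by default; an
optional cutoff exists for speed.

The coarse-grained Coulomb energy is k_e/ε_r · Σ q_a q_b / r_ab over
inter-model bead pairs, k_e = 332.0636 kcal·Å/(mol·e²), dielectric 1 by
default (configurable). In the optimizer only beads of target residues
within the contact cutoff of the peptide enter the sum — the term is
meant to score the interface, not the whole protein. The coarse
representation is deliberate: mutated side chains are placed without
relaxation, and bead-averaged positions tolerate the resulting local
clashes far better than full-atom electrostatics would.

Patch hydropathy attributes each surface point to the residue of its
nearest heavy atom (error if nothing lies within 5 Å), weights point
counts by a per-residue hydropathy index and divides by the total point
count. The shipped default scale is Kyte–Doolittle; the scale is a
two-column text file and fully substitutable, and results that depend on
it are scale-relative.

## Interface statistics

Contacts use the Cα criterion: residues of opposite chains are in
contact when their Cα–Cα distance is strictly below the cutoff (8 Å
default); a residue's occurrence is the fraction of frames with at least
one partner. (A minimum-interatomic-distance residue-pair measure is also
exposed for energy-context queries, where the Cα criterion is too
coarse.) The peptide template is the longest maximal run of consecutive
residues all above the occurrence threshold (25% default); ties break by
higher mean occurrence, then smaller start index; an option tolerates a
bounded number of below-threshold gaps (default none). RMSD is computed
without superposition by default (the definition has no fitting step),
with an optional Kabsch least-squares fit. Extension intervals use the
population standard deviation — the frames are the entire analysed
sample, and at a thousand frames the sample/population distinction is far
below any other uncertainty.

## Monte Carlo optimizer

Proposals pick a position uniformly and a replacement residue uniformly
from the alphabet minus the current residue. The default alphabet is the
19 standard residues excluding cysteine (unpaired cysteines risk stray
disulfides); both the exclusion and the alphabet are configurable.

The mutation penalty is D·(M_new − M_old)·M_new², signed by the direction
of the move and growing quadratically with total mutational load, so
drifting far from the original sequence becomes progressively harder
while early exploration stays cheap; a literal cubic variant
D·(M_new − M_old)³ is selectable. β defaults to 1 in cost units and is
configurable; chains report their acceptance rate so users can tune
toward the usual 20–50% window.

Each step rebuilds only the peptide: the target-side patch descriptors,
hydropathy and coarse-grained beads are computed once and cached, since
the target never changes. The peptide is scored *posed in the complex*
(its surface patch is the one facing the target), mutated in place by the
naive placer: backbone kept, CB kept or rebuilt with ideal tetrahedral
geometry, remaining side-chain heavy atoms placed from fixed per-residue
templates in a local frame along CA→CB — no rotamer search, no
relaxation. An adapter with the same call signature can delegate to an
external Scwrl4 binary when one is installed. Candidate filtering pools
accepted states of all chains, drops sequences with more than
`max_mutations` (default 5) changes, deduplicates keeping the best score,
and ranks by the physicochemical cost A·Z_d + B·E_c + C·H_d — the
mutation term is a search regularizer, not a quality measure.

Runs are exactly reproducible under (seed, configuration): the only
randomness is one numpy Generator per chain.

## Synthetic fixtures and what the tests show

The fixtures are geometric, not biological: extended poly-ALA chains at a
chosen Cα separation (0.01 Å seeded jitter breaks exact symmetry),
trajectories realizing prescribed per-residue contact occupancies exactly
(round(p·n_frames) in-contact frames, seeded frame choice, 50 Å
displacement otherwise), analytic disk images (constants, pure Zernike
modes, Gaussian bumps, seeded band-limited random images rotated without
resampling error) and single-atom spheres. Passing tests therefore
establish the correctness of the machinery — contact counting, segment
selection, energy sums, descriptor invariances, Metropolis statistics,
end-to-end cost descent — not the biological accuracy of any particular
design: real interfaces have irregular shapes, charged and aromatic
residues, solvent structure and conformational flexibility that the toy
complexes do not emulate, and the all-ALA fixtures make the Coulomb term
identically zero until mutations introduce charges.

Problem sizes in the shipped tests and the acceptance script are chosen
at desk scale: ten 6000-step chains for the stub-scored driver (the full
production scale), ten 200-step chains with the real scorers on a
6-residue peptide for the end-to-end check, 20-frame trajectories for the
oracle comparisons, and a 48² grid / order-12 expansion in the inner MC
loop (64² / order 20 are the defaults for production use).

## Known limitations

- The disk-image pixel binning uses the secant direction; authors of
  related surface-descriptor codes sometimes bin by projected xy
  coordinates instead. The two agree for shallow patches and differ near
  the 45° rim.
- The naive side-chain placer produces chemically plausible but
  unrefined geometries; LJ energies of mutated structures are therefore
  not meaningful (the cost function deliberately uses coarse-grained
  electrostatics and surface terms instead).
- The canonical frames (surface sampling, patch azimuth) assume
  non-degenerate principal axes; exactly symmetric inputs may resolve the
  ambiguity differently after a rigid motion.
- Binding-affinity prediction and MD refinement of designs are outside
  the package's scope; hooks (PQR input, DMS-file input, external placer
  adapter) mark the integration points.
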