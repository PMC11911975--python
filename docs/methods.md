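# Methods

## Cavity model

The quantity of interest is the volume of the active-site cavity of an
enzyme in solution: the largest contiguous empty region near the
catalytic residues, inside the protein, not occupied by protein atoms.
"Inside the protein" is operationalised as the convex hull of the
protein's *heavy* atoms (hydrogen positions are force-field dependent
and would wrinkle the hull), and "not occupied" as lying farther than
`vdW + probe` from every protein atom center.

Discretisation. An axis-aligned grid covers the protein bounding box
plus `padding`; voxel centers sit at `origin + (i + 0.5)·spacing`
(half-open voxels). Classification is per voxel center:

1. *protein* if the center is within `vdW(atom) + probe` of any
   protein atom (spatial k-d tree per distinct radius, so the result
   is independent of atom order);
2. otherwise *outside* if the center fails the signed half-space test
   against every hull facet at tolerance 1e-9 Å;
3. otherwise *free*.

Free voxels are labelled into connected components
(`scipy.ndimage.label`; labels renumbered by each component's first
voxel in lexicographic scan order so they are deterministic). The seed
zone is the set of free voxels within `seed_distance` of any
active-site atom; among components intersecting it, the largest by
voxel count is the cavity (ties: smaller label), and the number of
intersecting components is the splitting metric — a gate closing
between two sub-pockets reads as 1 → 2. Volume is
`count × spacing³`; occupancy counts solvent heavy atoms whose center
falls in a cavity voxel and divides by the volume in nm³.

### Parameters (defaults and why)

| parameter | default | notes |
|---|---|---|
| `spacing` | 0.5 Å | volume error is O(spacing) at the boundary; 0.25 Å reaches ~3 % on the validation pocket |
| `padding` | 3.0 Å | grid margin beyond the bounding box; any value ≥ the largest vdW radius works |
| `probe_radius` | 0 Å | occupancy by bare vdW spheres, the literal "not occupied by atoms" reading; exposed for probe-based variants |
| `seed_distance` | 8 Å | "close to the active site"; spans both a shallow surface region and a deeper channel in the validation geometries; configurable |
| `connectivity` | 26 | 6/18 selectable; 26 avoids spurious splitting at diagonal throats |

### Discretisation error, quantified

Center-in-voxel counting has a surface-skin error of order
`spacing/2` per face. On the default validation pocket (10 Å lattice
shell, free span ≈ 6.6 Å) the wall lattice (1.0 Å) and the voxel grid
are commensurate, so per-face errors align rather than cancel: the
measured volume error is 28 % at 1.0 Å, 14.5 % at 0.5 Å and 3.0 % at
0.25 Å — monotone in spacing, and fully reproducible. The error is a
property of the estimator and geometry, not noise; the test suite
asserts the monotone sequence and the ≤5 % bound at the finest
spacing. Densities inherit the volume error (the atom count itself is
exact), so densities at 0.5 Å spacing on small pockets carry the same
~10–15 % bias. For real proteins (no lattice resonance, larger
cavities) the relative error at a given spacing is smaller.

Whether occupancy should count atoms by center-in-voxel or by
sphere-voxel overlap was an open choice; center-in-voxel is
implemented because it makes planted-atom recovery exact and keeps
count independent of spacing. Sphere-overlap is not implemented.

## Descriptors

* **Rg** is the mass-weighted RMS distance from the center of mass;
  unweighted Rg uses unit masses. Invariant to rigid motion to 1e-9 Å.
* **Hydrogen bonds** use a geometric criterion: H···A ≤ 2.5 Å and
  D–H···A angle ≥ 135° (typical force-field-analysis defaults; both
  configurable). Donor hydrogens are resolved as hydrogen atoms of the
  same residue within 1.25 Å of the donor in the frame — a geometric
  convention that needs no bond topology; donors with no such hydrogen
  are skipped with a warning. Occupancy of a specific bond is the
  fraction of frames in which it is present.
* **Superposition** is the Kabsch SVD solution restricted to proper
  rotations (determinant correction), RMSD over the fit atoms after
  fitting. Cross-checked in the tests against an independent
  quaternion-eigenvalue implementation.
* **Clustering** is the neighbour-count (medoid-removal) scheme
  standard in MD post-processing: repeatedly take the frame with the
  most neighbours within `cutoff` (pairwise fitted RMSD) as a medoid
  and remove it with its neighbours. Ties break at the lowest frame
  index; cluster ids are ordered by size then medoid index; default
  cutoff 1.0 Å. Pairwise RMSD is O(n²) superpositions, fine for the
  hundreds-of-frames regime this targets.

Per-frame statistics are reported per trajectory (per replica);
replicas are summarised separately and never pooled.

## Solvent metrics

Acetalisation is pure element arithmetic:
`product = sugar + n·aldehyde − n·H₂O`, with every element conserved
(`product + n·H₂O = sugar + n·aldehyde` is a tested invariant). Each
cyclic acetal consumes two hydroxyl hydrogens, so the number of
substituted sugar hydrogens is `2n` — the implementation *derives* it
from the formulas and rejects inconsistent stoichiometries. Molar
masses use bundled IUPAC 2021 conventional atomic weights (4
decimals); values are kept at full precision internally and rounded to
2 decimals only for display, which reproduces tabulated solvent molar
masses bit-for-bit.

"Biogenic atoms preserved" is computed on a **mass basis**:
`(MW(sugar) − n·MW(H)) / MW(sugar)` = 146.10/150.13 = 97.3 % → "97 %"
for a xylose di-acetal. An atom-count basis would give 16/20 = 80 %
and contradict the quoted figure, so the mass basis is adopted and
documented. Biomass-utilisation efficiency on a xylan basis uses the
anhydroxylose repeat unit C5H8O4 (MW 132.11, the standard
polysaccharide convention); `stoichiometric = MW(retained)/MW(unit)`,
`actual = stoichiometric × yield`, with the molar yield an explicit
input (isolated yields are experiment-specific).

Hansen distance uses the conventional weighting
`Ra² = 4ΔδD² + ΔδP² + ΔδH²`; the factor 4 breaks the triangle
inequality, so Ra is a similarity score, not a metric. KAT nearest
neighbours are Euclidean in the (π*, β) plane; α is 0 for every
aprotic entry in the bundled table. The table carries the acetal
solvents and common reference solvents (DMF, NMP, THF, 1,4-dioxane,
diphenyl ether) with molar mass, density (acetal densities tabulated
at 50 °C), KAT, HSP and Nile-Red λmax values; molar volume is
`MW/density` at the tabulated temperature.

## Synthetic fixtures — what they do and do not show

`make_shell` builds a closed cubic lattice shell (1.0 Å spacing,
carbon, vdW 1.70 Å) around an interior pocket; the wall is required to
be ≥ 2 vdW radii thick and an escape test at generation time verifies
the pocket cannot leak. Three designated wall atoms get the residue
ids 105/224/187 so the same active-site spec works on fixtures and
real CaLB structures. Ground truth (free volume, component volumes) is
computed by a brute-force fine-grid oracle (default 0.1 Å) that shares
no code with the cavity engine. An optional gate — a plane of atoms
across the pocket — is either closed (splitting the pocket in two) or
parked inside the wall, with identical topology, so open/closed frames
interleave into one trajectory.

Solvent stand-ins are rigid random clusters of 1–18 heavy atoms
(≈ 2 Å radius for a small-acetal-like molecule, ≈ 3.5 Å for a bulky
one), placed by rejection sampling with a wall clearance; no chemistry
is simulated. Thermal motion is i.i.d. Gaussian jitter per frame. All
generators are deterministic under their seed.

These fixtures validate the *measurement machinery*: voxel
classification, flood fill, seed-zone logic, occupancy counting,
descriptor closed forms, determinism. They do not emulate protein
flexibility, solvation shells, periodic boundaries or force-field
physics, so passing tests certify the analysis pipeline — not any
claim about how a particular solvent changes a particular enzyme.
Reproducing solvent-specific cavity densities or Rg shifts requires
the original trajectories, which are not publicly deposited.

The crowded-cavity preset fills a ~0.91 nm³ pocket with
`round(38 × V_nm³)` single-atom solvent molecules, i.e. the ~38 heavy
atoms per nm³ occupancy regime reported for bulky acetal solvents —
used as a scale check, not a reproduction.

## Pipeline and determinism

A run is a flat, validated config (unknown keys rejected before any
computation); every parameter actually used, explicit or defaulted, is
echoed into `run.log` and the summary provenance block. In the
pipeline's role model every non-solvent atom counts as protein, which
matches ligand-free simulations and the fixtures. Outputs are TSV
per-frame tables plus a JSON summary whose statistics (mean,
population sd, min, max) are exactly recomputable from the tables; no
timestamps enter any output, so identical config + seed reproduces
every file byte-for-byte.

## Known limitations

* No periodic-boundary imaging: trajectories must be whole-molecule /
  pre-imaged.
* Binary trajectory formats (XTC/TRR/DCD) are out of contract; convert
  to multi-model PDB or XYZ first.
* Convex-hull clipping overestimates "inside the protein" for strongly
  non-convex shapes; surface-based (alpha-shape/SES) definitions are
  deliberately out of scope.
* Cavity volumes carry the O(spacing) boundary bias quantified above;
  compare volumes only at equal spacing.
* Secondary-structure assignment (DSSP) and energy-based hydrogen-bond
  definitions are not provided.
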