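# cavistat

Grid-based active-site cavity analysis for enzyme MD trajectories,
plus the solvent-side arithmetic used when screening bio-based solvents
for biocatalysis.

## What problem this addresses

Lipase-catalysed polycondensation (e.g. with *Candida antarctica*
lipase B, CaLB) is strongly solvent-dependent, and a key structural
question is what the solvent does to the enzyme's active-site cavity:
how large the cavity is, whether it transiently splits in two, how
densely solvent molecules crowd it, and how rigid the protein stays.
`cavistat` implements that analysis as a reusable, tested pipeline:

* **Cavity volume.** The cavity is defined as the largest contiguous
  region near the catalytic triad that lies inside the convex hull of
  the protein's heavy atoms and is not occupied by protein atoms. It
  is discretised on a regular voxel grid (default 0.5 Å): a voxel is
  *protein* if its center is within `vdW + probe` of a protein atom,
  *outside* if beyond the hull, otherwise *free*; free voxels are
  flood-filled into connected components (26-connectivity), the
  components within 8 Å of the active-site atoms form the seed zone,
  and the largest of them is the cavity with
  `V = N_voxels × spacing³` (Å³).
* **Solvent occupancy.** Solvent heavy atoms whose centers fall in
  cavity voxels, reported per nm³ of cavity volume.
* **Rigidity descriptors.** Radius of gyration
  `Rg = sqrt(Σ mᵢ‖rᵢ − r_com‖² / Σ mᵢ)`, geometric hydrogen bonds
  (H···A ≤ 2.5 Å and ∠D–H···A ≥ 135° by default), named atom-pair
  distances (e.g. Ser105:OG–His224:NE2), Kabsch superposition RMSD and
  neighbour-count (medoid-removal) conformational clustering.
* **Solvent metrics.** Di-acetal stoichiometry
  (`product = sugar + n·aldehyde − n·H₂O`), molar masses, mass-basis
  sugar retention, biomass-utilisation efficiency, Hansen distance
  `Ra² = 4ΔδD² + ΔδP² + ΔδH²` and Kamlet–Taft (π*, β) nearest
  neighbours over a bundled solvent-property table.
* **Synthetic fixtures.** Closed lattice shells with pockets of
  oracle-computed volume, gates that split the pocket, placed solvent
  clusters and Gaussian jitter — so every stage is validated against
  independent ground truth without needing the original trajectories.

## Worked example

```python
import numpy as np
import cavistat as cs

traj, gt = cs.make_shell(cs.ShellSpec())          # 10 Å pocket, known volume
site = cs.ActiveSiteSpec([105, 224, 187])          # the catalytic-triad residues
protein = cs.select(traj, role="protein")
series = cs.cavity_timeseries(traj, site, protein, np.array([], int),
                              cs.CavityParams(spacing=0.25))
print(gt.free_volume_A3, series.records[0][0].volume)
```

prints `299.48 290.5`: the oracle ground-truth pocket volume and the
measured cavity volume at 0.25 Å spacing (3 % discretisation error).
On the solvent side,

```sh
$ cavistat solvent acetal --aldehyde C4H8O
{"product": "C13H22O5", "mw_g_mol": 258.31, "substituted_hydrogens": 4, "retention_percent": 97}
```

derives dibutylxylose from butyraldehyde: its formula and molar mass,
the four sugar hydrogens replaced by the two cyclic acetals, and the
97 % of the xylose mass that survives into the solvent.

The `examples/` directory has one short narrative script per
capability (cavity volume, occupancy, rigidity descriptors, solvent
metrics); each prints the numbers it computes and what they mean. The
`cavistat` command exposes the same library thinly:
`cavistat run --config run.cfg`, `cavistat fixtures make <preset>`,
`cavistat solvent mw|acetal|efficiency|hsp|kat`.

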