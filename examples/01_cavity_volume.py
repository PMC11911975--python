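"""Measure a pocket volume on a synthetic shell and compare to ground truth.

Builds the default box-pocket fixture (a closed carbon shell around a
10 Å interior pocket, with three triad atoms on the inner wall), runs
the voxel-grid cavity detector at three grid spacings and prints the
volume next to the fixture's oracle-derived free volume: the error
should shrink as the grid refines.
"""

import numpy as np

import cavistat as cs

traj, gt = cs.make_shell(cs.ShellSpec())
site = cs.ActiveSiteSpec([105, 224, 187])
protein = cs.select(traj, role="protein")

print(f"ground-truth pocket volume: {gt.free_volume_A3:.1f} A^3 (fine-grid oracle)")
for spacing in (1.0, 0.5, 0.25):
    params = cs.CavityParams(spacing=spacing)
    series = cs.cavity_timeseries(traj, site, protein, np.array([], int), params)
    cav, _ = series.records[0]
    err = 100 * abs(cav.volume - gt.free_volume_A3) / gt.free_volume_A3
    print(f"spacing {spacing:4.2f} A -> volume {cav.volume:7.1f} A^3  (error {err:4.1f} %)")

print("\nThe cavity is the largest free region inside the protein convex hull")
print("near the active site; volume = voxel count x spacing^3, so coarser")
print("grids over-count the vdW boundary skin and the error drops with spacing.")
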