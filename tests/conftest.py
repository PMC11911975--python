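import numpy as np
import pytest

import cavistat as cs

TRIAD = [105, 224, 187]


@pytest.fixture(scope="session")
def box_pocket():
    """Default 10³ Å shell pocket with oracle ground truth."""
    traj, gt = cs.make_shell(cs.ShellSpec())
    return traj, gt


@pytest.fixture(scope="session")
def gated_shells():
    """Open/closed variants of a gated 12×6×6 pocket (shared topology)."""
    spec = cs.ShellSpec(inner_box=(12.0, 6.0, 6.0), gate_plane=6.0)
    open_traj, gt_open = cs.make_shell(spec, gate_open=True, oracle_spacing=0.2)
    closed_traj, gt_closed = cs.make_shell(spec, gate_open=False, oracle_spacing=0.2)
    return open_traj, gt_open, closed_traj, gt_closed


@pytest.fixture(scope="session")
def active_site():
    return cs.ActiveSiteSpec(TRIAD)


def run_cavity(traj, spacing=0.5, seed_distance=8.0, solvent_idx=None, **kw):
    """Convenience driver used across test modules."""
    site = cs.ActiveSiteSpec(TRIAD)
    prot = cs.select(traj, role="protein")
    sol = np.array([], int) if solvent_idx is None else solvent_idx
    params = cs.CavityParams(spacing=spacing, seed_distance=seed_distance, **kw)
    return cs.cavity_timeseries(traj, site, prot, sol, params)
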