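"""End-to-end orchestration: read → cavity per frame → occupancy →
descriptors → clustering → report.

A run is driven by a :class:`RunConfig` (built in Python or parsed from
a flat ``key = value`` config file); all parameters actually used —
explicit and defaulted — are echoed into the run log and the summary,
because defaults are where analyses silently diverge. Identical config
plus seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cavity import CavityParams, cavity_timeseries, timeseries_to_tsv
from .descriptors import (
    cluster_conformations,
    hbond_count_timeseries,
    rg_timeseries,
    series_to_tsv,
    triad_distances,
)
from .structure import (
    ActiveSiteSpec,
    ROLE_SOLVENT,
    Trajectory,
    assign_radii,
    read_trajectory,
    select,
)

_LIST_INT_FIELDS = {"active_site_residues"}
_LIST_STR_FIELDS = {"solvent_resnames"}


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run.

    In the pipeline's role model every atom that is not solvent counts
    as protein: inputs are expected to contain only the enzyme (or a
    synthetic stand-in) plus solvent, which matches both the fixtures
    and a ligand-free enzyme simulation.
    """

    input: str
    output_dir: str
    active_site_residues: list[int] = field(default_factory=lambda: [105, 224, 187])
    solvent_resnames: list[str] = field(default_factory=lambda: ["SLV"])
    spacing: float = 0.5
    padding: float = 3.0
    probe_radius: float = 0.0
    seed_distance: float = 8.0
    connectivity: int = 26
    hbond_dist_cutoff: float = 2.5
    hbond_angle_cutoff: float = 135.0
    cluster_cutoff: float = 1.0
    default_vdw_radius: float = 1.7
    seed: int = 0

    def validate(self) -> None:
        if self.spacing <= 0 or self.padding < 0:
            raise ValueError("spacing must be > 0 and padding ≥ 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not self.active_site_residues:
            raise ValueError("active_site_residues must not be empty")
        if self.cluster_cutoff <= 0:
            raise ValueError("cluster_cutoff must be > 0")

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file; unknown keys reject."""
        known = {f.name: f for f in dataclasses.fields(RunConfig)}
        values: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key in _LIST_INT_FIELDS:
                values[key] = [int(v) for v in val.replace(",", " ").split()]
            elif key in _LIST_STR_FIELDS:
                values[key] = [v for v in val.replace(",", " ").split()]
            elif known[key].type in ("int", int):
                values[key] = int(val)
            elif known[key].type in ("float", float):
                values[key] = float(val)
            else:
                values[key] = val
        missing = {"input", "output_dir"} - set(values)
        if missing:
            raise ValueError(f"{path}: missing required keys {sorted(missing)}")
        cfg = RunConfig(**values)  # type: ignore[arg-type]
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-frame tables plus a summary exactly recomputable from them."""

    config: RunConfig
    summary: dict
    output_dir: Path


def summarize(values: np.ndarray) -> dict[str, float]:
    """Mean, population sd, min and max of a per-frame series."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty series")
    return {
        "mean": float(v.mean()),
        "sd": float(v.std()),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline for one trajectory (one replica).

    Writes cavity.tsv, rg.tsv, hbonds.tsv, clusters.tsv, summary.json
    and run.log into the output directory. Replicas are separate runs;
    no cross-replica pooling is done here.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"cavistat {__version__}", f"config_hash {config.config_hash()}"]
    for f in dataclasses.fields(config):
        log_lines.append(f"param {f.name} = {getattr(config, f.name)}")

    traj = read_trajectory(config.input, solvent_resnames=config.solvent_resnames)
    # pipeline role model: everything that is not solvent is protein
    solvent_resnames = {s.upper() for s in config.solvent_resnames}
    for a in traj.atoms:
        if a.role != ROLE_SOLVENT and a.residue_name.upper() not in solvent_resnames:
            a.role = "protein"
    assign_radii(traj, default_radius=config.default_vdw_radius)
    log_lines.append(f"input frames = {traj.n_frames}, atoms = {traj.n_atoms}")

    protein_idx = select(traj, role="protein")
    protein_heavy = select(traj, role="protein", heavy=True)
    solvent_heavy = np.array(
        [a.serial for a in traj.atoms if a.role == ROLE_SOLVENT and a.is_heavy], dtype=int
    )
    site = ActiveSiteSpec(config.active_site_residues)

    params = CavityParams(
        spacing=config.spacing,
        padding=config.padding,
        probe_radius=config.probe_radius,
        seed_distance=config.seed_distance,
        connectivity=config.connectivity,
    )
    series = cavity_timeseries(traj, site, protein_idx, solvent_heavy, params)
    timeseries_to_tsv(series, outdir / "cavity.tsv")
    log_lines.append("stage cavity: ok")

    rg = rg_timeseries(traj, protein_heavy, mass_weighted=True)
    series_to_tsv({"rg_A": np.round(rg, 6)}, outdir / "rg.tsv")
    log_lines.append("stage rg: ok")

    protein_no = np.array(
        [
            a.serial
            for a in traj.atoms
            if a.role == "protein" and a.element.capitalize() in ("N", "O")
        ],
        dtype=int,
    )
    hb = hbond_count_timeseries(
        traj, protein_no, protein_no, config.hbond_dist_cutoff, config.hbond_angle_cutoff
    )
    series_to_tsv({"n_hbonds": hb}, outdir / "hbonds.tsv")
    log_lines.append("stage hbonds: ok")

    clusters = cluster_conformations(traj, protein_heavy, config.cluster_cutoff)
    series_to_tsv({"cluster": clusters.assignments}, outdir / "clusters.tsv")
    log_lines.append(f"stage clusters: ok ({clusters.n_clusters} clusters)")

    vols = np.array([c.volume for c, _ in series.records])
    dens = np.array([o.density for _, o in series.records if o.density is not None], float)
    ncomp = np.array([c.n_components_in_seed_zone for c, _ in series.records])
    summary = {
        "provenance": {
            "cavistat_version": __version__,
            "config_hash": config.config_hash(),
            "parameters": dataclasses.asdict(config),
        },
        "volume_A3": summarize(vols),
        "n_components_seed_zone": summarize(ncomp),
        "rg_A": summarize(rg),
        "n_hbonds": summarize(hb),
        "n_clusters": clusters.n_clusters,
        "cluster_sizes": clusters.sizes,
    }
    if dens.size:
        summary["density_per_nm3"] = summarize(dens)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    print("\n".join(log_lines), file=sys.stderr)
    return RunReport(config=config, summary=summary, output_dir=outdir)
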