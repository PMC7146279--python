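"""Orchestration of the full hinge-motion analysis.

Ties the stages together the way a production-trajectory study runs
them: discard the equilibration interval, compute per-frame lip
distance / state / hinge angle, the RMSD-to-initial-structure series
(on the full, untrimmed trajectory, since the point of that series is
to watch the approach to and departure from the starting conformation),
per-residue RMSF and optional ligand-enzyme hydrogen-bond counts on the
production frames only, and write CSV tables plus a JSON summary and a
provenance echo of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import HingescopeError, InsufficientFramesError
from .geometry import FluctuationProfile, rmsd_series, rmsf
from .hbonds import HBondCriteria, HBondSeries, hbond_count_series
from .hinge import HingeResult, StateThresholds, analyze_trajectory
from .structure_io import (
    RegionSet,
    StructureFrame,
    Trajectory,
    load_preset,
    read_pdb,
    read_trajectory,
    select_ca,
    write_timeseries,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "trim_equilibration", "run_analysis",
           "select_atoms"]


def trim_equilibration(traj: Trajectory, equilibration_time: float) -> Trajectory:
    """Drop the equilibration interval; frames strictly after the cutoff stay."""
    if equilibration_time < 0:
        raise ValueError("equilibration_time must be >= 0")
    if equilibration_time >= traj.times[-1]:
        raise ValueError(
            f"equilibration_time {equilibration_time} ns is not before the "
            f"final frame time {traj.times[-1]} ns"
        )
    if equilibration_time == 0:
        return traj
    keep = traj.times > equilibration_time
    if keep.sum() < 2:
        raise InsufficientFramesError(
            f"trimming at {equilibration_time} ns leaves {int(keep.sum())} frame(s)"
        )
    return Trajectory(traj.topology, traj.frames[keep], traj.times[keep])


def select_atoms(atoms, expr: str) -> np.ndarray:
    """Minimal selection language for H-bond partner groups.

    Supported forms: ``all``, ``protein`` (non-HETATM), ``het``,
    ``chain:<id>``, ``resname:<name>``, and comma-separated residue
    numbers ``resid:<a>-<b>[,<c>-<d>...]``. Terms joined by `` and ``
    are intersected.
    """
    mask = np.ones(len(atoms), dtype=bool)
    for term in expr.split(" and "):
        term = term.strip()
        if term == "all":
            continue
        elif term == "protein":
            mask &= np.array([not a.het for a in atoms])
        elif term == "het":
            mask &= np.array([a.het for a in atoms])
        elif term.startswith("chain:"):
            cid = term.split(":", 1)[1]
            mask &= np.array([a.chain_id == cid for a in atoms])
        elif term.startswith("resname:"):
            rn = term.split(":", 1)[1]
            mask &= np.array([a.residue_name == rn for a in atoms])
        elif term.startswith("resid:"):
            wanted = set()
            for part in term.split(":", 1)[1].split(","):
                a, _, b = part.partition("-")
                lo = int(a)
                hi = int(b) if b else lo
                wanted.update(range(lo, hi + 1))
            mask &= np.array([a.residue_number in wanted for a in atoms])
        else:
            raise ValueError(f"unknown selection term {term!r}")
    return np.flatnonzero(mask)


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs; see the CLI for file-based use."""

    topology: str | Path
    trajectory: str | Path | None = None  # None: topology is multi-model
    reference: str | Path | None = None  # None: first frame
    regions: str | RegionSet = "sace_cdomain"
    thresholds: StateThresholds = field(default_factory=StateThresholds)
    equilibration_time: float = 0.0
    timestep: float = 1.0  # ns per frame when the input carries no times
    hbond_selection_a: str | None = None  # e.g. "het" (ligand)
    hbond_selection_b: str | None = None  # e.g. "protein"
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    hbond_heavy_only: bool = False
    output_dir: str | Path | None = None
    seed: int = 0

    def resolve_regions(self) -> RegionSet:
        if isinstance(self.regions, RegionSet):
            return self.regions
        if str(self.regions).endswith((".yaml", ".yml")):
            return RegionSet.from_yaml(self.regions)
        return load_preset(str(self.regions))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            t = kwargs["thresholds"]
            kwargs["thresholds"] = StateThresholds(
                float(t["closed_max"]), float(t["open_min"])
            )
        if "hbond_criteria" in kwargs:
            c = kwargs["hbond_criteria"]
            kwargs["hbond_criteria"] = HBondCriteria(
                float(c["max_da_distance"]), float(c["max_hda_angle"])
            )
        return cls(**kwargs)

    def echo(self) -> dict:
        regions = self.resolve_regions()
        return {
            "topology": str(self.topology),
            "trajectory": str(self.trajectory) if self.trajectory else None,
            "reference": str(self.reference) if self.reference else None,
            "regions": {
                "chain_id": regions.chain_id,
                "lip1": regions.lip1,
                "lip2": regions.lip2,
                "subdomain1": regions.subdomain1,
                "subdomain2": regions.subdomain2,
            },
            "thresholds": {
                "closed_max": self.thresholds.closed_max,
                "open_min": self.thresholds.open_min,
            },
            "equilibration_time_ns": self.equilibration_time,
            "timestep_ns": self.timestep,
            "hbond": {
                "selection_a": self.hbond_selection_a,
                "selection_b": self.hbond_selection_b,
                "max_da_distance_A": self.hbond_criteria.max_da_distance,
                "max_hda_angle_deg": self.hbond_criteria.max_hda_angle,
                "heavy_atoms_only": self.hbond_heavy_only,
            },
            "seed": self.seed,
            "version": __version__,
        }


@dataclass
class AnalysisReport:
    hinge: HingeResult
    rmsd_times: np.ndarray
    rmsd: np.ndarray
    rmsf: FluctuationProfile
    hbonds: HBondSeries | None
    provenance: dict
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        out = {
            "hinge": self.hinge.summary(),
            "rmsd_A": {
                "max": float(np.max(self.rmsd)),
                "mean": float(np.mean(self.rmsd)),
            },
            "rmsf_A": {
                "max": float(np.max(self.rmsf.rmsf)),
                "mean": float(np.mean(self.rmsf.rmsf)),
            },
        }
        if self.hbonds is not None:
            out["hbonds"] = {
                "mean": self.hbonds.mean,
                "sd": self.hbonds.sd,
            }
        if self.warnings:
            out["warnings"] = list(self.warnings)
        return out

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = self.hinge.to_frame()
        write_timeseries(table, out / "hinge_timeseries.csv")
        write_timeseries(
            pd.DataFrame({"time_ns": self.rmsd_times, "rmsd_A": self.rmsd}),
            out / "rmsd_timeseries.csv",
        )
        write_timeseries(self.rmsf.to_frame(), out / "rmsf_profile.csv")
        if self.hbonds is not None:
            write_timeseries(
                pd.DataFrame(
                    {
                        "time_ns": self.hinge.times,
                        "n_hbonds": self.hbonds.counts,
                    }
                ),
                out / "hbond_timeseries.csv",
            )
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        with open(out / "provenance.yaml", "w") as fh:
            yaml.safe_dump(self.provenance, fh, sort_keys=False)


def _checksum(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def _load_inputs(
    config: AnalysisConfig,
) -> tuple[Trajectory, StructureFrame | None]:
    if config.trajectory is None:
        traj = read_pdb(config.topology, model_policy="all", timestep=config.timestep)
        if isinstance(traj, StructureFrame):
            raise HingescopeError("topology holds a single model; no trajectory")
    else:
        traj = read_trajectory(
            config.topology, config.trajectory, timestep=config.timestep
        )
    reference = (
        read_pdb(config.reference, model_policy="first")
        if config.reference
        else None
    )
    return traj, reference


def run_analysis(
    config: AnalysisConfig,
    traj: Trajectory | None = None,
    reference: StructureFrame | None = None,
) -> AnalysisReport:
    """Run the full pipeline; pass ``traj`` directly to skip file loading.

    Stage order: trim equilibration -> hinge observables -> RMSD (full
    trajectory) -> RMSF (production frames) -> optional H-bond counts
    (production frames) -> write artifacts if ``output_dir`` is set.
    Deterministic for fixed inputs and seed.
    """
    stage = "load"
    try:
        if traj is None:
            traj, file_reference = _load_inputs(config)
            reference = reference or file_reference
        regions = config.resolve_regions()

        stage = "trim"
        production = trim_equilibration(traj, config.equilibration_time)

        stage = "hinge"
        hinge = analyze_trajectory(
            production, regions, config.thresholds, reference
        )

        stage = "rmsd"
        all_ca = select_ca(
            traj,
            regions.subdomain1 + regions.subdomain2,
            regions.chain_id,
        )
        rmsd = rmsd_series(traj, all_ca.indices)

        stage = "rmsf"
        profile = rmsf(production, all_ca.indices, all_ca.indices)

        stage = "hbonds"
        hb: HBondSeries | None = None
        if config.hbond_selection_a and config.hbond_selection_b:
            sel_a = select_atoms(traj.topology, config.hbond_selection_a)
            sel_b = select_atoms(traj.topology, config.hbond_selection_b)
            hb = hbond_count_series(
                production,
                sel_a,
                sel_b,
                config.hbond_criteria,
                heavy_atoms_only=config.hbond_heavy_only,
            )

        stage = "report"
        provenance = {"config": config.echo()}
        for key in ("topology", "trajectory", "reference"):
            value = getattr(config, key)
            if value and Path(value).exists():
                provenance.setdefault("checksums_md5", {})[key] = _checksum(value)
        warn: list[str] = []
        if all_ca.missing_residues:
            warn.append(
                f"{len(all_ca.missing_residues)} subdomain residue(s) missing "
                f"from structure: {all_ca.missing_residues}"
            )
        if config.hbond_heavy_only and hb is not None:
            warn.append(
                "hydrogen bonds counted in heavy-atom-only mode "
                "(distance criterion only)"
            )
        report = AnalysisReport(
            hinge=hinge,
            rmsd_times=np.asarray(traj.times, dtype=float),
            rmsd=rmsd,
            rmsf=profile,
            hbonds=hb,
            provenance=provenance,
            warnings=warn,
        )
        if config.output_dir:
            report.write(config.output_dir)
        return report
    except HingescopeError as exc:
        raise HingescopeError(f"stage {stage!r} failed: {exc}") from exc
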