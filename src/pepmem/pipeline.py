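"""End-to-end orchestration: simulate -> classify -> thermo -> contacts -> ddg.

A run is described by a YAML/dict config; outputs are TSV/JSON files
plus a manifest recording parameters, content digests of every input and
output, and per-stage status. Identical config + seed gives identical
outputs (the manifest's wall-clock timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from pepmem import __version__
from pepmem.contacts import (
    ClassifierParams,
    bound_fraction_distribution,
    contact_series,
    segment_states,
)
from pepmem.profile import contact_counts, z_position
from pepmem.regression import ddg_headline, load_deltag_table, ols_fit, pair_deltag, paired_difference
from pepmem.synthetic import (
    SyntheticParams,
    emit_trajectory,
    sample_state_path,
    write_ground_truth,
    write_topology,
    write_trajectory,
)
from pepmem.systems import SystemInputError, load_system, write_table
from pepmem.thermo import ThermoParams, summarize

log = logging.getLogger("pepmem")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class SystemSpec:
    """One peptide-membrane system: either synthetic or loaded from files."""

    label: str
    synthetic: Optional[SyntheticParams] = None
    topology: Optional[Path] = None
    trajectory: Optional[Path] = None
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        from_files = self.topology is not None
        if from_files == (self.synthetic is not None):
            raise ConfigError(
                f"system {self.label!r}: supply exactly one of synthetic params "
                "or topology/trajectory paths"
            )
        if from_files and self.trajectory is None:
            raise ConfigError(f"system {self.label!r}: trajectory path missing")


@dataclass
class RunConfig:
    systems: list[SystemSpec]
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    output_dir: Path = Path("pepmem_out")
    seed: int = 0
    ddg_table: Optional[Path] = None    # None -> packaged reference table
    run_ddg: bool = True
    z_residue: Optional[int] = None     # peptide residue for the z series
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            systems = []
            for entry in raw.get("systems", []):
                entry = dict(entry)
                label = entry.pop("label")
                syn = entry.pop("synthetic", None)
                systems.append(
                    SystemSpec(
                        label=label,
                        synthetic=SyntheticParams(**syn) if syn is not None else None,
                        topology=Path(entry["topology"]) if "topology" in entry else None,
                        trajectory=Path(entry["trajectory"]) if "trajectory" in entry else None,
                        frame_interval=float(entry.get("frame_interval", 0.1)),
                    )
                )
            if not systems:
                raise ConfigError("config lists no systems")
            return cls(
                systems=systems,
                classifier=ClassifierParams(**raw.get("classifier", {})),
                thermo=ThermoParams(**raw.get("thermo", {})),
                output_dir=Path(raw.get("output_dir", "pepmem_out")),
                seed=int(raw.get("seed", 0)),
                ddg_table=Path(raw["ddg_table"]) if raw.get("ddg_table") else None,
                run_ddg=bool(raw.get("run_ddg", True)),
                z_residue=raw.get("z_residue"),
                log_level=str(raw.get("log_level", "INFO")),
            )
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return "sha256:" + h.hexdigest()


def _spawn_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(seed).spawn(index + 1)[index].generate_state(1)[0])


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for every system; return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "pepmem",
        "version": __version__,
        "seed": config.seed,
        "classifier": asdict(config.classifier),
        "thermo": asdict(config.thermo),
        "systems": [],
        "inputs": {},
        "outputs": {},
        "stages": {},
    }
    summaries = []
    for i, spec in enumerate(config.systems):
        stage = f"system[{spec.label}]"
        try:
            if spec.synthetic is not None:
                params = replace(spec.synthetic, seed=_spawn_seed(config.seed, i))
                manifest["systems"].append(
                    {"label": spec.label, "synthetic": asdict(params)}
                )
                truth = sample_state_path(params)
                topology, trajectory = emit_trajectory(params, truth)
                gro = out / f"{spec.label}.gro"
                pdb = out / f"{spec.label}.pdb"
                tsv = out / f"{spec.label}.truth.tsv"
                write_topology(topology, trajectory, gro)
                write_trajectory(topology, trajectory, pdb)
                write_ground_truth(truth, params.frame_interval, tsv)
                for p in (gro, pdb, tsv):
                    manifest["outputs"][str(p)] = _digest(p)
            else:
                for p in (spec.topology, spec.trajectory):
                    if not Path(p).exists():
                        raise SystemInputError(f"input file not found: {p}")
                    manifest["inputs"][str(p)] = _digest(Path(p))
                manifest["systems"].append(
                    {
                        "label": spec.label,
                        "topology": str(spec.topology),
                        "trajectory": str(spec.trajectory),
                    }
                )
                topology, trajectory = load_system(
                    spec.topology, spec.trajectory, frame_interval=spec.frame_interval
                )

            log.info("%s: %d atoms, %d frames", spec.label, trajectory.n_atoms, trajectory.n_frames)
            series = contact_series(trajectory, topology, config.classifier)
            track = segment_states(series, config.classifier, trajectory.frame_interval)
            sample = bound_fraction_distribution(series, track)

            frames = pd.DataFrame(
                {
                    "frame": np.arange(series.n_frames),
                    "time_ns": trajectory.times,
                    "bound_fraction": series.bound_fraction,
                    "raw_flag": series.raw_bound.astype(int),
                    "state": np.where(track.states, "bound", "unbound"),
                }
            )
            state_tsv = out / f"{spec.label}.states.tsv"
            write_table(frames, state_tsv)

            dist = pd.DataFrame(
                series.residue_min_dist,
                columns=[f"res{int(r) + 1}_min_dist" for r in series.peptide_residues],
            )
            dist.insert(0, "frame", np.arange(series.n_frames))
            dist_tsv = out / f"{spec.label}.residue_distances.tsv"
            write_table(dist, dist_tsv)

            counts = contact_counts(trajectory, topology, config.classifier)
            res_tsv = out / f"{spec.label}.residue_contacts.tsv"
            write_table(
                pd.DataFrame(
                    {
                        "residue": [int(r) + 1 for r in sorted(counts.residue_counts)],
                        "contacts": [counts.residue_counts[r] for r in sorted(counts.residue_counts)],
                    }
                ),
                res_tsv,
            )
            pct = counts.species_percent or {}
            sp_tsv = out / f"{spec.label}.species_contacts.tsv"
            write_table(
                pd.DataFrame(
                    {
                        "species": sorted(counts.species_counts),
                        "contacts": [counts.species_counts[s] for s in sorted(counts.species_counts)],
                        "percent": [pct.get(s, float("nan")) for s in sorted(counts.species_counts)],
                    }
                ),
                sp_tsv,
            )
            extra = [state_tsv, dist_tsv, res_tsv, sp_tsv]

            if config.z_residue is not None:
                series_z = z_position(trajectory, topology, int(config.z_residue))
                z_tsv = out / f"{spec.label}.zseries.tsv"
                write_table(
                    pd.DataFrame(
                        {
                            "frame": np.arange(trajectory.n_frames),
                            "z_position": series_z.values,
                        }
                    ),
                    z_tsv,
                )
                extra.append(z_tsv)

            summary = summarize(track, trajectory.total_time, spec.label, config.thermo)
            record = summary.to_record()
            record["bound_fraction_median"] = sample.summary()["median"]
            summaries.append(record)
            for p in extra:
                manifest["outputs"][str(p)] = _digest(p)
            manifest["stages"][stage] = "ok"
        except Exception as exc:
            manifest["stages"][stage] = f"error: {exc}"
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    summary_tsv = out / "binding_summary.tsv"
    write_table(pd.DataFrame(summaries), summary_tsv)
    manifest["outputs"][str(summary_tsv)] = _digest(summary_tsv)
    manifest["stages"]["thermo"] = "ok"

    if config.run_ddg:
        try:
            table = load_deltag_table(config.ddg_table)
            if config.ddg_table is not None:
                manifest["inputs"][str(config.ddg_table)] = _digest(config.ddg_table)
            pairs = pair_deltag(table)
            fit = ols_fit(pairs)
            ddg, ddg_hw = ddg_headline(fit)
            diff, diff_hw = paired_difference(pairs)
            ddg_json = out / "ddg_regression.json"
            payload = fit.to_dict()
            payload["ddg_intercept"] = {"value": ddg, "ci_halfwidth": ddg_hw}
            payload["ddg_paired_difference"] = {"value": diff, "ci_halfwidth": diff_hw}
            ddg_json.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            manifest["outputs"][str(ddg_json)] = _digest(ddg_json)
            manifest["stages"]["ddg"] = "ok"
        except Exception as exc:
            manifest["stages"]["ddg"] = f"error: {exc}"
            raise RuntimeError(f"stage ddg failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
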