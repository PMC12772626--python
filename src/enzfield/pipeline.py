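"""End-to-end orchestration: fields -> projections -> Fukui -> comparisons.

``run_pipeline`` drives the whole analysis for a set of substrate poses and
writes machine-readable CSV artifacts plus a JSON manifest (package version,
seed, parameters and a SHA-256 hash of every output). Stages degrade
gracefully: a pose without orbital data skips the Fukui stage with an
explicit log line; fewer than two poses skips the comparison stage.

Inputs may come from files (a :class:`RunConfig` naming a PQR topology and
per-pose trajectories, validated at construction) or directly from
in-memory :class:`~enzfield.synthetic.PoseEnsemble` bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cdft import (
    DescriptorSeries,
    boltzmann_weights,
    condense_fukui,
    ensemble_average,
    homo_lumo_gap,
)
from .electrostatics import (
    bond_forming_distances,
    convert_field_units,
    ensemble_field_at_atoms,
    probe_projection_series,
    rank_residue_contributions,
)
from .exceptions import ConfigurationError, DegenerateDistributionError
from .model_io import (
    read_energies,
    read_frames,
    read_orbital_data,
    read_pqr,
    resolve_selection,
    subsample_frames,
)
from .stats import alignment_summary, gaussian_kde, pose_comparison_table
from .synthetic import PoseEnsemble

__all__ = ["RunConfig", "run_pipeline", "load_config", "ensembles_from_config"]

logger = logging.getLogger("enzfield")

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """Declarative description of a file-based pipeline run."""

    topology: str
    frames: dict[str, str]  # pose label -> trajectory path
    substrate: str  # selection expression
    probes: list[str] = field(default_factory=lambda: ["C10:C13"])
    orbitals: dict[str, list[str]] = field(default_factory=dict)
    energies: dict[str, str] = field(default_factory=dict)
    temperature: float = 300.0
    units: str = "kcalmolea"
    subsample: int | None = None
    outdir: str = "enzfield_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.frames)) != len(self.frames):
            raise ConfigurationError("pose labels must be unique")
        missing = [p for p in [self.topology, *self.frames.values()] if not Path(p).exists()]
        missing += [p for p in self.energies.values() if not Path(p).exists()]
        for paths in self.orbitals.values():
            missing += [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigurationError(f"missing input files: {missing}")
        if self.units not in ("kcalmolea", "mvcm"):
            raise ConfigurationError("units must be 'kcalmolea' or 'mvcm'")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON) file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return RunConfig(**raw)


def _parse_probe(expr: str, topology) -> tuple[str, int, int]:
    try:
        a, b = expr.split(":")
    except ValueError:
        raise ConfigurationError(
            f"probe {expr!r}: expected 'ORIGIN:TARGET' atom names"
        ) from None
    return f"{a}->{b}", topology.index_of(a), topology.index_of(b)


def ensembles_from_config(config: RunConfig) -> dict[str, PoseEnsemble]:
    """Load per-pose ensembles from the files a RunConfig names."""
    from .model_io import ProbeVector

    topology, _ = read_pqr(config.topology)
    substrate = resolve_selection(topology, config.substrate, name="substrate")
    probes = [
        ProbeVector(name, o, t)
        for name, o, t in (_parse_probe(e, topology) for e in config.probes)
    ]
    out: dict[str, PoseEnsemble] = {}
    for pose, traj in config.frames.items():
        frames = read_frames(traj)
        if frames.n_atoms != topology.n_atoms:
            raise ConfigurationError(
                f"pose {pose}: trajectory has {frames.n_atoms} atoms, "
                f"topology {topology.n_atoms}"
            )
        if pose in config.energies:
            frames.energies = read_energies(config.energies[pose])
            if len(frames.energies) != frames.n_frames:
                raise ConfigurationError(
                    f"pose {pose}: {len(frames.energies)} energies for "
                    f"{frames.n_frames} frames"
                )
        if config.subsample:
            frames = subsample_frames(frames, config.subsample)
        orbitals = [read_orbital_data(p) for p in config.orbitals.get(pose, [])]
        out[pose] = PoseEnsemble(
            pose_label=pose,
            topology=topology,
            frames=frames,
            substrate=substrate,
            probes=probes,
            orbitals=orbitals,
        )
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    ensembles: dict[str, PoseEnsemble],
    outdir: str | Path,
    temperature: float = 300.0,
    units: str = "kcalmolea",
    use_boltzmann: bool = False,
    seed: int = 0,
) -> dict:
    """Run every analysis stage over per-pose ensembles.

    Writes, per pose: a long-format field/projection CSV, KDE tables,
    alignment summaries, a residue ranking, per-frame and ensemble Fukui
    tables (when orbitals are present), plus the pairwise pose-comparison
    table and a JSON manifest. Returns the manifest dict. Deterministic
    stages produce byte-identical CSVs on re-runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unit_scale = convert_field_units(1.0, "mvcm") if units == "mvcm" else 1.0
    stages: dict[str, dict] = {}
    outputs: list[Path] = []
    fukui_series: dict[str, dict[str, np.ndarray]] = {}
    projection_series: dict[str, dict[str, np.ndarray]] = {}

    for pose, ens in sorted(ensembles.items()):
        logger.info("stage=fields pose=%s n_frames=%d", pose, ens.frames.n_frames)
        records = ensemble_field_at_atoms(
            ens.topology, ens.frames, ens.substrate, decompose=False
        )
        atom_name = {a.atom_index: a.atom_name for a in ens.topology.atoms}
        rows = [
            {
                "frame": r.frame_index,
                "atom": atom_name[r.atom_index],
                "potential": r.potential,
                "Ex": r.field[0] * unit_scale,
                "Ey": r.field[1] * unit_scale,
                "Ez": r.field[2] * unit_scale,
            }
            for r in records
        ]
        fields_csv = outdir / f"fields_{pose}.csv"
        pd.DataFrame(rows).to_csv(fields_csv, index=False, float_format=_CSV_FLOAT)
        outputs.append(fields_csv)

        proj_rows = []
        for probe in ens.probes:
            series = probe_projection_series(
                ens.topology, ens.frames, probe, ens.substrate, pose_label=pose
            )
            projection_series.setdefault(f"projection:{probe.name}", {})[pose] = (
                series.projections * unit_scale
            )
            for f, (p, c) in enumerate(zip(series.projections, series.cosines)):
                proj_rows.append(
                    {"frame": f, "probe": probe.name,
                     "projection": p * unit_scale, "cosine": c}
                )
            summ = alignment_summary(series)
            align_csv = outdir / f"alignment_{pose}_{probe.name.replace('->', '_')}.csv"
            pd.DataFrame(
                [
                    {
                        "pose": pose,
                        "probe": probe.name,
                        "fraction_positive": summ.fraction_positive,
                        "mean_cosine": summ.mean_cosine,
                        "modal_bin_mass": summ.modal_mass,
                        "n_frames": summ.n_frames,
                    }
                ]
            ).to_csv(align_csv, index=False, float_format=_CSV_FLOAT)
            outputs.append(align_csv)
            try:
                kde = gaussian_kde(series.projections * unit_scale)
                kde_csv = outdir / f"kde_{pose}_{probe.name.replace('->', '_')}.csv"
                pd.DataFrame({"grid": kde.grid, "density": kde.density}).to_csv(
                    kde_csv, index=False, float_format=_CSV_FLOAT
                )
                outputs.append(kde_csv)
            except DegenerateDistributionError:
                logger.warning(
                    "stage=kde pose=%s probe=%s skipped: zero-variance projections",
                    pose, probe.name,
                )
        proj_csv = outdir / f"projections_{pose}.csv"
        pd.DataFrame(proj_rows).to_csv(proj_csv, index=False, float_format=_CSV_FLOAT)
        outputs.append(proj_csv)

        if ens.frames.n_frames >= 2:
            ranking = rank_residue_contributions(
                ens.topology, ens.frames, ens.probes[0], ens.substrate
            )
            rank_csv = outdir / f"residue_ranking_{pose}.csv"
            ranking.to_csv(rank_csv, index=False, float_format=_CSV_FLOAT)
            outputs.append(rank_csv)

        dist_csv = outdir / f"distances_{pose}.csv"
        pd.DataFrame(bond_forming_distances(ens.frames, ens.probes)).to_csv(
            dist_csv, index=False, float_format=_CSV_FLOAT
        )
        outputs.append(dist_csv)
        stages[f"fields:{pose}"] = {
            "n_frames": ens.frames.n_frames,
            "probes": [p.name for p in ens.probes],
            "units": units,
        }

        if not ens.orbitals:
            logger.warning("stage=fukui pose=%s skipped: no orbital data", pose)
            continue
        logger.info("stage=fukui pose=%s n_frames=%d", pose, len(ens.orbitals))
        weights = None
        if use_boltzmann and ens.frames.energies is not None:
            weights = boltzmann_weights(
                ens.frames.energies[: len(ens.orbitals)], temperature
            )
        frame_rows = []
        per_atom: dict[int, list[float]] = {}
        gaps = []
        for f, orb in enumerate(ens.orbitals):
            fk = condense_fukui(orb, "f-", frame_index=f)
            gaps.append(homo_lumo_gap(orb))
            for a, v in fk.values.items():
                per_atom.setdefault(a, []).append(v)
                frame_rows.append(
                    {"frame": f, "atom": atom_name.get(a, str(a)), "fminus": v}
                )
        fukui_csv = outdir / f"fukui_frames_{pose}.csv"
        pd.DataFrame(frame_rows).to_csv(fukui_csv, index=False, float_format=_CSV_FLOAT)
        outputs.append(fukui_csv)

        ens_rows = []
        for a, vals in sorted(per_atom.items()):
            series = DescriptorSeries(
                name=f"fminus:{atom_name.get(a, a)}",
                values=np.array(vals),
                weights=weights,
                pose_label=pose,
            )
            fukui_series.setdefault(series.name, {})[pose] = series.values
            ed = ensemble_average(series)
            ens_rows.append(
                {
                    "pose": pose,
                    "atom": atom_name.get(a, str(a)),
                    "mean_fminus": ed.mean,
                    "sem": ed.sem,
                    "n_frames": ed.n_frames,
                }
            )
        gap_series = DescriptorSeries(
            name="homo_lumo_gap", values=np.array(gaps), weights=weights,
            pose_label=pose,
        )
        fukui_series.setdefault("homo_lumo_gap", {})[pose] = gap_series.values
        ge = ensemble_average(gap_series)
        ens_rows.append(
            {"pose": pose, "atom": "(gap)", "mean_fminus": ge.mean,
             "sem": ge.sem, "n_frames": ge.n_frames}
        )
        ens_csv = outdir / f"fukui_ensemble_{pose}.csv"
        pd.DataFrame(ens_rows).to_csv(ens_csv, index=False, float_format=_CSV_FLOAT)
        outputs.append(ens_csv)
        stages[f"fukui:{pose}"] = {
            "n_frames": len(ens.orbitals),
            "weighting": "boltzmann" if weights is not None else "uniform",
            "temperature": temperature,
        }

    if len(ensembles) >= 2:
        comparisons = {**projection_series}
        comparisons.update(
            {k: v for k, v in fukui_series.items() if len(v) >= 2}
        )
        comparisons = {k: v for k, v in comparisons.items() if len(v) >= 2}
        if comparisons:
            table = pose_comparison_table(comparisons)
            tests_csv = outdir / "pose_comparisons.csv"
            table.to_csv(tests_csv, index=False, float_format=_CSV_FLOAT)
            outputs.append(tests_csv)
            stages["compare"] = {"n_tests": len(table)}
    else:
        logger.warning("stage=compare skipped: fewer than 2 poses")

    manifest = {
        "package": "enzfield",
        "version": __version__,
        "seed": seed,
        "temperature": temperature,
        "units": units,
        "stages": stages,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("stage=manifest outputs=%d", len(outputs))
    return manifest
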