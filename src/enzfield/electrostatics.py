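"""Environment electrostatic potentials and fields at substrate atoms.

The enzyme (plus any retained solvent) is treated as a fixed set of
molecular-mechanics point charges; the potential and field it exerts at
substrate positions are evaluated as direct Coulomb sums with no cutoff and
no periodic images (frames are assumed pre-imaged with the complex whole).
Field vectors are projected onto chemically meaningful atom-pair axes — for a
Diels-Alder substrate typically the diene axis C10->C13 and the bond-forming
axes C13->C14 / C10->C15 — and decomposed into per-residue contributions by
linearity of the Coulomb sum.

Units: potential kcal/(mol e), field kcal/(mol e A); ``convert_field_units``
reports fields in MV/cm. For probe-vector projections the field is evaluated
at the midpoint of the two probe atoms; per-atom records hold the field at
the atom position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import COULOMB_K, KCAL_MOL_E_A_TO_MV_CM
from .exceptions import (
    ConfigurationError,
    DegenerateGeometryError,
    SingularityError,
)
from .model_io import FrameSet, ProbeVector, Selection, Topology

__all__ = [
    "FieldRecord",
    "ProjectionSeries",
    "potential_at_point",
    "field_at_point",
    "ensemble_field_at_atoms",
    "project_on_vector",
    "project_field_on_probe",
    "probe_projection_series",
    "residue_decomposition",
    "rank_residue_contributions",
    "convert_field_units",
    "bond_forming_distances",
]

#: Minimum allowed distance (A) between an environment charge and the
#: evaluation point; anything closer indicates broken input.
MIN_SEPARATION = 1e-6

#: Field magnitudes below this are treated as directionless (cosine = NaN).
COSINE_FLOOR = 1e-12


@dataclass
class FieldRecord:
    """Potential and field of the environment at one atom in one frame."""

    frame_index: int
    atom_index: int
    potential: float
    field: np.ndarray
    residue_contributions: dict[tuple[int, str], np.ndarray] | None = None


@dataclass
class ProjectionSeries:
    """Per-frame projection of the environment field onto a probe axis."""

    probe: ProbeVector
    projections: np.ndarray
    cosines: np.ndarray
    pose_label: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.projections)


def _check_separation(diff: np.ndarray) -> None:
    """diff: (..., n_env, 3) displacement point - charge."""
    r2 = np.einsum("...ei,...ei->...e", diff, diff)
    bad = r2 < MIN_SEPARATION**2
    if bad.any():
        atom = int(np.argwhere(bad)[0][-1])
        raise SingularityError(
            f"environment atom {atom} coincides with the evaluation point "
            f"(separation < {MIN_SEPARATION} A)"
        )


def potential_at_point(
    charges: np.ndarray, positions: np.ndarray, point: np.ndarray
) -> float:
    """Coulomb potential V = k sum q_i / r_i at ``point``, in kcal/(mol e)."""
    charges = np.asarray(charges, float)
    positions = np.asarray(positions, float).reshape(-1, 3)
    diff = np.asarray(point, float) - positions
    _check_separation(diff[None, :, :])
    r = np.sqrt(np.einsum("ei,ei->e", diff, diff))
    return float(COULOMB_K * np.sum(charges / r))


def field_at_point(
    charges: np.ndarray, positions: np.ndarray, point: np.ndarray
) -> np.ndarray:
    """Coulomb field E = k sum q_i (p - r_i)/|p - r_i|^3, in kcal/(mol e A).

    A positive charge yields a field pointing away from it.
    """
    charges = np.asarray(charges, float)
    positions = np.asarray(positions, float).reshape(-1, 3)
    diff = np.asarray(point, float) - positions
    _check_separation(diff[None, :, :])
    r2 = np.einsum("ei,ei->e", diff, diff)
    inv_r3 = r2 ** -1.5
    return COULOMB_K * np.einsum("e,e,ei->i", charges, inv_r3, diff)


def _batched_potential_field(
    charges: np.ndarray, env_pos: np.ndarray, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized sums.

    env_pos: (n_frames, n_env, 3); points: (n_frames, n_pts, 3).
    Returns potentials (n_frames, n_pts) and fields (n_frames, n_pts, 3).
    """
    diff = points[:, :, None, :] - env_pos[:, None, :, :]
    _check_separation(diff)
    r2 = np.einsum("fpei,fpei->fpe", diff, diff)
    inv_r = 1.0 / np.sqrt(r2)
    pot = COULOMB_K * np.einsum("e,fpe->fp", charges, inv_r)
    fld = COULOMB_K * np.einsum("e,fpe,fpei->fpi", charges, inv_r**3, diff)
    return pot, fld


def _environment_indices(
    topology: Topology, substrate: Selection, environment: Selection | None
) -> np.ndarray:
    sub = set(substrate.atom_indices)
    if environment is None:
        env = np.array(
            [i for i in range(topology.n_atoms) if i not in sub], dtype=int
        )
        if env.size == 0:
            raise ConfigurationError("environment is empty")
        return env
    overlap = sub & set(environment.atom_indices)
    if overlap:
        raise ConfigurationError(
            f"substrate and environment selections overlap on atoms "
            f"{sorted(overlap)}"
        )
    return environment.indices


def ensemble_field_at_atoms(
    topology: Topology,
    frames: FrameSet,
    substrate: Selection,
    environment: Selection | None = None,
    decompose: bool = False,
) -> list[FieldRecord]:
    """Potential and field at every substrate atom in every frame.

    The environment defaults to all atoms outside the substrate selection;
    the substrate's own charges never contribute. With ``decompose=True``
    each record carries per-residue field contributions (their vector sum
    equals the total field by linearity).
    """
    if frames.n_atoms != topology.n_atoms:
        raise ConfigurationError("frames not aligned to topology")
    env_idx = _environment_indices(topology, substrate, environment)
    q = topology.charges[env_idx]
    env_pos = frames.coordinates[:, env_idx, :]
    points = frames.coordinates[:, substrate.indices, :]
    pot, fld = _batched_potential_field(q, env_pos, points)

    groups: list[tuple[tuple[int, str], np.ndarray]] = []
    if decompose:
        pos_of = {int(g): j for j, g in enumerate(env_idx)}
        for key, members in sorted(topology.residue_index.items(), key=lambda kv: kv[0]):
            local = np.array([pos_of[i] for i in members if int(i) in pos_of], int)
            if local.size:
                groups.append((key, local))

    records: list[FieldRecord] = []
    for f in range(frames.n_frames):
        for p, atom in enumerate(substrate.indices):
            contrib = None
            if decompose:
                contrib = {}
                for key, local in groups:
                    _, gf = _batched_potential_field(
                        q[local],
                        env_pos[f][local][None, :, :],
                        points[f, p][None, None, :],
                    )
                    contrib[key] = gf[0, 0]
            records.append(
                FieldRecord(
                    frame_index=f,
                    atom_index=int(atom),
                    potential=float(pot[f, p]),
                    field=fld[f, p],
                    residue_contributions=contrib,
                )
            )
    return records


def project_on_vector(
    field: np.ndarray, probe: ProbeVector, frame_coordinates: np.ndarray
) -> tuple[float, float]:
    """Project a field vector on the probe axis of one frame.

    Returns ``(projection, cosine)`` with projection = E . u for the unit
    vector u from origin to target atom; cosine is NaN when |E| is below
    the directionless floor.
    """
    coords = np.asarray(frame_coordinates, float)
    axis = coords[probe.target_atom] - coords[probe.origin_atom]
    norm = np.linalg.norm(axis)
    if norm < MIN_SEPARATION:
        raise DegenerateGeometryError(
            f"probe {probe.name!r}: zero-length axis in frame"
        )
    u = axis / norm
    field = np.asarray(field, float)
    proj = float(field @ u)
    mag = np.linalg.norm(field)
    cosine = proj / mag if mag >= COSINE_FLOOR else float("nan")
    return proj, cosine


def project_field_on_probe(
    topology: Topology,
    frame_coordinates: np.ndarray,
    probe: ProbeVector,
    substrate: Selection,
    environment: Selection | None = None,
) -> tuple[float, float]:
    """Field of the environment evaluated at the probe midpoint, projected.

    Convenience single-frame form of :func:`probe_projection_series`.
    """
    env_idx = _environment_indices(topology, substrate, environment)
    coords = np.asarray(frame_coordinates, float)
    midpoint = 0.5 * (coords[probe.origin_atom] + coords[probe.target_atom])
    e = field_at_point(topology.charges[env_idx], coords[env_idx], midpoint)
    return project_on_vector(e, probe, coords)


def probe_projection_series(
    topology: Topology,
    frames: FrameSet,
    probe: ProbeVector,
    substrate: Selection,
    environment: Selection | None = None,
    pose_label: str = "",
) -> ProjectionSeries:
    """Per-frame projected field on a probe axis (field at probe midpoint)."""
    env_idx = _environment_indices(topology, substrate, environment)
    q = topology.charges[env_idx]
    env_pos = frames.coordinates[:, env_idx, :]
    mid = 0.5 * (
        frames.coordinates[:, probe.origin_atom, :]
        + frames.coordinates[:, probe.target_atom, :]
    )
    _, fld = _batched_potential_field(q, env_pos, mid[:, None, :])
    fld = fld[:, 0, :]
    axis = (
        frames.coordinates[:, probe.target_atom, :]
        - frames.coordinates[:, probe.origin_atom, :]
    )
    norms = np.linalg.norm(axis, axis=1)
    if (norms < MIN_SEPARATION).any():
        f = int(np.argmax(norms < MIN_SEPARATION))
        raise DegenerateGeometryError(
            f"probe {probe.name!r}: zero-length axis in frame {f}"
        )
    u = axis / norms[:, None]
    proj = np.einsum("fi,fi->f", fld, u)
    mag = np.linalg.norm(fld, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = np.where(mag >= COSINE_FLOOR, proj / mag, np.nan)
    return ProjectionSeries(
        probe=probe, projections=proj, cosines=cosines, pose_label=pose_label
    )


def residue_decomposition(
    topology: Topology,
    frame_coordinates: np.ndarray,
    point: np.ndarray,
    environment: Selection | np.ndarray,
) -> dict[tuple[int, str], np.ndarray]:
    """Field at ``point`` split into per-residue contributions.

    Contribution of residue R is the Coulomb field from R's atoms only; the
    contributions sum to the total field exactly up to floating point.
    """
    env_idx = (
        environment.indices if isinstance(environment, Selection)
        else np.asarray(environment, int)
    )
    coords = np.asarray(frame_coordinates, float)
    env_set = set(int(i) for i in env_idx)
    out: dict[tuple[int, str], np.ndarray] = {}
    for key, members in sorted(topology.residue_index.items(), key=lambda kv: kv[0]):
        local = np.array([i for i in members if int(i) in env_set], int)
        if local.size:
            out[key] = field_at_point(
                topology.charges[local], coords[local], point
            )
    return out


def rank_residue_contributions(
    topology: Topology,
    frames: FrameSet,
    probe: ProbeVector,
    substrate: Selection,
    environment: Selection | None = None,
) -> pd.DataFrame:
    """Rank residues by their mean projected field contribution on a probe.

    Per frame, the field of each residue is evaluated at the probe midpoint
    and projected on the probe axis; residues are sorted by the absolute
    mean projected contribution (descending, ties broken by residue id).
    Needs at least 2 frames for the SEM.
    """
    if frames.n_frames < 2:
        raise ConfigurationError("ranking requires at least 2 frames for SEM")
    env_idx = _environment_indices(topology, substrate, environment)
    env_set = set(int(i) for i in env_idx)
    keys = []
    locals_: list[np.ndarray] = []
    for key, members in sorted(topology.residue_index.items(), key=lambda kv: kv[0]):
        local = np.array([i for i in members if int(i) in env_set], int)
        if local.size:
            keys.append(key)
            locals_.append(local)

    mid = 0.5 * (
        frames.coordinates[:, probe.origin_atom, :]
        + frames.coordinates[:, probe.target_atom, :]
    )
    axis = (
        frames.coordinates[:, probe.target_atom, :]
        - frames.coordinates[:, probe.origin_atom, :]
    )
    u = axis / np.linalg.norm(axis, axis=1)[:, None]

    rows = []
    name_of = {
        (a.residue_id, a.chain_id): a.residue_name for a in topology.atoms
    }
    for key, local in zip(keys, locals_):
        _, fld = _batched_potential_field(
            topology.charges[local],
            frames.coordinates[:, local, :],
            mid[:, None, :],
        )
        proj = np.einsum("fi,fi->f", fld[:, 0, :], u)
        rows.append(
            {
                "residue_id": key[0],
                "chain_id": key[1],
                "residue_name": name_of[key],
                "mean_projection": float(proj.mean()),
                "sem": float(proj.std(ddof=1) / np.sqrt(len(proj))),
                "n_frames": len(proj),
            }
        )
    df = pd.DataFrame(rows)
    df["abs_mean"] = df["mean_projection"].abs()
    df = (
        df.sort_values(["abs_mean", "residue_id"], ascending=[False, True])
        .drop(columns="abs_mean")
        .reset_index(drop=True)
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def convert_field_units(value, to: str = "mvcm"):
    """Convert field values between kcal/(mol e A) and MV/cm.

    The conversion factor (~4.336 MV/cm per kcal/(mol e A)) is derived from
    CODATA constants at import time.
    """
    arr = np.asarray(value, float)
    if to == "mvcm":
        out = arr * KCAL_MOL_E_A_TO_MV_CM
    elif to == "kcalmolea":
        out = arr / KCAL_MOL_E_A_TO_MV_CM
    else:
        raise ConfigurationError(f"unknown unit target {to!r}")
    return float(out) if np.isscalar(value) else out


def bond_forming_distances(
    frames: FrameSet, pairs: list[ProbeVector]
) -> dict[str, np.ndarray]:
    """Per-frame Euclidean distances (A) between each probe's atom pair."""
    out = {}
    for probe in pairs:
        d = (
            frames.coordinates[:, probe.target_atom, :]
            - frames.coordinates[:, probe.origin_atom, :]
        )
        out[probe.name] = np.linalg.norm(d, axis=1)
    return out
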