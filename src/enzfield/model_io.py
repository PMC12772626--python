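"""Shared data model and file I/O.

Defines the in-memory containers used by every analysis stage (topology with
partial charges, coordinate frames, selections, probe vectors, orbital data,
charge tables) and the readers/writers for the supported text formats:

* PQR (the canonical charge carrier: whitespace-separated ATOM/HETATM records
  carrying ``x y z charge radius``),
* multi-model PDB and XYZ trajectories (parsed through MDAnalysis),
* CSV charge tables and per-frame energies,
* a documented JSON schema for molecular-orbital data (see
  ``docs/file_formats.md``).

Conventions: atom indices are 0-based internally; 1-based serials appear only
in PDB/PQR records. Coordinates are Angstrom, charges elementary charges e,
energies kcal/mol.
"""

from __future__ import annotations

import difflib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    FrontierUndefinedError,
    ParseError,
    SelectionError,
)

__all__ = [
    "ChargedAtom",
    "Topology",
    "FrameSet",
    "Selection",
    "ProbeVector",
    "OrbitalData",
    "ChargeTable",
    "read_pqr",
    "write_pqr",
    "read_frames",
    "write_frames_pdb",
    "subsample_frames",
    "resolve_selection",
    "read_orbital_data",
    "write_orbital_data",
    "read_charge_table",
    "read_energies",
    "OCCUPATION_THRESHOLD",
]

#: Occupation (electrons) above which an MO counts as occupied.
OCCUPATION_THRESHOLD = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChargedAtom:
    """One point-charge atom of the topology."""

    atom_index: int
    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str = ""
    charge: float = 0.0
    element: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.charge):
            raise ConfigurationError(
                f"atom {self.atom_index} ({self.atom_name}): charge not finite"
            )


class Topology:
    """Ordered collection of :class:`ChargedAtom` with residue grouping.

    Parameters
    ----------
    atoms:
        Atoms in file order; ``atom_index`` must be the contiguous 0-based
        position of each atom in this list.
    """

    def __init__(self, atoms: Sequence[ChargedAtom]):
        atoms = list(atoms)
        if not atoms:
            raise ConfigurationError("topology must contain at least one atom")
        for i, a in enumerate(atoms):
            if a.atom_index != i:
                raise ConfigurationError(
                    f"atom_index {a.atom_index} at position {i}: indices must "
                    "be contiguous and 0-based"
                )
        self.atoms: list[ChargedAtom] = atoms
        self.charges: np.ndarray = np.array([a.charge for a in atoms], float)
        self.residue_index: dict[tuple[int, str], np.ndarray] = {}
        groups: dict[tuple[int, str], list[int]] = {}
        for a in atoms:
            groups.setdefault((a.residue_id, a.chain_id), []).append(a.atom_index)
        self.residue_index = {k: np.array(v, dtype=int) for k, v in groups.items()}

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.atoms)

    def atom_names(self) -> list[str]:
        return [a.atom_name for a in self.atoms]

    def index_of(self, atom_name: str) -> int:
        """Index of the first atom with this name (raises if absent)."""
        for a in self.atoms:
            if a.atom_name == atom_name:
                return a.atom_index
        raise SelectionError(f"no atom named {atom_name!r} in topology")


@dataclass
class FrameSet:
    """Per-frame coordinates (Angstrom), optionally with per-frame energies.

    ``coordinates`` has shape ``(n_frames, n_atoms, 3)`` and is index-aligned
    to the :class:`Topology` it is used with.
    """

    coordinates: np.ndarray
    energies: np.ndarray | None = None
    frame_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[-1] != 3:
            raise ConfigurationError(
                f"coordinates must have shape (n_frames, n_atoms, 3), got "
                f"{self.coordinates.shape}"
            )
        if not np.isfinite(self.coordinates).all():
            raise ConfigurationError("coordinates contain non-finite values")
        if self.energies is not None:
            self.energies = np.asarray(self.energies, float)
            if len(self.energies) != self.n_frames:
                raise ConfigurationError(
                    f"{len(self.energies)} energies for {self.n_frames} frames"
                )
        if self.frame_labels is not None and len(self.frame_labels) != self.n_frames:
            raise ConfigurationError("frame_labels length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class Selection:
    """Named, ordered set of atom indices."""

    name: str
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.atom_indices) == 0:
            raise SelectionError(f"selection {self.name!r} is empty")
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise SelectionError(f"selection {self.name!r} has duplicate indices")

    @property
    def indices(self) -> np.ndarray:
        return np.array(self.atom_indices, dtype=int)

    def __len__(self) -> int:
        return len(self.atom_indices)


@dataclass(frozen=True)
class ProbeVector:
    """Axis between two topology atoms onto which fields are projected."""

    name: str
    origin_atom: int
    target_atom: int

    def __post_init__(self) -> None:
        if self.origin_atom == self.target_atom:
            raise ConfigurationError(
                f"probe {self.name!r}: origin and target atoms coincide"
            )


@dataclass
class OrbitalData:
    """One frame's molecular orbitals.

    ``mo_coefficients`` has one column per MO and one row per basis function;
    ``basis_to_atom`` maps each basis row to a topology atom index. When
    ``overlap`` is None an orthonormal (identity-overlap) basis is assumed.
    """

    mo_coefficients: np.ndarray
    mo_energies: np.ndarray
    occupations: np.ndarray
    basis_to_atom: np.ndarray
    overlap: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mo_coefficients = np.asarray(self.mo_coefficients, float)
        self.mo_energies = np.asarray(self.mo_energies, float)
        self.occupations = np.asarray(self.occupations, float)
        self.basis_to_atom = np.asarray(self.basis_to_atom, int)
        if self.mo_coefficients.ndim != 2:
            raise ConfigurationError("mo_coefficients must be 2-D")
        nb, nmo = self.mo_coefficients.shape
        if len(self.mo_energies) != nmo or len(self.occupations) != nmo:
            raise ConfigurationError("energies/occupations length != number of MOs")
        if len(self.basis_to_atom) != nb:
            raise ConfigurationError("basis_to_atom must cover every basis row")
        if (self.occupations < 0).any():
            raise ConfigurationError("occupations must be non-negative")
        occ = self.occupations > OCCUPATION_THRESHOLD
        if occ.all() or (~occ).all():
            raise FrontierUndefinedError(
                "orbital data needs at least one occupied and one virtual MO"
            )
        if self.overlap is not None:
            self.overlap = np.asarray(self.overlap, float)
            if self.overlap.shape != (nb, nb):
                raise ConfigurationError("overlap must be n_basis x n_basis")
            if not np.allclose(self.overlap, self.overlap.T, atol=1e-8):
                raise ConfigurationError("overlap matrix is not symmetric")
            if not np.allclose(np.diag(self.overlap), 1.0, atol=1e-8):
                raise ConfigurationError("overlap diagonal must be 1 within 1e-8")

    @property
    def n_basis(self) -> int:
        return self.mo_coefficients.shape[0]

    @property
    def n_mo(self) -> int:
        return self.mo_coefficients.shape[1]

    def overlap_or_identity(self) -> np.ndarray:
        if self.overlap is None:
            return np.eye(self.n_basis)
        return self.overlap


@dataclass
class ChargeTable:
    """Atomic charges (e) from one electronic-structure context.

    ``label`` records the context the charges were computed in, e.g.
    ``"enzyme"``, ``"vacuum"`` or ``"solvent"``.
    """

    values: dict[int, float]
    label: str = ""

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ConfigurationError(f"charge for atom {k} not finite")

    def __getitem__(self, atom_index: int) -> float:
        return self.values[atom_index]

    def atom_set(self) -> frozenset[int]:
        return frozenset(self.values)


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path) -> tuple[Topology, FrameSet]:
    """Read a whitespace-separated PQR file.

    Records look like::

        ATOM  serial name resname [chain] resid x y z charge radius

    The chain column is optional (detected per record from the token count).
    Radii are parsed for format fidelity but ignored downstream.

    Returns the topology and a single-frame :class:`FrameSet`.
    """
    path = Path(path)
    atoms: list[ChargedAtom] = []
    coords: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            if len(rec) not in (10, 11):
                raise ParseError(
                    f"{path.name}, line {lineno}: expected 10 or 11 fields in "
                    f"{rec[0]} record, found {len(rec)}"
                )
            has_chain = len(rec) == 11
            try:
                name = rec[2]
                resname = rec[3]
                chain = rec[4] if has_chain else ""
                resid = int(rec[5 if has_chain else 4])
                x, y, z, charge, _radius = (
                    float(v) for v in rec[6 if has_chain else 5:][:5]
                )
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}, line {lineno}: malformed {rec[0]} record "
                    f"({exc})"
                ) from None
            atoms.append(
                ChargedAtom(
                    atom_index=len(atoms),
                    atom_name=name,
                    residue_name=resname,
                    residue_id=resid,
                    chain_id=chain,
                    charge=charge,
                )
            )
            coords.append([x, y, z])
    if not atoms:
        raise ParseError(f"{path.name}: no ATOM/HETATM records found")
    topology = Topology(atoms)
    frames = FrameSet(np.array(coords, float)[None, :, :])
    return topology, frames


def write_pqr(path: str | Path, topology: Topology, coordinates: np.ndarray) -> None:
    """Write one frame as PQR (coordinates to 3 decimals, charges to 4)."""
    coordinates = np.asarray(coordinates, float)
    if coordinates.shape != (topology.n_atoms, 3):
        raise ConfigurationError(
            f"coordinates shape {coordinates.shape} does not match topology "
            f"({topology.n_atoms} atoms)"
        )
    with open(path, "w") as fh:
        for a, (x, y, z) in zip(topology.atoms, coordinates):
            chain = f" {a.chain_id}" if a.chain_id else ""
            fh.write(
                f"ATOM {a.atom_index + 1:6d} {a.atom_name:<4s} "
                f"{a.residue_name:<4s}{chain} {a.residue_id:4d} "
                f"{x:10.3f} {y:10.3f} {z:10.3f} {a.charge:8.4f} {1.5:7.4f}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _scan_pdb_frame_counts(path: Path) -> list[int]:
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            tag = line[:6].strip()
            if tag == "MODEL":
                saw_model = True
                in_model = True
                current = 0
            elif tag == "ENDMDL":
                counts.append(current)
                in_model = False
            elif tag in ("ATOM", "HETATM"):
                current += 1
    if not saw_model:
        counts = [current]
    elif in_model:  # unterminated final MODEL
        counts.append(current)
    return counts


def _scan_xyz_frame_counts(path: Path) -> list[int]:
    counts: list[int] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"{path.name}, line {i + 1}: expected an atom count"
            ) from None
        counts.append(n)
        i += n + 2
    return counts


def read_frames(path: str | Path, format: str | None = None) -> FrameSet:
    """Read a multi-model PDB or XYZ trajectory (Angstrom preserved).

    ``format`` is ``"pdb"`` or ``"xyz"``; inferred from the suffix when None.
    Raises :class:`ParseError` naming the frame if the atom count varies.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format not in ("pdb", "xyz"):
        raise ConfigurationError(f"unsupported trajectory format {format!r}")

    counts = (
        _scan_pdb_frame_counts(path) if format == "pdb"
        else _scan_xyz_frame_counts(path)
    )
    if not counts or counts[0] == 0:
        raise ParseError(f"{path.name}: no atoms found")
    for k, c in enumerate(counts):
        if c != counts[0]:
            raise ParseError(
                f"frame {k + 1}: expected {counts[0]} atoms, found {c}"
            )

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(path))
        coords = np.array(
            [ts.positions.copy() for ts in universe.trajectory], dtype=float
        )
    return FrameSet(coords)


def write_frames_pdb(
    path: str | Path,
    topology: Topology,
    frames: FrameSet,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write frames as a multi-model PDB.

    ``bfactors`` (one per atom) fills the B-factor column of every model —
    used to color atoms by e.g. mean electrostatic potential.
    """
    if frames.n_atoms != topology.n_atoms:
        raise ConfigurationError("frame/topology atom count mismatch")
    b = np.zeros(topology.n_atoms) if bfactors is None else np.asarray(bfactors)
    with open(path, "w") as fh:
        for f in range(frames.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a, (x, y, z) in zip(topology.atoms, frames.coordinates[f]):
                name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
                chain = a.chain_id[:1] if a.chain_id else " "
                element = (a.element or a.atom_name[:1]).rjust(2)
                fh.write(
                    f"ATOM  {a.atom_index + 1:5d} {name:<4s} "
                    f"{a.residue_name:<4s}{chain}{a.residue_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b[a.atom_index]:6.2f}"
                    f"          {element}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def subsample_frames(frames: FrameSet, k: int) -> FrameSet:
    """Select ``k`` equally spaced frames (endpoints included).

    Indices are ``round(i*(n-1)/(k-1))`` for ``i = 0..k-1``; ``k == 1``
    returns the middle frame.
    """
    n = frames.n_frames
    if not 1 <= k <= n:
        raise ConfigurationError(f"k={k} out of range [1, {n}]")
    if k == 1:
        idx = np.array([n // 2])
    else:
        idx = np.round(np.arange(k) * (n - 1) / (k - 1)).astype(int)
    return FrameSet(
        frames.coordinates[idx],
        energies=None if frames.energies is None else frames.energies[idx],
        frame_labels=(
            None if frames.frame_labels is None
            else [frames.frame_labels[i] for i in idx]
        ),
    )


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def resolve_selection(topology: Topology, expr: str, name: str | None = None) -> Selection:
    """Resolve a selection expression against the topology.

    Mini-grammar (clauses unioned, separated by ``;``)::

        name  N1,N2,...    atoms by atom name
        resid R1,R2,...    all atoms of the given residue ids
        index I1,I2,...    explicit 0-based atom indices

    Resolution is by name/residue id, never by list position, so it is stable
    under atom reordering once indices are remapped. Unknown names raise a
    :class:`SelectionError` listing near-matches.
    """
    indices: list[int] = []
    seen: set[int] = set()

    def add(i: int) -> None:
        if i not in seen:
            seen.add(i)
            indices.append(i)

    for clause in expr.split(";"):
        clause = clause.strip()
        if not clause:
            continue
        parts = clause.split(None, 1)
        if len(parts) != 2:
            raise SelectionError(
                f"cannot parse clause {clause!r}: expected 'keyword values'"
            )
        keyword, values = parts
        tokens = [t.strip() for t in values.split(",") if t.strip()]
        if keyword == "name":
            known = topology.atom_names()
            for tok in tokens:
                matches = [a.atom_index for a in topology.atoms if a.atom_name == tok]
                if not matches:
                    near = difflib.get_close_matches(tok, known, n=3)
                    hint = f" (did you mean {', '.join(near)}?)" if near else ""
                    raise SelectionError(f"unknown atom name {tok!r}{hint}")
                for i in matches:
                    add(i)
        elif keyword == "resid":
            known_ids = sorted({a.residue_id for a in topology.atoms})
            for tok in tokens:
                try:
                    rid = int(tok)
                except ValueError:
                    raise SelectionError(f"resid {tok!r} is not an integer") from None
                matches = [a.atom_index for a in topology.atoms if a.residue_id == rid]
                if not matches:
                    raise SelectionError(
                        f"unknown residue id {rid} (known: {known_ids})"
                    )
                for i in matches:
                    add(i)
        elif keyword == "index":
            for tok in tokens:
                try:
                    i = int(tok)
                except ValueError:
                    raise SelectionError(f"index {tok!r} is not an integer") from None
                if not 0 <= i < topology.n_atoms:
                    raise SelectionError(
                        f"index {i} out of range [0, {topology.n_atoms})"
                    )
                add(i)
        else:
            raise SelectionError(
                f"unknown selection keyword {keyword!r} "
                "(expected name, resid or index)"
            )
    return Selection(name=name or expr, atom_indices=tuple(indices))


# ---------------------------------------------------------------------------
# orbital data / tables
# ---------------------------------------------------------------------------

def read_orbital_data(path: str | Path) -> OrbitalData:
    """Read molecular-orbital data from the JSON schema in docs/file_formats.md.

    Required keys: ``mo_coefficients`` (rows = basis functions, columns = MOs),
    ``mo_energies``, ``occupations``, ``basis_to_atom``. Optional: ``overlap``
    (identity assumed when absent), ``n_basis`` (cross-checked when present).
    """
    path = Path(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path.name}: invalid JSON ({exc})") from None
    missing = {"mo_coefficients", "mo_energies", "occupations", "basis_to_atom"} - set(raw)
    if missing:
        raise ParseError(f"{path.name}: missing keys {sorted(missing)}")
    data = OrbitalData(
        mo_coefficients=np.array(raw["mo_coefficients"], float),
        mo_energies=np.array(raw["mo_energies"], float),
        occupations=np.array(raw["occupations"], float),
        basis_to_atom=np.array(raw["basis_to_atom"], int),
        overlap=None if raw.get("overlap") is None else np.array(raw["overlap"], float),
    )
    if "n_basis" in raw and int(raw["n_basis"]) != data.n_basis:
        raise ParseError(
            f"{path.name}: n_basis={raw['n_basis']} but coefficient matrix has "
            f"{data.n_basis} rows"
        )
    return data


def write_orbital_data(path: str | Path, orbitals: OrbitalData) -> None:
    payload = {
        "n_basis": orbitals.n_basis,
        "mo_coefficients": orbitals.mo_coefficients.tolist(),
        "mo_energies": orbitals.mo_energies.tolist(),
        "occupations": orbitals.occupations.tolist(),
        "basis_to_atom": orbitals.basis_to_atom.tolist(),
    }
    if orbitals.overlap is not None:
        payload["overlap"] = orbitals.overlap.tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_charge_table(path: str | Path, label: str = "") -> ChargeTable:
    """Read a CSV with columns ``atom_index,charge`` (extra columns ignored)."""
    df = pd.read_csv(path)
    for col in ("atom_index", "charge"):
        if col not in df.columns:
            raise ParseError(f"{Path(path).name}: missing column {col!r}")
    return ChargeTable(
        values={int(i): float(q) for i, q in zip(df["atom_index"], df["charge"])},
        label=label,
    )


def read_energies(path: str | Path) -> np.ndarray:
    """Read per-frame energies (kcal/mol) from a CSV with an ``energy`` column."""
    df = pd.read_csv(path)
    if "energy" not in df.columns:
        raise ParseError(f"{Path(path).name}: missing column 'energy'")
    return df["energy"].to_numpy(float)
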