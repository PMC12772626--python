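"""Synthetic fixtures with the structure the analysis assumes.

Real inputs to this kind of analysis are QM/MM ensembles of an enzyme-bound
substrate. The generator emulates their essential features at desk scale:

* a beta-barrel-like **cage** of charged two-atom pseudo-residues around a
  small rigid substrate carrying the named atoms C10/C13 (diene termini) and
  C14/C15 (dienophile). Glutamate/arginine-like residues at the top of the
  cage and aspartate/arginine-like residues at the bottom give the cavity a
  net axial field; in the ``up`` pose the C10->C13 axis points along +z
  (toward the top ring), the ``down`` pose is the 180-degree flip about the
  x-axis. The C10/C13 midpoint sits exactly at the flip center, so with zero
  positional noise the projected field on the diene axis negates exactly
  between poses.
* frame-to-frame Gaussian positional noise on every atom, plus per-frame
  energies that grow quadratically with total displacement (a harmonic
  pseudo-potential) for Boltzmann-weighting tests.
* **Hueckel polyene orbitals** (tridiagonal alpha/beta Hamiltonian,
  diagonalized exactly) as frontier-orbital fixtures with closed-form
  condensed values.
* four-pose ensembles ("A"/"B" = up, "C"/"D" = down) whose per-frame HOMO is
  perturbed toward the terminal diene atoms in proportion to that frame's
  projected field, so the field/reactivity coupling the pipeline should
  recover is present by construction with a known effect size.

A single global seed fans out to per-pose, per-component seeds through
``numpy.random.SeedSequence(seed, spawn_key=...)``, so every sub-result is
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import electrostatics
from .exceptions import ConfigurationError
from .model_io import (
    ChargedAtom,
    FrameSet,
    OrbitalData,
    ProbeVector,
    Selection,
    Topology,
)

__all__ = [
    "CageSpec",
    "HuckelSpec",
    "PoseEnsemble",
    "generate_cage",
    "generate_huckel_orbitals",
    "generate_pose_ensembles",
    "DEFAULT_ORBITAL_GAIN",
    "DEFAULT_ORBITAL_JITTER",
]

#: Cage residues: (resname, resid, net charge e, ring, azimuth deg, dz A, radial offset A)
#: ring is "top", "bottom" or "mid". The first top residue sits closer to the
#: barrel axis (it "seals the cavity"), making it the designed dominant
#: contributor to the axial field — and the stagger in dz keeps every other
#: |contribution| distinct, so rankings have a unique, deterministic order.
_CAGE_LAYOUT = [
    ("GLU", 19, -1.0, "top", 0.0, 0.0, -2.0),
    ("GLU", 78, -1.0, "top", 120.0, 0.9, 0.0),
    ("ARG", 122, +1.0, "top", 240.0, 1.8, 0.0),
    ("ASP", 26, -1.0, "bottom", 90.0, 0.0, 0.0),
    ("ARG", 130, +1.0, "bottom", 270.0, 0.9, 0.0),
    ("ALA", 50, 0.0, "mid", 180.0, 0.0, 0.0),
]

#: Rigid substrate template (up pose), Angstrom. C10->C13 along +z with the
#: C10/C13 midpoint exactly at the origin (the flip center).
_SUBSTRATE = [
    ("C10", np.array([0.0, 0.0, -1.4]), -0.10),
    ("C11", np.array([1.0, 0.0, -0.5]), 0.05),
    ("C12", np.array([1.0, 0.0, 0.5]), 0.05),
    ("C13", np.array([0.0, 0.0, 1.4]), -0.10),
    ("C14", np.array([-2.2, 0.0, 1.2]), 0.05),
    ("C15", np.array([-2.2, 0.0, -1.2]), 0.05),
]

_SUBSTRATE_RESID = 200

#: Harmonic pseudo-potential stiffness for per-frame energies, kcal/mol/A^2.
_SPRING_K = 1.0

#: Default coupling of the HOMO perturbation to the projected field
#: (per kcal/(mol e A)) and the per-frame jitter of that perturbation.
DEFAULT_ORBITAL_GAIN = 0.003
DEFAULT_ORBITAL_JITTER = 0.02


@dataclass(frozen=True)
class CageSpec:
    """Parameters of the synthetic charged cage + substrate ensemble."""

    n_frames: int = 100
    substrate_pose: str = "up"
    noise_sd: float = 0.1
    barrel_radius: float = 8.0
    barrel_height: float = 10.0
    top_charges: tuple[float, ...] = (-1.0, -1.0, +1.0)
    bottom_charges: tuple[float, ...] = (-1.0, +1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.substrate_pose not in ("up", "down"):
            raise ConfigurationError(
                f"substrate_pose must be 'up' or 'down', got {self.substrate_pose!r}"
            )
        if self.barrel_radius <= 3.0 or self.barrel_height <= 0:
            raise ConfigurationError("barrel must be wider than 3 A and have height > 0")
        if len(self.top_charges) != 3 or len(self.bottom_charges) != 2:
            raise ConfigurationError("expected 3 top and 2 bottom residue charges")


@dataclass(frozen=True)
class HuckelSpec:
    """A linear polyene chain in the Hueckel approximation."""

    n: int = 4
    alpha: float = 0.0
    beta: float = -1.0
    n_electrons: int | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.n <= 8:
            raise ConfigurationError("chain length must be in [2, 8]")
        ne = self.n if self.n_electrons is None else self.n_electrons
        if ne % 2 != 0:
            raise ConfigurationError("n_electrons must be even (closed shell)")
        if not 2 <= ne <= 2 * self.n:
            raise ConfigurationError("n_electrons out of range [2, 2n]")

    @property
    def electrons(self) -> int:
        return self.n if self.n_electrons is None else self.n_electrons


@dataclass
class PoseEnsemble:
    """Everything the pipeline needs for one substrate pose."""

    pose_label: str
    topology: Topology
    frames: FrameSet
    substrate: Selection
    probes: list[ProbeVector]
    orbitals: list[OrbitalData]
    diene_atoms: dict[str, int] = field(default_factory=dict)


def _reference_coordinates(spec: CageSpec) -> tuple[list[ChargedAtom], np.ndarray]:
    atoms: list[ChargedAtom] = []
    coords: list[np.ndarray] = []
    flip = spec.substrate_pose == "down"
    for name, pos, q in _SUBSTRATE:
        p = pos * np.array([1.0, -1.0, -1.0]) if flip else pos
        atoms.append(
            ChargedAtom(
                atom_index=len(atoms),
                atom_name=name,
                residue_name="SUB",
                residue_id=_SUBSTRATE_RESID,
                chain_id="A",
                charge=q,
                element="C",
            )
        )
        coords.append(p)

    charge_of = dict(
        zip(
            [19, 78, 122],
            spec.top_charges,
        )
    ) | dict(zip([26, 130], spec.bottom_charges))
    for resname, resid, _default_q, ring, azimuth, dz, dr in _CAGE_LAYOUT:
        net_q = charge_of.get(resid, 0.0)
        if ring == "top":
            z = spec.barrel_height / 2.0 + dz
        elif ring == "bottom":
            z = -spec.barrel_height / 2.0 - dz
        else:
            z = dz
        r = spec.barrel_radius + dr
        phi = np.deg2rad(azimuth)
        center = np.array([r * np.cos(phi), r * np.sin(phi), z])
        tangent = np.array([-np.sin(phi), np.cos(phi), 0.0])
        for j, off in enumerate((-0.4, 0.4)):
            atoms.append(
                ChargedAtom(
                    atom_index=len(atoms),
                    atom_name=f"P{j + 1}",
                    residue_name=resname,
                    residue_id=resid,
                    chain_id="A",
                    charge=net_q / 2.0,
                )
            )
            coords.append(center + off * tangent)
    return atoms, np.array(coords)


def generate_cage(
    spec: CageSpec,
) -> tuple[Topology, FrameSet, Selection, list[ProbeVector]]:
    """Build the charged-cage ensemble for one pose.

    Returns the topology, the noisy frames (with harmonic per-frame energies
    in kcal/mol), the substrate selection, and the three standard probe
    vectors (diene axis C10->C13 and bond-forming axes C13->C14, C10->C15).
    Identical specs give bit-identical outputs.
    """
    atoms, ref = _reference_coordinates(spec)
    topology = Topology(atoms)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    noise = rng.normal(0.0, spec.noise_sd or 0.0, size=(spec.n_frames,) + ref.shape)
    if spec.noise_sd == 0.0:
        noise[:] = 0.0
    coords = ref[None, :, :] + noise
    energies = 0.5 * _SPRING_K * np.sum(noise**2, axis=(1, 2))
    frames = FrameSet(
        coords,
        energies=energies,
        frame_labels=[f"frame{i:04d}" for i in range(spec.n_frames)],
    )
    name_to_idx = {a.atom_name: a.atom_index for a in atoms if a.residue_name == "SUB"}
    substrate = Selection(
        name="substrate",
        atom_indices=tuple(
            a.atom_index for a in atoms if a.residue_id == _SUBSTRATE_RESID
        ),
    )
    probes = [
        ProbeVector("C10->C13", name_to_idx["C10"], name_to_idx["C13"]),
        ProbeVector("C13->C14", name_to_idx["C13"], name_to_idx["C14"]),
        ProbeVector("C10->C15", name_to_idx["C10"], name_to_idx["C15"]),
    ]
    return topology, frames, substrate, probes


def generate_huckel_orbitals(
    spec: HuckelSpec, basis_to_atom: np.ndarray | None = None
) -> OrbitalData:
    """Exact Hueckel orbitals of a linear polyene chain.

    The tridiagonal Hamiltonian (alpha on the diagonal, beta on the first
    off-diagonals) is diagonalized; orbitals are aufbau-occupied with the
    spec's electron count. Energies are in the (arbitrary) Hueckel unit set
    by alpha/beta; the identity overlap of the orthonormal Hueckel basis is
    left implicit. Coefficient signs are fixed (first nonzero positive) so
    outputs are deterministic.
    """
    n = spec.n
    h = spec.alpha * np.eye(n)
    idx = np.arange(n - 1)
    h[idx, idx + 1] = spec.beta
    h[idx + 1, idx] = spec.beta
    energies, vecs = np.linalg.eigh(h)
    for k in range(n):
        col = vecs[:, k]
        first = col[np.flatnonzero(np.abs(col) > 1e-12)[0]]
        if first < 0:
            vecs[:, k] = -col
    occupations = np.zeros(n)
    occupations[: spec.electrons // 2] = 2.0
    return OrbitalData(
        mo_coefficients=vecs,
        mo_energies=energies,
        occupations=occupations,
        basis_to_atom=(
            np.arange(n) if basis_to_atom is None else np.asarray(basis_to_atom, int)
        ),
    )


_POSE_ORIENTATION = {"A": "up", "B": "up", "C": "down", "D": "down"}


def _derive_seed(base_seed: int, *spawn_key: int) -> int:
    state = np.random.SeedSequence(base_seed, spawn_key=spawn_key).generate_state(1)
    return int(state[0] % (2**31))


def _perturb_homo(
    orbitals: OrbitalData, epsilon: float
) -> OrbitalData:
    """Shift HOMO amplitude toward the chain termini by ``epsilon``.

    The perturbation direction grows the terminal coefficients and shrinks
    the inner ones (keeping the norm stationary to first order); the result
    is renormalized exactly.
    """
    from .cdft import frontier_indices

    homo, _ = frontier_indices(orbitals)
    c = orbitals.mo_coefficients.copy()
    col = c[:, homo]
    n = len(col)
    direction = np.zeros(n)
    direction[0] = np.sign(col[0]) if col[0] else 1.0
    direction[-1] = np.sign(col[-1]) if col[-1] else 1.0
    # shrink the interior in proportion, golden-ratio weighting for n=4
    inner_scale = abs(col[0]) / max(abs(col[1]), 1e-12)
    for j in range(1, n - 1):
        direction[j] = -np.sign(col[j]) * inner_scale if col[j] else 0.0
    new = col + epsilon * direction
    new = new / np.linalg.norm(new)
    c[:, homo] = new
    return OrbitalData(
        mo_coefficients=c,
        mo_energies=orbitals.mo_energies.copy(),
        occupations=orbitals.occupations.copy(),
        basis_to_atom=orbitals.basis_to_atom.copy(),
        overlap=None if orbitals.overlap is None else orbitals.overlap.copy(),
    )


def generate_pose_ensembles(
    base: CageSpec,
    poses: tuple[str, ...] = ("A", "B", "C", "D"),
    orbital_gain: float = DEFAULT_ORBITAL_GAIN,
    orbital_jitter: float = DEFAULT_ORBITAL_JITTER,
) -> dict[str, PoseEnsemble]:
    """Generate the four-pose study design.

    Poses "A"/"B" are up-oriented replicas with distinct noise seeds,
    "C"/"D" down-oriented. Each frame's Hueckel-butadiene HOMO (mapped onto
    the diene atoms C10..C13) is perturbed toward the terminal atoms by
    ``orbital_gain * projected_field + jitter``, so up poses carry a larger
    condensed f- on C10/C13 by construction; ``orbital_gain=0`` with a
    zero-charge cage gives statistically indistinguishable poses (the null).
    """
    if len(poses) < 2:
        raise ConfigurationError("need at least 2 poses")
    unknown = [p for p in poses if p not in _POSE_ORIENTATION]
    if unknown:
        raise ConfigurationError(
            f"unknown pose labels {unknown}; known: {sorted(_POSE_ORIENTATION)}"
        )
    out: dict[str, PoseEnsemble] = {}
    for k, pose in enumerate(poses):
        spec = replace(
            base,
            substrate_pose=_POSE_ORIENTATION[pose],
            seed=_derive_seed(base.seed, k, 0),
        )
        topology, frames, substrate, probes = generate_cage(spec)
        diene_probe = probes[0]
        series = electrostatics.probe_projection_series(
            topology, frames, diene_probe, substrate, pose_label=pose
        )
        huckel = generate_huckel_orbitals(
            HuckelSpec(n=4),
            basis_to_atom=np.array(
                [topology.index_of(nm) for nm in ("C10", "C11", "C12", "C13")]
            ),
        )
        rng = np.random.default_rng(
            np.random.SeedSequence(base.seed, spawn_key=(k, 1))
        )
        jitter = rng.normal(0.0, orbital_jitter, size=frames.n_frames)
        orbitals = [
            _perturb_homo(huckel, orbital_gain * proj + eps)
            for proj, eps in zip(series.projections, jitter)
        ]
        out[pose] = PoseEnsemble(
            pose_label=pose,
            topology=topology,
            frames=frames,
            substrate=substrate,
            probes=probes,
            orbitals=orbitals,
            diene_atoms={
                nm: topology.index_of(nm) for nm in ("C10", "C13", "C14", "C15")
            },
        )
    return out
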