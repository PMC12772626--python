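"""Atom-condensed Fukui functions, frontier gaps and ensemble averaging.

Local reactivity is quantified with atom-condensed Fukui functions in the
frontier-molecular-orbital approximation: the nucleophilic function f- is the
HOMO density condensed onto atoms, the electrophilic function f+ the LUMO
density. Condensation is Mulliken-style on the supplied MO vector c and
overlap S,

    f(A) = sum_{mu in A} sum_nu c_mu c_nu S_mu_nu,

which for an orthonormal basis (identity overlap) reduces to summing squared
coefficients per atom; each condensed function carries one frontier electron
and therefore sums to 1 over atoms. A finite-difference route from atomic
charge tables of the N and N+-1 electron systems is provided for ingesting
charges computed elsewhere (e.g. Hirshfeld-I tables).

Per-frame descriptors are combined into ensemble values either with uniform
weights (molecular-dynamics frames sampled at temperature are already
Boltzmann-distributed) or with explicit Boltzmann weights from per-frame
energies, w_i = exp(-(E_i - E_min)/kT)/Z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .constants import HARTREE_TO_EV, KB_KCAL_MOL_K
from .exceptions import ConfigurationError, FrontierUndefinedError
from .model_io import OCCUPATION_THRESHOLD, ChargeTable, OrbitalData, Selection

__all__ = [
    "CondensedFukui",
    "DescriptorSeries",
    "EnsembleDescriptor",
    "frontier_indices",
    "condense_fukui",
    "fukui_fd_from_charges",
    "homo_lumo_gap",
    "charge_shift",
    "boltzmann_weights",
    "ensemble_average",
]


@dataclass
class CondensedFukui:
    """Condensed frontier density per atom for one frame.

    ``kind`` is ``"f-"`` (nucleophilic, HOMO) or ``"f+"`` (electrophilic,
    LUMO). ``has_negative`` flags (slightly) negative condensed values,
    possible only under non-identity overlap.
    """

    kind: str
    values: dict[int, float]
    frame_index: int = 0
    has_negative: bool = False

    def __getitem__(self, atom_index: int) -> float:
        return self.values[atom_index]

    def total(self) -> float:
        return float(sum(self.values.values()))


@dataclass
class DescriptorSeries:
    """Per-frame scalar descriptor with ensemble weights summing to 1."""

    name: str
    values: np.ndarray
    weights: np.ndarray | None = None
    pose_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ConfigurationError("descriptor values must be a non-empty 1-D array")
        if self.weights is None:
            self.weights = np.full(self.values.size, 1.0 / self.values.size)
        else:
            self.weights = np.asarray(self.weights, float)
            if self.weights.shape != self.values.shape:
                raise ConfigurationError("weights/values length mismatch")
            if (self.weights < 0).any():
                raise ConfigurationError("weights must be non-negative")
            if abs(self.weights.sum() - 1.0) > 1e-12:
                raise ConfigurationError("weights must sum to 1 within 1e-12")

    @property
    def n_frames(self) -> int:
        return self.values.size


@dataclass
class EnsembleDescriptor:
    """Weighted ensemble mean of a descriptor with its standard error."""

    name: str
    pose_label: str
    mean: float
    sem: float  # NaN when undefined (single frame / degenerate weights)
    n_frames: int


def frontier_indices(orbitals: OrbitalData) -> tuple[int, int]:
    """Indices (0-based) of the HOMO and LUMO.

    HOMO is the highest-energy occupied MO (occupation > 1e-6 electrons),
    LUMO the lowest-energy virtual MO; energy ties are broken by the larger
    index for the HOMO and the smaller for the LUMO.
    """
    occ = orbitals.occupations > OCCUPATION_THRESHOLD
    if not occ.any() or occ.all():
        raise FrontierUndefinedError(
            "need at least one occupied and one virtual orbital"
        )
    e = orbitals.mo_energies
    occ_idx = np.flatnonzero(occ)
    vir_idx = np.flatnonzero(~occ)
    # stable argmax/argmin with the spec'd tie-breaks
    homo = int(occ_idx[np.max(np.flatnonzero(e[occ_idx] == e[occ_idx].max()))])
    lumo = int(vir_idx[np.min(np.flatnonzero(e[vir_idx] == e[vir_idx].min()))])
    return homo, lumo


def condense_fukui(
    orbitals: OrbitalData, kind: str, frame_index: int = 0
) -> CondensedFukui:
    """Condense the frontier-orbital density onto atoms (Mulliken-style).

    Uses the HOMO column for ``kind="f-"`` and the LUMO column for
    ``kind="f+"``. The condensed values sum to the norm c^T S c of the MO;
    deviations from 1 up to 1e-3 are renormalized away, larger deviations
    indicate a non-normalized orbital and raise.
    """
    if kind not in ("f-", "f+"):
        raise ConfigurationError(f"kind must be 'f-' or 'f+', got {kind!r}")
    homo, lumo = frontier_indices(orbitals)
    c = orbitals.mo_coefficients[:, homo if kind == "f-" else lumo]
    s = orbitals.overlap_or_identity()
    per_basis = c * (s @ c)  # Mulliken population of each basis function
    total = float(per_basis.sum())
    if abs(total - 1.0) > 1e-3:
        raise ConfigurationError(
            f"frontier MO norm {total:.6f} deviates from 1 by more than 1e-3; "
            "coefficients are not normalized for this overlap"
        )
    if abs(total - 1.0) > 1e-8:
        per_basis = per_basis / total
    per_atom: dict[int, float] = {}
    for a in np.unique(orbitals.basis_to_atom):
        per_atom[int(a)] = float(per_basis[orbitals.basis_to_atom == a].sum())
    return CondensedFukui(
        kind=kind,
        values=per_atom,
        frame_index=frame_index,
        has_negative=bool(min(per_atom.values()) < 0),
    )


def fukui_fd_from_charges(
    q_n: ChargeTable, q_other: ChargeTable, kind: str
) -> CondensedFukui:
    """Finite-difference condensed Fukui values from atomic charge tables.

    ``f-(A) = q_A(N-1) - q_A(N)`` with ``q_other`` the (N-1)-electron table;
    ``f+(A) = q_A(N) - q_A(N+1)`` with ``q_other`` the (N+1)-electron table.
    The sum over atoms should be 1; a deviation beyond 1e-3 warns (supplied
    charge tables are often imperfectly normalized) but does not fail.
    """
    if kind not in ("f-", "f+"):
        raise ConfigurationError(f"kind must be 'f-' or 'f+', got {kind!r}")
    if q_n.atom_set() != q_other.atom_set():
        raise ConfigurationError(
            "charge tables cover different atom sets: "
            f"{sorted(q_n.atom_set() ^ q_other.atom_set())} not shared"
        )
    sign = 1.0 if kind == "f-" else -1.0
    values = {
        a: sign * (q_other[a] - q_n[a]) for a in sorted(q_n.atom_set())
    }
    total = sum(values.values())
    if abs(total - 1.0) > 1e-3:
        warnings.warn(
            f"finite-difference {kind} sums to {total:.4f}, not 1 "
            "(charge tables may be unnormalized)",
            stacklevel=2,
        )
    return CondensedFukui(
        kind=kind, values=values, has_negative=bool(min(values.values()) < 0)
    )


def homo_lumo_gap(orbitals: OrbitalData, units: str = "hartree") -> float:
    """Frontier gap e_LUMO - e_HOMO (may be negative; reported as-is)."""
    homo, lumo = frontier_indices(orbitals)
    gap = float(orbitals.mo_energies[lumo] - orbitals.mo_energies[homo])
    if units == "hartree":
        return gap
    if units == "eV":
        return gap * HARTREE_TO_EV
    raise ConfigurationError(f"unknown units {units!r} (hartree or eV)")


def charge_shift(
    q_env: ChargeTable, q_ref: ChargeTable, atoms: Selection
) -> dict[int, float]:
    """Per-atom charge change dq(A) = q_env(A) - q_ref(A) over a selection.

    Negative dq means the atom became more electron-rich in the environment.
    """
    missing = [
        a for a in atoms.atom_indices
        if a not in q_env.values or a not in q_ref.values
    ]
    if missing:
        raise ConfigurationError(f"atoms {missing} missing from a charge table")
    return {a: q_env[a] - q_ref[a] for a in atoms.atom_indices}


def boltzmann_weights(
    energies: np.ndarray, temperature: float = 300.0
) -> np.ndarray:
    """Normalized Boltzmann weights exp(-(E_i - E_min)/kT)/Z.

    Energies in kcal/mol; the minimum-energy shift makes the exponentials
    numerically safe at any temperature > 0.
    """
    energies = np.asarray(energies, float)
    if energies.size == 0:
        raise ConfigurationError("no energies supplied")
    if not np.isfinite(energies).all():
        raise ConfigurationError("energies must be finite")
    if temperature <= 0:
        raise ConfigurationError("temperature must be > 0 K")
    beta = 1.0 / (KB_KCAL_MOL_K * temperature)
    return softmax(-beta * (energies - energies.min()))


def ensemble_average(series: DescriptorSeries) -> EnsembleDescriptor:
    """Weighted ensemble mean and standard error of a descriptor series.

    mean = sum w_i x_i. The SEM uses the effective-sample-size convention
    n_eff = 1/sum w_i^2:

        SEM = sqrt( sum w_i (x_i - mean)^2 / (n_eff - 1) ),

    which reduces exactly to s/sqrt(n) (sample sd, n-1 denominator) for
    uniform weights. SEM is NaN when n_eff <= 1 (single frame or fully
    degenerate weights).
    """
    w = series.weights
    x = series.values
    mean = float(w @ x)
    n_eff = 1.0 / float(w @ w)
    if n_eff > 1.0 + 1e-12:
        sem = float(np.sqrt(w @ (x - mean) ** 2 / (n_eff - 1.0)))
    else:
        sem = float("nan")
    return EnsembleDescriptor(
        name=series.name,
        pose_label=series.pose_label,
        mean=mean,
        sem=sem,
        n_frames=series.n_frames,
    )
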