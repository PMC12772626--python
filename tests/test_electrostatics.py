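"""Coulomb sums, projections and residue decomposition.

Oracles: an independently coded double loop for the sums, central finite
differences of the potential for the field, and direct per-frame calls for
the ensemble reduction.
"""

import numpy as np
import pytest
from scipy import constants as spc

from enzfield import (
    COULOMB_K,
    ConfigurationError,
    DegenerateGeometryError,
    FrameSet,
    ProbeVector,
    Selection,
    SingularityError,
    bond_forming_distances,
    convert_field_units,
    ensemble_field_at_atoms,
    field_at_point,
    potential_at_point,
    probe_projection_series,
    project_on_vector,
    rank_residue_contributions,
    residue_decomposition,
)
from enzfield.constants import KCAL_MOL_E_A_TO_MV_CM


def potential_oracle(charges, positions, point):
    """Plain double-loop Coulomb sum, independent of the vectorized path."""
    v = 0.0
    for q, r in zip(charges, positions):
        d = 0.0
        for k in range(3):
            d += (point[k] - r[k]) ** 2
        v += q / d**0.5
    return COULOMB_K * v


def field_fd_oracle(charges, positions, point, h=1e-4):
    """-grad V by central differences on the potential."""
    e = np.zeros(3)
    for k in range(3):
        dp = np.array(point, float)
        dm = dp.copy()
        dp[k] += h
        dm[k] -= h
        e[k] = -(
            potential_at_point(charges, positions, dp)
            - potential_at_point(charges, positions, dm)
        ) / (2 * h)
    return e


class TestPointSums:
    def test_unit_charge_closed_forms(self):
        assert potential_at_point([1.0], [[0, 0, 0]], [1, 0, 0]) == pytest.approx(
            332.0637, abs=1e-10
        )
        np.testing.assert_allclose(
            field_at_point([1.0], [[0, 0, 0]], [1, 0, 0]),
            [332.0637, 0.0, 0.0],
            atol=1e-10,
        )

    def test_opposite_equidistant_charges_cancel_potential(self):
        v = potential_at_point(
            [1.0, -1.0], [[1, 0, 0], [-1, 0, 0]], [0, 1, 0]
        )
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_charges_cancel_field(self):
        e = field_at_point([1.0, 1.0], [[1, 0, 0], [-1, 0, 0]], [0, 0, 0])
        np.testing.assert_allclose(e, 0.0, atol=1e-12)

    def test_matches_double_loop_oracle(self, random_system):
        charges, positions, point = random_system
        assert potential_at_point(charges, positions, point) == pytest.approx(
            potential_oracle(charges, positions, point), abs=1e-10
        )

    def test_field_is_negative_gradient(self, rng):
        for _ in range(100):
            n = rng.integers(5, 25)
            charges = rng.uniform(-1, 1, n)
            positions = rng.uniform(-5, 5, (n, 3))
            point = rng.uniform(6, 9, 3)
            e = field_at_point(charges, positions, point)
            fd = field_fd_oracle(charges, positions, point)
            np.testing.assert_allclose(e, fd, rtol=1e-4, atol=1e-8)

    def test_coincident_atom_raises(self):
        with pytest.raises(SingularityError, match="atom 1"):
            potential_at_point([1.0, 1.0], [[1, 0, 0], [0, 0, 0]], [0, 0, 0])


class TestEnsembleReduction:
    def test_single_case_matches_point_call(self, toy_topology):
        frames = FrameSet(np.array([[[0, 0, 0], [3, 0, 0], [0, 4, 0]]], float))
        sub = Selection("sub", (0,))
        records = ensemble_field_at_atoms(toy_topology, frames, sub)
        assert len(records) == 1
        expected = field_at_point(
            toy_topology.charges[1:], frames.coordinates[0, 1:], [0, 0, 0]
        )
        np.testing.assert_allclose(records[0].field, expected, atol=1e-12)
        assert records[0].potential == pytest.approx(
            potential_at_point(
                toy_topology.charges[1:], frames.coordinates[0, 1:], [0, 0, 0]
            )
        )

    def test_zero_charge_environment_gives_zero(self, cage_up):
        topology, frames, substrate, _ = cage_up
        import enzfield

        zero = enzfield.Topology(
            [
                enzfield.ChargedAtom(
                    a.atom_index, a.atom_name, a.residue_name, a.residue_id,
                    a.chain_id, 0.0,
                )
                for a in topology.atoms
            ]
        )
        for r in ensemble_field_at_atoms(zero, frames, substrate):
            assert r.potential == 0.0
            assert (r.field == 0.0).all()

    def test_per_frame_records_match_direct_calls(self, cage_up):
        topology, frames, substrate, _ = cage_up
        sub3 = FrameSet(frames.coordinates[:3])
        records = ensemble_field_at_atoms(topology, sub3, substrate)
        env = np.array(
            [i for i in range(topology.n_atoms) if i not in substrate.atom_indices]
        )
        for r in records:
            point = sub3.coordinates[r.frame_index, r.atom_index]
            np.testing.assert_allclose(
                r.field,
                field_at_point(
                    topology.charges[env], sub3.coordinates[r.frame_index, env], point
                ),
                atol=1e-10,
            )

    def test_overlapping_selections_rejected(self, toy_topology):
        frames = FrameSet(np.zeros((1, 3, 3)))
        with pytest.raises(ConfigurationError, match="overlap"):
            ensemble_field_at_atoms(
                toy_topology, frames, Selection("s", (0, 1)), Selection("e", (1, 2))
            )

    def test_linearity_in_charges(self, cage_up):
        topology, frames, substrate, probes = cage_up
        import enzfield

        doubled = enzfield.Topology(
            [
                enzfield.ChargedAtom(
                    a.atom_index, a.atom_name, a.residue_name, a.residue_id,
                    a.chain_id, 2.0 * a.charge,
                )
                for a in topology.atoms
            ]
        )
        s1 = probe_projection_series(topology, frames, probes[0], substrate)
        s2 = probe_projection_series(doubled, frames, probes[0], substrate)
        np.testing.assert_allclose(s2.projections, 2.0 * s1.projections, rtol=1e-12)


class TestProjection:
    def test_axis_component(self):
        coords = np.array([[0, 0, 0], [1, 0, 0]], float)
        probe = ProbeVector("x", 0, 1)
        proj, cos = project_on_vector([1.0, 2.0, 3.0], probe, coords)
        assert proj == pytest.approx(1.0)

    def test_parallel_and_orthogonal(self):
        coords = np.array([[0, 0, 0], [0, 0, 2]], float)
        probe = ProbeVector("z", 0, 1)
        proj, cos = project_on_vector([0, 0, 5.0], probe, coords)
        assert proj == pytest.approx(5.0)
        assert cos == pytest.approx(1.0)
        proj, cos = project_on_vector([3.0, 0, 0], probe, coords)
        assert proj == pytest.approx(0.0)
        assert cos == pytest.approx(0.0)

    def test_tiny_field_flags_cosine_undefined(self):
        coords = np.array([[0, 0, 0], [0, 0, 2]], float)
        proj, cos = project_on_vector([0, 0, 1e-13], ProbeVector("z", 0, 1), coords)
        assert np.isnan(cos)

    def test_zero_length_probe_raises(self):
        coords = np.zeros((2, 3))
        with pytest.raises(DegenerateGeometryError):
            project_on_vector([1, 0, 0], ProbeVector("bad", 0, 1), coords)

    def test_translation_invariance(self, cage_up):
        topology, frames, substrate, probes = cage_up
        shifted = FrameSet(frames.coordinates + np.array([11.0, -7.0, 3.0]))
        a = probe_projection_series(topology, frames, probes[0], substrate)
        b = probe_projection_series(topology, shifted, probes[0], substrate)
        np.testing.assert_allclose(a.projections, b.projections, atol=1e-10)

    def test_rotation_equivariance(self, cage_up):
        # projections on co-rotated probes are invariant under rigid rotation
        from scipy.spatial.transform import Rotation

        topology, frames, substrate, probes = cage_up
        rot = Rotation.from_euler("zyx", [40, -25, 70], degrees=True).as_matrix()
        rotated = FrameSet(frames.coordinates @ rot.T)
        a = probe_projection_series(topology, frames, probes[0], substrate)
        b = probe_projection_series(topology, rotated, probes[0], substrate)
        np.testing.assert_allclose(a.projections, b.projections, atol=1e-10)
        np.testing.assert_allclose(a.cosines, b.cosines, atol=1e-10)


class TestDecomposition:
    def test_single_residue_equals_total(self, rng):
        from enzfield import ChargedAtom, Topology

        atoms = [ChargedAtom(i, f"P{i}", "GLU", 7, "", 0.3) for i in range(4)]
        topo = Topology(atoms)
        coords = rng.uniform(2, 5, (4, 3))
        dec = residue_decomposition(topo, coords, np.zeros(3), np.arange(4))
        assert list(dec) == [(7, "")]
        np.testing.assert_allclose(
            dec[(7, "")], field_at_point(topo.charges, coords, np.zeros(3)),
            atol=1e-12,
        )

    def test_mirror_residues_cancel(self):
        from enzfield import ChargedAtom, Topology

        atoms = [
            ChargedAtom(0, "P1", "GLU", 1, "", -0.5),
            ChargedAtom(1, "P1", "GLU", 2, "", 0.5),
        ]
        topo = Topology(atoms)
        coords = np.array([[0, 0, 3.0], [0, 0, -3.0]])
        dec = residue_decomposition(topo, coords, np.zeros(3), np.arange(2))
        total = dec[(1, "")] + dec[(2, "")]
        np.testing.assert_allclose(total[2], 2 * dec[(1, "")][2], atol=1e-12)
        np.testing.assert_allclose(
            np.linalg.norm(dec[(1, "")]), np.linalg.norm(dec[(2, "")]), atol=1e-12
        )

    def test_contributions_sum_to_total_on_cage(self, cage_up):
        topology, frames, substrate, _ = cage_up
        records = ensemble_field_at_atoms(
            topology, frames, substrate, decompose=True
        )
        for r in records:
            total = sum(r.residue_contributions.values())
            assert np.abs(total - r.field).max() < 1e-8 * (
                1 + np.linalg.norm(r.field)
            )

    def test_dominant_top_residue_ranks_first(self, cage_up):
        topology, frames, substrate, probes = cage_up
        ranking = rank_residue_contributions(
            topology, frames, probes[0], substrate
        )
        assert ranking.iloc[0]["residue_id"] == 19
        assert ranking.iloc[0]["residue_name"] == "GLU"
        assert ranking.iloc[0]["mean_projection"] > 0
        # sorted by |mean| descending
        mags = ranking["mean_projection"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()


class TestUnitsAndDistances:
    def test_mvcm_factor_from_codata(self):
        # re-derive independently: Faraday = N_A e; V/Angstrom -> MV/cm
        faraday = spc.N_A * spc.e
        expected = 4184.0 / faraday * 1e10 / 1e8
        assert KCAL_MOL_E_A_TO_MV_CM == pytest.approx(expected, rel=1e-12)
        assert KCAL_MOL_E_A_TO_MV_CM == pytest.approx(4.336, abs=5e-4)

    def test_round_trip_identity(self):
        x = 17.25
        back = convert_field_units(convert_field_units(x, "mvcm"), "kcalmolea")
        assert back == pytest.approx(x, rel=1e-12)

    def test_constant_bond_distance(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = 1.54
        d = bond_forming_distances(FrameSet(coords), [ProbeVector("b", 0, 1)])
        np.testing.assert_allclose(d["b"], 1.54)

    def test_distances_match_loop_oracle(self, rng):
        coords = rng.uniform(-5, 5, (10, 4, 3))
        frames = FrameSet(coords)
        pairs = [ProbeVector("p1", 0, 3), ProbeVector("p2", 1, 2)]
        result = bond_forming_distances(frames, pairs)
        for p in pairs:
            for f in range(10):
                expected = sum(
                    (coords[f, p.target_atom, k] - coords[f, p.origin_atom, k]) ** 2
                    for k in range(3)
                ) ** 0.5
                assert result[p.name][f] == pytest.approx(expected, abs=1e-12)
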