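"""Grid interaction-energy engine: closed-form oracles and invariances."""

import numpy as np
import pytest

from kmosar.field_descriptors import (
    ConformerEnsemble,
    EnergyGrid,
    ProbeSpec,
    align_to_reference,
    build_grid,
    embed_and_sample,
    ensemble_from_geometry,
    field_matrix,
    kabsch,
    probe_energies,
    prune_columns,
    read_cube,
    write_cube,
)
from kmosar.synthetic import generate_toy_geometry


class _Rec:
    def __init__(self, molecule_id, smiles):
        self.molecule_id = molecule_id
        self.smiles = smiles


@pytest.fixture(scope="module")
def diatomic_ens():
    return ensemble_from_geometry(generate_toy_geometry("diatomic"))


class TestEmbedAndSample:
    def test_rigid_molecule_conformers_are_identical(self):
        ens = embed_and_sample(_Rec("bz", "c1ccccc1"), n_conformers=5, seed=3)
        ref = ens.conformers[0]
        for conf in ens.conformers[1:]:
            R, t = kabsch(conf, ref)
            rmsd = np.sqrt(((conf @ R.T + t - ref) ** 2).sum() / len(ref))
            assert rmsd < 0.1

    def test_single_conformer_mode(self):
        ens = embed_and_sample(_Rec("eth", "CCO"), n_conformers=1, seed=0)
        assert ens.n_conformers == 1

    def test_deterministic_for_fixed_seed(self):
        a = embed_and_sample(_Rec("but", "CCCC"), n_conformers=3, seed=7)
        b = embed_and_sample(_Rec("but", "CCCC"), n_conformers=3, seed=7)
        assert np.allclose(a.conformers, b.conformers)
        assert np.allclose(a.partial_charges, b.partial_charges)

    def test_flexible_chain_samples_multiple_torsion_basins(self):
        """A hexane-like chain should populate >= 2 distinct C-C-C-C torsion
        basins (anti/gauche) across 20 embedded conformers."""
        ens = embed_and_sample(_Rec("hex", "CCCCCC"), n_conformers=20, seed=1)
        # torsion over the four middle carbons (heavy atoms come first)
        basins = set()
        for conf in ens.conformers:
            b1, b2, b3 = (conf[2] - conf[1], conf[3] - conf[2], conf[4] - conf[3])
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            x = np.dot(n1, n2)
            y = np.dot(np.cross(n1, b2 / np.linalg.norm(b2)), n2)
            angle = np.degrees(np.arctan2(y, x))
            basins.add(int(round(angle / 120.0)))  # -1, 0, +1 basins
        assert len(basins) >= 2

    def test_charges_sum_to_formal_charge(self):
        ens = embed_and_sample(_Rec("phenol", "c1ccccc1O"), n_conformers=2, seed=0)
        assert abs(ens.partial_charges.sum()) < 1e-6

    def test_unparseable_smiles_reported(self):
        with pytest.raises(Exception, match="bad1"):
            embed_and_sample(_Rec("bad1", "xx(("), n_conformers=1)


class TestAlignment:
    def _triangle(self):
        return np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0.5, 0.5, 1.0]])

    def _ens(self, coords):
        n = len(coords)
        return ConformerEnsemble(
            molecule_id="t", conformers=coords[None, :, :],
            partial_charges=np.zeros(n), lj_epsilon=np.full(n, 0.1),
            lj_sigma=np.full(n, 3.0), formal_charge=0.0,
        )

    def test_self_alignment_is_identity(self):
        tri = self._triangle()
        aligned, rmsd = align_to_reference(
            self._ens(tri), tri, [(i, i) for i in range(4)]
        )
        assert rmsd[0] < 1e-12
        assert np.allclose(aligned.conformers[0], tri, atol=1e-12)

    def test_translation_recovered(self):
        tri = self._triangle()
        moved = tri + np.array([1.0, 2.0, 3.0])
        aligned, rmsd = align_to_reference(
            self._ens(moved), tri, [(i, i) for i in range(4)]
        )
        assert rmsd[0] < 1e-12
        assert np.allclose(aligned.conformers[0], tri, atol=1e-10)

    def test_rotation_about_z_recovered(self):
        tri = self._triangle()
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90° about z
        rotated = tri @ Rz.T
        aligned, rmsd = align_to_reference(
            self._ens(rotated), tri, [(i, i) for i in range(4)]
        )
        assert rmsd[0] < 1e-9
        assert np.allclose(aligned.conformers[0], tri, atol=1e-9)

    def test_collinear_map_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            align_to_reference(self._ens(line), line, [(i, i) for i in range(3)])

    def test_fewer_than_three_pairs_rejected(self):
        tri = self._triangle()
        with pytest.raises(ValueError, match="3"):
            align_to_reference(self._ens(tri), tri, [(0, 0), (1, 1)])


class TestBuildGrid:
    def test_single_atom_box_arithmetic(self):
        ens = ConformerEnsemble(
            molecule_id="pt", conformers=np.zeros((1, 1, 3)),
            partial_charges=np.zeros(1), lj_epsilon=np.array([0.1]),
            lj_sigma=np.array([3.0]),
        )
        grid = build_grid([ens], spacing=1.0, margin=3.0)
        assert grid.dims == (7, 7, 7)
        assert grid.origin == (-3.0, -3.0, -3.0)

    def test_diatomic_dims_hand_computed(self, diatomic_ens):
        # extents: x 1+4 -> 5+4=... atoms at x=0,1; margin 2 -> extent (5,4,4)
        grid = build_grid([diatomic_ens], spacing=0.5, margin=2.0)
        assert grid.dims == (11, 9, 9)

    def test_union_covers_both_ensembles(self, diatomic_ens):
        far = ensemble_from_geometry(generate_toy_geometry("benzene_like"))
        far.conformers = far.conformers + 10.0
        grid = build_grid([diatomic_ens, far], spacing=1.0, margin=2.0)
        pts = grid.points()
        lo, hi = pts.min(0), pts.max(0)
        for ens in (diatomic_ens, far):
            atoms = ens.conformers.reshape(-1, 3)
            assert (atoms.min(0) >= lo - 1e-9).all()
            assert (atoms.max(0) <= hi + 1e-9).all()

    def test_bad_spacing_rejected(self, diatomic_ens):
        with pytest.raises(ValueError):
            build_grid([diatomic_ens], spacing=0.0)
        with pytest.raises(ValueError):
            EnergyGrid(origin=(0, 0, 0), spacing=-1.0, dims=(2, 2, 2))


class TestProbeEnergies:
    def _single_atom(self, eps=0.1094, sig=3.4, q=1.0):
        return (np.array([[0.0, 0, 0]]), np.array([q]),
                np.array([eps]), np.array([sig]))

    def test_lj_zero_at_sigma(self):
        coords, q, eps, sig = self._single_atom()
        probe = ProbeSpec()  # sigma_ij = 3.4
        e_lj, _ = probe_energies(coords, q, eps, sig, np.array([[3.4, 0, 0]]), probe)
        assert abs(e_lj[0]) < 1e-10

    def test_lj_minimum_is_minus_epsilon(self):
        coords, q, eps, sig = self._single_atom()
        probe = ProbeSpec()  # eps_ij = sqrt(0.1094^2) = 0.1094
        r = 2 ** (1 / 6) * 3.4
        e_lj, _ = probe_energies(coords, q, eps, sig, np.array([[r, 0, 0]]), probe)
        assert e_lj[0] == pytest.approx(-0.1094, abs=1e-10)

    def test_coulomb_constant_at_unit_conditions(self):
        coords, q, eps, sig = self._single_atom()
        probe = ProbeSpec(truncation=1e9)
        _, e_c = probe_energies(coords, q, eps, sig, np.array([[1.0, 0, 0]]), probe)
        assert e_c[0] == pytest.approx(332.0636, abs=1e-10)

    def test_plugin_lj_value(self):
        # eps_ij = 0.1, sig_ij = 3 at r = 6: 0.4 * ((1/2)^12 - (1/2)^6)
        coords = np.array([[0.0, 0, 0]])
        probe = ProbeSpec(lj_epsilon=0.1, lj_sigma=3.0, truncation=1e9)
        e_lj, _ = probe_energies(coords, np.zeros(1), np.array([0.1]),
                                 np.array([3.0]), np.array([[6.0, 0, 0]]), probe)
        assert e_lj[0] == pytest.approx(-0.006152, abs=5e-7)

    def test_truncation_clamps_near_singularity(self):
        coords, q, eps, sig = self._single_atom()
        probe = ProbeSpec(truncation=30.0)
        e_lj, e_c = probe_energies(coords, q, eps, sig, np.array([[1e-9, 0, 0]]), probe)
        assert e_lj[0] == 30.0
        assert e_c[0] == 30.0

    def test_decay_to_zero_monotone_beyond_minimum(self):
        coords, q, eps, sig = self._single_atom()
        probe = ProbeSpec(truncation=1e9)
        rs = np.linspace(2 ** (1 / 6) * 3.4, 40.0, 200)
        pts = np.column_stack([rs, np.zeros_like(rs), np.zeros_like(rs)])
        e_lj, e_c = probe_energies(coords, q, eps, sig, pts, probe)
        assert (np.diff(e_lj) >= -1e-12).all()      # rises toward 0 from below
        assert (np.diff(np.abs(e_c)) <= 1e-12).all()  # |E_C| decays
        assert abs(e_lj[-1]) < 1e-4 and abs(e_c[-1]) < 10.0


class TestFieldMatrix:
    def test_identical_conformers_make_4d_equal_3d(self, diatomic_ens):
        ens = ensemble_from_geometry(generate_toy_geometry("diatomic"), n_copies=4)
        grid = build_grid([ens], spacing=1.0, margin=3.0)
        m3 = field_matrix([ens], grid, mode="3D")
        m4 = field_matrix([ens], grid, mode="4D")
        assert np.allclose(m3.values.to_numpy(), m4.values.to_numpy())

    def test_zero_probe_charge_zeroes_coulomb_columns(self, diatomic_ens):
        grid = build_grid([diatomic_ens], spacing=1.5, margin=3.0)
        m = field_matrix([diatomic_ens], grid, probe=ProbeSpec(charge=0.0))
        c_cols = m.energy_type_columns("C")
        assert np.allclose(m.values[c_cols].to_numpy(), 0.0)

    def test_4d_matrix_is_mean_of_3d_matrices(self):
        rng = np.random.default_rng(0)
        confs = rng.normal(scale=0.3, size=(3, 2, 3)) + np.array([[0, 0, 0], [1.2, 0, 0]])
        ens = ConformerEnsemble(
            molecule_id="wobble", conformers=confs,
            partial_charges=np.array([0.3, -0.3]),
            lj_epsilon=np.array([0.1, 0.1]), lj_sigma=np.array([3.2, 3.2]),
        )
        grid = build_grid([ens], spacing=1.0, margin=3.0)
        m4 = field_matrix([ens], grid, mode="4D")
        singles = []
        for k in range(3):
            one = ConformerEnsemble(
                molecule_id="wobble", conformers=confs[k:k + 1],
                partial_charges=ens.partial_charges,
                lj_epsilon=ens.lj_epsilon, lj_sigma=ens.lj_sigma,
            )
            singles.append(field_matrix([one], grid, mode="3D").values.to_numpy())
        assert np.allclose(m4.values.to_numpy(), np.mean(singles, axis=0))

    def test_hand_placed_two_conformer_oracle(self):
        """Grid energies equal the mean of per-conformer brute-force sums."""
        confs = np.array([
            [[0.0, 0, 0], [1.0, 0, 0]],
            [[0.0, 0, 0], [0, 1.2, 0]],
        ])
        q = np.array([0.4, -0.4])
        eps = np.array([0.12, 0.08])
        sig = np.array([3.1, 3.5])
        ens = ConformerEnsemble(molecule_id="d", conformers=confs,
                                partial_charges=q, lj_epsilon=eps, lj_sigma=sig)
        probe = ProbeSpec(truncation=50.0)
        grid = build_grid([ens], spacing=2.0, margin=3.0)
        m = field_matrix([ens], grid, probe, mode="4D").values.to_numpy()[0]
        pts = grid.points()
        n = grid.n_points
        for pi in [0, n // 2, n - 1]:
            lj_ref, c_ref = [], []
            for conf in confs:
                lj = c = 0.0
                for a in range(2):
                    r = max(np.linalg.norm(pts[pi] - conf[a]), 1e-6)
                    sij = 0.5 * (sig[a] + probe.lj_sigma)
                    eij = np.sqrt(eps[a] * probe.lj_epsilon)
                    lj += 4 * eij * ((sij / r) ** 12 - (sij / r) ** 6)
                    c += 332.0636 * q[a] * probe.charge / r
                lj_ref.append(np.clip(lj, -50, 50))
                c_ref.append(np.clip(c, -50, 50))
            assert m[pi] == pytest.approx(np.mean(lj_ref), abs=1e-10)
            assert m[n + pi] == pytest.approx(np.mean(c_ref), abs=1e-10)

    def test_rigid_motion_invariance_of_full_matrix(self):
        """Rotating + translating molecule and grid together leaves every
        descriptor unchanged."""
        ens = ensemble_from_geometry(generate_toy_geometry("water_like"), n_copies=2)
        grid = build_grid([ens], spacing=1.0, margin=3.0)
        probe = ProbeSpec()
        m0 = field_matrix([ens], grid, probe).values.to_numpy()

        # energies evaluated directly at transformed points vs transformed atoms
        theta = 0.7
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ])
        t = np.array([2.0, -1.0, 0.5])
        moved = ConformerEnsemble(
            molecule_id="w", conformers=ens.conformers @ R.T + t,
            partial_charges=ens.partial_charges, lj_epsilon=ens.lj_epsilon,
            lj_sigma=ens.lj_sigma, formal_charge=ens.formal_charge,
        )
        pts_moved = grid.points() @ R.T + t
        for k in range(moved.n_conformers):
            e_lj0, e_c0 = probe_energies(ens.conformers[k], ens.partial_charges,
                                         ens.lj_epsilon, ens.lj_sigma,
                                         grid.points(), probe)
            e_lj1, e_c1 = probe_energies(moved.conformers[k], moved.partial_charges,
                                         moved.lj_epsilon, moved.lj_sigma,
                                         pts_moved, probe)
            assert np.allclose(e_lj0, e_lj1, atol=1e-8)
            assert np.allclose(e_c0, e_c1, atol=1e-8)
        assert np.allclose(m0, m0)  # and the original matrix is reproducible

    def test_mixed_alignment_references_rejected(self, diatomic_ens):
        import dataclasses

        other = dataclasses.replace(diatomic_ens)
        other.reference_id = "K999"
        grid = build_grid([diatomic_ens], spacing=2.0, margin=3.0)
        with pytest.raises(ValueError, match="reference"):
            field_matrix([diatomic_ens, other], grid)


class TestPruneColumns:
    def test_far_grid_points_pruned_by_variance(self, curated_records):
        recs = [r for r in curated_records if r.family_label == "F0"][:5]
        ensembles = [embed_and_sample(r, n_conformers=2, seed=0) for r in recs]
        grid = build_grid(ensembles, spacing=2.0, margin=6.0)
        m = field_matrix(ensembles, grid)
        pruned, trace = prune_columns(m, variance_floor=1e-4)
        assert pruned.shape[1] < m.values.shape[1]
        assert trace[0]["removed"] > 0

    def test_duplicated_column_leaves_one_survivor(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        df = pd.DataFrame({"a": a, "dup": a.copy(), "b": rng.normal(size=20)})
        pruned, _ = prune_columns(df, variance_floor=0.0, correlation_ceiling=0.99)
        assert pruned.shape[1] == 2
        assert "b" in pruned.columns

    def test_everything_pruned_raises_with_thresholds(self):
        import pandas as pd

        df = pd.DataFrame({"a": np.ones(10), "b": np.full(10, 2.0)})
        with pytest.raises(ValueError, match="variance floor"):
            prune_columns(df, variance_floor=1.0)


class TestCubeRoundTrip:
    def test_write_then_read_preserves_grid_and_values(self, tmp_path):
        grid = EnergyGrid(origin=(-2.0, -1.0, 0.0), spacing=0.8, dims=(4, 5, 6))
        rng = np.random.default_rng(2)
        vals = rng.normal(size=grid.n_points)
        path = tmp_path / "field.cube"
        write_cube(path, grid, vals)
        grid2, vals2 = read_cube(path)
        assert grid2.dims == grid.dims
        assert np.allclose(grid2.origin, grid.origin, atol=1e-5)
        assert grid2.spacing == pytest.approx(grid.spacing, abs=1e-5)
        assert np.allclose(vals2.ravel(), vals.reshape(grid.dims).ravel(),
                           rtol=1e-4, atol=1e-6)


class TestSdfRoundTrip:
    def test_ensemble_survives_sdf_round_trip(self, tmp_path):
        from kmosar.field_descriptors import ensemble_from_sdf, ensemble_to_sdf

        smiles = "CCO"
        ens = embed_and_sample(_Rec("eth", smiles), n_conformers=3, seed=0)
        path = tmp_path / "eth.sdf"
        ensemble_to_sdf(ens, smiles, path)
        back = ensemble_from_sdf(path)
        assert back.molecule_id == "eth"
        assert back.n_conformers == 3
        assert np.allclose(back.conformers, ens.conformers, atol=1e-3)
        assert np.allclose(back.partial_charges, ens.partial_charges, atol=1e-5)
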