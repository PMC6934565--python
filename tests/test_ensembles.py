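"""Structure-ensemble operators: SASA, RMSF, gyration, clustering, CVs, landscapes."""

import numpy as np
import pytest

import ubidyn as u
from ubidyn.ensembles import (
    BACKBONE_NAMES,
    kabsch_rmsd,
    landscape,
    min_distance_cvs,
    pca_embedding,
    rmsd_matrix,
    sasa_mean,
    sphere_points,
)
from ubidyn.synth import ToyEnsembleSpec, gen_toy_ensemble, isolated_domain
from ubidyn.types import AtomRecord, Ensemble


def _atoms(n, radius=1.7, chain="A", name="CA", element="C"):
    return [
        AtomRecord(name=name, element=element, radius=radius,
                   res_index=i + 1, res_name="GLY", chain=chain)
        for i in range(n)
    ]


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        ens = Ensemble(coords=np.zeros((1, 1, 3)), atoms=_atoms(1, radius=1.7))
        res = u.sasa(ens, probe=1.4, n_points=960)
        assert res.per_atom[0] == pytest.approx(4 * np.pi * 3.1**2, rel=1e-12)

    def test_distant_atoms_sum_of_spheres(self):
        coords = np.array([[[0, 0, 0], [100, 0, 0]]], dtype=float)
        ens = Ensemble(coords=coords, atoms=_atoms(2, radius=1.7))
        res = u.sasa(ens, probe=1.4)
        assert res.total == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-12)

    def test_caged_atom_has_zero_sasa(self):
        # Central atom surrounded by 26 large overlapping spheres.
        offsets = [
            np.array([i, j, k], dtype=float)
            for i in (-2.0, 0.0, 2.0) for j in (-2.0, 0.0, 2.0) for k in (-2.0, 0.0, 2.0)
            if (i, j, k) != (0.0, 0.0, 0.0)
        ]
        coords = np.array([[np.zeros(3), *offsets]])
        atoms = _atoms(27, radius=1.7)
        res = u.sasa(Ensemble(coords=coords, atoms=atoms), probe=1.4)
        assert res.per_atom[0] == 0.0

    def test_point_count_convergence(self, ub_like):
        lo = u.sasa(ub_like, n_points=960).total
        hi = u.sasa(ub_like, n_points=1920).total
        assert abs(hi - lo) / hi < 0.005

    def test_per_residue_sums_to_total(self, ub_like):
        res = u.sasa(ub_like)
        assert sum(res.per_residue.values()) == pytest.approx(res.total, rel=1e-12)

    def test_matches_independent_implementation(self, ub_like, tmp_path):
        """Cross-check against biotite's Shrake-Rupley on the packaged fixture."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb
        from ubidyn import io as uio

        path = tmp_path / "fixture.pdb"
        uio.write_ensemble(ub_like, path)
        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
        vdw = np.array([a.radius for a in ub_like.atoms])
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=vdw)
        ours = u.sasa(ub_like, probe=1.4, n_points=960)
        assert ours.total == pytest.approx(float(theirs.sum()), rel=0.01)

    def test_rotation_translation_invariance(self, ub_like, rng):
        from ubidyn.synth import _rotation_matrix

        rot = _rotation_matrix(rng.normal(size=3), 1.1)
        moved = Ensemble(
            coords=ub_like.coords @ rot.T + np.array([5.0, -3.0, 12.0]),
            atoms=ub_like.atoms,
        )
        a = u.sasa(ub_like, n_points=480).total
        b = u.sasa(moved, n_points=480).total
        assert a == pytest.approx(b, rel=2e-3)

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestDeltaSASA:
    SPEC = ToyEnsembleSpec(beads_per_domain=16, n_substates=1, frames_per_substate=2,
                           jitter_sigma=0.0, seed=4)

    def test_positive_exactly_at_contact_beads(self):
        dimer = gen_toy_ensemble(self.SPEC)
        mono = isolated_domain(self.SPEC)
        ds = u.delta_sasa(dimer, "A", mono, n_points=960)
        contacts = set(dimer.metadata["contacts"][0])
        for idx in ds.indices():
            if idx in contacts:
                assert ds.value(idx) > 1.0
            else:
                assert abs(ds.value(idx)) < 1e-9

    def test_chain_against_itself_is_zero(self):
        dimer = gen_toy_ensemble(self.SPEC)
        chain_a = dimer.subset(dimer.select(chain="A"))
        ds = u.delta_sasa(dimer.subset(dimer.select(chain="A")), "A", chain_a)
        assert all(abs(ds.value(i)) < 1e-12 for i in ds.indices())

    def test_distant_chains_zero_everywhere(self):
        dimer = gen_toy_ensemble(self.SPEC)
        coords = dimer.coords.copy()
        b_sel = dimer.select(chain="B")
        coords[:, b_sel, :] += np.array([500.0, 0.0, 0.0])
        far = Ensemble(coords=coords, atoms=dimer.atoms)
        mono = isolated_domain(self.SPEC)
        ds = u.delta_sasa(far, "A", mono)
        assert all(abs(ds.value(i)) < 1e-9 for i in ds.indices())

    def test_unmapped_residues_rejected(self):
        dimer = gen_toy_ensemble(self.SPEC)
        small = ToyEnsembleSpec(beads_per_domain=10, n_substates=1,
                                frames_per_substate=2, jitter_sigma=0.0, seed=4)
        mono = isolated_domain(small)
        with pytest.raises(u.ValidationError, match="1:1"):
            u.delta_sasa(dimer, "A", mono)


class TestRMSF:
    def test_static_ensemble_zero(self):
        ens = gen_toy_ensemble(
            ToyEnsembleSpec(beads_per_domain=8, n_substates=1, frames_per_substate=5,
                            jitter_sigma=0.0, seed=0)
        )
        series = u.rmsf(ens, selection=ens.select(chain="A"))
        assert all(v[0] < 1e-12 for v in series.values.values())

    def test_rigid_rotation_zero_after_alignment(self):
        from ubidyn.synth import _compact_cluster, _rotation_matrix

        base = _compact_cluster(10, 4.0)
        frames = [base @ _rotation_matrix(np.array([0.0, 0.0, 1.0]), a).T
                  for a in np.linspace(0, np.pi, 6)]
        ens = Ensemble(coords=np.array(frames), atoms=_atoms(10))
        series = u.rmsf(ens, selection=np.arange(10))
        assert all(v[0] < 1e-9 for v in series.values.values())

    def test_gaussian_jitter_converges_to_sigma_sqrt3(self):
        sigma = 0.5
        n_beads = 60
        ens = gen_toy_ensemble(
            ToyEnsembleSpec(beads_per_domain=n_beads, n_substates=1,
                            frames_per_substate=300, jitter_sigma=sigma, seed=21)
        )
        series = u.rmsf(ens, selection=ens.select(chain="A"))
        vals = np.array([v[0] for v in series.values.values()])
        # Rigid-body superposition absorbs 6 of the 3N noise degrees of
        # freedom, deflating the expectation by sqrt(1 - 6/(3N)).
        expected = sigma * np.sqrt(3) * np.sqrt(1.0 - 6.0 / (3 * n_beads))
        assert np.mean(vals) == pytest.approx(expected, rel=0.03)

    def test_window_shorter_than_two_rejected(self, toy_two_state):
        with pytest.raises(u.ValidationError):
            u.rmsf(toy_two_state, window=1)


class TestGyration:
    def test_coincident_atoms_zero(self):
        ens = Ensemble(coords=np.zeros((1, 4, 3)), atoms=_atoms(4))
        assert u.gyration(ens).mean == 0.0

    def test_two_equal_masses(self):
        coords = np.array([[[0.0, 0, 0], [6.0, 0, 0]]])
        ens = Ensemble(coords=coords, atoms=_atoms(2))
        assert u.gyration(ens).mean == pytest.approx(3.0, rel=1e-12)

    def test_textbook_formula_oracle(self, ub_like):
        masses = {"C": 12.011, "N": 14.007, "O": 15.999}
        m = np.array([masses[a.element] for a in ub_like.atoms])
        x = ub_like.coords[0]
        com = (x * m[:, None]).sum(axis=0) / m.sum()
        rg = np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum())
        assert u.gyration(ub_like).mean == pytest.approx(rg, rel=1e-9)

    def test_rotation_invariance(self, ub_like, rng):
        from ubidyn.synth import _rotation_matrix

        rot = _rotation_matrix(rng.normal(size=3), 0.7)
        moved = Ensemble(coords=ub_like.coords @ rot.T + 9.0, atoms=ub_like.atoms)
        assert u.gyration(moved).mean == pytest.approx(u.gyration(ub_like).mean, rel=1e-12)


class TestRMSDCluster:
    def test_duplicate_frames_single_cluster(self):
        base = np.random.default_rng(0).normal(size=(6, 3))
        ens = Ensemble(coords=np.repeat(base[None], 5, axis=0), atoms=_atoms(6))
        cl = u.rmsd_cluster(ens, k=1, selection=np.arange(6))
        assert np.allclose(cl.rmsd_matrix, 0.0)
        assert cl.k == 1
        assert cl.populations[0] == 1.0

    def test_two_substate_membership_exact(self, toy_two_state):
        cl = u.rmsd_cluster(toy_two_state, k=2,
                            selection=np.arange(toy_two_state.n_atoms))
        truth = toy_two_state.metadata["substate_labels"]
        # Agreement up to label permutation
        same = np.mean(cl.labels == truth)
        assert same in (0.0, 1.0)

    def test_kabsch_against_scipy_rotation_oracle(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(10):
            p = rng.normal(size=(12, 3))
            q = rng.normal(size=(12, 3))
            pc, qc = p - p.mean(0), q - q.mean(0)
            rot, rssd = Rotation.align_vectors(qc, pc)
            oracle = rssd / np.sqrt(len(p))
            assert kabsch_rmsd(p, q) == pytest.approx(oracle, abs=1e-9)

    def test_matrix_symmetry_and_zero_diagonal(self, toy_two_state):
        mat = rmsd_matrix(toy_two_state.coords[:6])
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)

    def test_populations_sum_to_one_and_singleton_centroid(self, toy_two_state):
        cl = u.rmsd_cluster(toy_two_state, k=5,
                            selection=np.arange(toy_two_state.n_atoms))
        assert sum(cl.populations.values()) == pytest.approx(1.0)
        for lab, frames in cl.centroids.items():
            members = cl.frame_indices[cl.labels == lab]
            if len(members) == 1:
                assert frames == members[0]

    def test_k_larger_than_frames_rejected(self, toy_two_state):
        with pytest.raises(u.ValidationError):
            u.rmsd_cluster(toy_two_state, k=1000)


class TestMinDistanceCVs:
    def test_known_separation(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 100.0
        atoms = _atoms(1, chain="A") + _atoms(1, chain="B")
        ens = Ensemble(coords=coords, atoms=atoms)
        cvs = min_distance_cvs(ens, core=(1, 1))
        assert cvs.shape == (1, 2)
        assert np.allclose(cvs, 100.0)

    def test_chain_swap_symmetry(self, toy_two_state):
        core = (1, 20)
        cvs = min_distance_cvs(toy_two_state, core=core)
        a_sel = toy_two_state.select(chain="A")
        b_sel = toy_two_state.select(chain="B")
        order = np.concatenate([b_sel, a_sel])
        swapped = Ensemble(
            coords=toy_two_state.coords[:, order, :],
            atoms=[toy_two_state.atoms[i] for i in order],
        )
        cvs_sw = min_distance_cvs(swapped, core=core)
        half = cvs.shape[1] // 2
        assert np.allclose(cvs[:, :half], cvs_sw[:, half:])
        assert np.allclose(cvs[:, half:], cvs_sw[:, :half])

    def test_brute_force_all_pairs_oracle(self, toy_two_state):
        core = (1, 20)
        cvs = min_distance_cvs(toy_two_state, core=core)
        a_sel = toy_two_state.select(chain="A", names={"CA"}, res_range=core)
        b_sel = toy_two_state.select(chain="B", names={"CA"}, res_range=core)
        for f in (0, toy_two_state.n_frames - 1):
            for ai, atom_i in enumerate(a_sel):
                best = min(
                    float(np.linalg.norm(
                        toy_two_state.coords[f, atom_i] - toy_two_state.coords[f, bj]
                    ))
                    for bj in b_sel
                )
                assert cvs[f, ai] == pytest.approx(best, abs=1e-12)

    def test_expected_dimensionality_for_two_72_cores(self):
        spec = ToyEnsembleSpec(beads_per_domain=72, n_substates=1,
                               frames_per_substate=1, jitter_sigma=0.0, seed=0)
        ens = gen_toy_ensemble(spec)
        cvs = min_distance_cvs(ens, core=(1, 72))
        assert cvs.shape[1] == 144


class TestLandscape:
    def test_uniform_density_zero_free_energy(self, rng):
        # All frames land in distinct bins with one frame each.
        emb = np.column_stack([np.arange(16, dtype=float), np.zeros(16)])
        cvs = rng.normal(size=(16, 4))
        land = landscape(cvs, bins=16, embedding=emb)
        occupied = np.isfinite(land.free_energy)
        assert np.allclose(land.free_energy[occupied], 0.0)

    def test_two_state_population_free_energy_difference(self, rng):
        p1, p2 = 300, 100
        emb = np.vstack([
            np.tile([0.0, 0.0], (p1, 1)), np.tile([10.0, 10.0], (p2, 1)),
        ]) + rng.normal(0, 0.05, size=(p1 + p2, 2))
        cvs = rng.normal(size=(p1 + p2, 6))
        land = landscape(cvs, bins=4, embedding=emb)
        finite = np.sort(land.free_energy[np.isfinite(land.free_energy)])
        df = finite[1] - finite[0]
        assert df == pytest.approx(np.log(p1 / p2), abs=0.05)

    def test_separated_cv_clusters_stay_separated(self, toy_two_state):
        from sklearn.metrics import silhouette_score

        cvs = min_distance_cvs(toy_two_state, core=(1, 20))
        emb = pca_embedding(cvs)
        score = silhouette_score(emb, toy_two_state.metadata["substate_labels"])
        assert score > 0.5

    def test_degenerate_cvs_rejected(self):
        with pytest.raises(u.ValidationError):
            landscape(np.ones((20, 4)), bins=4)

    def test_sparse_sampling_warns(self, rng):
        cvs = rng.normal(size=(20, 3))
        with pytest.warns(UserWarning, match="sparse"):
            landscape(cvs, bins=50)
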