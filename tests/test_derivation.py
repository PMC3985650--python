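"""The iterative update, its fixed point, convergence rule and end-to-end
behaviour on seeded synthetic training sets."""

import numpy as np
import pytest

import itscore_pr as it
from itscore_pr.atom_types import N_PROTEIN_TYPES, N_RNA_TYPES
from itscore_pr.derivation import (DerivationState, TrainingComplex,
                                   TrainingEnsemble, _native_ranks)
from itscore_pr.pair_statistics import normalize_histogram


def _identity_decoy_complex(typed_toy, n_decoys=3):
    """All poses identical to the native -> ensemble g equals observed g."""
    tp, tr = typed_toy
    decoys = [it.RigidTransform.identity() for _ in range(n_decoys)]
    return TrainingComplex(tp, tr, decoys, "ident")


class TestFixedPoint:
    def test_identical_poses_leave_potentials_unchanged(self, typed_toy,
                                                        grid):
        ens = TrainingEnsemble([_identity_decoy_complex(typed_toy)], grid)
        g_obs = it.observed_distribution(ens.native_pairs(), grid)
        rng = np.random.default_rng(3)
        from conftest import random_potential_table
        table = random_potential_table(rng, grid)
        state = DerivationState(0, table, np.ones(1, dtype=int), False)
        new = it.iterate_once(state, ens, g_obs)
        np.testing.assert_array_equal(new.table.u, table.u)

    def test_fixed_point_persists_over_many_iterations(self, typed_toy,
                                                       grid):
        ens = TrainingEnsemble([_identity_decoy_complex(typed_toy)], grid)
        g_obs = it.observed_distribution(ens.native_pairs(), grid)
        table = it.PotentialTable.zeros(grid)
        state = DerivationState(0, table, np.ones(1, dtype=int), False)
        for _ in range(5):
            state = it.iterate_once(state, ens, g_obs)
        np.testing.assert_array_equal(state.table.u, table.u)


class TestUpdateFormula:
    def test_single_bin_correction_arithmetic(self, grid, typed_toy):
        """With two poses at equal score, the update at each bin is
        (lambda/2)*kT*(mean pose g - observed g)."""
        tp, tr = typed_toy
        shifted = it.RigidTransform(np.eye(3), np.array([0.0, 0.0, 2.0]))
        c = TrainingComplex(tp, tr, [shifted], "two-pose")
        ens = TrainingEnsemble([c], grid)
        ens.ensure_caches()
        g_obs = it.observed_distribution(ens.native_pairs(), grid)
        table = it.PotentialTable.zeros(grid)   # zero scores -> equal weights
        state = DerivationState(0, table, np.ones(1, dtype=int), False)
        new = it.iterate_once(state, ens, g_obs, kT=1.0, lambda_step=1.0)
        g_poses = normalize_histogram(c.pose_histograms, grid)
        expected = 0.5 * (g_poses.mean(axis=0) - g_obs.g)
        expected[:, :, 50:] = 0.0
        np.testing.assert_allclose(new.table.u, np.minimum(expected, 100.0),
                                   atol=1e-12)

    def test_step_by_step_oracle_on_multi_complex_fixture(self, grid):
        """One full cycle against a hand-rolled score->weights->g->update
        pipeline on a 2-complex, 5-decoy fixture."""
        from conftest import random_potential_table, random_typed_pair
        from itscore_pr.scoring import pose_weights as pw
        rng = np.random.default_rng(77)
        complexes = []
        for label in ("a", "b"):
            tp, tr = random_typed_pair(rng, n_protein=15, n_rna=15)
            decoys = []
            for _ in range(5):
                from scipy.spatial.transform import Rotation
                R = Rotation.random(random_state=np.random.RandomState(
                    rng.integers(1 << 31))).as_matrix()
                decoys.append(it.RigidTransform(R, rng.normal(scale=4.0,
                                                              size=3)))
            complexes.append(TrainingComplex(tp, tr, decoys, label))
        ens = TrainingEnsemble(complexes, grid)
        ens.ensure_caches()
        g_obs = it.observed_distribution(ens.native_pairs(), grid)
        table = random_potential_table(rng, grid)
        state = DerivationState(0, table, np.ones(2, dtype=int), False)
        new = it.iterate_once(state, ens, g_obs, kT=1.3, lambda_step=0.7)

        # independent oracle
        g_sum = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
        for c in ens.complexes:
            scores = []
            for l in range(c.n_poses):
                rna = c.pose_rna(l)
                scores.append(it.score_pose(c.protein, rna, table).total)
            scores = np.asarray(scores)
            e = np.exp(-(scores - scores.min()) / 1.3)
            w = e / e.sum()
            for l in range(c.n_poses):
                g_sum += w[l] * normalize_histogram(c.pose_histograms[l],
                                                    grid)
        g_ens = g_sum / len(ens.complexes)
        expected = table.u + (0.7 / 2) * 1.3 * (g_ens - g_obs.g)
        expected = np.minimum(expected, table.penalty_cap)
        expected[:, :, 50:] = 0.0
        expected[~table.retained, :] = 0.0
        np.testing.assert_allclose(new.table.u, expected, atol=1e-9)

    def test_unretained_pairs_stay_zero(self, grid, typed_toy):
        tp, tr = typed_toy
        shifted = it.RigidTransform(np.eye(3), np.array([0.0, 1.0, 0.0]))
        ens = TrainingEnsemble([TrainingComplex(tp, tr, [shifted], "x")],
                               grid)
        g_obs = it.observed_distribution(ens.native_pairs(), grid)
        retained = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES), dtype=bool)
        retained[4, 1] = True
        table = it.PotentialTable.zeros(grid, retained=retained)
        state = DerivationState(0, table, np.ones(1, dtype=int), False)
        new = it.iterate_once(state, ens, g_obs)
        mask = np.ones_like(retained)
        mask[4, 1] = False
        assert np.all(new.table.u[mask, :] == 0.0)


class TestConvergenceRule:
    def test_strictly_lowest_native_converges(self):
        assert it.check_convergence([np.array([-5.0, -4.0, 0.0])])

    def test_tie_with_decoy_counts_as_failure(self):
        assert not it.check_convergence([np.array([-5.0, -5.0, 0.0])])

    def test_any_failing_complex_blocks_convergence(self):
        assert not it.check_convergence([np.array([-5.0, -4.0]),
                                         np.array([-1.0, -2.0])])

    def test_native_rank_counts_better_or_equal_decoys(self):
        ranks = _native_ranks([np.array([-1.0, -2.0, -1.5, 0.0])])
        assert ranks[0] == 3


class TestDerivePotentials:
    def test_decoys_without_contacts_converge_quickly(self, typed_toy, grid):
        tp, tr = typed_toy
        far = [it.RigidTransform(np.eye(3), np.array([100.0 + 5 * i, 0, 0]))
               for i in range(4)]
        ens = TrainingEnsemble([TrainingComplex(tp, tr, far, "far")], grid)
        cfg = it.DerivationConfig(occurrence_threshold=10, max_iter=20)
        table, state = it.derive_potentials(ens, grid, cfg)
        assert state.converged
        assert state.iteration <= 20

    def test_adversarial_identical_decoy_cannot_converge(self, typed_toy,
                                                         grid):
        tp, tr = typed_toy
        decoys = [it.RigidTransform.identity(),
                  it.RigidTransform(np.eye(3), np.array([60.0, 0, 0]))]
        ens = TrainingEnsemble([TrainingComplex(tp, tr, decoys, "adv")], grid)
        cfg = it.DerivationConfig(occurrence_threshold=10, max_iter=5)
        table, state = it.derive_potentials(ens, grid, cfg)
        assert not state.converged
        assert state.iteration == 5
        assert state.native_ranks[0] > 1

    def test_update_locality_beyond_cutoff(self, mini_ensemble, grid):
        _, ens = mini_ensemble
        cfg = it.DerivationConfig(occurrence_threshold=30, max_iter=6)
        table, _ = it.derive_potentials(ens, grid, cfg)
        assert np.all(table.u[:, :, 50:] == 0.0)

    def test_mini_recovery_converges_with_all_natives_first(self,
                                                            mini_ensemble,
                                                            grid):
        _, ens = mini_ensemble
        cfg = it.DerivationConfig(occurrence_threshold=30, max_iter=30)
        table, state = it.derive_potentials(ens, grid, cfg)
        assert state.converged
        assert np.all(state.native_ranks == 1)

    def test_empty_ensemble_rejected(self, grid):
        with pytest.raises(ValueError):
            TrainingEnsemble([], grid)


class TestModelApi:
    def test_fit_returns_results_with_diagnostics(self, mini_ensemble):
        _, ens = mini_ensemble
        model = it.ITScorePR(ens, it.DerivationConfig(occurrence_threshold=30,
                                                      max_iter=30))
        res = model.fit()
        assert res.converged
        assert res.n_iter >= 1
        assert len(res.failure_history) == res.n_iter
        assert res.native_ranks.shape == (len(ens.complexes),)
        text = res.summary()
        for needle in ("Training complexes", "Converged", "Retained pair"):
            assert needle in text

    def test_results_save_roundtrip_and_score(self, mini_ensemble, tmp_path):
        _, ens = mini_ensemble
        res = it.ITScorePR(ens, it.DerivationConfig(occurrence_threshold=30,
                                                    max_iter=30)).fit()
        path = tmp_path / "pot.tsv"
        res.save(path)
        back = it.read_potentials(path)
        assert (back.u == res.potentials.u).all()
        c = ens.complexes[0]
        s = res.score(c.protein, c.rna_native)
        assert np.isfinite(s)

    def test_converged_potentials_discriminate_all_natives(self,
                                                           mini_ensemble):
        _, ens = mini_ensemble
        res = it.ITScorePR(ens, it.DerivationConfig(occurrence_threshold=30,
                                                    max_iter=30)).fit()
        raw = res.converged_potentials
        for c in ens.complexes:
            scores = np.array([w.score(raw) for w in c.pose_weights])
            assert np.all(scores[0] < scores[1:])
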