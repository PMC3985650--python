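"""VDW curves, PMF construction, capping, smoothing, lookup, TSV round-trip."""

import numpy as np
import pytest

import itscore_pr as it
from itscore_pr.atom_types import N_PROTEIN_TYPES, N_RNA_TYPES
from itscore_pr.potentials import smooth_vector

from conftest import random_potential_table, random_typed_pair


class TestVdwEnergy:
    def test_minimum_at_contact_distance(self):
        assert it.vdw_energy(3.5, 3.5, 0.2) == pytest.approx(-0.2)

    def test_large_distance_matches_formula(self):
        r, R, e = 3 * 3.5, 3.5, 0.2
        q = (R / r) ** 6
        assert it.vdw_energy(r, R, e) == pytest.approx(e * (q * q - 2 * q))
        assert it.vdw_energy(r, R, e) < 0

    def test_repulsive_core_is_large_positive(self):
        assert it.vdw_energy(0.35, 3.5, 0.2) > 1e6

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            it.vdw_energy(0.0, 3.5, 0.2)

    def test_combination_rules(self, vdw_params):
        r, e = vdw_params.pair_params("Car", "P")
        assert r == pytest.approx(vdw_params.radius["Car"]
                                  + vdw_params.radius["P"])
        assert e == pytest.approx(np.sqrt(vdw_params.well_depth["Car"]
                                          * vdw_params.well_depth["P"]))


class TestPmf:
    def test_reference_with_single_pair_type_equals_that_type(self, grid):
        rng = np.random.default_rng(5)
        tp, tr = random_typed_pair(rng)
        tp.type_codes[:] = 2
        tr.type_codes[:] = 3
        ref = it.pmf_reference([(tp, tr)], grid)
        counts = it.complex_histogram(tp, tr, grid)
        g_single = it.normalize_histogram(counts[2, 3], grid)
        np.testing.assert_allclose(ref.g[2, 3], g_single, atol=1e-12)
        # the pooled reference is identical for every pair type
        np.testing.assert_allclose(ref.g[0, 0], ref.g[19, 11])

    def test_reference_pools_types_by_count(self, grid):
        rng = np.random.default_rng(15)
        tp, tr = random_typed_pair(rng)
        tp.type_codes[:] = np.where(np.arange(len(tp.type_codes)) % 2, 0, 1)
        tr.type_codes[:] = 0
        ref = it.pmf_reference([(tp, tr)], grid)
        counts = it.complex_histogram(tp, tr, grid)
        pooled = it.normalize_histogram(counts.sum(axis=(0, 1)), grid)
        np.testing.assert_allclose(ref.g[0, 0], pooled, atol=1e-12)

    def test_identical_distributions_give_zero_potential(self, grid):
        g = np.ones((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
        d = it.PairDistribution(grid, g)
        np.testing.assert_array_equal(it.pmf_potential(d, d), 0.0)

    def test_log_ratio_closed_form(self, grid):
        g_ref = np.ones((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
        g_obs = g_ref.copy()
        g_obs[0, 0, 30] = np.e
        u = it.pmf_potential(it.PairDistribution(grid, g_obs),
                             it.PairDistribution(grid, g_ref), kT=1.0)
        assert u[0, 0, 30] == pytest.approx(-1.0)

    def test_zero_handling(self, grid):
        g_ref = np.ones((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
        g_obs = np.zeros_like(g_ref)
        g_obs[0, 0, 20:] = 1.0          # first populated bin at index 20
        u = it.pmf_potential(it.PairDistribution(grid, g_obs),
                             it.PairDistribution(grid, g_ref),
                             penalty_cap=100.0)
        assert np.all(u[0, 0, :20] == 100.0)    # empty core -> cap
        np.testing.assert_allclose(u[0, 0, 20:], 0.0)
        # g_ref = 0 carries no information
        g_ref2 = np.zeros_like(g_ref)
        u2 = it.pmf_potential(it.PairDistribution(grid, g_obs),
                              it.PairDistribution(grid, g_ref2))
        np.testing.assert_allclose(u2[0, 0, 20:], 0.0)


class TestInitialPotentials:
    def test_zero_pmf_gives_capped_binned_vdw(self, grid, vdw_params):
        pmf = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
        table = it.initial_potentials(vdw_params, pmf, grid)
        r_ij, eps_ij = vdw_params.pair_params("Car", "Car")
        i = 4
        j = 1
        expected = np.minimum(
            it.vdw_energy(grid.centers, r_ij, eps_ij), 100.0)
        expected[grid.centers > 10.0 - 1e-12] = 0.0
        np.testing.assert_allclose(table.u[i, j], expected)

    def test_bins_beyond_cutoff_are_zero(self, grid, vdw_params):
        rng = np.random.default_rng(2)
        pmf = rng.normal(size=(N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
        table = it.initial_potentials(vdw_params, pmf, grid)
        assert np.all(table.u[:, :, 50:] == 0.0)

    def test_elementwise_sum_then_cap(self, grid, vdw_params):
        rng = np.random.default_rng(3)
        pmf = rng.normal(0, 50, size=(N_PROTEIN_TYPES, N_RNA_TYPES,
                                      grid.n_bins))
        table = it.initial_potentials(vdw_params, pmf, grid)
        rp, ep, rr, er = vdw_params.per_type_arrays()
        i, j, m = 7, 5, 20
        raw = it.vdw_energy(grid.centers[m], rp[i] + rr[j],
                            np.sqrt(ep[i] * er[j])) + pmf[i, j, m]
        assert table.u[i, j, m] == pytest.approx(min(raw, 100.0))

    def test_forbidden_core_pinned_exactly_at_cap(self, grid, vdw_params):
        pmf = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
        pmf[:, :, :15] = 100.0   # empty-core wall from the PMF
        table = it.initial_potentials(vdw_params, pmf, grid)
        assert np.all(table.u[:, :, :15] == 100.0)


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        v = np.full(30, 3.7)
        np.testing.assert_allclose(smooth_vector(v), v)

    def test_unit_impulse_kernel(self):
        v = np.zeros(20)
        v[10] = 1.0
        out = smooth_vector(v)
        np.testing.assert_allclose(out[8:13], [0.1, 0.2, 0.4, 0.2, 0.1])
        assert out.sum() == pytest.approx(1.0)

    def test_random_vector_matches_direct_convolution(self):
        rng = np.random.default_rng(14)
        v = rng.normal(size=50)
        out = smooth_vector(v)
        kernel = np.array([1, 2, 4, 2, 1], dtype=float)
        for i in range(50):
            num, den = 0.0, 0.0
            for k, w in zip(range(-2, 3), kernel):
                if 0 <= i + k < 50:
                    num += w * v[i + k]
                    den += w
            assert out[i] == pytest.approx(num / den)

    def test_contracts_zero_mean_perturbations(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=40)
        v -= v.mean()
        assert np.abs(smooth_vector(v)).max() < np.abs(v).max()

    def test_table_smoothing_keeps_cutoff_zero(self, grid):
        rng = np.random.default_rng(8)
        table = random_potential_table(rng, grid)
        smoothed = it.smooth(table)
        assert np.all(smoothed.u[:, :, 50:] == 0.0)
        assert np.all(smoothed.u <= table.penalty_cap + 1e-12)
        # interior bins follow the kernel over the active window
        i, j = np.argwhere(table.retained)[0]
        v = table.u[i, j, :50]
        expected = (v[18] + 2 * v[19] + 4 * v[20] + 2 * v[21] + v[22]) / 10
        assert smoothed.u[i, j, 20] == pytest.approx(expected)


class TestEvaluate:
    def test_bin_center_returns_stored_value(self, grid):
        table = it.PotentialTable.zeros(grid)
        table.u[4, 1, 17] = -1.3
        assert table.evaluate("Car", "Car", grid.centers[17]) == \
            pytest.approx(-1.3)

    def test_midpoint_interpolates_linearly(self, grid):
        table = it.PotentialTable.zeros(grid)
        table.u[0, 0, 10] = 2.0
        table.u[0, 0, 11] = 4.0
        r = 0.5 * (grid.centers[10] + grid.centers[11])
        assert table.evaluate("C2+", "C2X", r) == pytest.approx(3.0)

    def test_beyond_cutoff_is_zero(self, grid):
        rng = np.random.default_rng(0)
        table = random_potential_table(rng, grid)
        i, j = np.argwhere(table.retained)[0]
        from itscore_pr.atom_types import PROTEIN_TYPES, RNA_TYPES
        assert table.evaluate(PROTEIN_TYPES[i], RNA_TYPES[j], 11.0) == 0.0
        assert table.evaluate(PROTEIN_TYPES[i], RNA_TYPES[j], 10.0) == 0.0

    def test_below_first_center_hits_penalty_cap(self, grid):
        table = it.PotentialTable.zeros(grid, penalty_cap=100.0)
        assert table.evaluate("C2+", "C2X", 0.05) == 100.0

    def test_continuous_ramp_to_zero_at_cutoff(self, grid):
        table = it.PotentialTable.zeros(grid)
        table.u[0, 0, 49] = -2.0
        near = table.evaluate("C2+", "C2X", 9.999)
        assert abs(near) < 0.05
        mid = table.evaluate("C2+", "C2X", 9.95)
        assert mid == pytest.approx(-1.0)

    def test_unknown_pair_symbol_rejected(self, grid):
        table = it.PotentialTable.zeros(grid)
        with pytest.raises(ValueError):
            table.evaluate("BOGUS", "P", 3.0)

    def test_unretained_pair_scores_zero_everywhere(self, grid):
        retained = np.ones((N_PROTEIN_TYPES, N_RNA_TYPES), dtype=bool)
        retained[0, 0] = False
        u = np.full((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins), -5.0)
        table = it.PotentialTable(grid, u, retained=retained)
        assert table.evaluate("C2+", "C2X", 3.0) == 0.0
        assert table.evaluate("C2+", "C2X", 0.01) == 0.0

    def test_cap_invariant_over_random_inputs(self, grid):
        rng = np.random.default_rng(19)
        table = random_potential_table(rng, grid, penalty_cap=7.0)
        from itscore_pr.atom_types import PROTEIN_TYPES, RNA_TYPES
        r = rng.uniform(0, 12, size=200)
        for x in r:
            i = rng.integers(0, N_PROTEIN_TYPES)
            j = rng.integers(0, N_RNA_TYPES)
            assert table.evaluate(PROTEIN_TYPES[i], RNA_TYPES[j],
                                  float(x)) <= 7.0 + 1e-12


class TestTsvRoundTrip:
    def test_bit_exact(self, grid, tmp_path):
        rng = np.random.default_rng(23)
        table = random_potential_table(rng, grid)
        path = tmp_path / "pot.tsv"
        it.write_potentials(path, table)
        back = it.read_potentials(path)
        assert (back.u == table.u).all()
        np.testing.assert_array_equal(back.retained, table.retained)
        assert back.penalty_cap == table.penalty_cap
        assert back.grid.bin_width == table.grid.bin_width
        # writing again produces identical bytes
        path2 = tmp_path / "pot2.tsv"
        it.write_potentials(path2, back)
        assert path.read_bytes() == path2.read_bytes()

    def test_malformed_record_names_line(self, grid, tmp_path):
        rng = np.random.default_rng(1)
        table = random_potential_table(rng, grid)
        path = tmp_path / "bad.tsv"
        it.write_potentials(path, table)
        lines = path.read_text().splitlines()
        lines[10] = "Car\tCar\tnot_a_number\toops"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 11"):
            it.read_potentials(path)
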