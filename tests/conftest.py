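"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's accelerated code paths: plain
double loops, naive histogramming, the quaternion characteristic-polynomial
superposition method, and a literal greedy clustering sweep.
"""

import numpy as np
import pytest

import itscore_pr as it
from itscore_pr.atom_types import N_PROTEIN_TYPES, N_RNA_TYPES


@pytest.fixture(scope="session")
def type_table():
    return it.AtomTypeTable.default()


@pytest.fixture(scope="session")
def vdw_params():
    return it.VdwParams.default()


@pytest.fixture(scope="session")
def grid():
    return it.RadialGrid()


@pytest.fixture(scope="session")
def toy_complex():
    return it.make_toy_complex(it.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def typed_toy(toy_complex, type_table):
    p, r = toy_complex
    return it.assign_types(p, type_table), it.assign_types(r, type_table)


@pytest.fixture(scope="session")
def mini_ensemble():
    """Small seeded training ensemble shared by derivation tests."""
    g = it.RadialGrid()
    true = it.make_synthetic_table(g, seed=11)
    ens = it.simulate_training_set(true, K=3, L=30, seed=11)
    return true, ens


def random_typed_pair(rng, n_protein=25, n_rna=25, spread=14.0):
    """Random typed structures for oracle-equivalence fixtures."""
    def build(n, kind, n_types):
        coords = rng.uniform(-spread, spread, size=(n, 3))
        s = it.Structure(chain_ids=["A"] * n, residue_names=["UNK"] * n,
                         residue_numbers=list(range(1, n + 1)),
                         icodes=[""] * n, atom_names=["X"] * n,
                         coords=coords, kind=kind)
        codes = rng.integers(0, n_types, size=n)
        return it.TypedStructure(s, codes)
    return (build(n_protein, "protein", N_PROTEIN_TYPES),
            build(n_rna, "rna", N_RNA_TYPES))


def random_potential_table(rng, grid, penalty_cap=100.0):
    u = rng.normal(0.0, 2.0, size=(N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
    retained = rng.random((N_PROTEIN_TYPES, N_RNA_TYPES)) < 0.8
    return it.PotentialTable(grid, u, penalty_cap=penalty_cap,
                             retained=retained)


# ---------------------------------------------------------------------------
# independent oracles

def oracle_pairs_within(pa, pb, cutoff):
    """O(N^2) double loop: set of (i, j, distance) with d < cutoff."""
    out = []
    for i in range(len(pa)):
        for j in range(len(pb)):
            d = float(np.linalg.norm(pa[i] - pb[j]))
            if d < cutoff:
                out.append((i, j, d))
    return out


def oracle_histogram(tp, tr, grid):
    counts = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins),
                      dtype=np.int64)
    pc, pcodes = tp.typed_coords()
    rc, rcodes = tr.typed_coords()
    for i in range(len(pc)):
        for j in range(len(rc)):
            d = float(np.linalg.norm(pc[i] - rc[j]))
            if d < grid.r_max:
                counts[pcodes[i], rcodes[j], int(d // grid.bin_width)] += 1
    return counts


def oracle_score(tp, tr, table):
    """Brute-force scoring through the scalar evaluate() path."""
    from itscore_pr.atom_types import PROTEIN_TYPES, RNA_TYPES
    pc, pcodes = tp.typed_coords()
    rc, rcodes = tr.typed_coords()
    total = 0.0
    for i in range(len(pc)):
        for j in range(len(rc)):
            d = float(np.linalg.norm(pc[i] - rc[j]))
            if d < table.r_cut:
                total += table.evaluate(PROTEIN_TYPES[pcodes[i]],
                                        RNA_TYPES[rcodes[j]], d)
    return total


def oracle_superpose_rmsd(ref, mob):
    """Horn's quaternion characteristic-polynomial method for the minimum
    RMSD (independent of the Kabsch/SVD implementation)."""
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    P = ref - ref.mean(axis=0)
    Q = mob - mob.mean(axis=0)
    Sxx, Sxy, Sxz = (Q[:, 0] @ P[:, 0]), (Q[:, 0] @ P[:, 1]), (Q[:, 0] @ P[:, 2])
    Syx, Syy, Syz = (Q[:, 1] @ P[:, 0]), (Q[:, 1] @ P[:, 1]), (Q[:, 1] @ P[:, 2])
    Szx, Szy, Szz = (Q[:, 2] @ P[:, 0]), (Q[:, 2] @ P[:, 1]), (Q[:, 2] @ P[:, 2])
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K).max()
    n = len(ref)
    msd = (np.sum(P ** 2) + np.sum(Q ** 2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def oracle_greedy_cluster(scores, coords_list, radius):
    order = np.argsort(np.asarray(scores), kind="stable")
    kept = []
    for idx in order:
        ok = True
        for k in kept:
            d = np.sqrt(np.mean(np.sum(
                (coords_list[idx] - coords_list[k]) ** 2, axis=1)))
            if d < radius:
                ok = False
                break
        if ok:
            kept.append(int(idx))
    return kept
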