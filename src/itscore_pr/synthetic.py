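"""Deterministic synthetic complexes and decoy ensembles.

Everything downstream of structure input depends only on heavy-atom
distances and type assignments, so the toy complexes use idealized (not
physically relaxed) geometry: residues are rendered as deterministic
spherical atom clusters whose centers follow helical paths, with a protein
built from repeating ARG-PHE-ASP and an RNA from repeating A-U-G-C.  Every
atom name is drawn from the standard typing alphabet, so fixtures exercise
the full pipeline with zero untyped atoms and no external downloads.
Decoy ensembles mix uniform rigid placements on the protein surface shell
with small near-native jitters so the RMSD spectrum spans near-native
(< 5 A) to far (> 20 A) poses.  All randomness flows from a single integer
seed; identical seeds give byte-identical structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .atom_types import AtomTypeTable, TypedStructure, assign_types
from .pair_statistics import RadialGrid
from .potentials import DEFAULT_PENALTY_CAP, PotentialTable
from .refinement import RefinementConfig, refine_pose
from .scoring import score_pose
from .structure import PROTEIN, RNA, RigidTransform, Structure

PROTEIN_RESIDUE_ATOMS = {
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "PHE": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
}
_SUGAR_PHOSPHATE = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'",
                    "O3'", "C2'", "O2'", "C1'"]
RNA_RESIDUE_ATOMS = {
    "A": _SUGAR_PHOSPHATE + ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2",
                             "N3", "C4"],
    "G": _SUGAR_PHOSPHATE + ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2",
                             "N2", "N3", "C4"],
    "C": _SUGAR_PHOSPHATE + ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "U": _SUGAR_PHOSPHATE + ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"],
}

PROTEIN_SEQUENCE = ["ARG", "PHE", "ASP"]
RNA_SEQUENCE = ["A", "U", "G", "C"]


@dataclass
class FixtureSpec:
    seed: int = 0
    n_protein_residues: int = 12
    n_rna_residues: int = 8
    n_decoys: int = 100
    box: float = 120.0              # placement box edge, A
    clearance: float = 1.5          # decoy inter-atomic clash floor, A
    native_clearance: float = 2.2   # minimum inter-partner distance, native

    def __post_init__(self):
        if self.n_protein_residues < 1 or self.n_rna_residues < 1:
            raise ValueError("residue counts must be >= 1")
        if self.n_decoys < 1:
            raise ValueError("need at least one decoy")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, well-spread unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def _zigzag_centers(n: int, spacing: float, lateral: float):
    """Residue centers on a zigzag rod along z (alternating +/- y).

    The zigzag keeps neighboring residue clusters out of each other while
    packing residues densely along the chain axis, which is what gives the
    bound complex its >= 20-residue-contact interface."""
    z = np.arange(n) * spacing
    y = lateral * (-1.0) ** np.arange(n)
    return np.column_stack([np.zeros(n), y, z])


def _build_chain(sequence, atom_table, n_residues, centers, sphere_radius,
                 rng, kind, chain_id):
    chains, resnames, resnums, icodes, names, coords = [], [], [], [], [], []
    for i in range(n_residues):
        res = sequence[i % len(sequence)]
        atoms = atom_table[res]
        pts = _fibonacci_sphere(len(atoms)) * sphere_radius
        rot = Rotation.random(random_state=np.random.RandomState(
            rng.integers(0, 2 ** 31 - 1))).as_matrix()
        pts = pts @ rot.T + centers[i]
        pts = pts + rng.normal(0.0, 0.05, size=pts.shape)  # break symmetry
        for a, xyz in zip(atoms, pts):
            chains.append(chain_id)
            resnames.append(res)
            resnums.append(i + 1)
            icodes.append("")
            names.append(a)
            coords.append(xyz)
    return Structure(chain_ids=chains, residue_names=resnames,
                     residue_numbers=resnums, icodes=icodes, atom_names=names,
                     coords=coords, kind=kind)


def make_toy_complex(spec: FixtureSpec):
    """Deterministic bound toy complex (protein Structure, rna Structure).

    Partners are slid into contact along x until the minimum inter-partner
    atom distance reaches the native clearance; the construction guarantees
    >= 20 native residue-residue contacts at 5 A for the default sizes.
    """
    rng = np.random.default_rng(spec.seed)
    p_centers = _zigzag_centers(spec.n_protein_residues, spacing=2.7,
                                lateral=2.5)
    protein = _build_chain(PROTEIN_SEQUENCE, PROTEIN_RESIDUE_ATOMS,
                           spec.n_protein_residues, p_centers,
                           sphere_radius=1.6, rng=rng, kind=PROTEIN,
                           chain_id="A")
    r_centers = _zigzag_centers(spec.n_rna_residues, spacing=3.2, lateral=2.6)
    # center the RNA span on the protein span along z, offset along +x
    z_shift = (p_centers[:, 2].mean() - r_centers[:, 2].mean())
    r_centers = r_centers + np.array([9.0, 0.0, z_shift])
    rna = _build_chain(RNA_SEQUENCE, RNA_RESIDUE_ATOMS, spec.n_rna_residues,
                       r_centers, sphere_radius=2.1, rng=rng, kind=RNA,
                       chain_id="R")
    # slide the RNA along x to the requested native clearance
    from scipy.spatial.distance import cdist
    shift = 0.0
    step = 0.2
    for _ in range(400):
        d = cdist(protein.coords, rna.coords + np.array([shift, 0, 0])).min()
        if d >= spec.native_clearance:
            if d <= spec.native_clearance + step:
                break
            shift -= step
        else:
            shift += step
    rna = rna.with_coords(rna.coords + np.array([shift, 0.0, 0.0]))
    center = np.vstack([protein.coords, rna.coords]).mean(axis=0)
    protein = protein.with_coords(protein.coords - center)
    rna = rna.with_coords(rna.coords - center)
    extent = max(np.abs(protein.coords).max(), np.abs(rna.coords).max())
    if 2 * extent > spec.box:
        raise ValueError("complex exceeds the placement box")
    return protein, rna


class DecoyGenerationError(RuntimeError):
    pass


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def generate_decoys(protein: Structure, rna: Structure, L: int, seed: int,
                    near_native_fraction: float = 0.25,
                    clearance: float = 1.5):
    """L clash-free rigid transforms of the RNA against the fixed protein.

    A fixed fraction jitters the native pose (near-native, typically < 5 A
    RMSD); the rest are uniform rotations with the RNA centroid placed on
    the protein surface shell, so far poses (> 20 A RMSD) always occur for
    L of a few tens or more.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    from scipy.spatial.distance import cdist
    rng = np.random.default_rng(seed)
    cp = protein.coords.mean(axis=0)
    cr = rna.coords.mean(axis=0)
    r_prot = np.linalg.norm(protein.coords - cp, axis=1).max()
    r_rna = np.linalg.norm(rna.coords - cr, axis=1).max()
    n_near = int(round(near_native_fraction * L))
    transforms = []
    attempts = 0
    while len(transforms) < L:
        attempts += 1
        if attempts > 100 * L:
            raise DecoyGenerationError("clash rejection exceeded 100*L attempts")
        if len(transforms) < n_near:
            R = Rotation.from_rotvec(
                rng.normal(0.0, np.deg2rad(8.0), size=3)).as_matrix()
            t_c = rng.normal(0.0, 1.2, size=3)
            target = cr + t_c
        else:
            R = _random_rotation(rng)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rho = r_prot + r_rna + rng.uniform(-4.0, 4.0)
            target = cp + rho * u
        translation = target - R @ cr
        candidate = RigidTransform(R, translation)
        coords = candidate.apply(rna.coords)
        if cdist(protein.coords, coords).min() < clearance:
            continue
        transforms.append(candidate)
    return transforms


def make_synthetic_table(grid: RadialGrid, seed: int,
                         penalty_cap: float = DEFAULT_PENALTY_CAP,
                         r_cut: float = 10.0) -> PotentialTable:
    """A known smooth generating potential used as ground truth in recovery
    tests: per pair type a Morse well with seeded depth, location and width.

    Morse wells are compact -- they decay to ~0 within a few Angstroms of
    the minimum -- matching the short-ranged character of knowledge-based
    contact potentials (which approach zero well before the 10 A cutoff).
    """
    from .atom_types import N_PROTEIN_TYPES, N_RNA_TYPES
    rng = np.random.default_rng(seed)
    shape = (N_PROTEIN_TYPES, N_RNA_TYPES)
    eps = rng.uniform(0.3, 2.5, size=shape)[..., None]
    r0 = rng.uniform(3.0, 5.0, size=shape)[..., None]
    a = rng.uniform(1.2, 2.0, size=shape)[..., None]
    r = grid.centers[None, None, :]
    decay = np.exp(-a * (r - r0))
    u = eps * (decay * decay - 2.0 * decay)
    return PotentialTable(grid, u, penalty_cap, r_cut)


def simulate_training_set(true_table: PotentialTable, K: int, L: int,
                          seed: int, grid: RadialGrid | None = None,
                          table: AtomTypeTable | None = None):
    """Training ensemble whose natives are discriminated by `true_table`.

    For each of K toy complexes, L decoys are generated and scored with the
    generating potential; the lowest-scoring pose is locally refined under
    that potential and becomes the native, so the ground truth potential
    ranks every native strictly first -- the property the derivation must
    recover.  Returns a TrainingEnsemble (native = pose 0 per complex).
    """
    from .derivation import TrainingComplex, TrainingEnsemble
    grid = grid or true_table.grid
    table = table or AtomTypeTable.default()
    rng = np.random.default_rng(seed)
    complexes = []
    for k in range(K):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        # sizes follow the training-set bounds (protein > 20 residues,
        # RNA >= 10 nt) at the small end of their ranges
        spec = FixtureSpec(seed=sub,
                           n_protein_residues=int(rng.integers(21, 29)),
                           n_rna_residues=int(rng.integers(10, 15)),
                           n_decoys=L)
        protein, rna = make_toy_complex(spec)
        tp = assign_types(protein, table)
        tr = assign_types(rna, table)
        decoys = generate_decoys(protein, rna, L,
                                 seed=int(rng.integers(0, 2 ** 31 - 1)))
        scores = np.array([
            score_pose(tp, tr.with_coords(t.apply(rna.coords)),
                       true_table).total for t in decoys])
        best = int(np.argmin(scores))
        cfg = RefinementConfig(objective="itscore", max_evals=600)
        native_t, native_e = refine_pose(tp, tr, decoys[best], cfg, true_table)
        if native_e >= scores.min():
            raise RuntimeError("refinement failed to separate the native "
                               "strictly from the decoys")
        native_coords = native_t.apply(rna.coords)
        inv = RigidTransform(native_t.rotation.T,
                             -native_t.rotation.T @ native_t.translation)
        rel_decoys = [t.compose(inv) for t in decoys]
        complexes.append(TrainingComplex(
            protein=tp,
            rna_native=tr.with_coords(native_coords),
            decoys=rel_decoys,
            label=f"toy{k}"))
    return TrainingEnsemble(complexes, grid)
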