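"""Binned radial pair distribution functions g(r).

Distances between protein and RNA heavy atoms are histogrammed per type pair
on a fixed grid (0.2 A bins out to the 12 A reference sphere) and normalized
so that a uniform random arrangement gives g = 1: each bin count is divided
by its shell volume and by the mean pair density inside the sphere.  The
observed distribution averages per-complex g over the training set with equal
weight; the ensemble distribution Boltzmann-weights the per-pose g of a decoy
ensemble under the current trial potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atom_types import (N_PROTEIN_TYPES, N_RNA_TYPES, TypedStructure,
                         pairs_within)


@dataclass(frozen=True)
class RadialGrid:
    bin_width: float = 0.2
    r_max: float = 12.0

    def __post_init__(self):
        if self.bin_width <= 0 or self.r_max <= 0:
            raise ValueError("bin_width and r_max must be positive")
        n = self.r_max / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("r_max must be an integer number of bins")

    @property
    def n_bins(self) -> int:
        return int(round(self.r_max / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def shell_volumes(self) -> np.ndarray:
        e = self.edges
        return (4.0 * np.pi / 3.0) * (e[1:] ** 3 - e[:-1] ** 3)

    @property
    def sphere_volume(self) -> float:
        return (4.0 * np.pi / 3.0) * self.r_max ** 3

    def compatible(self, other: "RadialGrid") -> bool:
        return (abs(self.bin_width - other.bin_width) < 1e-12
                and abs(self.r_max - other.r_max) < 1e-12)


@dataclass
class PairDistribution:
    """Per-pair-type g(r) on a radial grid, with the raw counts behind it."""

    grid: RadialGrid
    g: np.ndarray                       # (20, 12, n_bins), g >= 0
    raw_counts: np.ndarray | None = None

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=np.float64)
        expected = (N_PROTEIN_TYPES, N_RNA_TYPES, self.grid.n_bins)
        if self.g.shape != expected:
            raise ValueError(f"g must have shape {expected}, got {self.g.shape}")
        if np.any(self.g < 0):
            raise ValueError("g must be non-negative")


def complex_histogram(protein: TypedStructure, rna: TypedStructure,
                      grid: RadialGrid) -> np.ndarray:
    """Raw pair counts per (type pair, bin); bins left-closed/right-open."""
    pc, pcodes = protein.typed_coords()
    rc, rcodes = rna.typed_coords()
    counts = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins),
                      dtype=np.int64)
    if len(pc) == 0 or len(rc) == 0:
        return counts
    ip, jr, d = pairs_within(pc, rc, grid.r_max)
    bins = np.floor(d / grid.bin_width).astype(np.int64)
    bins = np.minimum(bins, grid.n_bins - 1)  # guard FP edge of d < r_max
    np.add.at(counts, (pcodes[ip], rcodes[jr], bins), 1)
    return counts


def normalize_histogram(counts, grid: RadialGrid, n_pairs_in_sphere=None):
    """Shell-volume normalization: uniform density inside the sphere -> g = 1.

    g[..., m] = (counts[..., m] / V_shell(m)) / (n_pairs / V_sphere).
    `counts` may be a single radial vector or a stack with bins last; if
    `n_pairs_in_sphere` is omitted it is the per-channel total count.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape[-1] != grid.n_bins:
        raise ValueError("last axis of counts must match the grid")
    if n_pairs_in_sphere is None:
        n_pairs_in_sphere = counts.sum(axis=-1)
    n_pairs = np.asarray(n_pairs_in_sphere, dtype=np.float64)[..., np.newaxis]
    density = counts / grid.shell_volumes
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(n_pairs > 0, density * grid.sphere_volume / n_pairs, 0.0)
    return g


def observed_distribution(complexes, grid: RadialGrid) -> PairDistribution:
    """Unweighted average of per-complex normalized distributions."""
    if not complexes:
        raise ValueError("need at least one complex")
    total_counts = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins),
                            dtype=np.int64)
    g_sum = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
    for tp, tr in complexes:
        counts = complex_histogram(tp, tr, grid)
        total_counts += counts
        g_sum += normalize_histogram(counts, grid)
    return PairDistribution(grid, g_sum / len(complexes), total_counts)


@dataclass
class BoltzmannWeights:
    """Normalized pose probabilities exp(-E/kT)/Z for one complex."""

    weights: np.ndarray
    kT: float = 1.0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


def boltzmann_weights(scores, kT: float = 1.0) -> BoltzmannWeights:
    """Max-shifted softmin of pose energies (overflow-safe)."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if kT <= 0:
        raise ValueError("kT must be positive")
    shifted = -(scores - scores.min()) / kT
    w = np.exp(shifted)
    return BoltzmannWeights(w / w.sum(), kT)


def ensemble_distribution(per_pose_histograms, weights, grid: RadialGrid
                          ) -> PairDistribution:
    """Boltzmann-weighted pose-ensemble distribution, averaged over complexes.

    `per_pose_histograms` is one array (L, 20, 12, n_bins) per complex (raw
    counts per pose); `weights` is the matching BoltzmannWeights per complex.
    Per-pose histograms are normalized individually, weight-summed within a
    complex and averaged with weight 1/K across complexes.
    """
    if len(per_pose_histograms) != len(weights):
        raise ValueError("one weight vector per complex required")
    if not per_pose_histograms:
        raise ValueError("need at least one complex")
    g_sum = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
    for hists, bw in zip(per_pose_histograms, weights):
        w = bw.weights if isinstance(bw, BoltzmannWeights) else np.asarray(bw)
        hists = np.asarray(hists)
        if hists.shape[0] != len(w):
            raise ValueError("weight/pose length mismatch")
        g_poses = normalize_histogram(hists, grid)
        g_sum += np.tensordot(w, g_poses, axes=(0, 0))
    return PairDistribution(grid, g_sum / len(per_pose_histograms))


def distribution_to_frame(dist: PairDistribution):
    """Long-format export: pair_i, pair_j, r_center, g, counts."""
    import pandas as pd

    from .atom_types import PROTEIN_TYPES, RNA_TYPES
    rows = []
    counts = dist.raw_counts
    for i, pi in enumerate(PROTEIN_TYPES):
        for j, rj in enumerate(RNA_TYPES):
            if counts is not None and counts[i, j].sum() == 0 \
                    and not dist.g[i, j].any():
                continue
            for m, r in enumerate(dist.grid.centers):
                rows.append((pi, rj, r, dist.g[i, j, m],
                             0 if counts is None else int(counts[i, j, m])))
    return pd.DataFrame(rows, columns=["pair_i", "pair_j", "r_center",
                                       "g", "counts"])
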