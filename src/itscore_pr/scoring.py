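"""Pose scoring: the pair-potential binding score and the VDW-only score
used for decoy prefiltering.

Both scores sum over inter-molecular heavy-atom pairs strictly within the
10 A cutoff.  The pair-potential score additionally exposes the
interpolation-weight decomposition used by the derivation loop: for a rigid
pose the weights never change, so the score under any table u is the cached
tensor contraction sum(W * u) + n_core * penalty_cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atom_types import (N_PROTEIN_TYPES, N_RNA_TYPES, TypedStructure,
                         pairs_within)
from .potentials import PotentialTable, VdwParams, _interp_weights, vdw_energy


@dataclass
class PoseScore:
    total: float
    n_pairs_in_cutoff: int
    per_pair: np.ndarray | None = None  # optional (20, 12) breakdown


@dataclass
class ScoreWeights:
    """Cached interpolation weights of one rigid pose.

    score(u) = sum(W * u) + penalty_cap * sum(n_core[retained]).
    """

    W: np.ndarray        # (20, 12, n_active_bins)
    n_core: np.ndarray   # (20, 12) pairs below the first bin center
    n_pairs: int

    def score(self, table: PotentialTable) -> float:
        active = table.u[:, :, :table.n_active_bins]
        core = float(self.n_core[table.retained].sum())
        return float(np.vdot(self.W * table.retained[:, :, None], active)
                     + core * table.penalty_cap)


def pose_weights(protein: TypedStructure, rna: TypedStructure,
                 grid, r_cut: float = 10.0) -> ScoreWeights:
    """Interpolation weights of all typed pairs within the scoring cutoff."""
    pc, pcodes = protein.typed_coords()
    rc, rcodes = rna.typed_coords()
    n_active = int(round(r_cut / grid.bin_width))
    W = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, n_active))
    n_core = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES))
    if len(pc) == 0 or len(rc) == 0:
        return ScoreWeights(W, n_core, 0)
    ip, jr, d = pairs_within(pc, rc, r_cut)
    ic, jc = pcodes[ip], rcodes[jr]
    seg, w_lo, below, ramp_w = _interp_weights(d, grid, n_active)
    inside = seg >= 0
    s = seg[inside]
    np.add.at(W, (ic[inside], jc[inside], s), w_lo[inside])
    np.add.at(W, (ic[inside], jc[inside],
                  np.minimum(s + 1, n_active - 1)), 1.0 - w_lo[inside])
    tail = seg == -2
    np.add.at(W, (ic[tail], jc[tail], np.full(tail.sum(), n_active - 1)),
              ramp_w[tail])
    np.add.at(n_core, (ic[below], jc[below]), 1.0)
    return ScoreWeights(W, n_core, int(len(d)))


def score_pose(protein: TypedStructure, rna: TypedStructure,
               table: PotentialTable, breakdown: bool = False) -> PoseScore:
    """Pair-potential binding score of one pose.

    Sum of interpolated table energies over typed pairs within the cutoff;
    untyped atoms and unretained pairs contribute nothing.
    """
    if len(protein.structure) == 0 or len(rna.structure) == 0:
        raise ValueError("cannot score an empty structure")
    pc, pcodes = protein.typed_coords()
    rc, rcodes = rna.typed_coords()
    if len(pc) == 0 or len(rc) == 0:
        return PoseScore(0.0, 0)
    ip, jr, d = pairs_within(pc, rc, table.r_cut)
    e = table.evaluate_codes(pcodes[ip], rcodes[jr], d)
    per_pair = None
    if breakdown:
        per_pair = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES))
        np.add.at(per_pair, (pcodes[ip], rcodes[jr]), e)
    return PoseScore(float(e.sum()), int(len(d)), per_pair)


def score_vdw(protein: TypedStructure, rna: TypedStructure,
              params: VdwParams, cap: float = 100.0,
              r_cut: float = 10.0) -> float:
    """Sum of per-pair-capped 6-12 VDW energies within the cutoff."""
    if len(protein.structure) == 0 or len(rna.structure) == 0:
        raise ValueError("cannot score an empty structure")
    pc, pcodes = protein.typed_coords()
    rc, rcodes = rna.typed_coords()
    if len(pc) == 0 or len(rc) == 0:
        return 0.0
    rp, ep, rr, er = params.per_type_arrays()
    ip, jr, d = pairs_within(pc, rc, r_cut)
    if len(d) == 0:
        return 0.0
    r_ij = rp[pcodes[ip]] + rr[rcodes[jr]]
    eps_ij = np.sqrt(ep[pcodes[ip]] * er[rcodes[jr]])
    e = np.minimum(vdw_energy(d, r_ij, eps_ij), cap)
    return float(e.sum())
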