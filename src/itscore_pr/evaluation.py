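"""CAPRI-style quality assessment of predicted binding modes.

Three standard metrics compare a model pose with the native complex:
fnat (fraction of native residue-residue contacts recovered; a contact is a
residue pair whose nearest heavy atoms are within 5 A), the ligand RMSD
(RNA C4' RMSD after superposing the receptor Calpha traces) and the
interface RMSD (Calpha/C4' RMSD over the native interface residues after
superposing on exactly those atoms).  The CAPRI tiers combine them into
high / medium / acceptable / incorrect.  On top sit the ranking analytics:
greedy score-ordered clustering at 5 A RNA heavy-atom RMSD, top-N success
curves, and score-RMSD correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import pearsonr

from .atom_types import pairs_within
from .structure import Structure, rmsd_direct, superpose

CONTACT_CUTOFF = 5.0
INTERFACE_CUTOFF = 10.0
CLUSTER_RADIUS = 5.0

#: CAPRI thresholds (fnat, ligand RMSD, interface RMSD), protein-protein
#: convention; exposed so sensitivity checks can override them.
CAPRI_THRESHOLDS = {
    "high": dict(fnat=0.5, l_rmsd=1.0, i_rmsd=1.0),
    "medium": dict(fnat=0.3, l_rmsd=5.0, i_rmsd=2.0),
    "acceptable": dict(fnat=0.1, l_rmsd=10.0, i_rmsd=4.0),
}


class ComplexPose(NamedTuple):
    protein: Structure
    rna: Structure


@dataclass
class QualityMetrics:
    fnat: float
    l_rmsd: float
    i_rmsd: float
    capri_class: str

    def __post_init__(self):
        if not (0.0 <= self.fnat <= 1.0):
            raise ValueError("fnat must lie in [0, 1]")
        if self.l_rmsd < 0 or self.i_rmsd < 0:
            raise ValueError("RMSDs must be non-negative")


class UndefinedMetricError(ValueError):
    pass


def _residue_atom_index(s: Structure):
    """Map residue key -> atom index array."""
    index = {}
    for i, key in enumerate(s.residue_keys()):
        index.setdefault(key, []).append(i)
    return {k: np.asarray(v) for k, v in index.items()}


def residue_contacts(protein: Structure, rna: Structure,
                     cutoff: float = CONTACT_CUTOFF):
    """Set of (protein residue, RNA residue) pairs with nearest heavy atoms
    within `cutoff`."""
    ip, jr, _ = pairs_within(protein.coords, rna.coords, cutoff)
    pkeys = protein.residue_keys()
    rkeys = rna.residue_keys()
    return {(pkeys[i], rkeys[j]) for i, j in zip(ip, jr)}


def fnat(model: ComplexPose, native: ComplexPose) -> float:
    native_contacts = residue_contacts(native.protein, native.rna)
    if not native_contacts:
        raise UndefinedMetricError("native complex has no contacts")
    model_contacts = residue_contacts(model.protein, model.rna)
    return len(native_contacts & model_contacts) / len(native_contacts)


def _matched_coords(a: Structure, b: Structure, atom_name: str):
    """Coordinates of atoms named `atom_name` present in both structures,
    matched by residue identity."""
    sel_a = {k: a.coords[idx[0]] for k, idx in _residue_atom_index(
        a.subset(a.atom_names == atom_name)).items()}
    sel_b = {k: b.coords[idx[0]] for k, idx in _residue_atom_index(
        b.subset(b.atom_names == atom_name)).items()}
    shared = [k for k in sel_a if k in sel_b]
    ca = np.array([sel_a[k] for k in shared]).reshape(-1, 3)
    cb = np.array([sel_b[k] for k in shared]).reshape(-1, 3)
    return ca, cb, shared


def ligand_rmsd(model: ComplexPose, native: ComplexPose) -> float:
    """RNA C4' RMSD after optimal receptor Calpha superposition."""
    ca_nat, ca_mod, shared = _matched_coords(native.protein, model.protein, "CA")
    if len(shared) < 3:
        raise UndefinedMetricError("fewer than 3 shared receptor CA atoms")
    transform, _ = superpose(ca_nat, ca_mod)
    c4_nat, c4_mod, shared_rna = _matched_coords(native.rna, model.rna, "C4'")
    if not shared_rna:
        raise UndefinedMetricError("no shared RNA C4' atoms")
    return rmsd_direct(c4_nat, transform.apply(c4_mod))


def interface_residues(native: ComplexPose, cutoff: float = INTERFACE_CUTOFF):
    """Native residues of either partner with any heavy atom within `cutoff`
    of the other partner."""
    ip, jr, _ = pairs_within(native.protein.coords, native.rna.coords, cutoff)
    pkeys = native.protein.residue_keys()
    rkeys = native.rna.residue_keys()
    return ({pkeys[i] for i in ip}, {rkeys[j] for j in jr})


def interface_rmsd(model: ComplexPose, native: ComplexPose) -> float:
    """Calpha/C4' RMSD over native-interface residues, superposed on them."""
    prot_iface, rna_iface = interface_residues(native)
    if not prot_iface and not rna_iface:
        raise UndefinedMetricError("native interface is empty")
    ca_nat, ca_mod, shared_p = _matched_coords(native.protein, model.protein, "CA")
    c4_nat, c4_mod, shared_r = _matched_coords(native.rna, model.rna, "C4'")
    keep_p = [i for i, k in enumerate(shared_p) if k in prot_iface]
    keep_r = [i for i, k in enumerate(shared_r) if k in rna_iface]
    nat = np.vstack([ca_nat[keep_p].reshape(-1, 3),
                     c4_nat[keep_r].reshape(-1, 3)])
    mod = np.vstack([ca_mod[keep_p].reshape(-1, 3),
                     c4_mod[keep_r].reshape(-1, 3)])
    if len(nat) < 3:
        raise UndefinedMetricError("fewer than 3 interface anchor atoms")
    _, rmsd = superpose(nat, mod)
    return rmsd


def capri_class(fnat_value: float, l_rmsd: float, i_rmsd: float,
                thresholds=None) -> str:
    t = thresholds or CAPRI_THRESHOLDS
    h, m, a = t["high"], t["medium"], t["acceptable"]
    if fnat_value >= h["fnat"] and (l_rmsd <= h["l_rmsd"]
                                    or i_rmsd <= h["i_rmsd"]):
        return "high"
    if fnat_value >= m["fnat"] and (l_rmsd <= m["l_rmsd"]
                                    or i_rmsd <= m["i_rmsd"]):
        return "medium"
    if fnat_value >= a["fnat"] and (l_rmsd <= a["l_rmsd"]
                                    or i_rmsd <= a["i_rmsd"]):
        return "acceptable"
    return "incorrect"


def assess_pose(model: ComplexPose, native: ComplexPose) -> QualityMetrics:
    f = fnat(model, native)
    l = ligand_rmsd(model, native)
    i = interface_rmsd(model, native)
    return QualityMetrics(f, l, i, capri_class(f, l, i))


def cluster_ranked(scores, rna_coords_per_pose,
                   radius: float = CLUSTER_RADIUS):
    """Greedy sweep in ascending-score order; keep a pose iff its direct RNA
    heavy-atom RMSD to every kept pose is >= radius.  Returns kept pose
    indices in score order (the fixed protein frame, no re-superposition)."""
    scores = np.asarray(scores, dtype=np.float64)
    order = np.argsort(scores, kind="stable")
    kept = []
    for idx in order:
        coords = rna_coords_per_pose[idx]
        if all(rmsd_direct(coords, rna_coords_per_pose[k]) >= radius
               for k in kept):
            kept.append(int(idx))
    return kept


def success_curve(qualifying_ranks, top_n_max: int) -> np.ndarray:
    """success_rate(N) for N = 1..top_n_max.

    `qualifying_ranks` holds, per complex, the best (1-based) rank of a
    qualifying pose in its retained ranking, or None if no pose qualifies.
    """
    if top_n_max < 1:
        raise ValueError("top_n_max must be >= 1")
    ranks = np.array([np.inf if r is None else float(r)
                      for r in qualifying_ranks])
    n = np.arange(1, top_n_max + 1)
    return (ranks[None, :] <= n[:, None]).mean(axis=1)


def score_rmsd_correlation(scores, rmsds, thresholds=(5.0, 10.0, 20.0)):
    """Pearson r between score and RMSD among decoys with RMSD strictly
    below each threshold; None where fewer than 3 decoys qualify or the
    scores are degenerate."""
    scores = np.asarray(scores, dtype=np.float64)
    rmsds = np.asarray(rmsds, dtype=np.float64)
    out = {}
    for t in thresholds:
        mask = rmsds < t
        if mask.sum() < 3 or np.std(scores[mask]) == 0 \
                or np.std(rmsds[mask]) == 0:
            out[t] = None
            continue
        out[t] = float(pearsonr(scores[mask], rmsds[mask]).statistic)
    return out
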