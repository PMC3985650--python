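"""Atom typing: 20 protein + 12 RNA heavy-atom types and pair accounting.

The type alphabet groups chemically equivalent heavy atoms (e.g. all aromatic
ring carbons are one type) so that pair statistics pooled over a training set
are dense enough to support a distance-dependent potential per type pair.
Pairs too rare to yield reliable statistics are filtered out by occurrence
count and never receive a potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structure import PROTEIN, RNA, Structure

logger = logging.getLogger(__name__)

UNTYPED = -1

#: residue aliases normalized before lookup (protonation variants etc.)
_RESIDUE_ALIASES = {"HID": "HIS", "HIE": "HIS", "HIP": "HIS"}
#: legacy phosphate oxygen names
_ATOM_ALIASES = {"O1P": "OP1", "O2P": "OP2"}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_STANDARD_NT = {"A", "U", "G", "C"}

# Symbol order fixed by the published numbering; indices into count matrices.
PROTEIN_TYPES = ["C2+", "C2-", "C2M", "C2S", "Car", "C3C", "C3A", "C3X",
                 "N2N", "N2+", "N2X", "Nar", "N21", "N3+", "O2M", "O2S",
                 "O3H", "O2-", "S31", "S30"]
RNA_TYPES = ["C2X", "Car", "C3X", "N2N", "N2X", "Nar", "N21", "O2",
             "O31", "O32", "O2-", "P"]

N_PROTEIN_TYPES = len(PROTEIN_TYPES)
N_RNA_TYPES = len(RNA_TYPES)
N_PAIR_TYPES = N_PROTEIN_TYPES * N_RNA_TYPES  # 240


def _normalize_atom_name(name: str) -> str:
    name = name.strip().upper().replace("*", "'")
    return _ATOM_ALIASES.get(name, name)


def _normalize_residue(name: str) -> str:
    name = name.strip().upper()
    return _RESIDUE_ALIASES.get(name, name)


@dataclass
class AtomTypeTable:
    """(residue, atom name) -> type symbol maps with '*' wildcard rows."""

    protein_map: dict
    rna_map: dict

    @classmethod
    def default(cls) -> "AtomTypeTable":
        text = (resources.files("itscore_pr") / "data" / "atom_types.tsv").read_text()
        return cls.from_tsv_text(text)

    @classmethod
    def from_tsv_text(cls, text: str) -> "AtomTypeTable":
        pmap, rmap = {}, {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("kind\t"):
                continue
            kind, res, atom, sym = line.split("\t")
            key = (res.strip().upper(), _normalize_atom_name(atom))
            if kind == PROTEIN:
                pmap[key] = sym
            elif kind == RNA:
                rmap[key] = sym
            else:
                raise ValueError(f"unknown molecule kind in typing table: {kind!r}")
        table = cls(pmap, rmap)
        table._validate()
        return table

    def _validate(self):
        psyms = {s for s in self.protein_map.values()}
        rsyms = {s for s in self.rna_map.values()}
        if psyms != set(PROTEIN_TYPES):
            raise ValueError(f"protein typing table must cover exactly the "
                             f"{N_PROTEIN_TYPES} symbols; got {sorted(psyms)}")
        if rsyms != set(RNA_TYPES):
            raise ValueError(f"RNA typing table must cover exactly the "
                             f"{N_RNA_TYPES} symbols; got {sorted(rsyms)}")

    def lookup(self, kind: str, residue_name: str, atom_name: str):
        """Type symbol for one atom, or None if unmapped."""
        res = _normalize_residue(residue_name)
        atom = _normalize_atom_name(atom_name)
        if kind == PROTEIN:
            sym = self.protein_map.get((res, atom))
            if sym is None and res in _STANDARD_AA:
                sym = self.protein_map.get(("*", atom))
            return sym
        if kind == RNA:
            sym = self.rna_map.get((res, atom))
            if sym is None and res in _STANDARD_NT:
                sym = self.rna_map.get(("*", atom))
            return sym
        raise ValueError(f"unknown molecule kind: {kind!r}")

    def symbol_index(self, kind: str, symbol: str) -> int:
        types = PROTEIN_TYPES if kind == PROTEIN else RNA_TYPES
        return types.index(symbol)

    def pair_symbols(self):
        """All 240 enumerable (protein symbol, RNA symbol) pairs."""
        return [(p, r) for p in PROTEIN_TYPES for r in RNA_TYPES]


@dataclass
class TypedStructure:
    """A structure plus one integer type code per atom (UNTYPED = -1)."""

    structure: Structure
    type_codes: np.ndarray

    def __post_init__(self):
        self.type_codes = np.asarray(self.type_codes, dtype=np.int64)
        if len(self.type_codes) != len(self.structure):
            raise ValueError("one type code per atom required")

    @property
    def kind(self):
        return self.structure.kind

    def typed_mask(self) -> np.ndarray:
        return self.type_codes != UNTYPED

    def typed_coords(self):
        """(coords, codes) restricted to atoms that received a type."""
        m = self.typed_mask()
        return self.structure.coords[m], self.type_codes[m]

    def with_coords(self, coords) -> "TypedStructure":
        return TypedStructure(self.structure.with_coords(coords), self.type_codes)


def assign_types(s: Structure, table: AtomTypeTable | None = None) -> TypedStructure:
    """Annotate every atom with its type index; unmapped atoms get UNTYPED."""
    if table is None:
        table = AtomTypeTable.default()
    types = PROTEIN_TYPES if s.kind == PROTEIN else RNA_TYPES
    index = {sym: i for i, sym in enumerate(types)}
    codes = np.full(len(s), UNTYPED, dtype=np.int64)
    unmapped = []
    for i in range(len(s)):
        sym = table.lookup(s.kind, s.residue_names[i], s.atom_names[i])
        if sym is None:
            unmapped.append((s.residue_names[i], s.atom_names[i]))
        else:
            codes[i] = index[sym]
    if unmapped:
        logger.warning("%s: %d atoms left untyped (e.g. %s); they are "
                       "excluded from statistics and scoring",
                       s.id or s.kind, len(unmapped), unmapped[:3])
    return TypedStructure(s, codes)


@dataclass
class PairOccurrence:
    """Within-sphere occurrence counts per (protein type, RNA type) pair."""

    counts: np.ndarray
    retained: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_PROTEIN_TYPES, N_RNA_TYPES):
            raise ValueError("counts must be a 20x12 matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def count_pair_occurrences(complexes, r_sphere: float = 12.0) -> PairOccurrence:
    """Total protein-RNA pair count per type pair within the reference sphere.

    `complexes` is a sequence of (TypedStructure protein, TypedStructure rna)
    native complexes; distances strictly below `r_sphere` count.
    """
    if not complexes:
        raise ValueError("need at least one complex")
    counts = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES), dtype=np.int64)
    for tp, tr in complexes:
        pc, pcodes = tp.typed_coords()
        rc, rcodes = tr.typed_coords()
        if len(pc) == 0 or len(rc) == 0:
            continue
        ip, jr, _ = pairs_within(pc, rc, r_sphere)
        np.add.at(counts, (pcodes[ip], rcodes[jr]), 1)
    return PairOccurrence(counts)


def filter_pairs(occ: PairOccurrence, threshold: int = 1000) -> PairOccurrence:
    """Retain pairs with strictly more than `threshold` occurrences."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return PairOccurrence(occ.counts, retained=occ.counts > threshold)


def pairs_within(coords_a, coords_b, cutoff: float):
    """Indices and distances of inter-set pairs with distance < cutoff.

    KD-tree accelerated; contractually identical to the O(N^2) double loop
    (strict inequality at the cutoff).
    """
    coords_a = np.asarray(coords_a, dtype=np.float64)
    coords_b = np.asarray(coords_b, dtype=np.float64)
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    neighbor_lists = tree_a.query_ball_tree(tree_b, cutoff)
    ia = np.concatenate([np.full(len(lst), i, dtype=np.int64)
                         for i, lst in enumerate(neighbor_lists)]) \
        if neighbor_lists else np.empty(0, dtype=np.int64)
    jb = np.concatenate([np.asarray(lst, dtype=np.int64)
                         for lst in neighbor_lists]) \
        if neighbor_lists else np.empty(0, dtype=np.int64)
    if ia.size == 0:
        return ia, jb, np.empty(0, dtype=np.float64)
    d = np.linalg.norm(coords_a[ia] - coords_b[jb], axis=1)
    keep = d < cutoff  # query_ball_tree is <=; the contract is strict
    return ia[keep], jb[keep], d[keep]
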