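"""Binned pair potentials: initialization (6-12 VDW + PMF), smoothing,
capping, lookup and TSV round-trip.

The potential table holds one energy per 0.2 A bin per retained type pair.
Energies are zero at and beyond the 10 A scoring cutoff, capped at a
short-range penalty (100 by default, 10 in the soft mode used for unbound
docking), and evaluated by piecewise-linear interpolation between bin
centers with a linear ramp to zero at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .atom_types import (N_PROTEIN_TYPES, N_RNA_TYPES, PROTEIN_TYPES,
                         RNA_TYPES)
from .pair_statistics import PairDistribution, RadialGrid

DEFAULT_PENALTY_CAP = 100.0
SOFT_PENALTY_CAP = 10.0
DEFAULT_R_CUT = 10.0


@dataclass
class VdwParams:
    """Per-type 6-12 parameters; R_ij = R_i + R_j, eps_ij = sqrt(eps_i eps_j)."""

    radius: dict
    well_depth: dict

    def __post_init__(self):
        for sym, r in self.radius.items():
            if r <= 0:
                raise ValueError(f"radius of {sym} must be positive")
        for sym, e in self.well_depth.items():
            if e < 0:
                raise ValueError(f"well depth of {sym} must be non-negative")

    @classmethod
    def default(cls) -> "VdwParams":
        text = (resources.files("itscore_pr") / "data" / "vdw_params.tsv").read_text()
        return cls.from_tsv_text(text)

    @classmethod
    def from_tsv_text(cls, text: str) -> "VdwParams":
        radius, depth = {}, {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("symbol\t"):
                continue
            sym, r, e = line.split("\t")
            radius[sym] = float(r)
            depth[sym] = float(e)
        return cls(radius, depth)

    def pair_params(self, protein_symbol: str, rna_symbol: str):
        r = self.radius[protein_symbol] + self.radius[rna_symbol]
        e = float(np.sqrt(self.well_depth[protein_symbol]
                          * self.well_depth[rna_symbol]))
        return r, e

    def per_type_arrays(self):
        """(R, eps) arrays indexed by protein / RNA type code."""
        rp = np.array([self.radius[s] for s in PROTEIN_TYPES])
        ep = np.array([self.well_depth[s] for s in PROTEIN_TYPES])
        rr = np.array([self.radius[s] for s in RNA_TYPES])
        er = np.array([self.well_depth[s] for s in RNA_TYPES])
        return rp, ep, rr, er


def vdw_energy(r, r_ij, eps_ij):
    """6-12 potential eps*[(R/r)^12 - 2 (R/r)^6]; minimum -eps at r = R."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    q = (r_ij / r) ** 6
    return eps_ij * (q * q - 2.0 * q)


class PotentialTable:
    """Per-pair binned energies u(r) with cutoff and short-range cap."""

    def __init__(self, grid: RadialGrid, u: np.ndarray,
                 penalty_cap: float = DEFAULT_PENALTY_CAP,
                 r_cut: float = DEFAULT_R_CUT,
                 retained: np.ndarray | None = None):
        self.grid = grid
        self.penalty_cap = float(penalty_cap)
        self.r_cut = float(r_cut)
        n_cut = self.r_cut / grid.bin_width
        if abs(n_cut - round(n_cut)) > 1e-9:
            raise ValueError("r_cut must fall on a bin edge")
        self.n_active_bins = int(round(n_cut))
        if retained is None:
            retained = np.ones((N_PROTEIN_TYPES, N_RNA_TYPES), dtype=bool)
        self.retained = np.asarray(retained, dtype=bool)
        self.u = self._conform(np.asarray(u, dtype=np.float64))

    def _conform(self, u: np.ndarray) -> np.ndarray:
        expected = (N_PROTEIN_TYPES, N_RNA_TYPES, self.grid.n_bins)
        if u.shape != expected:
            raise ValueError(f"u must have shape {expected}, got {u.shape}")
        u = np.minimum(u, self.penalty_cap)
        u[:, :, self.n_active_bins:] = 0.0   # zero at and beyond r_cut
        u[~self.retained, :] = 0.0           # unretained pairs score zero
        return u

    def with_u(self, u: np.ndarray) -> "PotentialTable":
        return PotentialTable(self.grid, u, self.penalty_cap, self.r_cut,
                              self.retained)

    @classmethod
    def zeros(cls, grid: RadialGrid, **kw) -> "PotentialTable":
        u = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
        return cls(grid, u, **kw)

    def evaluate(self, protein_symbol: str, rna_symbol: str, r: float) -> float:
        """Energy at distance r for one named type pair."""
        try:
            i = PROTEIN_TYPES.index(protein_symbol)
            j = RNA_TYPES.index(rna_symbol)
        except ValueError:
            raise ValueError(f"unknown pair symbol "
                             f"({protein_symbol}, {rna_symbol})") from None
        return float(self.evaluate_codes(np.array([i]), np.array([j]),
                                         np.array([float(r)]))[0])

    def evaluate_codes(self, icodes, jcodes, r) -> np.ndarray:
        """Vectorized lookup by type codes.

        Piecewise-linear between bin centers; below the first center the
        penalty cap applies, between the last active center and r_cut the
        value ramps linearly to 0, and beyond r_cut it is 0.  Unretained
        pairs are 0 everywhere.
        """
        r = np.asarray(r, dtype=np.float64)
        if np.any(r < 0):
            raise ValueError("r must be non-negative")
        seg, w_lo, below, ramp_w = _interp_weights(r, self.grid,
                                                   self.n_active_bins)
        out = np.zeros_like(r, dtype=np.float64)
        u = self.u
        inside = seg >= 0
        s = seg[inside]
        out[inside] = (w_lo[inside] * u[icodes[inside], jcodes[inside], s]
                       + (1.0 - w_lo[inside])
                       * u[icodes[inside], jcodes[inside],
                           np.minimum(s + 1, self.grid.n_bins - 1)])
        tail = seg == -2
        out[tail] = ramp_w[tail] * u[icodes[tail], jcodes[tail],
                                     self.n_active_bins - 1]
        out[below] = self.penalty_cap
        out[~self.retained[icodes, jcodes]] = 0.0
        return out


def _interp_weights(r, grid: RadialGrid, n_active: int):
    """Decompose distances into interpolation segments.

    Returns (seg, w_lo, below, ramp_w): seg >= 0 means linear interpolation
    between centers seg and seg+1 with weight w_lo on seg; seg == -2 means
    the terminal ramp [last active center, r_cut) with weight ramp_w on the
    last active bin; seg == -1 otherwise.  `below` marks r below the first
    bin center (penalty cap); r >= r_cut contributes nothing.
    """
    r = np.asarray(r, dtype=np.float64)
    dr = grid.bin_width
    c0 = dr / 2.0
    last_center = (n_active - 0.5) * dr
    r_cut = n_active * dr
    seg = np.full(r.shape, -1, dtype=np.int64)
    w_lo = np.zeros_like(r)
    ramp_w = np.zeros_like(r)
    below = r < c0
    mid = (r >= c0) & (r < last_center)
    s = np.floor((r - c0) / dr).astype(np.int64)
    s = np.clip(s, 0, n_active - 2) if n_active >= 2 else np.zeros_like(s)
    frac = (r - (c0 + s * dr)) / dr
    seg[mid] = s[mid]
    w_lo[mid] = 1.0 - frac[mid]
    tail = (r >= last_center) & (r < r_cut)
    seg[tail] = -2
    ramp_w[tail] = (r_cut - r[tail]) / (r_cut - last_center)
    return seg, w_lo, below, ramp_w


def pmf_reference(complexes, grid: RadialGrid) -> PairDistribution:
    """Type-agnostic reference: pool all pair types into one distribution.

    This is the classic 'randomly mixed atoms' reference state; every pair
    type receives the same pooled g(r).
    """
    from .pair_statistics import complex_histogram, normalize_histogram
    if not complexes:
        raise ValueError("need at least one complex")
    pooled = np.zeros(grid.n_bins, dtype=np.int64)
    for tp, tr in complexes:
        pooled += complex_histogram(tp, tr, grid).sum(axis=(0, 1))
    g_pooled = normalize_histogram(pooled, grid)
    g = np.broadcast_to(g_pooled, (N_PROTEIN_TYPES, N_RNA_TYPES,
                                   grid.n_bins)).copy()
    return PairDistribution(grid, g)


def pmf_potential(g_obs: PairDistribution, g_ref: PairDistribution,
                  kT: float = 1.0,
                  penalty_cap: float = DEFAULT_PENALTY_CAP) -> np.ndarray:
    """u = -kT ln(g_obs/g_ref) where both positive.

    Bins with g_ref = 0 carry no information and get 0.  Bins with
    g_obs = 0 below the first populated bin of that pair are treated as the
    repulsive core and get the penalty cap; empty bins above it get 0.
    """
    if not g_obs.grid.compatible(g_ref.grid):
        raise ValueError("grid mismatch between observed and reference g")
    go, gr = g_obs.g, g_ref.g
    u = np.zeros_like(go)
    both = (go > 0) & (gr > 0)
    u[both] = -kT * np.log(go[both] / gr[both])
    populated = go > 0
    any_pop = populated.any(axis=-1)
    first_pop = np.where(any_pop, populated.argmax(axis=-1), 0)
    bins = np.arange(go.shape[-1])
    core = (~populated) & (bins < first_pop[..., None]) & any_pop[..., None]
    u[core] = penalty_cap
    return u


def initial_potentials(vdw: VdwParams, pmf: np.ndarray, grid: RadialGrid,
                       penalty_cap: float = DEFAULT_PENALTY_CAP,
                       r_cut: float = DEFAULT_R_CUT,
                       retained=None) -> PotentialTable:
    """u0 = 6-12 VDW at bin centers + PMF, capped and zeroed beyond r_cut.

    Bins the PMF marked as forbidden core (at the penalty cap) are pinned
    exactly at the cap -- the wall is an assigned penalty, not a term the
    VDW contribution should perturb.
    """
    rp, ep, rr, er = vdw.per_type_arrays()
    r_ij = rp[:, None] + rr[None, :]
    eps_ij = np.sqrt(ep[:, None] * er[None, :])
    centers = grid.centers
    u_vdw = vdw_energy(centers[None, None, :], r_ij[..., None],
                       eps_ij[..., None])
    u = u_vdw + pmf
    u[pmf >= penalty_cap] = penalty_cap
    return PotentialTable(grid, u, penalty_cap, r_cut, retained)


def smooth_vector(values: np.ndarray) -> np.ndarray:
    """1:2:4:2:1 weighted moving average; boundary kernels truncated and
    renormalized over the available bins."""
    v = np.asarray(values, dtype=np.float64)
    if v.shape[-1] < 1:
        raise ValueError("need at least one bin")
    kernel = np.array([1.0, 2.0, 4.0, 2.0, 1.0])
    n = v.shape[-1]
    out = np.zeros_like(v)
    norm = np.zeros(n)
    for k, w in zip(range(-2, 3), kernel):
        lo_src, hi_src = max(0, -k), min(n, n - k)
        lo_dst = max(0, k)
        hi_dst = lo_dst + (hi_src - lo_src)
        out[..., lo_src:hi_src] += w * v[..., lo_dst:hi_dst]
        norm[lo_src:hi_src] += w
    return out / norm


def smooth(table: PotentialTable) -> PotentialTable:
    """Smooth the statistically estimated bins of every retained pair once.

    The kernel damps statistical fluctuation, so it runs over the window of
    estimated energies only: the contiguous short-range head pinned at the
    penalty cap (an artificial clash wall, not an estimate) and the hard
    zero beyond the cutoff both act as window boundaries and are neither
    changed nor blended into their neighbors; at the window edges the
    kernel is truncated and renormalized.
    """
    n = table.n_active_bins
    u = table.u.copy()
    for i, j in np.argwhere(table.retained):
        head = 0
        while head < n and u[i, j, head] == table.penalty_cap:
            head += 1
        if head < n:
            u[i, j, head:n] = smooth_vector(u[i, j, head:n])
    return table.with_u(u)


# ---------------------------------------------------------------------------
# TSV round-trip (bit-exact: floats serialized with repr round-tripping)

def write_potentials(path, table: PotentialTable) -> None:
    with open(path, "w") as fh:
        fh.write("# itscore-pr potential table\n")
        fh.write(f"# bin_width\t{table.grid.bin_width!r}\n")
        fh.write(f"# r_max\t{table.grid.r_max!r}\n")
        fh.write(f"# r_cut\t{table.r_cut!r}\n")
        fh.write(f"# penalty_cap\t{table.penalty_cap!r}\n")
        fh.write("pair_i\tpair_j\tr_center\tu\n")
        centers = table.grid.centers
        for i, pi in enumerate(PROTEIN_TYPES):
            for j, rj in enumerate(RNA_TYPES):
                if not table.retained[i, j]:
                    continue
                for m in range(table.grid.n_bins):
                    fh.write(f"{pi}\t{rj}\t{float(centers[m])!r}\t"
                             f"{float(table.u[i, j, m])!r}\n")


def read_potentials(path) -> PotentialTable:
    meta = {}
    u = None
    retained = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES), dtype=bool)
    pidx = {s: i for i, s in enumerate(PROTEIN_TYPES)}
    ridx = {s: i for i, s in enumerate(RNA_TYPES)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    meta[parts[0]] = float(parts[1])
                continue
            if line.startswith("pair_i\t") or not line.strip():
                if u is None:
                    grid = RadialGrid(meta["bin_width"], meta["r_max"])
                    u = np.zeros((N_PROTEIN_TYPES, N_RNA_TYPES, grid.n_bins))
                continue
            try:
                pi, rj, r_center, val = line.split("\t")
                i, j = pidx[pi], ridx[rj]
                m = int(round(float(r_center) / meta["bin_width"] - 0.5))
                u[i, j, m] = float(val)
                retained[i, j] = True
            except (ValueError, KeyError) as exc:
                raise ValueError(
                    f"{path}: malformed potential record at line {lineno}: "
                    f"{line!r}") from exc
    if u is None:
        raise ValueError(f"{path}: no potential records found")
    grid = RadialGrid(meta["bin_width"], meta["r_max"])
    return PotentialTable(grid, u, meta.get("penalty_cap", DEFAULT_PENALTY_CAP),
                          meta.get("r_cut", DEFAULT_R_CUT), retained)
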