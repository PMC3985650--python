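"""Rigid-body pose refinement by derivative-free simplex minimization.

A pose is parameterized by six numbers: a translation (A) and an axis-angle
rotation (radians) about the centroid of the starting RNA pose.  The
objective is either the capped 6-12 VDW score (used to relieve atomic
clashes in sampled binding modes before training) or the pair-potential
score (used to locally polish scored decoys).  Nelder-Mead with the
starting pose as a simplex vertex guarantees the returned energy never
exceeds the starting energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .atom_types import TypedStructure
from .potentials import PotentialTable, VdwParams
from .scoring import score_pose, score_vdw
from .structure import RigidTransform


@dataclass
class RefinementConfig:
    objective: str = "vdw"          # "vdw" or "itscore"
    trans_step: float = 1.0         # A, initial simplex step per translation
    rot_step_deg: float = 5.0       # deg, initial simplex step per rotation
    ftol: float = 1e-4              # convergence tolerance on the objective
    max_evals: int = 2000
    vdw_cap: float = 100.0

    def __post_init__(self):
        if self.objective not in ("vdw", "itscore"):
            raise ValueError("objective must be 'vdw' or 'itscore'")
        if self.trans_step <= 0 or self.rot_step_deg <= 0 or self.ftol <= 0:
            raise ValueError("steps and tolerance must be positive")


def _delta_transform(x, center):
    """Rigid transform rotating by axis-angle x[3:] about `center`, then
    translating by x[:3]."""
    R = Rotation.from_rotvec(x[3:]).as_matrix()
    t = np.asarray(x[:3]) + center - R @ center
    return RigidTransform(R, t)


def refine_pose(protein: TypedStructure, rna: TypedStructure,
                start: RigidTransform, cfg: RefinementConfig,
                table_or_params):
    """Locally minimize the objective over the 6 rigid-body parameters.

    `rna` carries the reference (native-frame) coordinates; `start` is the
    pose being refined.  Returns (refined RigidTransform, final energy).
    Deterministic for fixed inputs.
    """
    if cfg.objective == "vdw":
        if not isinstance(table_or_params, VdwParams):
            raise TypeError("VDW objective requires VdwParams")
        params = table_or_params

        def objective_for(pose_rna):
            return score_vdw(protein, pose_rna, params, cfg.vdw_cap)
    else:
        if not isinstance(table_or_params, PotentialTable):
            raise TypeError("itscore objective requires a PotentialTable")
        table = table_or_params

        def objective_for(pose_rna):
            return score_pose(protein, pose_rna, table).total

    start_coords = start.apply(rna.structure.coords)
    center = start_coords.mean(axis=0)

    def objective(x):
        delta = _delta_transform(x, center)
        pose = rna.with_coords(delta.apply(start_coords))
        return objective_for(pose)

    x0 = np.zeros(6)
    e0 = objective(x0)
    if not np.isfinite(e0):
        raise ValueError("objective is non-finite at the starting pose")
    rot_step = np.deg2rad(cfg.rot_step_deg)
    x_best, e_best = x0, e0
    # severely clashed starts sit on the flat capped-energy plateau, where
    # the initial simplex sees no gradient; deterministic step doubling
    # widens the simplex until it straddles the plateau edge
    for scale in (1.0, 2.0, 4.0):
        simplex = [x_best]
        for i in range(6):
            v = x_best.copy()
            v[i] += scale * (cfg.trans_step if i < 3 else rot_step)
            simplex.append(v)
        res = minimize(objective, x_best, method="Nelder-Mead",
                       options={"initial_simplex": np.array(simplex),
                                "fatol": cfg.ftol, "xatol": 1e-6,
                                "maxfev": cfg.max_evals, "disp": False})
        if float(res.fun) < e_best:
            x_best, e_best = res.x, float(res.fun)
            break
    if e_best > e0:  # Nelder-Mead keeps the best vertex; guard regardless
        x_best, e_best = x0, e0
    delta = _delta_transform(x_best, center)
    return delta.compose(start), e_best


def build_training_ensemble_entry(protein: TypedStructure,
                                  rna_native: TypedStructure,
                                  candidates, params: VdwParams,
                                  cfg: RefinementConfig | None = None,
                                  top_n: int = 1000, label: str = ""):
    """VDW-refine candidate poses, rank by VDW score, keep the top
    ``min(top_n, available)`` and append the (unrefined) native.

    Returns a TrainingComplex (native = pose 0, then the ranked decoys)
    together with the ranked VDW scores.
    """
    from .derivation import TrainingComplex
    if not candidates:
        raise ValueError("need at least one candidate pose")
    cfg = cfg or RefinementConfig(objective="vdw")
    refined = [refine_pose(protein, rna_native, t, cfg, params)
               for t in candidates]
    order = np.argsort([e for _, e in refined], kind="stable")[:top_n]
    decoys = [refined[i][0] for i in order]
    scores = [refined[i][1] for i in order]
    return TrainingComplex(protein, rna_native, decoys, label), scores
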