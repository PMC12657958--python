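"""Early-stage target: distance glidepaths and harmonic-amplitude refinement.

Close pairs of non-hydrogen atoms are assigned a linear "glidepath"
d_q(p) = d0 + p (d1 - d0) between their start and end distances.  The
early-stage target is a weighted least-squares functional of the deviation
of the calculated distances d_p from their glidepaths, integrated over
progress:

    J_early = sqrt( sum_pairs  int_0^1  w_ij (d_q - d_p)^2 dp ),
    w_ij = 1 / (1 + d_p)

The weight upweights close contacts.  The integral is evaluated by the
trapezoid rule on the 12-interval progress grid (the integrand vanishes at
both endpoints by construction).  Harmonic amplitudes are refined against
J_early by a staged quasi-Newton (L-BFGS) schedule: first f1 for every
torsion, then (f1, f2), then (f1, f2, f3), each stage iterated to a 1e-3
absolute convergence tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .path import PathState, ProgressGrid
from .structure import ConformerPair

logger = logging.getLogger(__name__)

MIN_BOND_SEPARATION = 4  # pairs closer than this many bonds are excluded


@dataclass(frozen=True)
class DistancePair:
    """One close pair's glidepath definition (convenience view)."""

    i: int
    j: int
    d0: float
    d1: float

    def glidepath(self, p):
        return self.d0 + np.asarray(p) * (self.d1 - self.d0)


class PairTable:
    """Vectorised list of close pairs with start/end distances."""

    def __init__(self, i, j, d0, d1):
        self.i = np.asarray(i, dtype=int)
        self.j = np.asarray(j, dtype=int)
        self.d0 = np.asarray(d0, dtype=float)
        self.d1 = np.asarray(d1, dtype=float)

    def __len__(self) -> int:
        return len(self.i)

    def __getitem__(self, k: int) -> DistancePair:
        return DistancePair(int(self.i[k]), int(self.j[k]),
                            float(self.d0[k]), float(self.d1[k]))

    def distances(self, coords: np.ndarray) -> np.ndarray:
        """Calculated pair distances; coords (..., n_atoms, 3)."""
        diff = coords[..., self.i, :] - coords[..., self.j, :]
        return np.linalg.norm(diff, axis=-1)

    def subset(self, mask: np.ndarray) -> "PairTable":
        return PairTable(self.i[mask], self.j[mask],
                         self.d0[mask], self.d1[mask])


def select_pairs(pair: ConformerPair, cutoff: float = 8.0,
                 include_hydrogens: bool = False) -> PairTable:
    """Build the close-pair table for the early (or late) stage target.

    A pair qualifies if either its start or end distance is below
    ``cutoff``, the atoms are separated by more than three bonds, and the
    two atoms do not belong to the same aromatic ring.  Hydrogens are
    excluded from the early-stage table (they ride on heavier atoms and add
    no degrees of freedom) but included in the late-stage one.  The list is
    deterministic: sorted by (i, j).
    """
    s = pair.structure
    if include_hydrogens:
        atoms = np.arange(s.n_atoms)
    else:
        atoms = np.nonzero(~s.is_hydrogen)[0]
    cand: set[tuple[int, int]] = set()
    for coords in (pair.start_coords, pair.end_coords):
        tree = cKDTree(coords[atoms])
        for a, b in tree.query_pairs(cutoff):
            i, j = int(atoms[a]), int(atoms[b])
            cand.add((min(i, j), max(i, j)))
    within3 = pair.topology.neighbors_within3()
    ring = pair.topology.aromatic_ring_id
    sel = []
    for i, j in sorted(cand):
        if j in within3[i]:
            continue
        if ring[i] >= 0 and ring[i] == ring[j]:
            continue
        sel.append((i, j))
    if not sel:
        return PairTable([], [], [], [])
    ii = np.array([t[0] for t in sel])
    jj = np.array([t[1] for t in sel])
    d0 = np.linalg.norm(pair.start_coords[ii] - pair.start_coords[jj],
                        axis=-1)
    d1 = np.linalg.norm(pair.end_coords[ii] - pair.end_coords[jj], axis=-1)
    return PairTable(ii, jj, d0, d1)


def j_early(path: PathState, pairs: PairTable,
            grid: ProgressGrid | None = None) -> float:
    """Evaluate the early-stage target for the current path parameters."""
    if len(pairs) == 0:
        return 0.0
    grid = grid if grid is not None else path.grid
    frames = path.frames(grid.points, superpose_frames=False)
    d_p = pairs.distances(frames)                       # (n_p, n_pairs)
    d_q = pairs.d0[None, :] + grid.points[:, None] * (
        pairs.d1 - pairs.d0)[None, :]
    w = 1.0 / (1.0 + d_p)
    integrand = np.sum(w * (d_q - d_p) ** 2, axis=1)
    total = np.trapezoid(integrand, grid.points)
    if not np.isfinite(total):
        k = int(np.nanargmax(np.abs(w * (d_q - d_p) ** 2).max(axis=0)))
        raise FloatingPointError(
            f"non-finite early-stage target; worst pair atoms "
            f"({int(pairs.i[k])}, {int(pairs.j[k])})")
    return float(np.sqrt(total))


def refine_early(
    path: PathState,
    pairs: PairTable,
    grid: ProgressGrid | None = None,
    tol: float = 1e-3,
    max_cycles: int = 40,
    lbfgs_maxiter: int = 25,
) -> dict:
    """Staged L-BFGS refinement of harmonic amplitudes against J_early.

    Stages activate amplitude sets {f1}, {f1, f2}, {f1, f2, f3} across all
    torsion channels jointly; each stage repeats L-BFGS cycles until the
    target changes by less than ``tol`` (absolute).  The refinement never
    increases the target: the best parameters seen are always kept.

    Returns a report dict with the target value before/after each stage.
    """
    grid = grid if grid is not None else path.grid
    n_t = path.n_torsions
    report = {"initial": j_early(path, pairs, grid), "stages": []}
    best_amps = path.amplitude_matrix()
    best_j = report["initial"]

    for stage in (1, 2, 3):
        active = stage  # number of active amplitude orders

        def objective(x, active=active):
            amps = path.amplitude_matrix()
            amps[:, :active] = x.reshape(n_t, active)
            path.set_amplitudes(amps)
            return j_early(path, pairs, grid)

        prev = best_j
        for _ in range(max_cycles):
            x0 = best_amps[:, :active].ravel()
            res = minimize(objective, x0, method="L-BFGS-B",
                           options={"maxiter": lbfgs_maxiter})
            if res.fun < best_j:
                best_j = float(res.fun)
                amps = path.amplitude_matrix()
                amps[:, :active] = res.x.reshape(n_t, active)
                best_amps = amps
            if abs(prev - best_j) < tol:
                break
            prev = best_j
        path.set_amplitudes(best_amps)
        report["stages"].append({"order": stage, "j_early": best_j})
        logger.info("early stage %d: J_early = %.6f", stage, best_j)
    report["final"] = best_j
    return report
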