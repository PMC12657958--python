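"""Late-stage target: thresholded van der Waals clashes + torsion energies.

The early-stage target does not sufficiently penalise close clashes, so a
second energy is evaluated once directions and harmonics are roughly set:

    J_late = J_VdW + J_torsion

J_VdW uses a two-term Lennard-Jones potential evaluated both at the
glidepath distance d_q (the reference) and the calculated distance d_p;
only the positive excess VdW(d_p) - VdW(d_q) counts, so pre-existing
contacts (e.g. hydrogen bonds) are not penalised.  Because atoms can pass
closest to each other *between* integration grid points, each interval's
contribution uses the minimum inter-atomic distance of cubic interpolants
through four consecutive frames of each atom's track.

J_torsion sums, over every central bond and every torsion angle centred on
it, a bell-curve eclipse penalty E(t) = z_T (1 + (t/60)^2)^-3 where z_T
combines the atomic numbers of the two terminal atoms.

Sidechain clashes are resolved by per-residue Nelder-Mead simplex descents
over the harmonic amplitudes of torsions that move only sidechain atoms,
followed by a joint descent for the five residues with the highest energy
attribution, repeated until J_late no longer drops by more than 5%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .early import PairTable, select_pairs
from .path import PathState, ProgressGrid
from .structure import ConformerPair

logger = logging.getLogger(__name__)

SIGMA_SCALE = 0.75       # sigma^i = 0.75 x van der Waals radius
BELL_WIDTH = 60.0        # deg
SPLINE_SAMPLES = 33      # per-interval samples of the cubic interpolant
SPLINE_RISK_FACTOR = 1.5  # screen: spline-refine pairs possibly dipping
SPLINE_SAFETY = 0.5      # A, margin for interpolant overshoot


@dataclass
class VdWParams:
    """Lennard-Jones parameters: uniform well depth, scaled Bondi radii."""

    epsilon: float = 1.0
    pair_cutoff: float = 8.0


@dataclass
class TorsionEnergyParams:
    sigma_bell: float = BELL_WIDTH


@dataclass
class LateTarget:
    """Late-stage energy breakdown with per-residue attribution."""

    j_vdw: float
    j_torsion: float
    per_residue: dict = field(default_factory=dict)

    @property
    def value(self) -> float:
        return self.j_vdw + self.j_torsion


def lj(d, sigma, epsilon=1.0):
    """Two-term Lennard-Jones potential 4 eps ((s/d)^12 - (s/d)^6)."""
    x = (np.asarray(sigma) / np.asarray(d)) ** 6
    return 4.0 * epsilon * (x * x - x)


def pair_sigma(structure, i, j) -> float:
    """Combined sigma: arithmetic mean of the two scaled vdW radii."""
    return SIGMA_SCALE * 0.5 * (
        structure.vdw_radii[i] + structure.vdw_radii[j])


def vdw_pair_term(path: PathState, i: int, j: int, p: float,
                  params: VdWParams | None = None) -> float:
    """Instantaneous thresholded VdW excess for one atom pair at progress p.

    The glidepath reference distance interpolates the endpoint distances
    linearly; the calculated distance comes from the reconstructed frame.
    """
    params = params if params is not None else VdWParams()
    s = path.pair.structure
    d0 = float(np.linalg.norm(path.pair.start_coords[i]
                              - path.pair.start_coords[j]))
    d1 = float(np.linalg.norm(path.pair.end_coords[i]
                              - path.pair.end_coords[j]))
    frame = path.reconstruct_frame(p, superpose_frame=False)
    d_p = float(np.linalg.norm(frame[i] - frame[j]))
    if d_p == 0.0:
        raise ZeroDivisionError(f"coincident atoms {i}, {j} at p={p}")
    d_q = d0 + p * (d1 - d0)
    sig = pair_sigma(s, i, j)
    excess = lj(d_p, sig, params.epsilon) - lj(d_q, sig, params.epsilon)
    return float(max(excess, 0.0))


def torsion_energy(t_degrees, z_t, sigma_bell: float = BELL_WIDTH):
    """Bell-curve torsion eclipse energy E(t) = z_T (1 + (t/sigma)^2)^-3."""
    t = np.asarray(t_degrees, dtype=float)
    return z_t * (1.0 + (t / sigma_bell) ** 2) ** -3


# ---------------------------------------------------------------------------
# Torsion-combo table


class TorsionComboTable:
    """All torsion angles centred on every bond, as azimuth offsets.

    Because bond lengths and angles never change, every torsion centred on a
    bond differs from the bond's canonical torsion value by a constant
    offset; rigid (non-rotatable) bonds contribute constant angles.
    """

    def __init__(self, pair: ConformerPair):
        from .geometry import dihedral

        topo = pair.topology
        s = pair.structure
        g = topo.graph
        torsion_of_bond = {frozenset(t.bond): k
                           for k, t in enumerate(topo.rotatable_torsions)}
        base, z_t, channel, bond_atoms = [], [], [], []
        coords = pair.start_coords
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            nu = [x for x in g[u] if x != v]
            nv = [x for x in g[v] if x != u]
            if not nu or not nv:
                continue
            k = torsion_of_bond.get(frozenset((u, v)), -1)
            if k >= 0:
                ref = pair.start_torsions[k]
            for a in nu:
                for b in nv:
                    d = dihedral(coords[a], coords[u], coords[v], coords[b])
                    base.append(d - (ref if k >= 0 else 0.0))
                    z_t.append(np.hypot(s.atomic_numbers[a],
                                        s.atomic_numbers[b]))
                    channel.append(k)
                    bond_atoms.append((u, v))
        self.base = np.array(base)          # offset, or absolute if rigid
        self.z_t = np.array(z_t)
        self.channel = np.array(channel, dtype=int)
        self.bond_atoms = bond_atoms
        self.n = len(base)

    def values(self, torsion_matrix: np.ndarray) -> np.ndarray:
        """Torsion angles (wrapped) for all combos; input (n_p, n_channels)."""
        n_p = torsion_matrix.shape[0]
        t = np.broadcast_to(self.base, (n_p, self.n)).copy()
        governed = self.channel >= 0
        t[:, governed] += torsion_matrix[:, self.channel[governed]]
        return (t + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# Spline-corrected minimum distances


def _lagrange_weights(xs: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """Weights (n_samples, 4) of the cubic through nodes xs at samples."""
    w = np.empty((len(samples), len(xs)))
    for k in range(len(xs)):
        num = np.ones_like(samples)
        den = 1.0
        for m in range(len(xs)):
            if m == k:
                continue
            num = num * (samples - xs[m])
            den = den * (xs[k] - xs[m])
        w[:, k] = num / den
    return w


def _interval_window(n: int, n_steps: int) -> list[int]:
    lo = min(max(n - 1, 0), n_steps - 3)
    return [lo, lo + 1, lo + 2, lo + 3]


def spline_min_distance(path: PathState, i: int, j: int, interval: int,
                        frames: np.ndarray | None = None,
                        n_samples: int = SPLINE_SAMPLES
                        ) -> tuple[float, float]:
    """Minimum distance between atoms i and j within one grid interval.

    Each atom's track is interpolated by the cubic through its positions at
    four consecutive grid frames (window shifted inward at the path ends);
    the distance is minimised over the fractional sub-interval.  Returns
    (min_distance, p_at_min).
    """
    grid = path.grid
    if frames is None:
        frames = path.grid_frames(superpose_frames=True)
    window = _interval_window(interval, grid.n_steps)
    xs = grid.points[window]
    samples = np.linspace(grid.points[interval], grid.points[interval + 1],
                          n_samples)
    w = _lagrange_weights(xs, samples)
    pi = w @ frames[window, i, :]
    pj = w @ frames[window, j, :]
    d = np.linalg.norm(pi - pj, axis=-1)
    return _refine_min(d, samples)


def _refine_min(d: np.ndarray, samples: np.ndarray) -> tuple[float, float]:
    k = int(np.argmin(d))
    if 0 < k < len(d) - 1:
        y0, y1, y2 = d[k - 1], d[k], d[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 1e-12:
            off = 0.5 * (y0 - y2) / denom
            off = float(np.clip(off, -1.0, 1.0))
            h = samples[1] - samples[0]
            p_min = samples[k] + off * h
            d_min = y1 - 0.25 * (y0 - y2) * off
            return float(d_min), float(p_min)
    return float(d[k]), float(samples[k])


# ---------------------------------------------------------------------------
# J_late


class LateContext:
    """Precomputed tables for late-stage evaluation of one conformer pair."""

    def __init__(self, pair: ConformerPair, params: VdWParams | None = None):
        self.pair = pair
        self.params = params if params is not None else VdWParams()
        self.pairs = select_pairs(pair, cutoff=self.params.pair_cutoff,
                                  include_hydrogens=True)
        s = pair.structure
        self.sigma = SIGMA_SCALE * 0.5 * (
            s.vdw_radii[self.pairs.i] + s.vdw_radii[self.pairs.j])
        self.combos = TorsionComboTable(pair)
        self.res_index = np.zeros(s.n_atoms, dtype=int)
        for r_id, resi in enumerate(s.residues):
            self.res_index[resi.atom_indices] = r_id
        self.residue_keys = [resi.key for resi in s.residues]


def j_late(path: PathState, ctx: LateContext,
           sigma_bell: float = BELL_WIDTH,
           attribution: bool = True,
           pair_mask: np.ndarray | None = None,
           combo_mask: np.ndarray | None = None) -> LateTarget:
    """Evaluate the late-stage target (optionally on a masked subproblem)."""
    grid = path.grid
    eps = ctx.params.epsilon
    frames = path.grid_frames(superpose_frames=True)
    n_res = len(ctx.residue_keys)
    res_acc = np.zeros(n_res)

    # --- torsion part ------------------------------------------------------
    tmat = path.torsion_values(grid.points)
    base, z_t, channel = ctx.combos.base, ctx.combos.z_t, ctx.combos.channel
    bond_atoms = ctx.combos.bond_atoms
    if combo_mask is not None:
        base, z_t, channel = base[combo_mask], z_t[combo_mask], \
            channel[combo_mask]
        bond_atoms = [b for b, m in zip(ctx.combos.bond_atoms, combo_mask)
                      if m]
    t = np.broadcast_to(base, (len(grid.points), len(base))).copy()
    governed = channel >= 0
    t[:, governed] += tmat[:, channel[governed]]
    t = (t + 180.0) % 360.0 - 180.0
    e = torsion_energy(t, z_t[None, :], sigma_bell)
    per_combo = np.trapezoid(e, grid.points, axis=0)
    j_torsion = float(per_combo.sum())
    if attribution:
        for val, (u, v) in zip(per_combo, bond_atoms):
            if val != 0.0:
                res_acc[ctx.res_index[u]] += val
                ru, rv = ctx.res_index[u], ctx.res_index[v]
                if rv != ru:
                    res_acc[rv] += val

    # --- van der Waals part ------------------------------------------------
    pairs = ctx.pairs
    sigma = ctx.sigma
    if pair_mask is not None:
        pairs = pairs.subset(pair_mask)
        sigma = sigma[pair_mask]
    j_vdw = 0.0
    if len(pairs):
        d_knots = pairs.distances(frames)        # (n_p, n_pairs)
        ii, jj = pairs.i, pairs.j
        dp_grid = grid.spacing
        for n in range(grid.n_steps):
            d_a, d_b = d_knots[n], d_knots[n + 1]
            rep = np.where(d_a <= d_b, d_a, d_b)
            p_rep = np.where(d_a <= d_b, grid.points[n], grid.points[n + 1])
            # screen for pairs whose true minimum may dip between knots
            window = _interval_window(n, grid.n_steps)
            disp = np.linalg.norm(
                np.diff(frames[window], axis=0), axis=-1).max(axis=0)
            risk = (rep - (disp[ii] + disp[jj]) - SPLINE_SAFETY
                    < SPLINE_RISK_FACTOR * sigma)
            if risk.any():
                xs = grid.points[window]
                samples = np.linspace(grid.points[n], grid.points[n + 1],
                                      SPLINE_SAMPLES)
                w = _lagrange_weights(xs, samples)
                sub_i = ii[risk]
                sub_j = jj[risk]
                pos_i = np.einsum("sk,kma->sma", w, frames[window][:, sub_i])
                pos_j = np.einsum("sk,kma->sma", w, frames[window][:, sub_j])
                d = np.linalg.norm(pos_i - pos_j, axis=-1)   # (S, m)
                mins = np.empty(d.shape[1])
                pmins = np.empty(d.shape[1])
                for m in range(d.shape[1]):
                    mins[m], pmins[m] = _refine_min(d[:, m], samples)
                rep = rep.copy()
                p_rep = p_rep.copy()
                rep[risk] = mins
                p_rep[risk] = pmins
            d_q = pairs.d0 + p_rep * (pairs.d1 - pairs.d0)
            term = lj(rep, sigma, eps) - lj(d_q, sigma, eps)
            term = np.where(term > 0.0, term, 0.0) * dp_grid
            j_vdw += float(term.sum())
            if attribution and np.any(term):
                np.add.at(res_acc, ctx.res_index[ii], term)
                other = ctx.res_index[jj] != ctx.res_index[ii]
                np.add.at(res_acc, ctx.res_index[jj[other]], term[other])

    per_residue = {}
    if attribution:
        per_residue = {ctx.residue_keys[r]: float(res_acc[r])
                       for r in range(n_res) if res_acc[r] > 0.0}
    return LateTarget(j_vdw=j_vdw, j_torsion=j_torsion,
                      per_residue=per_residue)


# ---------------------------------------------------------------------------
# Refinement


def _eligible_by_residue(pair: ConformerPair) -> dict:
    """Residue key -> torsion channel indices moving only that sidechain."""
    s = pair.structure
    out: dict = {}
    for k, t in enumerate(pair.topology.rotatable_torsions):
        if t.affects_main_chain:
            continue
        res_keys = {s.residue_of(a) for a in t.moved_set}
        if len(res_keys) != 1:
            continue
        out.setdefault(res_keys.pop(), []).append(k)
    return out


def _masks_for_channels(ctx: LateContext, pair: ConformerPair,
                        channels: list[int]) -> tuple[np.ndarray, np.ndarray]:
    moved = set()
    for k in channels:
        moved |= pair.topology.rotatable_torsions[k].moved_set
    moved_arr = np.zeros(pair.structure.n_atoms, dtype=bool)
    moved_arr[list(moved)] = True
    pm = moved_arr[ctx.pairs.i] | moved_arr[ctx.pairs.j]
    cm = np.isin(ctx.combos.channel, channels)
    return pm, cm


def _nelder_mead(objective, x0: np.ndarray, step: float,
                 fatol: float, maxiter: int):
    simplex = np.vstack([x0] + [x0 + step * e
                                for e in np.eye(len(x0))])
    return minimize(objective, x0, method="Nelder-Mead",
                    options={"initial_simplex": simplex, "fatol": fatol,
                             "xatol": 1e-3, "maxiter": maxiter,
                             "maxfev": 4 * maxiter})


def refine_late(
    path: PathState,
    ctx: LateContext | None = None,
    *,
    simplex_step_deg: float = 10.0,
    rel_tol: float = 0.05,
    top_residues: int = 5,
    sigma_bell: float = BELL_WIDTH,
    max_rounds: int = 10,
    nm_fatol: float = 1e-4,
    nm_maxiter: int = 200,
) -> dict:
    """Two-stage Nelder-Mead clash resolution.

    Stage A runs an independent simplex descent per residue over the
    harmonic amplitudes of its sidechain-only torsions (initial simplex
    step 10 deg), merging results deterministically in residue order; stage
    B runs one joint descent for the residues with the highest late-stage
    energy attribution.  Rounds repeat until the relative decrease of
    J_late is at most ``rel_tol``.  The target never increases: candidate
    amplitude updates are only kept when they lower the global value.
    """
    ctx = ctx if ctx is not None else LateContext(path.pair)
    eligible = _eligible_by_residue(path.pair)
    report = {"rounds": []}
    base_target = j_late(path, ctx, sigma_bell)
    report["initial"] = base_target.value
    current = base_target.value

    for round_no in range(max_rounds):
        base_amps = path.amplitude_matrix()
        # ---- stage A: independent per-residue descents --------------------
        proposals = []
        for res_key in sorted(eligible, key=_residue_sort_key):
            channels = eligible[res_key]
            pm, cm = _masks_for_channels(ctx, path.pair, channels)
            if not pm.any() and not cm.any():
                continue

            def local(x, channels=channels, pm=pm, cm=cm):
                amps = base_amps.copy()
                for col, k in enumerate(channels):
                    amps[k] = x[3 * col:3 * col + 3]
                path.set_amplitudes(amps)
                t = j_late(path, ctx, sigma_bell, attribution=False,
                           pair_mask=pm, combo_mask=cm)
                return t.value

            x0 = np.concatenate([base_amps[k] for k in channels])
            try:
                res = _nelder_mead(local, x0, simplex_step_deg,
                                   nm_fatol, nm_maxiter)
            except FloatingPointError:
                logger.warning("non-finite energy in descent for %s; "
                               "reverting", res_key)
                continue
            if np.isfinite(res.fun) and res.fun < local(x0) - 1e-12:
                proposals.append((res_key, channels, res.x))
        # merge in residue order, keep only global improvements
        path.set_amplitudes(base_amps)
        merged = base_amps.copy()
        for res_key, channels, x in proposals:
            for col, k in enumerate(channels):
                merged[k] = x[3 * col:3 * col + 3]
        path.set_amplitudes(merged)
        stage_a = j_late(path, ctx, sigma_bell)
        if stage_a.value > current:
            # conflicting sidechain updates: accept greedily instead
            path.set_amplitudes(base_amps)
            merged = base_amps.copy()
            best = current
            for res_key, channels, x in proposals:
                trial = merged.copy()
                for col, k in enumerate(channels):
                    trial[k] = x[3 * col:3 * col + 3]
                path.set_amplitudes(trial)
                val = j_late(path, ctx, sigma_bell,
                             attribution=False).value
                if val < best:
                    merged = trial
                    best = val
            path.set_amplitudes(merged)
            stage_a = j_late(path, ctx, sigma_bell)

        # ---- stage B: joint descent of worst residues ----------------------
        ranked = sorted(stage_a.per_residue.items(), key=lambda kv: -kv[1])
        worst = [k for k, _ in ranked[:top_residues] if k in eligible]
        stage_b_val = stage_a.value
        if worst:
            channels = sorted(
                k for res_key in worst for k in eligible[res_key])
            amps_b = path.amplitude_matrix()
            pm, cm = _masks_for_channels(ctx, path.pair, channels)

            def joint(x, channels=channels, pm=pm, cm=cm):
                amps = amps_b.copy()
                for col, k in enumerate(channels):
                    amps[k] = x[3 * col:3 * col + 3]
                path.set_amplitudes(amps)
                return j_late(path, ctx, sigma_bell, attribution=False,
                              pair_mask=pm, combo_mask=cm).value

            x0 = np.concatenate([amps_b[k] for k in channels])
            res = _nelder_mead(joint, x0, simplex_step_deg,
                               nm_fatol, nm_maxiter)
            accepted = False
            if np.isfinite(res.fun) and res.fun < joint(x0) - 1e-12:
                amps = amps_b.copy()
                for col, k in enumerate(channels):
                    amps[k] = res.x[3 * col:3 * col + 3]
                path.set_amplitudes(amps)
                trial = j_late(path, ctx, sigma_bell,
                               attribution=False).value
                if trial < stage_a.value:
                    stage_b_val = trial
                    accepted = True
            if not accepted:
                path.set_amplitudes(amps_b)

        report["rounds"].append({
            "round": round_no + 1,
            "after_stage_a": stage_a.value,
            "after_stage_b": stage_b_val,
        })
        improved = current - stage_b_val
        rel = improved / current if current > 0 else 0.0
        current = stage_b_val
        if rel <= rel_tol:
            break
    report["final"] = current
    return report


def _residue_sort_key(key):
    chain, seq, icode = key
    return (chain, seq, icode)
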