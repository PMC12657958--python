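"""Torsion-angle trajectory parameterisation.

Each rotatable torsion follows a linear interpolation between its start and
end value plus up to three refinable harmonic perturbations that vanish at
the endpoints:

    t_i(p) = theta_i^0 + p (theta_i^1 - theta_i^0) + sum_j f_j sin(j p pi)

where p in [0, 1] is the dimensionless progress coordinate.  theta_i^1 is
direction-resolved: theta_i^1 - theta_i^0 is the signed travel, which may
exceed 180 deg in magnitude (a long-way rotation) or be adjusted by +-360
deg ("flip").  Direction choice follows the shape of the linear Cartesian
blend of the end states; flips are accepted when they shorten the total
distance travelled by the atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import dihedral, is_collinear, superpose, wrap_angle
from .structure import ConformerPair

logger = logging.getLogger(__name__)

SHORT_WAY_THRESHOLD = 30.0  # deg; at or below, travel is always the short way
DIRECTION_P_STEP = 0.1      # p-spacing of the unwrapping scan


@dataclass
class TorsionChannel:
    """One rotatable torsion's refinable trajectory parameters."""

    index: int
    theta0: float
    theta1: float  # direction-resolved; theta1 - theta0 is the signed travel
    amplitudes: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    @property
    def travel(self) -> float:
        return self.theta1 - self.theta0


def evaluate_torsion(channel: TorsionChannel, p) -> np.ndarray | float:
    """Torsion value (degrees) at progress ``p`` (scalar or array)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("progress p must lie in [0, 1]")
    t = channel.theta0 + p * (channel.theta1 - channel.theta0)
    for j, f in enumerate(channel.amplitudes, start=1):
        if f != 0.0:
            t = t + f * np.sin(j * p * np.pi)
    return float(t) if t.ndim == 0 else t


@dataclass
class ProgressGrid:
    """Evenly spaced integration grid on [0, 1]: n_steps intervals."""

    n_steps: int = 12

    @property
    def points(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_steps + 1)

    @property
    def spacing(self) -> float:
        return 1.0 / self.n_steps


def resolve_direction(pair: ConformerPair, torsion_index: int) -> float:
    """Signed travel (degrees) for one torsion.

    Wrapped differences of at most 30 deg always take the short way.  Larger
    differences follow the rotation sense implied by the linear Cartesian
    blend of the end states: the torsion is measured on linearly
    interpolated atom positions at p = 0, 0.1, ..., 1 and successively
    unwrapped by {-360, 0, +360} to stay closest to the previous value; the
    unwrapped value at p = 1 fixes the sign and winding of the travel.
    """
    theta0 = pair.start_torsions[torsion_index]
    theta1 = pair.end_torsions[torsion_index]
    delta = wrap_angle(theta1 - theta0)
    if abs(delta) <= SHORT_WAY_THRESHOLD:
        return float(delta)
    quad = pair.topology.rotatable_torsions[torsion_index].atoms
    a0 = pair.start_coords[list(quad)]
    a1 = pair.end_coords[list(quad)]
    ps = np.arange(0.0, 1.0 + 1e-9, DIRECTION_P_STEP)
    prev = None
    first = None
    for p in ps:
        pos = a0 + p * (a1 - a0)
        if (is_collinear(pos[0], pos[1], pos[2])
                or is_collinear(pos[1], pos[2], pos[3])):
            t = pair.topology.rotatable_torsions[torsion_index]
            logger.warning(
                "degenerate interpolated quadruple for torsion %s at p=%.1f;"
                " falling back to short-way direction", t.selector, p)
            return float(delta)
        val = dihedral(pos[0], pos[1], pos[2], pos[3])
        if prev is not None:
            val = val + 360.0 * np.round((prev - val) / 360.0)
        else:
            first = val
        prev = val
    return float(prev - first)


class PathState:
    """A conformer pair plus the per-torsion trajectory parameters."""

    def __init__(self, pair: ConformerPair, grid: ProgressGrid | None = None,
                 resolve: bool = True):
        self.pair = pair
        self.grid = grid if grid is not None else ProgressGrid()
        self.channels: list[TorsionChannel] = []
        for k in range(pair.model.n_torsions):
            theta0 = float(pair.start_torsions[k])
            if resolve:
                travel = resolve_direction(pair, k)
            else:
                travel = float(wrap_angle(pair.end_torsions[k] - theta0))
            self.channels.append(TorsionChannel(k, theta0, theta0 + travel))
        self._frame_cache: dict = {}

    # -- parameter access ---------------------------------------------------

    @property
    def n_torsions(self) -> int:
        return len(self.channels)

    def amplitude_matrix(self) -> np.ndarray:
        return np.array([c.amplitudes for c in self.channels])

    def set_amplitudes(self, amplitudes: np.ndarray) -> None:
        amplitudes = np.asarray(amplitudes, dtype=float)
        for c, row in zip(self.channels, amplitudes):
            c.amplitudes = row.copy()
        self.invalidate()

    def invalidate(self) -> None:
        self._frame_cache.clear()

    # -- evaluation ---------------------------------------------------------

    def torsion_values(self, p) -> np.ndarray:
        """Matrix of torsion values, shape (n_p, n_torsions)."""
        p = np.atleast_1d(np.asarray(p, dtype=float))
        theta0 = np.array([c.theta0 for c in self.channels])
        travel = np.array([c.travel for c in self.channels])
        amps = self.amplitude_matrix()  # (T, 3)
        t = theta0[None, :] + p[:, None] * travel[None, :]
        for j in range(3):
            fj = amps[:, j]
            if np.any(fj != 0.0):
                t = t + fj[None, :] * np.sin((j + 1) * p[:, None] * np.pi)
        return t

    def frames(self, p, superpose_frames: bool = True) -> np.ndarray:
        """Cartesian frames at progress values ``p``, shape (n_p, n, 3).

        Frames are built by forward kinematics from the start geometry and
        the current torsion values, then (optionally) rigid-body superposed
        onto the linear Cartesian blend of the end states over non-hydrogen
        atoms.  Energies are distance-based and therefore invariant to this
        standardisation; it only fixes the exported reference frame.
        """
        p = np.atleast_1d(np.asarray(p, dtype=float))
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError("progress p must lie in [0, 1]")
        t = self.torsion_values(p)
        theta0 = np.array([c.theta0 for c in self.channels])
        deltas = t - theta0[None, :]
        coords = self.pair.model.build(deltas)
        if superpose_frames:
            fit = ~self.pair.structure.is_hydrogen
            start = self.pair.start_coords
            end = self.pair.end_coords
            out = np.empty_like(coords)
            for k, pk in enumerate(p):
                blend = start + pk * (end - start)
                out[k] = superpose(coords[k], blend, fit_mask=fit)
            coords = out
        return coords

    def grid_frames(self, superpose_frames: bool = False) -> np.ndarray:
        key = ("grid", superpose_frames,
               tuple(self.amplitude_matrix().ravel()),
               tuple(c.theta1 for c in self.channels))
        if key not in self._frame_cache:
            self._frame_cache.clear()
            self._frame_cache[key] = self.frames(
                self.grid.points, superpose_frames=superpose_frames)
        return self._frame_cache[key]

    def reconstruct_frame(self, p: float,
                          superpose_frame: bool = True) -> np.ndarray:
        """Coordinates (n_atoms, 3) at a single progress value."""
        return self.frames([p], superpose_frames=superpose_frame)[0]

    def copy_amplitudes(self) -> np.ndarray:
        return self.amplitude_matrix()


# ---------------------------------------------------------------------------
# Flips


def path_length_metric(path: PathState) -> float:
    """Total distance travelled by all atoms along the progress grid.

    Sum over atoms of the polyline length of the atom's trajectory through
    the standardised frames at the grid points.
    """
    frames = path.frames(path.grid.points, superpose_frames=True)
    seg = np.diff(frames, axis=0)
    return float(np.sum(np.linalg.norm(seg, axis=-1)))


def evaluate_flip(path: PathState, torsion_index: int
                  ) -> tuple[bool, float, float]:
    """Try the +-360 deg flip of one torsion's travel.

    The candidate travel is the current travel minus 360 deg of its own
    sign.  The flip is accepted (and applied) iff the total path-length
    metric strictly decreases; ties keep the original direction.

    Returns (accepted, metric_before, metric_after_candidate).
    """
    ch = path.channels[torsion_index]
    if abs(ch.travel) <= SHORT_WAY_THRESHOLD:
        raise ValueError("flip evaluation requires |travel| > 30 deg")
    before = path_length_metric(path)
    original_theta1 = ch.theta1
    ch.theta1 = original_theta1 - 360.0 * np.sign(ch.travel)
    path.invalidate()
    after = path_length_metric(path)
    if after < before:
        return True, before, after
    ch.theta1 = original_theta1
    path.invalidate()
    return False, before, after


def resolve_flips(path: PathState) -> list[tuple[int, bool]]:
    """Scan all large-travel torsions for beneficial flips.

    Candidates are visited in order of descending |travel|; each accepted
    flip updates the path before the next candidate is tested.
    """
    order = sorted(
        (k for k, c in enumerate(path.channels)
         if abs(c.travel) > SHORT_WAY_THRESHOLD),
        key=lambda k: -abs(path.channels[k].travel),
    )
    results = []
    for k in order:
        accepted, _, _ = evaluate_flip(path, k)
        results.append((k, accepted))
    return results


# ---------------------------------------------------------------------------
# Manual overrides


def parse_flip_file(text: str) -> list[tuple[str, int, str, float, np.ndarray]]:
    """Parse a manual-override file.

    One record per line: ``chain resnum torsion_name offset_degrees
    [f1 f2 f3]``.  Blank lines and ``#`` comments are ignored.
    """
    records = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (4, 7):
            raise ValueError(
                f"flip file line {ln}: expected 'chain resnum name offset"
                " [f1 f2 f3]', got {line!r}")
        chain, resnum, name, offset = parts[0], int(parts[1]), parts[2], \
            float(parts[3])
        amps = np.array([float(x) for x in parts[4:7]]) if len(parts) == 7 \
            else np.zeros(3)
        records.append((chain, resnum, name, offset, amps))
    return records


def apply_flip_overrides(path: PathState, text: str) -> None:
    """Apply manual travel offsets / forced amplitudes from a flip file."""
    for chain, resnum, name, offset, amps in parse_flip_file(text):
        k = path.pair.topology.torsion_index(chain, resnum, name)
        ch = path.channels[k]
        ch.theta1 += offset
        if np.any(amps != 0.0):
            ch.amplitudes = amps.copy()
    path.invalidate()
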