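"""Late-stage energy: Lennard-Jones threshold, torsion bells, splines, NM."""

import numpy as np
import pytest

from coldpath import (
    LateContext,
    PathState,
    VdWParams,
    harmonize_geometry,
    j_late,
    read_structure,
    refine_late,
    resolve_flips,
    spline_min_distance,
    torsion_energy,
    vdw_pair_term,
)
from coldpath.geometry import kabsch_rotation
from coldpath.late import SIGMA_SCALE, _nelder_mead, lj
from coldpath.path import ProgressGrid


class TestClosedForms:
    def test_torsion_bell_at_zero_equals_z(self):
        z = np.hypot(6, 6)          # carbon-carbon terminal atoms
        assert z == pytest.approx(np.sqrt(72.0))
        assert torsion_energy(0.0, z) == pytest.approx(z)

    def test_torsion_bell_at_width_is_eighth(self):
        z = 8.4853
        assert torsion_energy(60.0, z) == pytest.approx(z / 8.0)

    def test_lj_minimum_is_minus_epsilon(self):
        sigma = 1.3
        d = 2.0 ** (1 / 6) * sigma
        assert lj(d, sigma, epsilon=1.0) == pytest.approx(-1.0)
        assert lj(d, sigma, epsilon=2.5) == pytest.approx(-2.5)

    def test_pair_term_direct_arithmetic(self):
        """d_q = 2 sigma, d_p = 0.9 sigma: positive excess, exact value."""
        sigma = 1.0
        expected = 4 * (0.9 ** -12 - 0.9 ** -6) - 4 * (2.0 ** -12 - 2.0 ** -6)
        got = max(lj(0.9 * sigma, sigma) - lj(2.0 * sigma, sigma), 0.0)
        assert got == pytest.approx(expected)
        assert got > 0.0


class TestVdWPairTerm:
    def test_identity_transition_zero(self, helix_coil_texts):
        start_txt, _ = helix_coil_texts
        s, topo = read_structure(start_txt)
        pair = harmonize_geometry(s, s, topology=topo)
        path = PathState(pair)
        ctx = LateContext(pair)
        k = len(ctx.pairs) // 2
        i, j = int(ctx.pairs.i[k]), int(ctx.pairs.j[k])
        assert vdw_pair_term(path, i, j, 0.4) == pytest.approx(0.0,
                                                               abs=1e-12)

    def test_symmetric_in_atom_order(self, helix_coil_path):
        path = helix_coil_path
        ctx = LateContext(path.pair)
        k = int(np.argmin(ctx.pairs.d0))
        i, j = int(ctx.pairs.i[k]), int(ctx.pairs.j[k])
        assert vdw_pair_term(path, i, j, 0.3) == pytest.approx(
            vdw_pair_term(path, j, i, 0.3))


class TestSplineMinDistance:
    def test_stationary_atoms_constant(self, helix_coil_path):
        path = helix_coil_path
        s = path.pair.structure
        # two backbone atoms of residue 1 barely move; use a static pair
        i = s.atom_index("A", 1, "N")
        j = s.atom_index("A", 1, "CA")
        frames = np.repeat(path.pair.start_coords[None], 13, axis=0)
        d, p = spline_min_distance(path, i, j, 5, frames=frames)
        expected = np.linalg.norm(path.pair.start_coords[i]
                                  - path.pair.start_coords[j])
        assert d == pytest.approx(expected, abs=1e-9)

    def test_uniform_linear_motion_closed_form(self, helix_coil_path):
        """Straight-line motion: spline min equals line-line closest approach."""
        path = helix_coil_path
        grid = path.grid
        ps = grid.points
        n_atoms = path.pair.structure.n_atoms
        frames = np.zeros((13, n_atoms, 3))
        # atom 0 moves along x; atom 1 crosses it along y offset in z
        v0 = np.array([2.0, 0.0, 0.0])
        v1 = np.array([0.0, 3.0, 0.0])
        o1 = np.array([1.0, -1.5, 0.4])
        for k, p in enumerate(ps):
            frames[k, 0] = v0 * p
            frames[k, 1] = o1 + v1 * p
        interval = 5
        d, p_at = spline_min_distance(path, 0, 1, interval, frames=frames)
        # closed form: minimise |(o1 + v1 p) - v0 p| over the sub-interval
        rel0 = o1
        relv = v1 - v0
        p_star = -np.dot(rel0, relv) / np.dot(relv, relv)
        p_star = np.clip(p_star, ps[interval], ps[interval + 1])
        expected = np.linalg.norm(rel0 + relv * p_star)
        assert d == pytest.approx(expected, rel=1e-6)
        assert p_at == pytest.approx(p_star, abs=1e-3)

    def test_near_miss_dip_between_grid_points(self, helix_coil_path):
        """A crossing between knots is caught below both knot distances."""
        path = helix_coil_path
        grid = path.grid
        ps = grid.points
        n_atoms = path.pair.structure.n_atoms
        frames = np.zeros((13, n_atoms, 3))
        for k, p in enumerate(ps):
            # atom 0 sweeps a parabola dipping towards atom 1 at p ~ 0.46
            frames[k, 0] = np.array([10.0 * (p - 0.46) ** 2 + 0.3,
                                     p, 0.0])
            frames[k, 1] = np.array([0.0, p, 0.0])
        interval = 5   # p in [0.4167, 0.5]
        d, p_at = spline_min_distance(path, 0, 1, interval, frames=frames)
        knot_d = [np.linalg.norm(frames[interval, 0] - frames[interval, 1]),
                  np.linalg.norm(frames[interval + 1, 0]
                                 - frames[interval + 1, 1])]
        assert d < min(knot_d)
        # dense-sampling oracle on the same cubic interpolant
        dense, _ = spline_min_distance(path, 0, 1, interval, frames=frames,
                                       n_samples=1000)
        assert d == pytest.approx(dense, rel=0.01)


class TestJLate:
    def test_identity_clash_free(self, helix_coil_texts):
        start_txt, _ = helix_coil_texts
        s, topo = read_structure(start_txt)
        pair = harmonize_geometry(s, s, topology=topo)
        path = PathState(pair)
        ctx = LateContext(pair)
        target = j_late(path, ctx)
        assert target.j_vdw == pytest.approx(0.0, abs=1e-9)
        assert target.j_torsion > 0.0

    def test_planted_clash_detected_and_attributed(self, clash_pair):
        path = PathState(clash_pair)
        resolve_flips(path)
        ctx = LateContext(clash_pair)
        target = j_late(path, ctx)
        assert target.j_vdw > 10.0
        ranked = sorted(target.per_residue.items(), key=lambda kv: -kv[1])
        top_residues = {key[1] for key, _ in ranked[:2]}
        assert top_residues == {2, 5}   # the crossing Phe and Leu

    def test_epsilon_scales_vdw_only(self, clash_pair):
        path = PathState(clash_pair)
        resolve_flips(path)
        t1 = j_late(path, LateContext(clash_pair, VdWParams(epsilon=1.0)),
                    attribution=False)
        t2 = j_late(path, LateContext(clash_pair, VdWParams(epsilon=2.0)),
                    attribution=False)
        assert t2.j_vdw == pytest.approx(2.0 * t1.j_vdw, rel=1e-9)
        assert t2.j_torsion == pytest.approx(t1.j_torsion, rel=1e-12)

    def test_invariant_under_global_rigid_motion(self, clash_pair):
        path = PathState(clash_pair)
        ctx = LateContext(clash_pair)
        ref = j_late(path, ctx, attribution=False)

        rng = np.random.default_rng(3)
        rot = kabsch_rotation(rng.normal(size=(4, 3)),
                              rng.normal(size=(4, 3)))
        shift = np.array([-4.0, 9.0, 2.0])
        s = clash_pair.structure
        from coldpath import Topology
        s_rot = s.with_coords(clash_pair.start_coords @ rot.T + shift)
        e_rot = s.with_coords(clash_pair.end_coords @ rot.T + shift)
        pair_rot = harmonize_geometry(s_rot, e_rot,
                                      topology=Topology(s_rot))
        path_rot = PathState(pair_rot)
        got = j_late(path_rot, LateContext(pair_rot), attribution=False)
        assert got.value == pytest.approx(ref.value, rel=1e-6)


class TestRefineLate:
    def test_clash_free_terminates_first_round(self, helix_coil_texts):
        start_txt, _ = helix_coil_texts
        s, topo = read_structure(start_txt)
        pair = harmonize_geometry(s, s, topology=topo)
        path = PathState(pair)
        ctx = LateContext(pair)
        report = refine_late(path, ctx, nm_maxiter=30)
        assert len(report["rounds"]) == 1

    def test_rotamer_clash_resolved(self, rotamer_refined):
        """The planted crossing clash refines to the numerical floor."""
        path, ctx, report, _ = rotamer_refined
        target = j_late(path, ctx, attribution=False)
        assert target.j_vdw < 0.1          # no steric overlap at eps scale
        assert report["final"] <= report["initial"]

    def test_rounds_monotone_nonincreasing(self, rotamer_refined):
        _, _, report, _ = rotamer_refined
        seq = [report["initial"]]
        for r in report["rounds"]:
            seq.append(r["after_stage_a"])
            seq.append(r["after_stage_b"])
        assert all(b <= a + 1e-9 for a, b in zip(seq, seq[1:]))

    def test_main_chain_amplitudes_untouched(self, rotamer_refined):
        """Only sidechain-exclusive torsions are refined by the protocol."""
        path, _, _, amps_before = rotamer_refined
        topo = path.pair.topology
        amps_after = path.amplitude_matrix()
        for k, t in enumerate(topo.rotatable_torsions):
            if t.affects_main_chain:
                assert np.allclose(amps_after[k], amps_before[k])

    def test_simplex_matches_grid_search_oracle(self, rotamer_pair):
        """1-D Nelder-Mead lands within 5 deg of a 1-deg grid search."""
        path = PathState(rotamer_pair)
        resolve_flips(path)
        ctx = LateContext(rotamer_pair)
        k = path.pair.topology.torsion_index("A", 5, "chi1")

        def objective(f1):
            amps = np.zeros((path.n_torsions, 3))
            amps[k, 0] = float(f1)
            path.set_amplitudes(amps)
            return j_late(path, ctx, attribution=False).j_vdw

        grid = [(objective(f1), f1) for f1 in np.arange(-180.0, 180.5, 1.0)]
        grid_min = min(grid)
        res = _nelder_mead(lambda x: objective(x[0]), np.array([0.0]),
                           10.0, 1e-4, 200)
        assert abs(res.x[0] - grid_min[1]) <= 5.0
        assert res.fun <= grid_min[0] * 1.05 + 1e-9
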