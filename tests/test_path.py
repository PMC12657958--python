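"""Trajectory parameterisation: harmonics, directions, flips, frames."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coldpath import (
    PathState,
    TorsionChannel,
    apply_flip_overrides,
    evaluate_flip,
    evaluate_torsion,
    path_length_metric,
    resolve_direction,
    resolve_flips,
)
from coldpath.fixtures import FixtureSpec, build_peptide
from coldpath.geometry import bond_length, dihedral, rmsd, wrap_angle
from coldpath.structure import harmonize_geometry, read_structure


class TestEvaluateTorsion:
    def test_linear_midpoint(self):
        ch = TorsionChannel(0, 10.0, 70.0)
        assert evaluate_torsion(ch, 0.5) == pytest.approx(40.0)

    def test_first_harmonic_peaks_at_midpoint(self):
        ch = TorsionChannel(0, 10.0, 70.0, np.array([8.0, 0.0, 0.0]))
        assert evaluate_torsion(ch, 0.5) == pytest.approx(48.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(theta0=st.floats(-180, 180), travel=st.floats(-400, 400),
           f1=st.floats(-90, 90), f2=st.floats(-90, 90),
           f3=st.floats(-90, 90))
    def test_endpoints_exact_for_any_amplitudes(self, theta0, travel,
                                                f1, f2, f3):
        ch = TorsionChannel(0, theta0, theta0 + travel,
                            np.array([f1, f2, f3]))
        assert evaluate_torsion(ch, 0.0) == pytest.approx(theta0, abs=1e-9)
        assert evaluate_torsion(ch, 1.0) == pytest.approx(theta0 + travel,
                                                          abs=1e-9)

    def test_progress_out_of_range_rejected(self):
        ch = TorsionChannel(0, 0.0, 10.0)
        with pytest.raises(ValueError):
            evaluate_torsion(ch, 1.5)
        with pytest.raises(ValueError):
            evaluate_torsion(ch, -0.1)


class TestFrames:
    def test_endpoint_frames_match_states(self, helix_coil_path):
        path = helix_coil_path
        pair = path.pair
        assert rmsd(path.reconstruct_frame(0.0), pair.start_coords) < 1e-6
        assert rmsd(path.reconstruct_frame(1.0), pair.end_coords) < 1e-6

    def test_endpoints_preserved_under_amplitudes(self, helix_coil_path,
                                                  rng):
        path = helix_coil_path
        path.set_amplitudes(rng.uniform(-40, 40,
                                        (path.n_torsions, 3)))
        assert rmsd(path.reconstruct_frame(0.0),
                    path.pair.start_coords) < 1e-6
        assert rmsd(path.reconstruct_frame(1.0),
                    path.pair.end_coords) < 1e-6
        path.set_amplitudes(np.zeros((path.n_torsions, 3)))

    def test_bond_geometry_conserved_mid_path(self, helix_coil_path, rng):
        """Only torsions move: bond lengths are those of the start state."""
        path = helix_coil_path
        path.set_amplitudes(rng.uniform(-30, 30, (path.n_torsions, 3)))
        frame = path.reconstruct_frame(0.37, superpose_frame=False)
        topo = path.pair.topology
        for u, v in topo.graph.edges:
            assert bond_length(frame[u], frame[v]) == pytest.approx(
                bond_length(path.pair.start_coords[u],
                            path.pair.start_coords[v]), rel=1e-6)
        path.set_amplitudes(np.zeros((path.n_torsions, 3)))

    def test_mid_path_dihedral_matches_interpolant(self, helix_coil_path):
        """The dihedral measured in a frame equals the channel value."""
        path = helix_coil_path
        topo = path.pair.topology
        k = topo.torsion_index("A", 3, "phi")
        p = 0.5
        frame = path.reconstruct_frame(p, superpose_frame=False)
        quad = topo.rotatable_torsions[k].atoms
        measured = dihedral(*[frame[i] for i in quad])
        expected = evaluate_torsion(path.channels[k], p)
        assert wrap_angle(measured - expected) == pytest.approx(0.0,
                                                                abs=1e-6)


class TestResolveDirection:
    def test_short_way_through_wrap(self):
        """theta 350 -> 10 deg travels +20, not -340."""
        spec = FixtureSpec("ASA", start={2: {"chi1": -10.0}},
                           end={2: {"chi1": 10.0}})
        s_txt, e_txt = build_peptide(spec)
        s, topo = read_structure(s_txt)
        e, _ = read_structure(e_txt)
        pair = harmonize_geometry(s, e, topology=topo)
        k = topo.torsion_index("A", 2, "chi1")
        assert resolve_direction(pair, k) == pytest.approx(20.0, abs=0.1)

    def test_large_travel_follows_cartesian_blend(self, flip_pair):
        """Above 30 deg the sign follows the blend's unwrapped sweep."""
        pair = flip_pair
        topo = pair.topology
        k = topo.torsion_index("A", 2, "chi1")
        travel = resolve_direction(pair, k)
        # independent dense unwrapping oracle on blended positions
        quad = topo.rotatable_torsions[k].atoms
        a0 = pair.start_coords[list(quad)]
        a1 = pair.end_coords[list(quad)]
        prev = None
        for p in np.linspace(0, 1, 2001):
            pos = a0 + p * (a1 - a0)
            val = dihedral(pos[0], pos[1], pos[2], pos[3])
            if prev is not None:
                val += 360.0 * np.round((prev - val) / 360.0)
            else:
                first = val
            prev = val
        assert travel == pytest.approx(prev - first, abs=0.5)
        # and is consistent with the wrapped endpoint difference
        assert wrap_angle(travel - wrap_angle(
            pair.end_torsions[k] - pair.start_torsions[k])) == \
            pytest.approx(0.0, abs=1e-6)

    def test_reversal_invariance(self, flip_pair):
        """Reversing the quadruple leaves the measured travel unchanged."""
        pair = flip_pair
        topo = pair.topology
        k = topo.torsion_index("A", 2, "chi1")
        quad = topo.rotatable_torsions[k].atoms
        c = pair.start_coords
        assert dihedral(c[quad[0]], c[quad[1]], c[quad[2]], c[quad[3]]) == \
            pytest.approx(dihedral(c[quad[3]], c[quad[2]], c[quad[1]],
                                   c[quad[0]]))


class TestFlips:
    def test_planted_350_flip_accepted(self, helix_coil_pair):
        """A +350 deg travel flips to -10 deg (shorter atom paths)."""
        path = PathState(helix_coil_pair)
        k = path.pair.topology.torsion_index("A", 3, "chi1")
        ch = path.channels[k]
        ch.theta1 = ch.theta0 + 350.0
        path.invalidate()
        accepted, before, after = evaluate_flip(path, k)
        assert accepted and after < before
        assert ch.travel == pytest.approx(-10.0)

    def test_harmful_flip_rejected(self, helix_coil_pair):
        """A +40 deg travel keeps its direction: -320 deg sweeps farther."""
        path = PathState(helix_coil_pair)
        k = path.pair.topology.torsion_index("A", 3, "chi1")
        ch = path.channels[k]
        ch.theta1 = ch.theta0 + 40.0
        path.invalidate()
        accepted, before, after = evaluate_flip(path, k)
        assert not accepted
        assert ch.travel == pytest.approx(40.0)
        assert after >= before

    def test_metric_matches_dense_polyline_oracle(self, helix_coil_path):
        """Grid polyline length is within 1% of dense-sampled path length."""
        path = helix_coil_path
        metric = path_length_metric(path)
        frames = path.frames(np.linspace(0, 1, 201), superpose_frames=True)
        dense = float(np.sum(np.linalg.norm(np.diff(frames, axis=0),
                                            axis=-1)))
        assert metric == pytest.approx(dense, rel=0.01)

    def test_scan_order_is_descending_travel(self, clash_pair):
        path = PathState(clash_pair)
        original = {k: abs(c.travel) for k, c in enumerate(path.channels)
                    if abs(c.travel) > 30.0}
        results = resolve_flips(path)
        visited = [original[k] for k, _ in results]
        assert visited == sorted(visited, reverse=True)
        assert set(k for k, _ in results) == set(original)


class TestOverrides:
    def test_flip_file_round_trip(self, helix_coil_pair):
        path = PathState(helix_coil_pair)
        k = path.pair.topology.torsion_index("A", 3, "chi1")
        before = path.channels[k].theta1
        apply_flip_overrides(path, "# comment\nA 3 chi1 360\n")
        assert path.channels[k].theta1 == pytest.approx(before + 360.0)
        apply_flip_overrides(path, "A 3 chi1 0 15 0 0\n")
        assert path.channels[k].amplitudes[0] == pytest.approx(15.0)

    def test_malformed_flip_file_rejected(self, helix_coil_pair):
        path = PathState(helix_coil_pair)
        with pytest.raises(ValueError):
            apply_flip_overrides(path, "A 3 chi1\n")
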