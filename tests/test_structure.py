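"""Structure model: parsing, topology, harmonisation, canonicalisation."""

import numpy as np
import pytest

from coldpath import (
    StructureError,
    canonicalize_symmetric_sidechains,
    harmonize_geometry,
    read_structure,
)
from coldpath.fixtures import FixtureSpec, build_peptide
from coldpath.geometry import bond_angle, bond_length, rmsd, wrap_angle


def torsion_names(topology, res_seq=None):
    return [
        t.name for t in topology.rotatable_torsions
        if res_seq is None or t.res_seq == res_seq
    ]


class TestReadStructure:
    def test_dipeptide_torsion_set(self):
        """Ala-Ala: peptide omega, phi, psi and methyl rotors are present."""
        start_txt, _ = build_peptide(FixtureSpec("AA"))
        _, topo = read_structure(start_txt)
        names = torsion_names(topo)
        assert "psi" in torsion_names(topo, 1)       # res 1 psi
        assert "omega" in torsion_names(topo, 2)     # peptide bond
        assert "phi" in torsion_names(topo, 2)       # res 2 phi
        # methyl rotors on both CB atoms
        assert torsion_names(topo, 1).count("CA-CB") == 1
        assert torsion_names(topo, 2).count("CA-CB") == 1

    def test_glycine_has_no_sidechain_torsions(self):
        start_txt, _ = build_peptide(FixtureSpec("GAG"))
        _, topo = read_structure(start_txt)
        for res in (1, 3):
            assert all(
                name in ("phi", "psi", "omega", "CA-N", "CA-C")
                for name in torsion_names(topo, res)
            )

    def test_altloc_rejected(self):
        start_txt, _ = build_peptide(FixtureSpec("AA"))
        lines = []
        flagged = False
        for ln in start_txt.splitlines():
            if ln.startswith("ATOM") and not flagged:
                ln = ln[:16] + "A" + ln[17:]
                flagged = True
            lines.append(ln)
        with pytest.raises(StructureError, match="[Aa]lternate"):
            read_structure("\n".join(lines))

    def test_missing_hydrogens_rejected(self):
        start_txt, _ = build_peptide(FixtureSpec("AA"))
        stripped = "\n".join(
            ln for ln in start_txt.splitlines()
            if not (ln.startswith("ATOM") and ln[76:78].strip() == "H")
        )
        with pytest.raises(StructureError, match="hydrogen"):
            read_structure(stripped)

    def test_unknown_residue_rejected(self):
        start_txt, _ = build_peptide(FixtureSpec("AA"))
        with pytest.raises(StructureError, match="unknown residue"):
            read_structure(start_txt.replace("ALA A", "XYZ A"))

    def test_pdb_round_trip(self, helix_coil_pair):
        s = helix_coil_pair.structure
        s2, _ = read_structure(s.to_pdb_text())
        assert list(s2.names) == list(s.names)
        assert np.abs(s2.coords - s.coords).max() < 1e-3

    def test_enumeration_deterministic(self, helix_coil_texts):
        start_txt, _ = helix_coil_texts
        _, topo1 = read_structure(start_txt)
        _, topo2 = read_structure(start_txt)
        t1 = [(t.atoms, t.bond, t.name) for t in topo1.rotatable_torsions]
        t2 = [(t.atoms, t.bond, t.name) for t in topo2.rotatable_torsions]
        assert t1 == t2

    def test_rotatable_bonds_avoid_rings(self):
        """Proline's ring freezes phi; aromatic ring bonds are rigid."""
        start_txt, _ = build_peptide(FixtureSpec("APA"))
        _, topo = read_structure(start_txt)
        assert "phi" not in torsion_names(topo, 2)
        start_txt, _ = build_peptide(FixtureSpec("AFA"))
        s, topo = read_structure(start_txt)
        ring = {i for i in range(s.n_atoms)
                if topo.aromatic_ring_id[i] >= 0}
        for t in topo.rotatable_torsions:
            assert not (t.bond[0] in ring and t.bond[1] in ring)


class TestTorsionMeasurement:
    def test_set_then_measure_inverse(self, helix_coil_pair, rng):
        """Setting any torsion offset and re-measuring recovers it mod 360."""
        model = helix_coil_pair.model
        topo = helix_coil_pair.topology
        deltas = rng.uniform(-720, 720, model.n_torsions)
        coords = model.build(deltas)
        measured = topo.measure_torsions(coords)
        err = wrap_angle(measured - model.ref_torsions - deltas)
        assert np.abs(err).max() < 1e-9


class TestHarmonize:
    def test_identity(self, helix_coil_texts):
        start_txt, _ = helix_coil_texts
        s, topo = read_structure(start_txt)
        pair = harmonize_geometry(s, s, topology=topo)
        assert np.abs(pair.end_coords - s.coords).max() < 1e-6

    def test_single_chi_rotation_reproduced(self):
        """End differing by one chi1 rotation rebuilds to within 1e-3 A."""
        spec = FixtureSpec("ASA", start={2: {"chi1": -65.0}},
                           end={2: {"chi1": 55.0}})
        start_txt, end_txt = build_peptide(spec)
        s, topo = read_structure(start_txt)
        e, _ = read_structure(end_txt)
        pair = harmonize_geometry(s, e, topology=topo)
        assert rmsd(pair.end_coords, e.coords) < 1e-3

    def test_perturbed_bond_lengths_replaced_by_start(self):
        start_txt, end_txt = build_peptide(
            FixtureSpec("AAA", end={2: {"phi": -60.0}}))
        s, topo = read_structure(start_txt)
        e, _ = read_structure(end_txt)
        # stretch every bond of the end state by 3% (angles, torsions kept)
        e_scaled = e.with_coords(e.coords * 1.03)
        with pytest.warns(UserWarning):
            pair = harmonize_geometry(s, e_scaled, topology=topo,
                                      ca_warn_threshold=0.0)
        for u, v in topo.graph.edges:
            b_start = bond_length(pair.start_coords[u], pair.start_coords[v])
            b_end = bond_length(pair.end_coords[u], pair.end_coords[v])
            assert b_end == pytest.approx(b_start, rel=1e-9)

    def test_atom_mismatch_reported(self):
        start_txt, end_txt = build_peptide(FixtureSpec("AA"))
        truncated = "\n".join(end_txt.splitlines()[:-5])
        s, topo = read_structure(start_txt)
        e, _ = read_structure(truncated)
        with pytest.raises(StructureError, match="different atom sets"):
            harmonize_geometry(s, e, topology=topo)

    def test_geometry_conserved_between_states(self, helix_coil_pair):
        """After harmonisation every bond length and angle agrees."""
        pair = helix_coil_pair
        topo = pair.topology
        for u, v in topo.graph.edges:
            assert bond_length(pair.end_coords[u], pair.end_coords[v]) == \
                pytest.approx(
                    bond_length(pair.start_coords[u], pair.start_coords[v]),
                    rel=1e-6)
        # angles via each placement triple (g, p, atom)
        for c, pl in topo.placements.items():
            a_start = bond_angle(pair.start_coords[pl.g],
                                 pair.start_coords[pl.parent],
                                 pair.start_coords[c])
            a_end = bond_angle(pair.end_coords[pl.g],
                               pair.end_coords[pl.parent],
                               pair.end_coords[c])
            assert a_end == pytest.approx(a_start, rel=1e-6)


class TestCanonicalize:
    def test_phe_chi2_mismatch_reduced(self, symmetric_pair):
        """chi2 of 10 vs 195 deg becomes 10 vs 15 deg (travel 5 deg)."""
        pair = symmetric_pair
        k = pair.topology.torsion_index("A", 2, "chi2")
        before = wrap_angle(pair.end_torsions[k] - pair.start_torsions[k])
        assert abs(before) == pytest.approx(175.0, abs=1.0)
        fixed = canonicalize_symmetric_sidechains(pair, resolution=2.0)
        after = wrap_angle(fixed.end_torsions[k] - fixed.start_torsions[k])
        assert abs(after) == pytest.approx(5.0, abs=1.0)

    def test_already_minimal_unchanged(self):
        spec = FixtureSpec("AFA", start={2: {"chi2": 10.0}},
                           end={2: {"chi2": 40.0}})
        start_txt, end_txt = build_peptide(spec)
        s, topo = read_structure(start_txt)
        e, _ = read_structure(end_txt)
        pair = harmonize_geometry(s, e, topology=topo)
        fixed = canonicalize_symmetric_sidechains(pair, resolution=2.0)
        assert np.allclose(fixed.end_torsions, pair.end_torsions)

    @pytest.mark.parametrize("resolution,expect_flip", [(1.5, False),
                                                        (3.0, True)])
    def test_asn_rule_depends_on_resolution(self, resolution, expect_flip):
        """Asn terminal torsion is reconciled only at low resolution."""
        spec = FixtureSpec("ANA", start={2: {"chi2": 10.0}},
                           end={2: {"chi2": -170.0}})
        start_txt, end_txt = build_peptide(spec)
        s, topo = read_structure(start_txt)
        e, _ = read_structure(end_txt)
        pair = harmonize_geometry(s, e, topology=topo)
        k = topo.torsion_index("A", 2, "chi2")
        fixed = canonicalize_symmetric_sidechains(pair, resolution=resolution)
        delta = wrap_angle(fixed.end_torsions[k] - fixed.start_torsions[k])
        if expect_flip:
            assert abs(delta) == pytest.approx(0.0, abs=1.0)
        else:
            assert abs(delta) == pytest.approx(180.0, abs=1.0)
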