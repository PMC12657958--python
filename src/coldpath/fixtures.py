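"""Synthetic, fully hydrogenated toy peptides for testing and demos.

``build_peptide`` constructs a pair of PDB texts (start and end conformer)
for an arbitrary sequence with per-residue torsion prescriptions.  Geometry
comes from the bundled idealised residue templates, so both end states share
exactly the same bond lengths and angles and differ only in torsion angles —
the regularised input the interpolation engine assumes.

Presets at the bottom plant specific algorithmic situations: a large-travel
flip candidate, a mid-path sidechain clash, and a symmetric-sidechain
naming mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import templates
from .geometry import bond_angle, bond_length, kabsch_rotation, nerf_place
from .structure import KinematicModel, Structure, StructureError, Topology

# inter-residue ideal geometry (Engh & Huber style values)
PEPTIDE_C_N = 1.329      # A
ANGLE_CA_C_N = 116.2     # deg
ANGLE_C_N_CA = 121.7     # deg
ANGLE_C_N_H = 119.15     # deg
N_H = 1.01               # A
C_O = 1.231              # A
ANGLE_CA_C_O = 120.1     # deg

DEFAULT_PHI = -139.0     # extended-strand baseline
DEFAULT_PSI = 135.0
DEFAULT_OMEGA = 180.0


@dataclass
class FixtureSpec:
    """Recipe for a toy conformer pair.

    ``start`` and ``end`` map 1-based residue numbers to torsion
    prescriptions, e.g. ``{2: {"phi": -57, "psi": -47, "chi1": 60}}``.
    Unprescribed torsions take identical baseline values in both states.
    """

    sequence: str
    start: dict[int, dict[str, float]] = field(default_factory=dict)
    end: dict[int, dict[str, float]] = field(default_factory=dict)
    chain: str = "A"
    seed: int = 0


def build_peptide(spec: FixtureSpec) -> tuple[str, str]:
    """Build (start_pdb_text, end_pdb_text) for a fixture recipe."""
    if len(spec.sequence) < 1:
        raise ValueError("sequence must contain at least one residue")
    raw = _assemble_reference(spec)
    topo = Topology(raw)
    model = KinematicModel(topo, raw.coords)
    start = _apply_prescriptions(raw, topo, model, spec.start, spec.chain)
    end = _apply_prescriptions(raw, topo, model, spec.end, spec.chain)
    return start.to_pdb_text(), end.to_pdb_text()


def _kept_atoms(res_name: str, first: bool, last: bool) -> list[int]:
    names, _, _, _ = templates.template(res_name)
    keep = []
    for k, nm in enumerate(names):
        if nm == "HXT":
            continue
        if nm == "OXT" and not last:
            continue
        if nm == "H2" and not first:
            continue
        if nm == "H" and not first and res_name == "PRO":
            continue  # proline backbone nitrogen carries no amide hydrogen
        keep.append(k)
    return keep


def _assemble_reference(spec: FixtureSpec) -> Structure:
    """Rigidly chain template residues into one valid reference structure."""
    seq3 = []
    for c in spec.sequence.upper():
        if c not in templates.ONE_TO_THREE:
            raise ValueError(f"unknown one-letter residue code {c!r}")
        seq3.append(templates.ONE_TO_THREE[c])

    all_names, all_elements, all_coords = [], [], []
    res_seqs, res_names = [], []
    prev = None  # dict of backbone positions of previous residue
    n_res = len(seq3)
    for i, rname in enumerate(seq3):
        names, elements, coords, _ = templates.template(rname)
        keep = _kept_atoms(rname, first=(i == 0), last=(i == n_res - 1))
        local = {names[k]: coords[k].copy() for k in keep}
        if prev is None:
            placed = local
        else:
            n_pos = nerf_place(prev["N"], prev["CA"], prev["C"],
                               PEPTIDE_C_N, ANGLE_CA_C_N, DEFAULT_PSI)
            ca_pos = nerf_place(prev["CA"], prev["C"], n_pos,
                                bond_length(local["N"], local["CA"]),
                                ANGLE_C_N_CA, DEFAULT_OMEGA)
            c_pos = nerf_place(prev["C"], n_pos, ca_pos,
                               bond_length(local["CA"], local["C"]),
                               bond_angle(local["N"], local["CA"],
                                          local["C"]),
                               DEFAULT_PHI)
            placed = _rigid_map(local, {"N": n_pos, "CA": ca_pos,
                                        "C": c_pos})
            if "H" in placed:
                placed["H"] = nerf_place(prev["CA"], prev["C"], n_pos,
                                         N_H, ANGLE_C_N_H, 0.0)
            # carbonyl O of the previous residue must be anti to this N
            prev_o = nerf_place(prev["N"], prev["CA"], prev["C"],
                                C_O, ANGLE_CA_C_O, DEFAULT_PSI + 180.0)
            all_coords[prev["O_index"]] = prev_o
        order = [names[k] for k in keep]
        start_index = len(all_names)
        for nm in order:
            all_names.append(nm)
            all_elements.append(elements[names.index(nm)])
            all_coords.append(placed[nm])
            res_seqs.append(i + 1)
            res_names.append(rname)
        prev = {
            "N": placed["N"], "CA": placed["CA"], "C": placed["C"],
            "O_index": start_index + order.index("O"),
        }
    n = len(all_names)
    return Structure(
        names=all_names,
        elements=all_elements,
        chains=[spec.chain] * n,
        res_seqs=res_seqs,
        icodes=[""] * n,
        res_names=res_names,
        serials=list(range(1, n + 1)),
        coords=np.array(all_coords),
    )


def _rigid_map(local: dict, targets: dict) -> dict:
    """Rigid transform of a residue so its N, CA, C land on target points."""
    src = np.array([local["N"], local["CA"], local["C"]])
    dst = np.array([targets["N"], targets["CA"], targets["C"]])
    src_c, dst_c = src.mean(axis=0), dst.mean(axis=0)
    rot = kabsch_rotation(src - src_c, dst - dst_c)
    return {nm: (xyz - src_c) @ rot.T + dst_c for nm, xyz in local.items()}


def _apply_prescriptions(raw, topo, model, prescriptions, chain) -> Structure:
    deltas = np.zeros(model.n_torsions)
    for res_seq, torsions in prescriptions.items():
        for name, target in torsions.items():
            try:
                k = topo.torsion_index(chain, res_seq, name)
            except KeyError as exc:
                raise StructureError(
                    f"prescription {chain}:{res_seq}:{name} does not match a "
                    "rotatable torsion (ring torsions are frozen)"
                ) from exc
            deltas[k] = target - model.ref_torsions[k]
    coords = model.build(deltas)
    return raw.with_coords(coords)


# ---------------------------------------------------------------------------
# Presets


def preset(name: str, seed: int = 0) -> FixtureSpec:
    """Named fixture recipes exercising specific algorithmic branches."""
    if name == "helix-coil":
        n = 5
        helix = {i: {"phi": -57.0, "psi": -47.0} for i in range(2, n)}
        strand = {i: {"phi": -139.0, "psi": 135.0} for i in range(2, n)}
        return FixtureSpec("AASAA", start=helix, end=strand, seed=seed)
    if name == "flip":
        # chi1 travelling most of a full turn: flip candidate (> 30 deg)
        return FixtureSpec(
            "ALA",
            start={2: {"chi1": 60.0}},
            end={2: {"chi1": -160.0}},
            seed=seed,
        )
    if name == "clash":
        # helix i, i+3 contact: Phe ring and Leu sidechain cross through a
        # shared region mid-transition (both end states are clash-free)
        helix = {i: {"phi": -57.0, "psi": -47.0} for i in range(2, 6)}
        start = {i: dict(v) for i, v in helix.items()}
        end = {i: dict(v) for i, v in helix.items()}
        start[2]["chi1"] = -60.0
        end[2]["chi1"] = 60.0
        start[5]["chi1"] = 60.0
        end[5]["chi1"] = 180.0
        return FixtureSpec("AFAALA", start=start, end=end, seed=seed)
    if name == "rotamer":
        # single-rotamer crossing clash resolvable by one chi1 harmonic:
        # retiming the Thr sweep lets it pass before the Phe ring arrives
        helix = {i: {"phi": -57.0, "psi": -47.0} for i in range(2, 6)}
        start = {i: dict(v) for i, v in helix.items()}
        end = {i: dict(v) for i, v in helix.items()}
        start[2]["chi1"] = -60.0
        end[2]["chi1"] = 60.0
        start[5]["chi1"] = 60.0
        end[5]["chi1"] = -60.0
        return FixtureSpec("AFAATA", start=start, end=end, seed=seed)
    if name == "symmetric":
        # phenylalanine ring labelled 180 deg apart in the two end states
        return FixtureSpec(
            "AFA",
            start={2: {"chi2": 10.0}},
            end={2: {"chi2": -165.0}},
            seed=seed,
        )
    raise KeyError(f"unknown preset {name!r}")
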