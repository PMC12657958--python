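"""Trajectory export and geometric diagnostics.

Exports refined paths as multi-model PDB files and computes the analyses
used to interrogate transporter mechanisms: gate-triangle areas (a solvent
accessibility proxy spanned by three Calpha atoms), segment RMSD against a
reference conformation, and the maximum mid-path excursion of a selection
away from the straight-line Cartesian blend of the end states.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .geometry import kabsch_rotation, rmsd, superpose
from .path import PathState
from .structure import Structure

__all__ = [
    "Trajectory",
    "TriangleProbe",
    "export_trajectory",
    "read_trajectory",
    "triangle_area",
    "segment_rmsd",
    "max_excursion",
    "parse_selection",
    "profile_table",
]


@dataclass
class Trajectory:
    """Frames sampled along the path plus their progress values."""

    structure: Structure
    progress: np.ndarray          # (n_frames,)
    frames: np.ndarray            # (n_frames, n_atoms, 3)


@dataclass(frozen=True)
class TriangleProbe:
    """Three Calpha selectors, e.g. ``TriangleProbe.parse("A:58,A:227,A:378")``."""

    selectors: tuple[tuple[str, int], ...]

    @classmethod
    def parse(cls, text: str) -> "TriangleProbe":
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 3:
            raise ValueError("a triangle probe needs exactly 3 selectors")
        sels = []
        for p in parts:
            chain, num = p.split(":")
            sels.append((chain, int(num)))
        return cls(tuple(sels))


def export_trajectory(path: PathState, n_frames: int = 101) -> str:
    """Multi-model PDB text with frames at evenly spaced progress values."""
    if n_frames < 2:
        raise ValueError("a trajectory needs at least the two endpoints")
    ps = np.linspace(0.0, 1.0, n_frames)
    frames = path.frames(ps, superpose_frames=True)
    st = gemmi.Structure()
    for k in range(n_frames):
        model = path.pair.structure.with_coords(
            frames[k]).to_gemmi_model(str(k + 1))
        _append_het(model, path.pair.het_atoms, ps[k])
        st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def _append_het(model: "gemmi.Model", het_atoms, p: float) -> None:
    """Append rigidly carried ligand atoms on the linear Cartesian blend."""
    groups: dict[tuple, list] = {}
    for rec in het_atoms:
        groups.setdefault(tuple(rec[:3]), []).append(rec)
    for (chain_name, seq, rname), records in groups.items():
        chain = next((c for c in model if c.name == chain_name), None)
        if chain is None:
            model.add_chain(gemmi.Chain(chain_name))
            chain = model[-1]
        res = gemmi.Residue()
        res.name = rname
        res.seqid = gemmi.SeqId(seq, " ")
        res.het_flag = "H"
        for _, _, _, name, element, pos0, pos1 in records:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*(pos0 + p * (pos1 - pos0)))
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)


def read_trajectory(pdb_text: str) -> Trajectory:
    """Read a multi-model PDB back into a Trajectory (p assumed uniform)."""
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in trajectory")
    frames = []
    base = Structure.from_gemmi_model(st[0])
    for model in st:
        s = Structure.from_gemmi_model(model)
        frames.append(s.coords)
    n = len(frames)
    ps = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    return Trajectory(structure=base, progress=ps,
                      frames=np.stack(frames))


def _ca_index(structure: Structure, chain: str, seq: int) -> int:
    try:
        return structure.atom_index(chain, seq, "CA")
    except KeyError as exc:
        raise KeyError(f"residue {chain}:{seq} has no Calpha in this "
                       "structure") from exc


def triangle_area(frame: np.ndarray, structure: Structure,
                  probe: TriangleProbe) -> float:
    """Area (A^2) of the triangle spanned by the probe's three Calphas."""
    pts = np.array([frame[_ca_index(structure, c, n)]
                    for c, n in probe.selectors])
    return float(0.5 * np.linalg.norm(
        np.cross(pts[1] - pts[0], pts[2] - pts[0])))


def parse_selection(structure: Structure, text: str) -> np.ndarray:
    """Calpha atom indices for selections like ``"A:1-43"`` or ``"A:58"``.

    Comma-separated terms are united.
    """
    idx: list[int] = []
    for term in text.split(","):
        term = term.strip()
        m = re.fullmatch(r"([^:]+):(-?\d+)(?:-(-?\d+))?", term)
        if not m:
            raise ValueError(f"cannot parse selection term {term!r}")
        chain, lo = m.group(1), int(m.group(2))
        hi = int(m.group(3)) if m.group(3) else lo
        for seq in range(lo, hi + 1):
            try:
                idx.append(structure.atom_index(chain, seq, "CA"))
            except KeyError:
                continue
    if not idx:
        raise ValueError(f"selection {text!r} matches no Calpha atoms")
    return np.array(idx, dtype=int)


def segment_rmsd(frame: np.ndarray, reference: np.ndarray,
                 selection: np.ndarray,
                 ref_selection: np.ndarray | None = None) -> float:
    """Calpha RMSD of a selection after least-squares superposition.

    ``selection`` indexes the frame; ``ref_selection`` (defaults to the
    same indices) indexes the reference coordinates.
    """
    ref_selection = selection if ref_selection is None else ref_selection
    a = frame[selection]
    b = reference[ref_selection]
    if a.shape != b.shape:
        raise ValueError(
            f"selection sizes differ: {a.shape[0]} vs {b.shape[0]} atoms")
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    rot = kabsch_rotation(a_c, b_c)
    return rmsd(a_c @ rot.T, b_c)


def max_excursion(path: PathState, selection: np.ndarray,
                  n_frames: int = 101) -> tuple[float, float]:
    """Largest mid-path deviation of a selection from the linear blend.

    For each sampled progress value the standardised frame (see
    ``PathState.frames``) is compared against the straight-line Cartesian
    blend of the harmonised end states; the deviation is the RMS
    displacement of the selected Calpha atoms.  Returns (max_deviation_A,
    progress_at_max).  By construction the deviation vanishes at p = 0 and
    p = 1, so a non-zero result is a genuinely mid-path excursion.
    """
    ps = np.linspace(0.0, 1.0, n_frames)
    frames = path.frames(ps, superpose_frames=True)
    start = path.pair.start_coords[selection]
    end = path.pair.end_coords[selection]
    devs = np.empty(n_frames)
    for k, p in enumerate(ps):
        blend = start + p * (end - start)
        diff = frames[k][selection] - blend
        devs[k] = np.sqrt(np.mean(np.sum(diff * diff, axis=-1)))
    k = int(np.argmax(devs))
    return float(devs[k]), float(ps[k])


def profile_table(path: PathState, n_frames: int = 101,
                  triangles: dict[str, TriangleProbe] | None = None,
                  late_ctx=None) -> pd.DataFrame:
    """Per-frame diagnostics as a DataFrame (one row per exported frame).

    Columns: frame, p, per-probe triangle areas, and instantaneous energy
    terms when a late-stage context is supplied.
    """
    from .late import torsion_energy

    ps = np.linspace(0.0, 1.0, n_frames)
    frames = path.frames(ps, superpose_frames=True)
    rows = {"frame": np.arange(n_frames), "p": ps}
    if triangles:
        s = path.pair.structure
        for name, probe in triangles.items():
            rows[f"area_{name}"] = [
                triangle_area(frames[k], s, probe) for k in range(n_frames)]
    if late_ctx is not None:
        tmat = path.torsion_values(ps)
        t = late_ctx.combos.values(tmat)
        rows["torsion_energy"] = torsion_energy(
            t, late_ctx.combos.z_t[None, :]).sum(axis=1)
    return pd.DataFrame(rows)
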