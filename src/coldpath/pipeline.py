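"""End-to-end orchestration: from two PDB texts to a refined path.

The stages mirror the method: read and harmonise the end states,
reconcile symmetric sidechains, resolve torsion directions and flips,
refine harmonic amplitudes against the early-stage glidepath target, then
resolve residual clashes against the late-stage energy.
"""

from __future__ import annotations

import logging

from .config import PathConfig
from .early import refine_early, select_pairs, j_early
from .late import LateContext, VdWParams, j_late, refine_late
from .path import PathState, ProgressGrid, apply_flip_overrides, \
    resolve_flips
from .structure import canonicalize_symmetric_sidechains, \
    harmonize_geometry, read_structure

logger = logging.getLogger(__name__)


def morph(
    start_pdb: str,
    end_pdb: str,
    config: PathConfig | None = None,
    flips: str | None = None,
    refine: bool = True,
) -> tuple[PathState, dict]:
    """Compute a cold-inbetween path between two conformations.

    Parameters
    ----------
    start_pdb, end_pdb : PDB-format texts of the two end states (same atom
        set, explicit hydrogens, regularised geometry).
    config : engine parameters; defaults throughout.
    flips : optional manual-override file text (see
        ``path.parse_flip_file``).
    refine : skip both refinement stages when False (linear torsion path
        with resolved directions only).

    Returns (path, report); the report collects energies before/after each
    stage and the end-state rebuild quality.
    """
    cfg = config if config is not None else PathConfig()
    start, topo = read_structure(start_pdb, ligands=cfg.ligands)
    end, _ = read_structure(end_pdb, ligands=cfg.ligands)
    pair = harmonize_geometry(start, end, topology=topo)
    report: dict = {"end_rebuild_ca_rmsd": pair.end_rebuild_ca_rmsd}
    if cfg.resolution is not None:
        pair = canonicalize_symmetric_sidechains(pair, cfg.resolution)
    grid = ProgressGrid(cfg.integration_steps)
    path = PathState(pair, grid=grid)
    if flips:
        apply_flip_overrides(path, flips)
    flip_results = resolve_flips(path)
    report["flips_accepted"] = sum(1 for _, acc in flip_results if acc)
    report["flip_candidates"] = len(flip_results)

    pairs = select_pairs(pair, cutoff=cfg.pair_cutoff)
    report["n_early_pairs"] = len(pairs)
    report["j_early_linear"] = j_early(path, pairs, grid)
    if refine:
        early_rep = refine_early(path, pairs, grid, tol=cfg.early_tol)
        report["early"] = early_rep

    ctx = LateContext(pair, VdWParams(epsilon=cfg.epsilon,
                                      pair_cutoff=cfg.late_pair_cutoff))
    report["j_late_before"] = j_late(path, ctx, attribution=False).value
    if refine:
        late_rep = refine_late(
            path, ctx,
            simplex_step_deg=cfg.simplex_step_deg,
            rel_tol=cfg.late_rel_tol,
            top_residues=cfg.top_residues,
        )
        report["late"] = late_rep
        report["j_late_after"] = late_rep["final"]
        report["j_early_final"] = j_early(path, pairs, grid)
    return path, report
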