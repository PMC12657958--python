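"""Run configuration with the tunable parameters that matter."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class PathConfig:
    """Knobs of the interpolation engine.

    Attributes
    ----------
    pair_cutoff : A, early-stage close-pair limit (either endpoint distance
        below this includes the pair).
    integration_steps : number of progress-grid intervals for numerical
        integration of both targets.
    early_tol : absolute convergence tolerance on the early-stage target per
        L-BFGS cycle.
    late_pair_cutoff : A, late-stage pair limit; may need to be larger than
        8 A for large-scale rearrangements.
    epsilon : Lennard-Jones well depth (uniform; only relative magnitudes
        matter for minimisation).
    simplex_step_deg : initial Nelder-Mead simplex step for amplitude
        refinement, degrees.
    late_rel_tol : stop late-stage rounds once the relative decrease of
        J_late is at most this.
    top_residues : number of worst residues refined jointly in stage B.
    ligands : "drop" to ignore HETATM groups, "rigid" to carry them as
        rigid bodies on the linear Cartesian blend in exported frames.
    resolution : A, of the underlying structures; extends the symmetric-
        sidechain reconciliation to Asn/Gln/His when above 2.4 A.
    """

    pair_cutoff: float = 8.0
    integration_steps: int = 12
    early_tol: float = 1e-3
    late_pair_cutoff: float = 8.0
    epsilon: float = 1.0
    simplex_step_deg: float = 10.0
    late_rel_tol: float = 0.05
    top_residues: int = 5
    ligands: str = "drop"
    resolution: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)
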