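# Methods

## The problem

Membrane transporters (and many other proteins) work by switching between
experimentally determined conformations — outward-open to inward-open in the
alternate-access model — but crystallography and cryo-EM only capture the end
states. `coldpath` interpolates between two such structures in
**torsion-angle space**, producing a "cold" trajectory: one that minimises
fluctuations in kinetic and potential energy along the way while deliberately
omitting thermal motion. The result is not a dynamical trajectory with a
timescale; it is a geometric hypothesis for the transition mechanism around
which thermally driven paths are expected to scatter.

## Model

### Degrees of freedom

Both end states must share one atom set with explicit hydrogens and
regularised covalent geometry. Bond lengths and bond angles are **frozen**:
the start structure is authoritative for them, and the end state is rebuilt
by forward kinematics from the start state's bond lengths/angles plus the end
state's measured torsion angles (`harmonize_geometry`). After harmonisation
the conformers differ exclusively in torsion angles; the Calpha RMSD between
the rebuilt and the deposited end state is reported as a regularisation
check (warning above 0.5 Å).

Rotatable torsions are enumerated from a template-derived bond graph
(residue templates from the Chemical Component Dictionary, peptide bonds by
sequence adjacency, disulfides by S–S < 2.5 Å). A bond is rotatable iff it is
a bridge of the bond graph (no bond inside a ring can rotate — torsion-only
kinematics cannot close rings) and both endpoints have further substituents.
Peptide ω bonds *are* rotatable: real transitions include peptide flips.
Methyl, hydroxyl and terminal-amine rotors are included.

Reconstruction uses a NeRF-style kinematic tree per chain, anchored at the
first three backbone atoms, vectorised over frames and over atoms of equal
tree depth. Exported frames are additionally least-squares superposed (over
non-hydrogen atoms) onto the linear Cartesian blend of the end states; all
energies are functions of inter-atomic distances within a frame and are
therefore invariant to this standardisation.

### Torsion trajectories

Each rotatable torsion follows

    t_i(p) = θ_i⁰ + p (θ_i¹ − θ_i⁰) + Σ_{j=1..3} f_j sin(j p π),   p ∈ [0, 1]

with refinable harmonic amplitudes f_j (degrees, default 0) that vanish at
the endpoints, so the end states are always reproduced exactly.

**Direction choice.** θ_i¹ − θ_i⁰ is a signed travel, not a wrapped
difference. Wrapped differences of ≤ 30° always take the short way. Larger
ones follow the rotation sense of the straight-line Cartesian blend of the
end states: the torsion is measured on blended atom positions at
p = 0, 0.1, …, 1, successively unwrapped by {−360°, 0°, +360°} to stay
closest to the previous value; the unwrapped endpoint fixes sign and
winding. Degenerate (collinear) blended quadruples fall back to the short
way with a logged warning.

**Flips.** Every torsion travelling more than 30° is then tested, in
descending |travel| order, against the alternative travel ∓360°; a flip is
accepted iff the summed polyline length of all atom trajectories across the
progress grid strictly decreases (ties keep the original). Sequentially
accepted flips update the path before the next candidate. Manual overrides
(a plain-text flip file: `chain resnum torsion_name offset [f1 f2 f3]`)
mirror the practical need to curate a handful of hard cases by hand.

**Symmetric sidechains.** Before direction resolution, terminal two-fold
symmetric torsions (Phe/Tyr χ2, Asp χ2, Glu χ3, Arg χ5) of the end state
are shifted by 180° whenever that reduces the apparent travel — the
deposited naming of symmetric branches is arbitrary. Above 2.4 Å resolution
the rule extends to Asn χ2, Gln χ3 and His χ2, whose branch identities
cannot be distinguished in weak density.

### Early-stage target

All non-hydrogen atom pairs separated by more than three bonds, not in the
same aromatic ring, and closer than 8 Å in *either* end state receive a
linear distance glidepath d_q(p) = d⁰ + p (d¹ − d⁰). The target is

    J_early = sqrt( Σ_pairs ∫₀¹ ω (d_q − d_p)² dp ),   ω = 1/(1 + d_p)

with d_p the calculated distance; ω up-weights close contacts. The integral
uses the trapezoid rule on a 13-point (12-interval) grid — the integrand
vanishes at both endpoints, so low-order quadrature suffices (measured
agreement with a 10⁴-point oracle: ≲ 0.05%, test bound 2%). The pair list is
frozen after selection. Amplitudes are refined by L-BFGS (finite-difference
gradients) in stages {f₁}, then {f₁,f₂}, then {f₁,f₂,f₃} over all channels
jointly, each stage iterated until the target changes by < 10⁻³; the best
parameters seen are always kept, so the target never increases.

### Late-stage target

The early target under-penalises genuine steric clashes, so a second energy
is minimised afterwards:

    J_late = J_VdW + J_torsion

*J_VdW* compares a two-term Lennard-Jones energy 4ε[(σ/d)¹² − (σ/d)⁶] at the
calculated distance with the same expression at the glidepath distance and
counts only the positive excess — contacts already present in the end
states (e.g. hydrogen bonds) are free. σ per atom is 0.75 × its van der
Waals radius; a pair uses the arithmetic mean of the two σ (the symmetric
choice; exposed in config). ε is uniform 1.0 — only relative magnitudes
matter for minimisation. Hydrogens are included here (pairs within the late
cutoff, same >3-bond exclusion). Because atoms can pass closest *between*
grid points, each interval's contribution evaluates the minimum distance of
cubic interpolants through four consecutive frames of each atom's track
(windows shifted inward at the path ends); the minimum is located by
sampling the interpolant at 33 points plus parabolic refinement (≤ 0.01%
from a 1000-point dense search). Pairs that cannot dip near contact —
screened by knot distances minus within-window displacements — skip the
spline work.

*J_torsion* sums, over every central bond and all torsion angles centred on
it, a bell-curve eclipse penalty E(t) = z_T (1 + (t/60°)²)⁻³ with
z_T = sqrt(z_{A'}² + z_{B'}²) from the atomic numbers of the two terminal
atoms. Both terms are integrated over the same 13-point grid (trapezoid; an
open design choice — a per-frame sum differs only by a constant factor).

**Clash resolution.** Stage A runs an independent Nelder-Mead descent per
residue over the amplitudes of torsions that move only that residue's
sidechain (initial simplex step 10°, termination at 10⁻⁴ energy spread or
200 iterations), each against the subproblem of pairs touching its moved
atoms; results are merged deterministically in residue order, falling back
to greedy acceptance if independent updates conflict. Stage B ranks
residues by their energy attribution (pair terms credited to both atoms'
residues) and runs one joint descent for the top five. Rounds repeat until
J_late drops by at most 5%. Candidate updates are kept only when the global
target decreases, so the protocol is monotone and bit-reproducible (no
shared mutable state; reruns are identical).

## Synthetic data

The `fixtures` module builds fully hydrogenated peptides from idealised
residue templates, with per-residue torsion prescriptions for both end
states; both states share exactly the same covalent geometry by
construction, which is precisely the regularised input the engine assumes.
Presets plant one algorithmic situation each:

- `helix-coil` — AASAA, α-helical (φ=−57°, ψ=−47°) to extended
  (φ=−139°, ψ=135°) backbone; exercises direction choice and early-stage
  refinement.
- `flip` — a Leu χ1 travelling 140°, a flip candidate.
- `clash` — AFAALA on a helical backbone: Phe and Leu sidechains (i, i+3)
  cross through a shared region mid-path; both end states are clash-free.
- `rotamer` — AFAATA: a Phe/Thr crossing resolvable by a single χ1
  harmonic (retiming the Thr sweep ahead of the ring's arrival), with an
  unambiguous 1-D optimum.
- `symmetric` — a Phe χ2 labelled 10° vs −165° between the end states.

What these toys do **not** emulate: crystallographic coordinate error and
incomplete regularisation, ligands/ions in the transition region, membrane
or solvent contacts, and system sizes where pair lists reach millions —
so passing tests demonstrate correctness of the machinery, not transporter-
scale performance or robustness to experimental model error. Full-scale
transporter analyses additionally require curated manual flip overrides;
the engine supports them through the flip file.

## Numerical choices and degenerate inputs

- Progress-grid size 12 intervals (default, configurable); direction-choice
  p-spacing fixed at 0.1.
- "Resolved to zero" clash energy means the numerical floor: arc-vs-chord
  distance mismatch leaves O(10⁻²–10⁻¹) ε of positive thresholded LJ even on
  clash-free moving systems; the planted clash (433 ε) refines below 0.1 ε,
  i.e. no steric overlap at the ε scale.
- Ties in flip evaluation keep the original direction; equal-energy
  Nelder-Mead proposals are resolved by residue order (deterministic).
- Collinear dihedral quadruples (exactly straight angles) are the only
  degenerate geometry; they are detected and fall back to short-way travel.
- Alternate locations, missing hydrogens, unknown residues and chain breaks
  are rejected at parse/topology time with the offending residue named.
- HETATM groups are dropped by default; with `ligands="rigid"` they are
  carried on the linear Cartesian blend in exported frames but take no part
  in kinematics or energies (their influence on the path is not modelled).

## Problem sizes

Tests and the acceptance script use 3–7-residue peptides (50–120 atoms,
20–50 rotatable torsions, 10³–10⁴ late-stage pairs); a full refinement of
such a system takes seconds to ~1 minute on one CPU. The engine's cost is
dominated by frame reconstruction inside the optimisers and scales linearly
in atoms × grid points per objective evaluation; transporter-sized systems
(~10³ residues) are expected to take hours, matching the intended
offline-analysis usage.

## Known limitations

- No electrostatics, solvation or membrane terms; no thermal sampling, no
  timescale.
- Relative rigid-body motion between disconnected chains is not
  representable in torsion space; multi-chain inputs are only meaningful
  when inter-chain placement is unchanged (or chains are disulfide-linked).
- The late-stage landscape is multi-modal; "tangled" sidechains may need
  manual harmonic overrides rather than automated global search.
- Imperfections in the end states are imprinted on the whole trajectory;
  inputs should be regularised and checked beforehand.
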