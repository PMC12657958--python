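# coldpath

**Minimum-energy-fluctuation interpolation between protein conformations in
torsion-angle space** ("cold inbetweening").

Experimental structural biology routinely delivers two end states of a
conformational transition — e.g. the outward-open and inward-open forms of a
membrane transporter — but not the path between them. `coldpath` generates
that path as a trajectory in internal coordinates: bond lengths and angles
are frozen, and every rotatable torsion t_i interpolates between its
end-state values with refinable harmonic perturbations,

    t_i(p) = θ_i⁰ + p (θ_i¹ − θ_i⁰) + Σ_{j=1}^{3} f_j sin(j p π),  p ∈ [0, 1].

The amplitudes f_j are chosen so that inter-atomic distances track linear
"glidepaths" d_q(p) = d⁰ + p (d¹ − d⁰) between their end-state values
(early stage, a weighted least-squares target J_early minimised by staged
L-BFGS), after which residual sidechain clashes are resolved against a
late-stage energy J_late = J_VdW + J_torsion — a glidepath-thresholded
Lennard-Jones excess plus a bell-curve torsion-eclipse penalty — using
per-residue Nelder-Mead descents. Torsion rotation directions (including
±360° "flips") are resolved from the Cartesian blend of the end states and
a total-path-length criterion, with a plain-text override file for the hard
cases. Trajectories export as multi-model PDB; analysis helpers compute
gate-triangle areas, segment RMSD against references, and mid-path
excursions — the diagnostics used to interrogate alternate-access
transporter mechanisms.

The deliberate omission of thermal motion is the point: the trajectory is a
low-noise mechanical hypothesis, complementary to (not a substitute for) MD.

Audience: structural biologists and method developers who have two prepared
conformations of the same polypeptide (identical atom sets, explicit
hydrogens, regularised geometry) and want a mechanistic interpolation plus
its geometric analysis.

## Worked example

Build a synthetic helix→strand transition, refine it, and look at the
numbers (no external files needed — the fixture generator writes both end
states):

```python
import numpy as np
from coldpath import (PathState, LateContext, harmonize_geometry,
                      j_early, j_late, read_structure, refine_early,
                      resolve_flips, select_pairs)
from coldpath.fixtures import build_peptide, preset

start_txt, end_txt = build_peptide(preset("helix-coil"))
start, topo = read_structure(start_txt)
end, _ = read_structure(end_txt)

pair = harmonize_geometry(start, end, topology=topo)
path = PathState(pair)
resolve_flips(path)

pairs = select_pairs(pair)                  # close-pair glidepaths
print(f"J_early (linear path): {j_early(path, pairs):.4f}")
report = refine_early(path, pairs)
print(f"J_early (refined):     {report['final']:.4f}")
```

prints

```
J_early (linear path): 2.6024
J_early (refined):     1.5410
```

i.e. harmonic perturbations cut the weighted RMS deviation of the 250
atom-pair distances from their glidepaths by ~41% relative to naive linear
torsion interpolation — backbone atoms now travel nearly straight lines
even though they move purely by bond rotations.

Clash resolution on a planted sidechain crossing (`rotamer` preset — a Phe
ring and a Thr sidechain sweep through the same region mid-path):

```python
from coldpath import refine_late

start_txt, end_txt = build_peptide(preset("rotamer"))
start, topo = read_structure(start_txt)
end, _ = read_structure(end_txt)
pair = harmonize_geometry(start, end, topology=topo)
path = PathState(pair)
resolve_flips(path)

ctx = LateContext(pair)
print(f"J_VdW before: {j_late(path, ctx).j_vdw:.1f}")
refine_late(path, ctx)
print(f"J_VdW after:  {j_late(path, ctx).j_vdw:.3f}")
```

```
J_VdW before: 432.9
J_VdW after:  0.070
```

The clash energy (in units of the Lennard-Jones well depth ε) drops by
99.98%: retiming the Thr χ1 sweep lets it pass before the ring arrives.

From the shell, the same pipeline is:

```bash
coldpath fixture --preset helix-coil --out fix/
coldpath run --start fix/start.pdb --end fix/end.pdb --out traj.pdb --frames 101
coldpath analyze --traj traj.pdb --triangle "A:1,A:3,A:5" --out profile.csv
coldpath flip --start fix/start.pdb --end fix/end.pdb   # list flip candidates
```

`traj.pdb` is a 101-model PDB (1% progress steps) viewable in PyMOL/ChimeraX;
`profile.csv` holds per-frame probe values. The `examples/` directory has
one short narrative script per capability.

Real transporter inputs (e.g. PDB pairs 6BVG/5IWS, 8E6N/8E6I, 6FHZ/6HFB)
must be prepared first: re-refined/regularised, hydrogenated, and reduced to
a common atom set — see `docs/methods.md` for the assumptions, and use
`coldpath flip` plus a flip-override file for the manual direction
curation such transitions need.

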