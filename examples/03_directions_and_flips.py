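"""Torsion direction choice and +-360 degree flip evaluation.

A Leu chi1 travels 140 degrees between the end states; the direction is
resolved from the Cartesian blend of the end states, and the alternative
-220 degree rotation is tested against the total distance travelled by the
atoms.  A manually planted +350 degree travel demonstrates an accepted flip.
"""

from coldpath import (PathState, evaluate_flip, harmonize_geometry,
                      read_structure, resolve_flips)
from coldpath.fixtures import build_peptide, preset

start_txt, end_txt = build_peptide(preset("flip"))
start, topo = read_structure(start_txt)
end, _ = read_structure(end_txt)
pair = harmonize_geometry(start, end, topology=topo)
path = PathState(pair)

k = topo.torsion_index("A", 2, "chi1")
print(f"Leu2 chi1 resolved travel: {path.channels[k].travel:+.1f} deg")
results = resolve_flips(path)
for idx, accepted in results:
    sel = topo.rotatable_torsions[idx].selector
    print(f"flip candidate {sel}: {'accepted' if accepted else 'kept'}"
          f" -> travel {path.channels[idx].travel:+.1f} deg")

# plant an absurd winding and watch the flip correct it
ch = path.channels[k]
ch.theta1 = ch.theta0 + 350.0
path.invalidate()
accepted, before, after = evaluate_flip(path, k)
print(f"planted +350 deg travel: flip accepted={accepted}, "
      f"path length {before:.1f} -> {after:.1f} A, "
      f"new travel {ch.travel:+.1f} deg")
print("The metric is the summed polyline length of every atom's track;")
print("a flip is kept only when it strictly shortens the overall motion.")
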