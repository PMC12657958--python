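"""Structure model: PDB parsing, covalent topology, torsion kinematics.

A protein is represented by a :class:`Structure` (parallel arrays of atom
attributes plus coordinates), a :class:`Topology` (bond graph, rigid rings,
rotatable torsions and the kinematic tree used for internal-coordinate
reconstruction) and, for a transition, a :class:`ConformerPair` holding the
two harmonised end states.

Torsion-only kinematics cannot change bond lengths or bond angles, so the
pair of end states must share one covalent geometry.  ``harmonize_geometry``
rebuilds the end state by forward kinematics from the start state's bond
lengths and angles combined with the end state's measured torsion angles;
after that, the two conformers differ exclusively in torsion angles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import networkx as nx
import numpy as np

from . import templates
from .geometry import (
    bond_angle,
    bond_length,
    dihedral,
    nerf_place,
    rmsd,
    superpose,
    wrap_angle,
)

DISULFIDE_MAX = 2.5  # A, S-S bond detection
PEPTIDE_MAX = 1.8    # A, C-N bond sanity for sequence-adjacent residues


class StructureError(ValueError):
    """Raised for malformed or unsupported input structures."""


# ---------------------------------------------------------------------------
# Structure container


@dataclass(frozen=True)
class AtomSite:
    """One atom of a structure (a convenience view; arrays are primary)."""

    serial: int
    name: str
    element: str
    residue_id: tuple[str, int, str]
    position: np.ndarray
    atomic_number: int
    vdw_radius: float
    is_hydrogen: bool
    aromatic_ring_id: int | None


@dataclass
class Residue:
    chain: str
    seq: int
    icode: str
    name: str
    atom_indices: list[int]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq, self.icode)


class Structure:
    """Parallel-array container for one conformer."""

    def __init__(self, names, elements, chains, res_seqs, icodes, res_names,
                 serials, coords):
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.chains = np.asarray(chains, dtype=object)
        self.res_seqs = np.asarray(res_seqs, dtype=int)
        self.icodes = np.asarray(icodes, dtype=object)
        self.res_names = np.asarray(res_names, dtype=object)
        self.serials = np.asarray(serials, dtype=int)
        self.coords = np.asarray(coords, dtype=float)
        zs, radii = [], []
        for el in self.elements:
            z, r = templates.element_info(el)
            zs.append(z)
            radii.append(r)
        self.atomic_numbers = np.array(zs, dtype=int)
        self.vdw_radii = np.array(radii, dtype=float)
        self.is_hydrogen = np.array(
            [templates.is_hydrogen(e) for e in self.elements], dtype=bool
        )
        self.residues = self._collect_residues()
        self.het_atoms: list[tuple] = []

    def _collect_residues(self) -> list[Residue]:
        residues: list[Residue] = []
        index: dict[tuple, int] = {}
        for i in range(len(self.names)):
            key = (self.chains[i], int(self.res_seqs[i]), self.icodes[i])
            if key not in index:
                index[key] = len(residues)
                residues.append(
                    Residue(key[0], key[1], key[2], self.res_names[i], [])
                )
            residues[index[key]].atom_indices.append(i)
        return residues

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_of(self, i: int) -> tuple[str, int, str]:
        return (self.chains[i], int(self.res_seqs[i]), self.icodes[i])

    def atom_index(self, chain: str, seq: int, name: str,
                   icode: str = "") -> int:
        hits = np.nonzero(
            (self.chains == chain)
            & (self.res_seqs == seq)
            & (self.icodes == icode)
            & (self.names == name)
        )[0]
        if len(hits) != 1:
            raise KeyError(f"atom {chain}:{seq}{icode}:{name} "
                           f"({len(hits)} matches)")
        return int(hits[0])

    def atom_sites(self, topology: "Topology | None" = None) -> list[AtomSite]:
        ring_id = topology.aromatic_ring_id if topology is not None else None
        sites = []
        for i in range(self.n_atoms):
            rid = None
            if ring_id is not None and ring_id[i] >= 0:
                rid = int(ring_id[i])
            sites.append(AtomSite(
                serial=int(self.serials[i]),
                name=self.names[i],
                element=self.elements[i],
                residue_id=self.residue_of(i),
                position=self.coords[i].copy(),
                atomic_number=int(self.atomic_numbers[i]),
                vdw_radius=float(self.vdw_radii[i]),
                is_hydrogen=bool(self.is_hydrogen[i]),
                aromatic_ring_id=rid,
            ))
        return sites

    def with_coords(self, coords: np.ndarray) -> "Structure":
        clone = Structure.__new__(Structure)
        clone.__dict__.update(self.__dict__)
        clone.coords = np.asarray(coords, dtype=float)
        return clone

    # -- PDB I/O ------------------------------------------------------------

    @classmethod
    def from_pdb_text(cls, pdb_text: str, *, ligands: str = "drop"
                      ) -> "Structure":
        st = gemmi.read_pdb_string(pdb_text)
        if len(st) != 1:
            raise StructureError(
                f"expected a single model, found {len(st)}"
            )
        return cls.from_gemmi_model(st[0], ligands=ligands)

    @classmethod
    def from_gemmi_model(cls, model: "gemmi.Model", *, ligands: str = "drop"
                         ) -> "Structure":
        if ligands not in ("drop", "rigid"):
            raise ValueError("ligands must be 'drop' or 'rigid'")
        names, elements, chains, seqs, icodes, rnames, serials, xyz = (
            [], [], [], [], [], [], [], []
        )
        het: list[tuple] = []
        for chain in model:
            for res in chain:
                rname = res.name.upper()
                if rname not in templates.AMINO_ACIDS:
                    is_het = res.het_flag == "H"
                    if is_het and rname in ("HOH", "WAT"):
                        continue
                    if is_het and ligands == "drop":
                        continue
                    if is_het and ligands == "rigid":
                        for atom in res:
                            het.append((chain.name, res.seqid.num, rname,
                                        atom.name, atom.element.name,
                                        (atom.pos.x, atom.pos.y,
                                         atom.pos.z)))
                        continue
                    raise StructureError(
                        f"unknown residue {rname} {chain.name}:{res.seqid.num}"
                        " (standard amino acids only; HETATM ligands are"
                        " dropped unless carried rigidly)"
                    )
                for atom in res:
                    if atom.altloc not in ("", "\x00"):
                        raise StructureError(
                            "alternate locations present at "
                            f"{chain.name}:{res.seqid.num}:{atom.name}; "
                            "supply a single-conformer model"
                        )
                    names.append(atom.name)
                    elements.append(atom.element.name)
                    chains.append(chain.name)
                    seqs.append(res.seqid.num)
                    icodes.append((res.seqid.icode or "").strip())
                    rnames.append(rname)
                    serials.append(atom.serial)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if not names:
            raise StructureError("no protein atoms found")
        out = cls(names, elements, chains, seqs, icodes, rnames, serials,
                  np.array(xyz))
        out.het_atoms = het  # rigidly carried ligand atoms (may be empty)
        return out

    def to_pdb_text(self) -> str:
        st = self.to_gemmi()
        return st.make_pdb_string()

    def to_gemmi(self) -> "gemmi.Structure":
        st = gemmi.Structure()
        st.add_model(self.to_gemmi_model())
        st.setup_entities()
        return st

    def to_gemmi_model(self, name: str = "1") -> "gemmi.Model":
        model = gemmi.Model(name)
        serial = 0
        for resi in self.residues:
            if not len(model) or model[-1].name != resi.chain:
                model.add_chain(gemmi.Chain(resi.chain))
            chain = model[-1]
            res = gemmi.Residue()
            res.name = resi.name
            res.seqid = gemmi.SeqId(resi.seq, resi.icode or " ")
            for i in resi.atom_indices:
                atom = gemmi.Atom()
                atom.name = self.names[i]
                atom.element = gemmi.Element(self.elements[i])
                serial += 1
                atom.serial = serial
                atom.pos = gemmi.Position(*self.coords[i])
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        return model


# ---------------------------------------------------------------------------
# Topology


@dataclass(frozen=True)
class TorsionDefinition:
    """One rotatable torsion: central bond, canonical quadruple, moved atoms.

    ``bond`` is oriented (fixed-side atom, moved-side atom); rotating the
    torsion displaces ``moved_set`` (one connected component of the bond
    graph with the central bond removed) about the bond axis.
    """

    atoms: tuple[int, int, int, int]
    bond: tuple[int, int]
    moved_set: frozenset[int]
    affects_main_chain: bool
    name: str
    chain: str
    res_seq: int
    azimuth_atoms: tuple[int, ...] = field(repr=False, default=())

    @property
    def selector(self) -> str:
        return f"{self.chain}:{self.res_seq}:{self.name}"


@dataclass
class _Placement:
    parent: int
    g: int
    ref: int
    torsion_index: int  # governing rotatable-torsion index, -1 if rigid


class Topology:
    """Bond graph, rings, rotatable torsions and the kinematic tree."""

    def __init__(self, structure: Structure):
        self.structure = structure
        self.graph = _build_bond_graph(structure)
        self.bonds = frozenset(frozenset(e) for e in self.graph.edges)
        self._check_connectivity()
        self.aromatic_ring_id = _assign_aromatic_rings(structure)
        self.ring_atoms = _ring_atoms(self.graph)
        self._build_tree()
        self._enumerate_torsions()
        self._neighbors_within3 = None

    # -- invariant helpers --------------------------------------------------

    def _check_connectivity(self) -> None:
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(self.graph)):
            for a in comp:
                comp_of[a] = ci
        s = self.structure
        for chain_name in dict.fromkeys(s.chains):
            idx = np.nonzero(s.chains == chain_name)[0]
            comps = {comp_of[int(i)] for i in idx}
            if len(comps) > 1:
                raise StructureError(
                    f"chain {chain_name} is not covalently connected "
                    "(chain break); a continuous chain of torsion angles "
                    "is required"
                )

    def bond_graph_distance(self, i: int, j: int) -> int:
        return nx.shortest_path_length(self.graph, i, j)

    def neighbors_within3(self) -> list[frozenset]:
        """For each atom, the set of atoms within 3 bonds (excluding self)."""
        if self._neighbors_within3 is None:
            out = []
            for i in range(self.structure.n_atoms):
                seen = {i}
                frontier = {i}
                for _ in range(3):
                    frontier = {
                        n for f in frontier for n in self.graph[f]
                    } - seen
                    seen |= frontier
                out.append(frozenset(seen - {i}))
            self._neighbors_within3 = out
        return self._neighbors_within3

    # -- kinematic tree -----------------------------------------------------

    def _build_tree(self) -> None:
        g = self.graph
        n = self.structure.n_atoms
        heavy_first = self.structure.is_hydrogen

        def sorted_nbrs(u, exclude):
            nbrs = [v for v in g[u] if v not in exclude]
            return sorted(nbrs, key=lambda v: (bool(heavy_first[v]), v))

        self.parent = np.full(n, -1, dtype=int)
        self.anchors: list[tuple[int, int, int]] = []
        self.place_order: list[int] = []
        children: dict[int, list[int]] = {i: [] for i in range(n)}

        for comp in nx.connected_components(g):
            comp = set(comp)
            root = min(comp)
            if len(comp) < 3:
                raise StructureError(
                    "a connected unit of fewer than 3 atoms cannot anchor "
                    "torsion kinematics"
                )
            # BFS spanning tree with deterministic child order
            visited = {root}
            order = [root]
            queue = [root]
            while queue:
                u = queue.pop(0)
                for v in sorted_nbrs(u, visited):
                    visited.add(v)
                    self.parent[v] = u
                    children[u].append(v)
                    order.append(v)
                    queue.append(v)
            a0 = root
            a1 = children[a0][0]
            a2 = children[a1][0] if children[a1] else children[a0][1]
            self.anchors.append((a0, a1, a2))
            self.place_order.extend(order)
        self.children = children

    def _enumerate_torsions(self) -> None:
        g = self.graph
        s = self.structure
        anchor_lookup = {a0: (a0, a1, a2) for (a0, a1, a2) in self.anchors}

        bridges = set()
        for comp in nx.connected_components(g):
            bridges |= {frozenset(e) for e in nx.bridges(g.subgraph(comp))}

        rotatable: list[TorsionDefinition] = []
        for e in sorted((tuple(sorted(b)) for b in bridges)):
            u, v = e
            if g.degree(u) < 2 or g.degree(v) < 2:
                continue
            # orient: A = fixed side, B = moved side
            if self.parent[v] == u:
                child, par = v, u
            elif self.parent[u] == v:
                child, par = u, v
            else:  # pragma: no cover - bridges always tree edges
                continue
            root_triple = anchor_lookup.get(par)
            if root_triple is not None and child == root_triple[1]:
                # bond between the tree root and its first child: realise the
                # rotation on the root's remaining substituents (e.g. an
                # N-terminal amine rotor) so the anchor triple stays fixed
                a0, a1, a2 = root_triple
                a_side, b_side = a1, a0
                azi = tuple(c for c in self.children[a0]
                            if c not in (a1, a2))
            else:
                a_side, b_side = par, child
                azi = tuple(self.children[child])
            if not azi:
                continue
            moved = set(azi)
            stack = list(azi)
            while stack:
                x = stack.pop()
                for c in self.children[x]:
                    moved.add(c)
                    stack.append(c)
            quad, name = self._canonical_quad(a_side, b_side, azi, moved)
            owner = b_side
            if name in ("phi", "psi") or name.startswith("chi"):
                # conventional owner: the residue containing the sidechain /
                # backbone bond; for psi that is the residue of CA and C
                owner = b_side if name != "psi" else a_side
            res = s.residue_of(owner)
            moved_names = {s.names[m] for m in moved}
            affects_mc = bool(moved_names & templates.MAIN_CHAIN_ATOMS)
            rotatable.append(TorsionDefinition(
                atoms=quad,
                bond=(a_side, b_side),
                moved_set=frozenset(moved),
                affects_main_chain=affects_mc,
                name=name,
                chain=res[0],
                res_seq=res[1],
                azimuth_atoms=azi,
            ))
        self.rotatable_torsions = rotatable
        self._torsion_of_bond = {
            frozenset(t.bond): k for k, t in enumerate(rotatable)
        }
        # governing torsion for each placed atom
        self._finalize_placements()

    def _canonical_quad(self, a, b, azi, moved):
        """Choose the reference quadruple (A', A, B, B') and a torsion name."""
        s = self.structure
        g = self.graph
        name_a, name_b = s.names[a], s.names[b]
        res_a, res_b = s.residue_of(a), s.residue_of(b)
        heavy_key = lambda v: (bool(s.is_hydrogen[v]), v)

        def named(res_key, atom_name):
            try:
                return self.structure.atom_index(
                    res_key[0], res_key[1], atom_name, res_key[2])
            except KeyError:
                return None

        quad = None
        name = None
        if res_a == res_b:
            chi = templates.chi_name_for_bond(s.res_names[a], name_a, name_b)
            if chi is not None:
                k = int(chi[3:]) - 1
                conv = templates.CHI_QUADS[s.res_names[a]][k]
                idxs = [named(res_a, nm) for nm in conv]
                if all(i is not None for i in idxs) and \
                        idxs[1] == a and idxs[2] == b and idxs[3] in moved:
                    quad, name = tuple(idxs), chi
            if quad is None and {name_a, name_b} == {"N", "CA"}:
                prev_c = self._preceding_atom(a if name_a == "N" else b, "C")
                this_c = named(res_a, "C")
                n_i = a if name_a == "N" else b
                ca_i = b if name_a == "N" else a
                if prev_c is not None and this_c is not None and \
                        (n_i, ca_i) == (a, b) and this_c in moved:
                    quad, name = (prev_c, n_i, ca_i, this_c), "phi"
            if quad is None and {name_a, name_b} == {"CA", "C"}:
                n_i = named(res_a, "N")
                next_n = self._following_atom(a if name_a == "C" else b, "N")
                ca_i = a if name_a == "CA" else b
                c_i = b if name_a == "CA" else a
                if n_i is not None and next_n is not None and \
                        (ca_i, c_i) == (a, b) and next_n in moved:
                    quad, name = (n_i, ca_i, c_i, next_n), "psi"
        else:
            # inter-residue C-N bond: omega, owned by the later residue
            if {name_a, name_b} == {"C", "N"}:
                c_i = a if name_a == "C" else b
                n_i = b if name_a == "C" else a
                ca_prev = named(s.residue_of(c_i), "CA")
                ca_next = named(s.residue_of(n_i), "CA")
                if ca_prev is not None and ca_next is not None and \
                        (c_i, n_i) == (a, b) and ca_next in moved:
                    quad, name = (ca_prev, c_i, n_i, ca_next), "omega"
        if quad is None:
            a_prime = sorted((v for v in g[a] if v != b and v not in moved),
                             key=heavy_key)[0]
            b_prime = sorted(azi, key=heavy_key)[0]
            quad = (a_prime, a, b, b_prime)
            name = f"{name_a}-{name_b}"
        return quad, name

    def _preceding_atom(self, n_index: int, name: str) -> int | None:
        """Backbone atom `name` of the residue peptide-bonded before this N."""
        for nbr in self.graph[n_index]:
            if self.structure.names[nbr] == "C" and \
                    self.structure.residue_of(nbr) != \
                    self.structure.residue_of(n_index):
                if name == "C":
                    return nbr
        return None

    def _following_atom(self, c_index: int, name: str) -> int | None:
        for nbr in self.graph[c_index]:
            if self.structure.names[nbr] == "N" and \
                    self.structure.residue_of(nbr) != \
                    self.structure.residue_of(c_index):
                if name == "N":
                    return nbr
        return None

    def _finalize_placements(self) -> None:
        anchor_atoms = {a for t in self.anchors for a in t}
        self.placements: dict[int, _Placement] = {}
        for c in self.place_order:
            if c in anchor_atoms:
                continue
            p = int(self.parent[c])
            triple = next(
                (t for t in self.anchors if p in (t[0], t[1])), None)
            if triple is not None and p == triple[0]:
                # extra children of the root: azimuth about the root/first-
                # child bond, governed by its torsion (e.g. terminal amine)
                a0, a1, a2 = triple
                ti = self._torsion_of_bond.get(frozenset((a0, a1)), -1)
                place = _Placement(parent=p, g=a1, ref=a2, torsion_index=ti)
            elif triple is not None and p == triple[1]:
                # extra children of the first child: referenced against the
                # anchored grandchild, so the root bond does not move them
                a0, a1, a2 = triple
                place = _Placement(parent=p, g=a0, ref=a2, torsion_index=-1)
            else:
                gg = int(self.parent[p])
                if self.parent[gg] != -1:
                    rr = int(self.parent[gg])
                else:
                    trip = next(t for t in self.anchors if gg == t[0])
                    rr = trip[1] if p != trip[1] else trip[2]
                ti = self._torsion_of_bond.get(frozenset((gg, p)), -1)
                if ti >= 0 and c not in \
                        self.rotatable_torsions[ti].azimuth_atoms:
                    ti = -1
                place = _Placement(parent=p, g=gg, ref=int(rr),
                                   torsion_index=ti)
            self.placements[c] = place
        # sanity: azimuth atoms of each torsion must be governed by it
        for k, t in enumerate(self.rotatable_torsions):
            for c in t.azimuth_atoms:
                pl = self.placements.get(c)
                if pl is not None and pl.torsion_index != k:
                    pl.torsion_index = k

    # -- measurement --------------------------------------------------------

    def measure_torsions(self, coords: np.ndarray) -> np.ndarray:
        """Measure all rotatable torsions (degrees, wrapped) in ``coords``."""
        out = np.empty(len(self.rotatable_torsions))
        for k, t in enumerate(self.rotatable_torsions):
            i, j, l, m = t.atoms
            out[k] = dihedral(coords[i], coords[j], coords[l], coords[m])
        return out

    def torsion_index(self, chain: str, res_seq: int, name: str) -> int:
        for k, t in enumerate(self.rotatable_torsions):
            if t.chain == chain and t.res_seq == res_seq and t.name == name:
                return k
        raise KeyError(f"no rotatable torsion {chain}:{res_seq}:{name}")


def _build_bond_graph(s: Structure) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(s.n_atoms))
    extra_n_hydrogens = {"H1", "H2", "H3"}
    for resi in s.residues:
        names, _, _, bonds = templates.template(resi.name)
        local = {}
        for i in resi.atom_indices:
            nm = s.names[i]
            if nm in local:
                raise StructureError(
                    f"duplicate atom {nm} in {resi.chain}:{resi.seq}"
                )
            local[nm] = i
        n_hydro = sum(1 for i in resi.atom_indices if s.is_hydrogen[i])
        if n_hydro == 0:
            raise StructureError(
                f"residue {resi.chain}:{resi.seq} ({resi.name}) has no "
                "hydrogen atoms; supply a model with explicit hydrogens"
            )
        known = set(names) | extra_n_hydrogens
        for nm, i in local.items():
            if nm not in known:
                raise StructureError(
                    f"unknown atom name {nm} in {resi.chain}:{resi.seq} "
                    f"({resi.name})"
                )
        for bond in bonds:
            na, nb = tuple(bond)
            if na in local and nb in local:
                g.add_edge(local[na], local[nb])
        # terminal amine hydrogens named H1/H2/H3 bond to N
        for nm in extra_n_hydrogens & set(local):
            if frozenset((nm, "N")) not in bonds and "N" in local:
                g.add_edge(local[nm], local["N"])
    # peptide bonds between sequence-adjacent residues of the same chain
    by_chain: dict[str, list[Residue]] = {}
    for resi in s.residues:
        by_chain.setdefault(resi.chain, []).append(resi)
    for chain_residues in by_chain.values():
        for r1, r2 in zip(chain_residues, chain_residues[1:]):
            try:
                c = s.atom_index(r1.chain, r1.seq, "C", r1.icode)
                n = s.atom_index(r2.chain, r2.seq, "N", r2.icode)
            except KeyError:
                continue
            if bond_length(s.coords[c], s.coords[n]) < PEPTIDE_MAX:
                g.add_edge(c, n)
    # disulfides
    sg = [i for i in range(s.n_atoms)
          if s.res_names[i] == "CYS" and s.names[i] == "SG"]
    for ii in range(len(sg)):
        for jj in range(ii + 1, len(sg)):
            if bond_length(s.coords[sg[ii]], s.coords[sg[jj]]) < DISULFIDE_MAX:
                g.add_edge(sg[ii], sg[jj])
    return g


def _assign_aromatic_rings(s: Structure) -> np.ndarray:
    ring_id = np.full(s.n_atoms, -1, dtype=int)
    next_id = 0
    for resi in s.residues:
        rings = templates.AROMATIC_RINGS.get(resi.name)
        if not rings:
            continue
        for ring in rings:
            members = []
            for i in resi.atom_indices:
                if s.names[i] in ring:
                    members.append(i)
            if len(members) == len(ring):
                ring_id[members] = next_id
                next_id += 1
    return ring_id


def _ring_atoms(g: nx.Graph) -> frozenset:
    atoms = set()
    for cycle in nx.cycle_basis(g):
        atoms.update(cycle)
    return frozenset(atoms)


# ---------------------------------------------------------------------------
# Kinematics


class KinematicModel:
    """Forward kinematics: rebuild Cartesian frames from torsion offsets.

    Internal coordinates (bond lengths, bond angles, base azimuths) are
    measured once from a reference coordinate set; ``build`` then produces
    coordinates for arbitrary per-torsion angular offsets, vectorised over a
    batch of frames.  Only torsions can move — bond lengths and angles are
    conserved exactly.
    """

    def __init__(self, topology: Topology, ref_coords: np.ndarray):
        self.topology = topology
        self.ref_coords = np.asarray(ref_coords, dtype=float)
        self.ref_torsions = topology.measure_torsions(self.ref_coords)
        order = []
        anchor_atoms = {a for t in topology.anchors for a in t}
        for c in topology.place_order:
            if c in topology.placements:
                order.append(c)
        self._order = order
        n = len(order)
        self._p = np.array([topology.placements[c].parent for c in order])
        self._g = np.array([topology.placements[c].g for c in order])
        self._r = np.array([topology.placements[c].ref for c in order])
        self._ti = np.array(
            [topology.placements[c].torsion_index for c in order])
        self._atoms = np.array(order)
        rc = self.ref_coords
        self._lengths = bond_length(rc[self._p], rc[self._atoms])
        self._angles = bond_angle(rc[self._g], rc[self._p], rc[self._atoms])
        self._phis = dihedral(rc[self._r], rc[self._g], rc[self._p],
                              rc[self._atoms])
        # group placements into dependency levels (tree depth) so each level
        # can be placed in one vectorised call
        depth = np.zeros(self.ref_coords.shape[0], dtype=int)
        for c in topology.place_order:
            p = topology.parent[c]
            if p != -1:
                depth[c] = depth[p] + 1
        order_depth = depth[self._atoms]
        self._levels = [
            np.nonzero(order_depth == d)[0]
            for d in range(order_depth.max() + 1) if np.any(order_depth == d)
        ] if len(order) else []

    @property
    def n_torsions(self) -> int:
        return len(self.topology.rotatable_torsions)

    def build(self, deltas: np.ndarray) -> np.ndarray:
        """Coordinates for torsion offsets ``deltas`` (degrees).

        ``deltas[k]`` is added to rotatable torsion ``k`` relative to the
        reference structure.  Accepts shape (T,) for a single frame or
        (F, T) for a batch; returns (n_atoms, 3) or (F, n_atoms, 3).
        """
        deltas = np.asarray(deltas, dtype=float)
        single = deltas.ndim == 1
        if single:
            deltas = deltas[None, :]
        nf = deltas.shape[0]
        coords = np.empty((nf, self.ref_coords.shape[0], 3))
        for (a0, a1, a2) in self.topology.anchors:
            coords[:, a0] = self.ref_coords[a0]
            coords[:, a1] = self.ref_coords[a1]
            coords[:, a2] = self.ref_coords[a2]
        for level in self._levels:
            atoms = self._atoms[level]
            phi = np.broadcast_to(self._phis[level], (nf, len(level))).copy()
            ti = self._ti[level]
            governed = ti >= 0
            if governed.any():
                phi[:, governed] += deltas[:, ti[governed]]
            coords[:, atoms] = nerf_place(
                coords[:, self._r[level]],
                coords[:, self._g[level]],
                coords[:, self._p[level]],
                np.broadcast_to(self._lengths[level], (nf, len(level))),
                np.broadcast_to(self._angles[level], (nf, len(level))),
                phi,
            )
        return coords[0] if single else coords


# ---------------------------------------------------------------------------
# Conformer pair


@dataclass
class ConformerPair:
    """Two harmonised end states sharing one covalent topology."""

    structure: Structure
    topology: Topology
    model: KinematicModel
    start_coords: np.ndarray
    end_coords: np.ndarray
    start_torsions: np.ndarray  # theta_i^0, degrees, wrapped
    end_torsions: np.ndarray    # theta_i^1, degrees, wrapped
    end_rebuild_ca_rmsd: float = 0.0
    # rigidly carried ligand atoms: (chain, seq, resname, atom, element,
    # start position, end position)
    het_atoms: list = field(default_factory=list)

    def rebuild_end(self) -> None:
        """Recompute end coordinates from the current end torsions."""
        rebuilt = self.model.build(self.end_torsions - self.start_torsions)
        fit = ~self.structure.is_hydrogen
        self.end_coords = superpose(rebuilt, self.end_coords, fit_mask=fit)


def read_structure(pdb_text: str, *, ligands: str = "drop"
                   ) -> tuple[Structure, Topology]:
    """Parse a PDB text into a structure and its covalent topology.

    The structure must be a single model with no alternate locations and
    explicitly modelled hydrogens.  Bonds are inferred from residue
    templates, peptide links between sequence-adjacent residues and
    disulfide bridges (S-S below 2.5 A).
    """
    s = Structure.from_pdb_text(pdb_text, ligands=ligands)
    return s, Topology(s)


def harmonize_geometry(
    start: Structure,
    end: Structure,
    *,
    topology: Topology | None = None,
    ca_warn_threshold: float = 0.5,
) -> ConformerPair:
    """Rebuild the end state on the start state's covalent geometry.

    The start structure supplies every bond length and bond angle; the end
    structure supplies only its measured torsion angles.  The rebuilt end is
    rigid-body superposed onto the original end coordinates and the Calpha
    RMSD between the two is recorded (a warning is raised above
    ``ca_warn_threshold`` A, indicating poorly regularised input geometry).
    """
    _check_same_atoms(start, end)
    topo = topology if topology is not None else Topology(start)
    model = KinematicModel(topo, start.coords)
    theta0 = wrap_angle(model.ref_torsions)
    theta1 = wrap_angle(topo.measure_torsions(end.coords))
    rebuilt = model.build(theta1 - theta0)
    fit = ~start.is_hydrogen
    rebuilt = superpose(rebuilt, end.coords, fit_mask=fit)
    ca_mask = np.array([nm == "CA" for nm in start.names])
    ca_rmsd = rmsd(rebuilt[ca_mask], end.coords[ca_mask])
    if ca_rmsd > ca_warn_threshold:
        warnings.warn(
            f"end-state rebuild deviates by {ca_rmsd:.3f} A Calpha RMSD from "
            "the supplied end structure; check that both inputs have "
            "regularised bond lengths and angles",
            stacklevel=2,
        )
    het_pairs = []
    if start.het_atoms or end.het_atoms:
        end_het = {rec[:4]: rec for rec in end.het_atoms}
        if set(end_het) != {rec[:4] for rec in start.het_atoms}:
            raise StructureError(
                "ligand (HETATM) atom sets differ between start and end")
        for rec in start.het_atoms:
            chain, seq, rname, name, element, pos0 = rec
            pos1 = end_het[rec[:4]][5]
            het_pairs.append((chain, seq, rname, name, element,
                              np.array(pos0), np.array(pos1)))
    return ConformerPair(
        structure=start,
        topology=topo,
        model=model,
        start_coords=start.coords.copy(),
        end_coords=rebuilt,
        start_torsions=theta0,
        end_torsions=theta1,
        end_rebuild_ca_rmsd=ca_rmsd,
        het_atoms=het_pairs,
    )


def _check_same_atoms(start: Structure, end: Structure) -> None:
    def keys(s):
        return [
            (s.chains[i], int(s.res_seqs[i]), s.icodes[i], s.res_names[i],
             s.names[i], s.elements[i])
            for i in range(s.n_atoms)
        ]

    ka, kb = keys(start), keys(end)
    if ka != kb:
        only_a = sorted(set(ka) - set(kb))
        only_b = sorted(set(kb) - set(ka))
        raise StructureError(
            "start and end structures have different atom sets; "
            f"only in start: {only_a[:8]}; only in end: {only_b[:8]}"
        )


def canonicalize_symmetric_sidechains(
    pair: ConformerPair, resolution: float
) -> ConformerPair:
    """Reconcile 180 deg-symmetric sidechain torsions between the end states.

    For Phe, Tyr, Asp, Glu and Arg the terminal sidechain torsion is
    chemically two-fold symmetric, so the deposited end-state value may
    differ by an arbitrary 180 deg naming choice.  Whenever shifting the end
    torsion by 180 deg reduces the apparent travel, the shift is applied (and
    the end state rebuilt).  Above 2.4 A resolution the same rule extends to
    Asn, Gln and His, whose terminal groups cannot be distinguished in weak
    electron density.
    """
    rules = dict(templates.SYMMETRIC_CHI_ALWAYS)
    if resolution > templates.LOW_RES_THRESHOLD:
        rules.update(templates.SYMMETRIC_CHI_LOW_RES)
    theta1 = pair.end_torsions.copy()
    changed = False
    for resi in pair.structure.residues:
        chi = rules.get(resi.name)
        if chi is None:
            continue
        try:
            k = pair.topology.torsion_index(resi.chain, resi.seq,
                                            f"chi{chi}")
        except KeyError:
            continue
        delta = wrap_angle(theta1[k] - pair.start_torsions[k])
        flipped = wrap_angle(delta + 180.0)
        if abs(flipped) < abs(delta):
            theta1[k] = wrap_angle(theta1[k] + 180.0)
            changed = True
    if not changed:
        return pair
    new_pair = ConformerPair(
        structure=pair.structure,
        topology=pair.topology,
        model=pair.model,
        start_coords=pair.start_coords,
        end_coords=pair.end_coords.copy(),
        start_torsions=pair.start_torsions,
        end_torsions=theta1,
        end_rebuild_ca_rmsd=pair.end_rebuild_ca_rmsd,
    )
    new_pair.rebuild_end()
    return new_pair
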