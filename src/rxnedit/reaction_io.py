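"""Reaction SMILES parsing, graph construction and featurization.

A reaction string ``reactants>>product`` (dot-separated molecules allowed on
either side) is parsed with RDKit into a pair of :class:`MolGraph` objects.
Hydrogens are implicit: graphs contain heavy atoms only, and hydrogen counts
enter as atom features and labeling rules.  Atom-map numbers, when present on
every product atom, define an index-based ground-truth atom map from product
atoms to reactant atoms.

Feature vectors are concatenated one-hot blocks over closed vocabularies with
an "other" bucket, so the atom and bond feature widths are constants
(:data:`ATOM_FEATURE_DIM`, :data:`BOND_FEATURE_DIM`) across a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

__all__ = [
    "AtomRecord",
    "BondRecord",
    "MolGraph",
    "Reaction",
    "DualGraph",
    "ReactionParseError",
    "MapValidationError",
    "parse_reaction",
    "featurize",
    "build_dual_graph",
    "canonicalize_and_remap",
    "permute_molgraph",
    "permute_reaction",
    "reaction_to_smiles",
    "render_mapped_reaction",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
]


class ReactionParseError(ValueError):
    """Raised when a reaction SMILES cannot be parsed."""


class MapValidationError(ValueError):
    """Raised when atom-map numbers are inconsistent."""


# ---------------------------------------------------------------- vocabularies
# Closed sets covering the elements common in organic reaction corpora;
# anything else falls into the trailing "other" bucket.
ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I",
            "B", "Si", "Sn", "Se", "Cu", "Zn", "Mg"]
FORMAL_CHARGES = [-2, -1, 0, 1, 2]
CHIRAL_TAGS = ["CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW"]
HYBRIDIZATIONS = ["SP", "SP2", "SP3", "SP3D", "SP3D2"]
DEGREES = [0, 1, 2, 3, 4, 5, 6]
H_COUNTS = [0, 1, 2, 3, 4]

BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]
BOND_STEREO = ["STEREONONE", "STEREOZ", "STEREOE"]


def _one_hot(value, vocab: list) -> np.ndarray:
    """One-hot over vocab + reserved trailing 'other' bucket."""
    vec = np.zeros(len(vocab) + 1)
    try:
        vec[vocab.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


ATOM_FEATURE_DIM = (len(ELEMENTS) + 1) + (len(FORMAL_CHARGES) + 1) + \
    (len(CHIRAL_TAGS) + 1) + (len(HYBRIDIZATIONS) + 1) + 1 + \
    (len(DEGREES) + 1) + (len(H_COUNTS) + 1) + 1
BOND_FEATURE_DIM = (len(BOND_TYPES) + 1) + 1 + (len(BOND_STEREO) + 1) + 1


# ------------------------------------------------------------------ containers
@dataclass(frozen=True)
class AtomRecord:
    element: str
    atomic_num: int
    formal_charge: int
    chiral_tag: str
    hybridization: str
    aromatic: bool
    degree: int
    total_hs: int
    in_ring: bool
    map_number: int = 0


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    bond_type: str
    conjugated: bool
    stereo: str
    in_ring: bool


@dataclass
class MolGraph:
    """Heavy-atom molecular graph; may hold several disconnected molecules."""

    atoms: list
    bonds: list                       # BondRecord list, canonical i < j order
    adjacency: np.ndarray             # symmetric {0,1}, zero diagonal
    component_ids: np.ndarray
    atom_features: np.ndarray | None = None
    bond_features: np.ndarray | None = None
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def bond_index(self) -> dict:
        """Map (i, j) with i < j to position in the bond list."""
        return {(b.i, b.j): k for k, b in enumerate(self.bonds)}

    def bond_type_map(self) -> dict:
        return {(b.i, b.j): b.bond_type for b in self.bonds}

    def neighbors(self, i: int) -> np.ndarray:
        return np.nonzero(self.adjacency[i])[0]


@dataclass
class Reaction:
    reactants: MolGraph
    product: MolGraph
    atom_map: dict | None = None      # product atom index -> reactant atom index
    class_label: int | None = None
    raw_smiles: str = ""

    def require_map(self) -> dict:
        if self.atom_map is None:
            raise MapValidationError("reaction has no ground-truth atom map")
        return self.atom_map


@dataclass
class DualGraph:
    """Line graph of the product: one node per bond, edges between bonds
    sharing exactly one atom."""

    bond_nodes: list                  # list of (i, j) product bonds, i < j
    dual_edges: list                  # list of (u, v) dual-node pairs, u < v
    bond_node_features: np.ndarray
    incidence: dict                   # (i, j) -> dual node index

    @property
    def n_nodes(self) -> int:
        return len(self.bond_nodes)


# -------------------------------------------------------------------- parsing
def _mol_to_graph(mol: Chem.Mol) -> MolGraph:
    n = mol.GetNumAtoms()
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(AtomRecord(
            element=a.GetSymbol(),
            atomic_num=a.GetAtomicNum(),
            formal_charge=a.GetFormalCharge(),
            chiral_tag=str(a.GetChiralTag()),
            hybridization=str(a.GetHybridization()),
            aromatic=a.GetIsAromatic(),
            degree=a.GetDegree(),
            total_hs=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
            map_number=a.GetAtomMapNum(),
        ))
    adjacency = np.zeros((n, n), dtype=np.int8)
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        adjacency[i, j] = adjacency[j, i] = 1
        bonds.append(BondRecord(
            i=i, j=j,
            bond_type=str(b.GetBondType()),
            conjugated=b.GetIsConjugated(),
            stereo=str(b.GetStereo()),
            in_ring=b.IsInRing(),
        ))
    bonds.sort(key=lambda b: (b.i, b.j))
    component_ids = np.zeros(n, dtype=np.int64)
    for ci, frag in enumerate(Chem.GetMolFrags(mol)):
        component_ids[list(frag)] = ci
    return MolGraph(atoms=atoms, bonds=bonds, adjacency=adjacency,
                    component_ids=component_ids, mol=mol)


def _parse_side(smiles: str, side: str) -> MolGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ReactionParseError(f"unparsable SMILES on {side} side: {smiles!r}")
    return _mol_to_graph(mol)


def parse_reaction(smiles: str, with_features: bool = True) -> Reaction:
    """Parse ``reactants>>product`` into a :class:`Reaction`.

    The atom map is populated iff every product atom carries a map number and
    each of those numbers also appears on the reactant side.  Duplicate map
    numbers within a side, or product map numbers with no reactant partner,
    raise :class:`MapValidationError`.
    """
    parts = smiles.split(">>")
    if len(parts) != 2:
        raise ReactionParseError(
            f"expected exactly one '>>' separator, got {smiles!r}")
    reactants = _parse_side(parts[0], "reactant")
    product = _parse_side(parts[1], "product")

    atom_map = None
    maps_r = _collect_maps(reactants, "reactant")
    maps_p = _collect_maps(product, "product")
    if len(maps_p) == product.n_atoms and product.n_atoms > 0:
        orphans = sorted(set(maps_p) - set(maps_r))
        if orphans:
            raise MapValidationError(
                f"product map numbers absent from reactants: {orphans}")
        atom_map = {maps_p[m]: maps_r[m] for m in maps_p}

    if with_features:
        featurize(reactants)
        featurize(product)
    return Reaction(reactants=reactants, product=product,
                    atom_map=atom_map, raw_smiles=smiles)


def _collect_maps(graph: MolGraph, side: str) -> dict:
    """Map number -> atom index for mapped atoms; reject duplicates."""
    out: dict = {}
    for idx, a in enumerate(graph.atoms):
        if a.map_number > 0:
            if a.map_number in out:
                raise MapValidationError(
                    f"duplicate atom-map number {a.map_number} on {side} side")
            out[a.map_number] = idx
    return out


# -------------------------------------------------------------- featurization
def _atom_feature(a: AtomRecord) -> np.ndarray:
    return np.concatenate([
        _one_hot(a.element, ELEMENTS),
        _one_hot(a.formal_charge, FORMAL_CHARGES),
        _one_hot(a.chiral_tag, CHIRAL_TAGS),
        _one_hot(a.hybridization, HYBRIDIZATIONS),
        [1.0 if a.aromatic else 0.0],
        _one_hot(a.degree, DEGREES),
        _one_hot(a.total_hs, H_COUNTS),
        [1.0 if a.in_ring else 0.0],
    ])


def _bond_feature(b: BondRecord) -> np.ndarray:
    return np.concatenate([
        _one_hot(b.bond_type, BOND_TYPES),
        [1.0 if b.conjugated else 0.0],
        _one_hot(b.stereo, BOND_STEREO),
        [1.0 if b.in_ring else 0.0],
    ])


def featurize(graph: MolGraph) -> MolGraph:
    """Populate X and E in place (and return the graph)."""
    graph.atom_features = (
        np.stack([_atom_feature(a) for a in graph.atoms])
        if graph.atoms else np.zeros((0, ATOM_FEATURE_DIM)))
    graph.bond_features = (
        np.stack([_bond_feature(b) for b in graph.bonds])
        if graph.bonds else np.zeros((0, BOND_FEATURE_DIM)))
    return graph


# ----------------------------------------------------------------- dual graph
def build_dual_graph(product: MolGraph) -> DualGraph:
    """Line graph over the product's bonds (deterministic (i, j) ordering)."""
    if product.bond_features is None:
        featurize(product)
    bond_nodes = [(b.i, b.j) for b in product.bonds]
    incidence = {bn: k for k, bn in enumerate(bond_nodes)}
    dual_edges = []
    for u in range(len(bond_nodes)):
        for v in range(u + 1, len(bond_nodes)):
            if len(set(bond_nodes[u]) & set(bond_nodes[v])) == 1:
                dual_edges.append((u, v))
    return DualGraph(bond_nodes=bond_nodes, dual_edges=dual_edges,
                     bond_node_features=product.bond_features.copy(),
                     incidence=incidence)


# ----------------------------------------------------------- canonicalization
def canonicalize_and_remap(reaction: Reaction) -> Reaction:
    """Re-number product atoms by their canonical SMILES ranking and re-emit
    a canonically atom-mapped reaction.

    Map numbers are regenerated from the structure-only canonical ranking of
    the product (1..|V_P| in rank order), so any two atom orderings of the
    same mapped reaction produce the identical canonical reaction SMILES.
    Reactant atom order is preserved.
    """
    atom_map = reaction.require_map()
    if reaction.product.mol is None or reaction.reactants.mol is None:
        raise MapValidationError("canonicalization requires RDKit mols")

    p = Chem.Mol(reaction.product.mol)
    for a in p.GetAtoms():
        a.SetAtomMapNum(0)
    ranks = list(Chem.CanonicalRankAtoms(p, breakTies=True))
    # old product index -> new map number (rank + 1)
    for old_idx, a in enumerate(p.GetAtoms()):
        a.SetAtomMapNum(ranks[old_idx] + 1)

    r = Chem.Mol(reaction.reactants.mol)
    for a in r.GetAtoms():
        a.SetAtomMapNum(0)
    for old_idx, r_idx in atom_map.items():
        r.GetAtomWithIdx(r_idx).SetAtomMapNum(ranks[old_idx] + 1)

    smiles = (Chem.MolToSmiles(r, canonical=False) + ">>" +
              Chem.MolToSmiles(p, canonical=True))
    out = parse_reaction(smiles)
    out.class_label = reaction.class_label
    return out


def render_mapped_reaction(reaction: Reaction, assignment) -> str:
    """Emit the reaction SMILES with atom-map numbers encoding `assignment`
    (product atom i and reactant atom assignment[i] share map number i+1)."""
    if reaction.product.mol is None or reaction.reactants.mol is None:
        raise ValueError("rendering requires RDKit mols")
    p = Chem.Mol(reaction.product.mol)
    r = Chem.Mol(reaction.reactants.mol)
    for a in p.GetAtoms():
        a.SetAtomMapNum(0)
    for a in r.GetAtoms():
        a.SetAtomMapNum(0)
    for i, ri in enumerate(assignment):
        p.GetAtomWithIdx(int(i)).SetAtomMapNum(i + 1)
        r.GetAtomWithIdx(int(ri)).SetAtomMapNum(i + 1)
    return (Chem.MolToSmiles(r, canonical=False) + ">>" +
            Chem.MolToSmiles(p, canonical=False))


def reaction_to_smiles(reaction: Reaction) -> str:
    """Emit the reaction as an atom-mapped SMILES in the stored atom order."""
    if reaction.product.mol is None or reaction.reactants.mol is None:
        raise ValueError("serialization requires RDKit mols")
    return (Chem.MolToSmiles(reaction.reactants.mol, canonical=False) + ">>" +
            Chem.MolToSmiles(reaction.product.mol, canonical=False))


# ---------------------------------------------------------------- permutation
def permute_molgraph(graph: MolGraph, perm) -> MolGraph:
    """Reorder atoms so new atom k is old atom perm[k]; bonds re-canonicalized."""
    perm = list(int(x) for x in perm)
    n = graph.n_atoms
    if sorted(perm) != list(range(n)):
        raise ValueError("perm must be a permutation of atom indices")
    inv = np.empty(n, dtype=np.int64)
    for new, old in enumerate(perm):
        inv[old] = new
    atoms = [graph.atoms[old] for old in perm]
    bonds = []
    for b in graph.bonds:
        i, j = int(inv[b.i]), int(inv[b.j])
        if i > j:
            i, j = j, i
        bonds.append(replace(b, i=i, j=j))
    order = sorted(range(len(bonds)), key=lambda k: (bonds[k].i, bonds[k].j))
    bonds = [bonds[k] for k in order]
    adjacency = graph.adjacency[np.ix_(perm, perm)]
    mol = None
    if graph.mol is not None:
        mol = Chem.RenumberAtoms(graph.mol, perm)
    out = MolGraph(atoms=atoms, bonds=bonds, adjacency=adjacency,
                   component_ids=graph.component_ids[perm], mol=mol)
    if graph.atom_features is not None:
        out.atom_features = graph.atom_features[perm]
        # recompute bond rows in the new canonical order
        old_index = graph.bond_index()
        rows = []
        for b in bonds:
            oi, oj = perm[b.i], perm[b.j]
            if oi > oj:
                oi, oj = oj, oi
            rows.append(graph.bond_features[old_index[(oi, oj)]])
        out.bond_features = (np.stack(rows) if rows
                             else np.zeros((0, BOND_FEATURE_DIM)))
    return out


def permute_reaction(reaction: Reaction, perm_p=None, perm_r=None) -> Reaction:
    """Permute product and/or reactant atom order, re-indexing the map."""
    product = reaction.product
    reactants = reaction.reactants
    atom_map = dict(reaction.atom_map) if reaction.atom_map else None
    if perm_p is not None:
        product = permute_molgraph(product, perm_p)
        if atom_map is not None:
            atom_map = {new: atom_map[old] for new, old in enumerate(perm_p)}
    if perm_r is not None:
        reactants = permute_molgraph(reactants, perm_r)
        if atom_map is not None:
            inv = {old: new for new, old in enumerate(perm_r)}
            atom_map = {p: inv[r] for p, r in atom_map.items()}
    return Reaction(reactants=reactants, product=product, atom_map=atom_map,
                    class_label=reaction.class_label,
                    raw_smiles=reaction.raw_smiles)
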