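"""Deterministic generator of atom-mapped toy reactions with known edits.

Ten hand-coded transformation templates (esterification, amide coupling,
etherification, amine alkylation, alcohol oxidation, alkene hydrogenation,
acid deprotonation, thioether formation, aryl esterification, N-methylation)
are applied to sampled R-group scaffolds.  Each template is written directly
as a graph edit on an RDKit molecule — leaving-group deletion, bond
formation, bond-order change or charge change — so the ground-truth atom
map, the reactive atom/bond sets and the class index are exact by
construction, not re-derived from any labeling code.

The scaffold pool mixes alkyl chains with aromatic rings; `symmetric_fraction`
controls how often an aryl scaffold (whose atoms fall into nontrivial WL
equivalence classes) is drawn, which stresses mapping ambiguity.  Optional
random atom-order permutation defeats positional shortcuts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import BondType

from .labeling import EditLabels, derive_labels
from .reaction_io import Reaction, parse_reaction

__all__ = ["GeneratorConfig", "GeneratedReaction", "generate",
           "write_dataset", "load_dataset", "split_dataset", "N_CLASSES"]

N_CLASSES = 10

DEFAULT_ALKYL = ["C", "CC", "CCC", "C(C)C"]
DEFAULT_ARYL = ["c1ccccc1", "c1ccc(C)cc1"]


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_reactions: int = 100
    class_weights: list | None = None          # length N_CLASSES, renormalized
    scaffold_pool: list | None = None          # R-group SMILES, attach at atom 0
    symmetric_fraction: float = 0.3
    permute_atoms: bool = True

    def __post_init__(self):
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if len(w) != N_CLASSES or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("class_weights must be 10 nonnegative values "
                                 "with positive sum")
        if not 0.0 <= self.symmetric_fraction <= 1.0:
            raise ValueError("symmetric_fraction must lie in [0, 1]")


@dataclass
class GeneratedReaction:
    reaction: Reaction
    labels: EditLabels
    class_label: int
    smiles: str


# ------------------------------------------------------------------- assembly
class _Assembler:
    """Incrementally builds the (multi-component) reactant complex."""

    def __init__(self):
        self.rw = Chem.RWMol()

    def atom(self, symbol: str, charge: int = 0) -> int:
        a = Chem.Atom(symbol)
        a.SetFormalCharge(charge)
        return self.rw.AddAtom(a)

    def bond(self, i: int, j: int, order: BondType = BondType.SINGLE) -> None:
        self.rw.AddBond(i, j, order)

    def frag(self, smiles: str) -> int:
        """Copy a fragment in; returns the index of its attachment atom
        (atom 0 of the fragment SMILES)."""
        frag = Chem.MolFromSmiles(smiles)
        if frag is None:
            raise ValueError(f"bad scaffold SMILES {smiles!r}")
        offset = self.rw.GetNumAtoms()
        for a in frag.GetAtoms():
            na = Chem.Atom(a.GetSymbol())
            na.SetFormalCharge(a.GetFormalCharge())
            na.SetIsAromatic(a.GetIsAromatic())
            self.rw.AddAtom(na)
        for b in frag.GetBonds():
            self.rw.AddBond(offset + b.GetBeginAtomIdx(),
                            offset + b.GetEndAtomIdx(), b.GetBondType())
        return offset

    def attach(self, base: int, smiles: str) -> int:
        a = self.frag(smiles)
        self.bond(base, a)
        return a

    def mol(self) -> Chem.Mol:
        m = self.rw.GetMol()
        Chem.SanitizeMol(m)
        return m


@dataclass
class _Edit:
    """A template instance: the reactant complex plus its edit script."""

    reactants: Chem.Mol
    bonds_added: list = field(default_factory=list)     # (i, j, BondType)
    order_changes: list = field(default_factory=list)   # (i, j, BondType)
    charge_changes: dict = field(default_factory=dict)  # atom -> new charge
    atoms_removed: list = field(default_factory=list)   # leaving-group atoms
    reactive_atoms: set = field(default_factory=set)    # reactant atom indices
    reactive_bonds: set = field(default_factory=set)    # frozensets of indices


def _apply_edit(edit: _Edit) -> tuple:
    """Return (mapped reactant mol, mapped product mol, reactive map sets)."""
    r = Chem.Mol(edit.reactants)
    for idx, a in enumerate(r.GetAtoms()):
        a.SetAtomMapNum(idx + 1)
    prw = Chem.RWMol(r)
    for i, j, t in edit.bonds_added:
        prw.AddBond(i, j, t)
    for i, j, t in edit.order_changes:
        prw.GetBondBetweenAtoms(i, j).SetBondType(t)
    for i, ch in edit.charge_changes.items():
        prw.GetAtomWithIdx(i).SetFormalCharge(ch)
    for i in sorted(edit.atoms_removed, reverse=True):
        prw.RemoveAtom(i)
    p = prw.GetMol()
    Chem.SanitizeMol(p)
    atom_maps = {i + 1 for i in edit.reactive_atoms}
    bond_maps = {frozenset(i + 1 for i in pair) for pair in edit.reactive_bonds}
    return r, p, atom_maps, bond_maps


# ------------------------------------------------------------------ templates
def _acid(asm: _Assembler, r_smiles: str) -> tuple:
    """R-COOH; returns (carbonyl C, hydroxyl O)."""
    c = asm.atom("C")
    o_dbl = asm.atom("O")
    o_h = asm.atom("O")
    asm.bond(c, o_dbl, BondType.DOUBLE)
    asm.bond(c, o_h)
    asm.attach(c, r_smiles)
    return c, o_h


def _acyl_halide(asm: _Assembler, r_smiles: str) -> tuple:
    c = asm.atom("C")
    o = asm.atom("O")
    x = asm.atom("Cl")
    asm.bond(c, o, BondType.DOUBLE)
    asm.bond(c, x)
    asm.attach(c, r_smiles)
    return c, x


def _alkyl_halide(asm: _Assembler, r_smiles: str, halogen: str = "Br") -> tuple:
    c = asm.atom("C")
    x = asm.atom(halogen)
    asm.bond(c, x)
    asm.attach(c, r_smiles)
    return c, x


def _hetero(asm: _Assembler, symbol: str, r_smiles: str) -> int:
    h = asm.atom(symbol)
    asm.attach(h, r_smiles)
    return h


def _t_esterification(pick) -> _Edit:
    asm = _Assembler()
    a, oh = _acid(asm, pick())
    o = _hetero(asm, "O", pick(aryl_ok=False))
    return _Edit(asm.mol(), bonds_added=[(a, o, BondType.SINGLE)],
                 atoms_removed=[oh], reactive_atoms={o},
                 reactive_bonds={frozenset((a, o))})


def _t_amide(pick) -> _Edit:
    asm = _Assembler()
    a, cl = _acyl_halide(asm, pick())
    n = _hetero(asm, "N", pick())
    return _Edit(asm.mol(), bonds_added=[(a, n, BondType.SINGLE)],
                 atoms_removed=[cl], reactive_atoms={n},
                 reactive_bonds={frozenset((a, n))})


def _t_ether(pick) -> _Edit:
    asm = _Assembler()
    c, x = _alkyl_halide(asm, pick())
    o = _hetero(asm, "O", pick(aryl_ok=False))
    return _Edit(asm.mol(), bonds_added=[(c, o, BondType.SINGLE)],
                 atoms_removed=[x], reactive_atoms={o},
                 reactive_bonds={frozenset((c, o))})


def _t_amine_alkylation(pick) -> _Edit:
    asm = _Assembler()
    c, x = _alkyl_halide(asm, pick())
    n = _hetero(asm, "N", pick())
    return _Edit(asm.mol(), bonds_added=[(c, n, BondType.SINGLE)],
                 atoms_removed=[x], reactive_atoms={n},
                 reactive_bonds={frozenset((c, n))})


def _t_oxidation(pick) -> _Edit:
    asm = _Assembler()
    c = asm.atom("C")
    o = asm.atom("O")
    asm.bond(c, o)
    asm.attach(c, pick())
    asm.attach(c, pick())
    return _Edit(asm.mol(), order_changes=[(c, o, BondType.DOUBLE)],
                 reactive_atoms={c, o}, reactive_bonds={frozenset((c, o))})


def _t_hydrogenation(pick) -> _Edit:
    asm = _Assembler()
    c1 = asm.atom("C")
    c2 = asm.atom("C")
    asm.bond(c1, c2, BondType.DOUBLE)
    asm.attach(c1, pick())
    asm.attach(c2, pick())
    return _Edit(asm.mol(), order_changes=[(c1, c2, BondType.SINGLE)],
                 reactive_atoms={c1, c2}, reactive_bonds={frozenset((c1, c2))})


def _t_deprotonation(pick) -> _Edit:
    asm = _Assembler()
    _, oh = _acid(asm, pick())
    return _Edit(asm.mol(), charge_changes={oh: -1}, reactive_atoms={oh})


def _t_thioether(pick) -> _Edit:
    asm = _Assembler()
    c, x = _alkyl_halide(asm, pick())
    s = _hetero(asm, "S", pick(aryl_ok=False))
    return _Edit(asm.mol(), bonds_added=[(c, s, BondType.SINGLE)],
                 atoms_removed=[x], reactive_atoms={s},
                 reactive_bonds={frozenset((c, s))})


def _t_aryl_ester(pick) -> _Edit:
    asm = _Assembler()
    a, cl = _acyl_halide(asm, pick(aryl_ok=False))
    o = _hetero(asm, "O", pick(aryl_required=True))
    return _Edit(asm.mol(), bonds_added=[(a, o, BondType.SINGLE)],
                 atoms_removed=[cl], reactive_atoms={o},
                 reactive_bonds={frozenset((a, o))})


def _t_n_methylation(pick) -> _Edit:
    asm = _Assembler()
    c = asm.atom("C")
    i = asm.atom("I")
    asm.bond(c, i)
    n = _hetero(asm, "N", pick())
    return _Edit(asm.mol(), bonds_added=[(c, n, BondType.SINGLE)],
                 atoms_removed=[i], reactive_atoms={n},
                 reactive_bonds={frozenset((c, n))})


TEMPLATES = [
    _t_esterification,       # class 1
    _t_amide,                # class 2
    _t_ether,                # class 3
    _t_amine_alkylation,     # class 4
    _t_oxidation,            # class 5
    _t_hydrogenation,        # class 6
    _t_deprotonation,        # class 7
    _t_thioether,            # class 8
    _t_aryl_ester,           # class 9
    _t_n_methylation,        # class 10
]


# -------------------------------------------------------------- identifiability
def _is_identifiable(reaction: Reaction, atom_labels: np.ndarray,
                     bond_labels: np.ndarray) -> bool:
    """Whether the declared ground truth is a function of the reaction.

    If the product graph has an automorphism that moves a reactive atom or
    bond onto a non-reactive one, or relocates the truth map across reactant
    WL equivalence classes (e.g. a symmetric secondary amine built from two
    different components), then the declared edit set cannot be recovered by
    any observer of the reaction and the instance must be rejected.
    """
    from .matching import wl_partition

    p = reaction.product.mol
    autos = p.GetSubstructMatches(p, uniquify=False, maxMatches=10_000)
    if len(autos) <= 1:
        return True
    bond_lab = {(b.i, b.j): int(z)
                for b, z in zip(reaction.product.bonds, bond_labels)}
    truth = reaction.atom_map
    r_class = wl_partition(reaction.reactants).class_of
    for g in autos:
        for i in range(reaction.product.n_atoms):
            if atom_labels[g[i]] != atom_labels[i]:
                return False
            if r_class[truth[g[i]]] != r_class[truth[i]]:
                return False
        for (i, j), z in bond_lab.items():
            gi, gj = g[i], g[j]
            if gi > gj:
                gi, gj = gj, gi
            if bond_lab[(gi, gj)] != z:
                return False
    return True


# ------------------------------------------------------------------ generation
def _mapped_smiles(mol: Chem.Mol, rng, permute: bool) -> str:
    if permute:
        perm = [int(x) for x in rng.permutation(mol.GetNumAtoms())]
        mol = Chem.RenumberAtoms(mol, perm)
    return Chem.MolToSmiles(mol, canonical=False)


def generate(config: GeneratorConfig) -> list:
    """Emit `n_reactions` atom-mapped reactions with exact edit ground truth."""
    rng = np.random.default_rng(config.seed)
    weights = (np.asarray(config.class_weights, dtype=float)
               if config.class_weights is not None else np.ones(N_CLASSES))
    weights = weights / weights.sum()
    pool = config.scaffold_pool or (DEFAULT_ALKYL + DEFAULT_ARYL)
    alkyl = [s for s in pool if Chem.MolFromSmiles(s) is not None
             and not any(a.GetIsAromatic() for a in Chem.MolFromSmiles(s).GetAtoms())]
    aryl = [s for s in pool if s not in alkyl]

    def pick(aryl_ok: bool = True, aryl_required: bool = False) -> str:
        if aryl_required or (aryl_ok and aryl
                             and rng.random() < config.symmetric_fraction):
            return aryl[rng.integers(len(aryl))] if aryl else pool[0]
        return alkyl[rng.integers(len(alkyl))]

    out: list[GeneratedReaction] = []
    while len(out) < config.n_reactions:
        k = int(rng.choice(N_CLASSES, p=weights))
        try:
            edit = TEMPLATES[k](pick)
            r_mol, p_mol, atom_maps, bond_maps = _apply_edit(edit)
            smiles = (_mapped_smiles(r_mol, rng, config.permute_atoms) + ">>"
                      + _mapped_smiles(p_mol, rng, config.permute_atoms))
            reaction = parse_reaction(smiles)
        except (Chem.rdchem.AtomValenceException, ValueError) as err:
            warnings.warn(f"skipping infeasible template {k + 1}: {err}")
            continue
        reaction.class_label = k + 1
        atom_labels = np.array(
            [1 if a.map_number in atom_maps else 0
             for a in reaction.product.atoms], dtype=np.int64)
        mapnum = [a.map_number for a in reaction.product.atoms]
        bond_labels = np.array(
            [1 if frozenset((mapnum[b.i], mapnum[b.j])) in bond_maps else 0
             for b in reaction.product.bonds], dtype=np.int64)
        if not _is_identifiable(reaction, atom_labels, bond_labels):
            warnings.warn(f"skipping template {k + 1} instance with "
                          "non-identifiable ground truth (symmetric product)")
            continue
        out.append(GeneratedReaction(
            reaction=reaction,
            labels=EditLabels(atom_labels=atom_labels, bond_labels=bond_labels),
            class_label=k + 1, smiles=smiles))
    return out


# ------------------------------------------------------------------------- io
def write_dataset(reactions: list, path) -> None:
    """CSV with columns id,rxn_smiles,class."""
    rows = [{"id": i, "rxn_smiles": g.smiles, "class": g.class_label}
            for i, g in enumerate(reactions)]
    pd.DataFrame(rows, columns=["id", "rxn_smiles", "class"]).to_csv(
        path, index=False)


def load_dataset(path) -> list:
    """Read a dataset CSV back; labels are re-derived from the atom maps."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        reaction = parse_reaction(row["rxn_smiles"])
        label = int(row["class"]) if not pd.isna(row.get("class")) else None
        reaction.class_label = label
        labels = derive_labels(reaction) if reaction.atom_map else None
        out.append(GeneratedReaction(reaction=reaction, labels=labels,
                                     class_label=label,
                                     smiles=row["rxn_smiles"]))
    return out


def split_dataset(items: list, fractions=(0.8, 0.1, 0.1)) -> tuple:
    """Deterministic contiguous split (counts within 1 of proportionality)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(items)
    a = int(round(fractions[0] * n))
    b = int(round((fractions[0] + fractions[1]) * n))
    return items[:a], items[a:b], items[b:]
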