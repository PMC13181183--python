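"""Reaction-center labels on the product graph.

Given an atom-mapped reaction, each product atom is labeled reactive when its
total hydrogen count or formal charge differs from its mapped reactant atom,
and each product bond is labeled reactive when the mapped reactant atom pair
is not bonded (the bond was formed in the forward direction, i.e. is the
retrosynthetic break) or is bonded with a different bond type.

Reactant bonds with no product counterpart (retro "new bond formation") have
no home on the product graph and are deliberately not labeled.  Bond types
are compared after aromaticity perception, so Kekulé alternation inside an
aromatic ring never flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reaction_io import Reaction

__all__ = ["EditLabels", "derive_atom_labels", "derive_bond_labels", "derive_labels"]


@dataclass
class EditLabels:
    """Binary reactivity labels aligned to the product's atoms and bond list."""

    atom_labels: np.ndarray
    bond_labels: np.ndarray

    @property
    def n_edits(self) -> int:
        return int(self.atom_labels.sum() + self.bond_labels.sum())


def derive_atom_labels(reaction: Reaction) -> np.ndarray:
    atom_map = reaction.require_map()
    y = np.zeros(reaction.product.n_atoms, dtype=np.int64)
    for i, a_p in enumerate(reaction.product.atoms):
        a_r = reaction.reactants.atoms[atom_map[i]]
        if a_p.total_hs != a_r.total_hs or a_p.formal_charge != a_r.formal_charge:
            y[i] = 1
    return y


def derive_bond_labels(reaction: Reaction) -> np.ndarray:
    atom_map = reaction.require_map()
    r_types = reaction.reactants.bond_type_map()
    z = np.zeros(reaction.product.n_bonds, dtype=np.int64)
    for k, b in enumerate(reaction.product.bonds):
        ri, rj = atom_map[b.i], atom_map[b.j]
        if ri > rj:
            ri, rj = rj, ri
        r_type = r_types.get((ri, rj))
        if r_type is None or r_type != b.bond_type:
            z[k] = 1
    return z


def derive_labels(reaction: Reaction) -> EditLabels:
    return EditLabels(atom_labels=derive_atom_labels(reaction),
                      bond_labels=derive_bond_labels(reaction))
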