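"""Evaluation metrics for edits, classes, mappings and thresholds.

Top-n edit accuracy pools each reaction's atoms and bonds into one ranked
candidate list (edits are heterogeneous) and counts the reaction correct at
level n when the full ground-truth edit set of size e appears within the top
n - 1 + e ranked candidates, i.e. the edit set is recovered allowing n - 1
spurious intrusions.  With a single true edit this reduces to the usual
"true edit within the top n" convention of retrosynthesis baselines, which
is also available directly via ``single_edit=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score

__all__ = ["EvalReport", "rank_edits", "edit_set_recovered",
           "top_n_edit_accuracy", "classification_accuracy",
           "select_thresholds", "consistency"]


@dataclass
class EvalReport:
    top_n_edit: dict = field(default_factory=dict)   # n -> accuracy
    class_accuracy: float = float("nan")
    map_accuracy: float = float("nan")
    atom_f1: float = float("nan")
    bond_f1: float = float("nan")
    thresholds: tuple = (0.5, 0.5)
    consistency: float = float("nan")
    n_reactions: int = 0
    n_zero_edit: int = 0
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "top_n_edit": {str(k): v for k, v in self.top_n_edit.items()},
            "class_accuracy": self.class_accuracy,
            "map_accuracy": self.map_accuracy,
            "atom_f1": self.atom_f1,
            "bond_f1": self.bond_f1,
            "thresholds": list(self.thresholds),
            "consistency": self.consistency,
            "n_reactions": self.n_reactions,
            "n_zero_edit": self.n_zero_edit,
            "per_class": {str(k): v for k, v in self.per_class.items()},
        }


def rank_edits(atom_scores, bond_scores) -> list:
    """One ranked candidate list per reaction: ('atom', i) and ('bond', k)
    entries sorted by descending score; ties broken by kind then index so the
    ranking is deterministic."""
    cands = ([(float(s), 0, i) for i, s in enumerate(np.asarray(atom_scores))]
             + [(float(s), 1, k) for k, s in enumerate(np.asarray(bond_scores))])
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [("atom" if kind == 0 else "bond", idx) for _, kind, idx in cands]


def edit_set_recovered(atom_scores, bond_scores, atom_labels, bond_labels,
                       n: int, single_edit: bool = False) -> bool:
    """Whether the reaction counts as correct at level n (see module docs)."""
    truth = {("atom", i) for i in np.flatnonzero(np.asarray(atom_labels))}
    truth |= {("bond", k) for k in np.flatnonzero(np.asarray(bond_labels))}
    if not truth:
        raise ValueError("reaction has no true edits")
    ranked = rank_edits(atom_scores, bond_scores)
    if single_edit:
        return bool(truth & set(ranked[:n]))
    cutoff = n - 1 + len(truth)
    return truth <= set(ranked[:cutoff])


def top_n_edit_accuracy(scores, labels, n: int, single_edit: bool = False):
    """Fraction of reactions whose edit set is recovered at level n.

    `scores` and `labels` are per-reaction sequences of (atom, bond) array
    pairs.  Reactions with zero true edits are excluded from the rate and
    counted separately; returns (accuracy, n_zero_edit).
    """
    hits, total, zero = 0, 0, 0
    for (a_s, b_s), (a_l, b_l) in zip(scores, labels):
        if np.asarray(a_l).sum() + np.asarray(b_l).sum() == 0:
            zero += 1
            continue
        total += 1
        if edit_set_recovered(a_s, b_s, a_l, b_l, n, single_edit=single_edit):
            hits += 1
    acc = hits / total if total else float("nan")
    return acc, zero


def classification_accuracy(predicted, true) -> float:
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    return float(np.mean(predicted == true))


def select_thresholds(atom_scores, atom_labels, bond_scores, bond_labels,
                      grid=None) -> tuple:
    """Grid search maximizing F1 independently for atoms and bonds; ties go
    to the lower threshold."""
    if grid is None:
        grid = np.linspace(0.05, 0.95, 19)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")

    def best(scores, labels):
        scores = np.concatenate([np.asarray(s, dtype=float).ravel() for s in scores]) \
            if isinstance(scores, (list, tuple)) else np.asarray(scores, dtype=float)
        labels = np.concatenate([np.asarray(l).ravel() for l in labels]) \
            if isinstance(labels, (list, tuple)) else np.asarray(labels)
        if scores.size == 0 or labels.sum() == 0:
            return float(grid[0])
        f1s = [f1_score(labels, (scores >= t).astype(int), zero_division=0)
               for t in grid]
        return float(grid[int(np.argmax(f1s))])   # argmax -> first (lowest) tie

    return best(atom_scores, atom_labels), best(bond_scores, bond_labels)


def consistency(class_correct, edit_correct) -> float:
    """Fraction of reactions where both class and Top-1 edits are correct."""
    class_correct = np.asarray(class_correct, dtype=bool)
    edit_correct = np.asarray(edit_correct, dtype=bool)
    if class_correct.shape != edit_correct.shape:
        raise ValueError("flag vectors differ in length")
    return float(np.mean(class_correct & edit_correct))
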