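"""Training losses for the multi-task objective.

Reactivity (atom and bond) uses a hybrid Dice-Focal loss: Dice optimizes
overlap under heavy class imbalance, focal cross-entropy emphasizes hard
examples, and `lambda_dice` mixes them (default 0.4).  The mapping head is
trained with a row-wise negative log-likelihood on the Sinkhorn-normalized
correspondence matrix, and classification with standard cross-entropy.

Tasks are combined either with fixed lambda coefficients,

    L_total = lambda_map L_map + lambda_react (L_atom + L_bond) + lambda_cls L_cls,

or with homoscedastic uncertainty weighting,

    L_total = sum_i ( L_i / (2 sigma_i^2) + log sigma_i ),

where the per-task log-variances s_i = log sigma_i^2 are learned jointly with
the model.  All functions accept NumPy arrays or autodiff Tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad

__all__ = [
    "LossConfig",
    "focal_loss",
    "dice_loss",
    "reactivity_loss",
    "mapping_loss",
    "classification_loss",
    "total_loss",
    "EPS",
]

EPS = 1e-8   # clamp for every log/probability operation


@dataclass
class LossConfig:
    lambda_map: float = 1.0
    lambda_react: float = 1.0
    lambda_cls: float = 1.0
    lambda_dice: float = 0.4
    focal_gamma: float = 2.0
    focal_alpha: float = 5.0          # positive-class upweighting factor
    dice_smooth: float = 1.0
    weighting_mode: str = "fixed"     # "fixed" | "uncertainty"
    # learnable s_i = log sigma_i^2 per task, created by the trainer
    log_variances: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.lambda_dice <= 1.0:
            raise ValueError("lambda_dice must lie in [0, 1]")
        if self.weighting_mode not in ("fixed", "uncertainty"):
            raise ValueError(f"unknown weighting_mode {self.weighting_mode!r}")


def focal_loss(scores, labels, gamma: float = 2.0, alpha: float = 1.0):
    """Mean of -alpha_t (1 - p_t)^gamma log p_t.

    p_t is the probability of the true class; alpha_t applies the
    positive-class weight `alpha` on label-1 elements and 1 on label-0.
    With gamma=0 and alpha=1 this is exactly binary cross-entropy.
    """
    labels = np.asarray(labels, dtype=np.float64)
    p_t = scores * labels + (1.0 - scores) * (1.0 - labels)
    p_t = ad.clip(p_t, EPS, 1.0)
    alpha_t = alpha * labels + (1.0 - labels)
    return ad.mean(-1.0 * alpha_t * (1.0 - p_t) ** gamma * ad.log(p_t))


def dice_loss(scores, labels, smooth: float = 1.0):
    """1 - (2 sum(p y) + s) / (sum p + sum y + s)."""
    labels = np.asarray(labels, dtype=np.float64)
    inter = ad.total_sum(scores * labels)
    denom = ad.total_sum(scores) + float(labels.sum()) + smooth
    return 1.0 - (2.0 * inter + smooth) / denom


def reactivity_loss(atom_scores, atom_labels, bond_scores, bond_labels,
                    config: LossConfig):
    """Hybrid Dice-Focal loss per target: lam*Dice + (1-lam)*Focal."""
    lam = config.lambda_dice

    def hybrid(scores, labels):
        f = focal_loss(scores, labels, gamma=config.focal_gamma,
                       alpha=config.focal_alpha)
        d = dice_loss(scores, labels, smooth=config.dice_smooth)
        return lam * d + (1.0 - lam) * f

    l_atom = hybrid(atom_scores, atom_labels)
    # a product may have no bonds; an empty target contributes zero loss
    n_bonds = bond_scores.shape[0] if hasattr(bond_scores, "shape") else len(bond_scores)
    if n_bonds == 0:
        l_bond = ad.Tensor(0.0) if isinstance(atom_scores, ad.Tensor) else 0.0
    else:
        l_bond = hybrid(bond_scores, bond_labels)
    return l_atom, l_bond


def mapping_loss(soft, truth_map):
    """Row-wise NLL of the true reactant atom under the soft correspondence."""
    if isinstance(truth_map, dict):
        rows = np.array(sorted(truth_map), dtype=np.intp)
        cols = np.array([truth_map[i] for i in sorted(truth_map)], dtype=np.intp)
    else:
        truth_map = np.asarray(truth_map, dtype=np.intp)
        rows = np.arange(truth_map.shape[0], dtype=np.intp)
        cols = truth_map
    if isinstance(soft, ad.Tensor):
        picked = ad.gather2d(soft, rows, cols)
    else:
        picked = np.asarray(soft)[rows, cols]
    return ad.mean(-1.0 * ad.log(ad.clip(picked, EPS, 1.0)))


def classification_loss(class_probs, label: int):
    """Cross-entropy of the true class (labels are 1-based)."""
    k = int(label) - 1
    if isinstance(class_probs, ad.Tensor):
        p = ad.gather2d(class_probs.reshape(1, -1), [0], [k])
        return ad.mean(-1.0 * ad.log(ad.clip(p, EPS, 1.0)))
    p = np.asarray(class_probs).ravel()[k]
    return float(-np.log(max(p, EPS)))


def total_loss(l_map, l_atom, l_bond, l_cls, config: LossConfig):
    """Combine the task losses per the configured weighting mode."""
    if config.weighting_mode == "fixed":
        return (config.lambda_map * l_map
                + config.lambda_react * (l_atom + l_bond)
                + config.lambda_cls * l_cls)
    tasks = {"map": l_map, "react": l_atom + l_bond, "cls": l_cls}
    total = None
    for name, loss in tasks.items():
        s = config.log_variances.get(name, 0.0)   # s = log sigma^2
        term = ad.exp(-1.0 * s) * 0.5 * loss + 0.5 * s
        total = term if total is None else total + term
    return total
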