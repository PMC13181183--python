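"""Training and evaluation orchestration.

Training teacher-forces the cross-attention with ground-truth atom maps and
optimizes the multi-task objective with AdamW.  Early stopping monitors an
equal-weight scalarization of validation atom F1, bond F1 and class F1.
Defaults mirror the reference configuration (batch 32, lr 1e-4, weight decay
5e-5, patience 10); desk-scale runs shrink the encoder and raise the
learning rate, since the full-scale schedule is tied to a 50k-reaction
corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score

from .autodiff import AdamW, Tensor
from .matching import symmetry_aware_accuracy, wl_partition
from .metrics import (EvalReport, classification_accuracy, consistency,
                      edit_set_recovered, select_thresholds,
                      top_n_edit_accuracy)
from .model import EncoderConfig, ReactionModel
from .objective import (LossConfig, classification_loss, mapping_loss,
                        reactivity_loss, total_loss)

__all__ = ["RunConfig", "train_model", "evaluate_model", "TASK_NAMES"]

TASK_NAMES = ("map", "react", "cls")


@dataclass
class RunConfig:
    model: EncoderConfig = field(default_factory=EncoderConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 5e-5
    patience: int = 10
    max_epochs: int = 50
    seed: int = 0
    mode: str = "full"
    n_classes: int = 10
    clip_norm: float = 5.0   # global gradient-norm clip; 0 disables
    sinkhorn_iterations: int = 10
    sinkhorn_temperature: float = 0.1
    similarity_norm: str = "cosine"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        model = EncoderConfig(**d.get("model", {}))
        loss = LossConfig(**d.get("loss", {}))
        training = dict(d.get("training", {}))
        return cls(model=model, loss=loss, **training)


def _truth_assignment(reaction) -> np.ndarray:
    m = reaction.require_map()
    return np.array([m[i] for i in range(reaction.product.n_atoms)],
                    dtype=np.int64)


def _reaction_losses(model, item, config: RunConfig):
    """Forward one reaction and return its combined training loss."""
    reaction, labels = item.reaction, item.labels
    teacher = reaction.atom_map if reaction.atom_map is not None else None
    fw = model.forward(reaction, mode=config.mode, teacher_map=teacher)
    zero = Tensor(0.0)
    l_map = (mapping_loss(fw.tensors["soft"], reaction.atom_map)
             if fw.tensors["soft"] is not None and reaction.atom_map else zero)
    l_atom, l_bond = reactivity_loss(
        fw.tensors["atom"], labels.atom_labels,
        fw.tensors["bond"], labels.bond_labels, config.loss)
    l_cls = (classification_loss(fw.tensors["class_probs"], item.class_label)
             if item.class_label is not None else zero)
    return total_loss(l_map, l_atom, l_bond, l_cls, config.loss)


def train_model(train_items: list, config: RunConfig, val_items: list | None = None,
                stop_fn=None, eval_every: int = 5):
    """Train a :class:`ReactionModel`; returns (model, per-epoch log rows).

    `stop_fn(model, epoch) -> bool`, checked every `eval_every` epochs, allows
    callers to stop once a training-set target is reached.
    """
    if config.mode == "full":
        for item in train_items:
            item.reaction.require_map()
    model = ReactionModel(config.model, n_classes=config.n_classes,
                          sinkhorn_iterations=config.sinkhorn_iterations,
                          temperature=config.sinkhorn_temperature,
                          similarity_norm=config.similarity_norm)
    if config.loss.weighting_mode == "uncertainty" and not config.loss.log_variances:
        config.loss.log_variances = {
            t: Tensor(0.0, requires_grad=True) for t in TASK_NAMES}
    params = dict(model.params)
    sigma_names = []
    for t, s in config.loss.log_variances.items():
        if isinstance(s, Tensor):
            params[f"log_var_{t}"] = s
            sigma_names.append(f"log_var_{t}")
    opt = AdamW(params, lr=config.learning_rate,
                weight_decay=config.weight_decay, no_decay=set(sigma_names))
    rng = np.random.default_rng(config.seed)

    log: list[dict] = []
    best_score, best_params, since_best = -np.inf, None, 0
    n = len(train_items)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            total = None
            for idx in batch:
                loss = _reaction_losses(model, train_items[idx], config)
                total = loss if total is None else total + loss
            total = total * (1.0 / len(batch))
            total.backward()
            if config.clip_norm:
                _clip_gradients(params, config.clip_norm)
            opt.step()
            epoch_loss += total.item() * len(batch)
        row = {"epoch": epoch, "train_loss": epoch_loss / n}
        for t in TASK_NAMES:
            s = config.loss.log_variances.get(t)
            if isinstance(s, Tensor):
                row[f"sigma_{t}"] = float(np.exp(0.5 * s.item()))
        if val_items:
            score = _validation_score(model, val_items, config)
            row["val_score"] = score
            if score > best_score:
                best_score, since_best = score, 0
                best_params = {k: p.data.copy() for k, p in model.params.items()}
            else:
                since_best += 1
                if since_best > config.patience:
                    log.append(row)
                    break
        log.append(row)
        if stop_fn is not None and (epoch + 1) % eval_every == 0 and stop_fn(model, epoch):
            break
    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
    return model, log


def _clip_gradients(params: dict, max_norm: float) -> None:
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float(np.sum(p.grad ** 2))
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale


def _validation_score(model, items, config: RunConfig) -> float:
    """Equal-weight mean of atom F1, bond F1 and class F1 at threshold 0.5."""
    atom_s, atom_l, bond_s, bond_l, pred_c, true_c = [], [], [], [], [], []
    for item in items:
        fw = model.forward(item.reaction, mode=config.mode)
        atom_s.append(fw.edit_scores.atom_scores)
        bond_s.append(fw.edit_scores.bond_scores)
        atom_l.append(item.labels.atom_labels)
        bond_l.append(item.labels.bond_labels)
        if item.class_label is not None:
            pred_c.append(fw.class_scores.predicted)
            true_c.append(item.class_label)
    a = f1_score(np.concatenate(atom_l), np.concatenate(atom_s) >= 0.5,
                 zero_division=0)
    b = f1_score(np.concatenate(bond_l), np.concatenate(bond_s) >= 0.5,
                 zero_division=0)
    c = (f1_score(true_c, pred_c, average="macro", zero_division=0)
         if true_c else 0.0)
    return float(np.mean([a, b, c]))


def evaluate_model(model: ReactionModel, items: list, mode: str = "full",
                   thresholds: tuple | None = None) -> EvalReport:
    """Full evaluation: Top-n edit accuracy, class accuracy, symmetry-aware
    mapping accuracy, F1 at (selected) thresholds, and consistency."""
    scores, labels = [], []
    pred_classes, true_classes = [], []
    map_accs, edit_flags, class_flags = [], [], []
    for item in items:
        fw = model.forward(item.reaction, mode=mode)
        s = (fw.edit_scores.atom_scores, fw.edit_scores.bond_scores)
        l = (item.labels.atom_labels, item.labels.bond_labels)
        scores.append(s)
        labels.append(l)
        has_edit = l[0].sum() + l[1].sum() > 0
        edit_flags.append(
            edit_set_recovered(s[0], s[1], l[0], l[1], n=1) if has_edit else True)
        if item.class_label is not None:
            pred_classes.append(fw.class_scores.predicted)
            true_classes.append(item.class_label)
            class_flags.append(pred_classes[-1] == true_classes[-1])
        else:
            class_flags.append(True)
        if fw.assignment is not None and item.reaction.atom_map is not None:
            truth = _truth_assignment(item.reaction)
            map_accs.append(symmetry_aware_accuracy(
                fw.assignment, truth, wl_partition(item.reaction.reactants)))

    report = EvalReport(n_reactions=len(items))
    for n in (1, 3, 5):
        acc, zero = top_n_edit_accuracy(scores, labels, n)
        report.top_n_edit[n] = acc
        report.n_zero_edit = zero
    if true_classes:
        report.class_accuracy = classification_accuracy(pred_classes, true_classes)
        per: dict = {}
        for p, t, e in zip(pred_classes, true_classes, edit_flags):
            d = per.setdefault(t, {"n": 0, "class_hits": 0, "edit_hits": 0})
            d["n"] += 1
            d["class_hits"] += int(p == t)
            d["edit_hits"] += int(e)
        report.per_class = {
            k: {"support": d["n"],
                "class_accuracy": d["class_hits"] / d["n"],
                "edit_accuracy": d["edit_hits"] / d["n"]}
            for k, d in sorted(per.items())}
    if map_accs:
        report.map_accuracy = float(np.mean(map_accs))
    if thresholds is None:
        thresholds = select_thresholds(
            [s[0] for s in scores], [l[0] for l in labels],
            [s[1] for s in scores], [l[1] for l in labels])
    report.thresholds = thresholds
    atom_all = np.concatenate([s[0] for s in scores])
    bond_all = np.concatenate([s[1] for s in scores]) if any(
        s[1].size for s in scores) else np.zeros(0)
    atom_lab = np.concatenate([l[0] for l in labels])
    bond_lab = np.concatenate([l[1] for l in labels]) if any(
        np.asarray(l[1]).size for l in labels) else np.zeros(0)
    report.atom_f1 = float(f1_score(atom_lab, atom_all >= thresholds[0],
                                    zero_division=0))
    if bond_all.size:
        report.bond_f1 = float(f1_score(bond_lab, bond_all >= thresholds[1],
                                        zero_division=0))
    report.consistency = consistency(class_flags, edit_flags)
    return report
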