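"""Differentiable soft graph matching and symmetry handling.

Product atoms are aligned to reactant atoms through a similarity matrix
(dot products of node embeddings) normalized by Sinkhorn scaling into a
(nearly) doubly stochastic correspondence matrix.  Hard assignments are the
row-wise argmax.  Weisfeiler-Lehman color refinement partitions each graph
into structural equivalence classes, which are used both to repair
non-injective assignments among symmetric atoms and to score mappings in a
symmetry-aware way.

`similarity`, `sinkhorn` and `consistency_score` accept either NumPy arrays
or autodiff Tensors, so the same code sits inside the training graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .reaction_io import MolGraph

__all__ = [
    "CorrespondenceMatrix",
    "WLPartition",
    "similarity",
    "sinkhorn",
    "hard_assign",
    "wl_partition",
    "symmetry_refine",
    "consistency_score",
    "symmetry_aware_accuracy",
]


@dataclass
class CorrespondenceMatrix:
    """Soft |V_P| x |V_R| alignment and its derived hard assignment."""

    raw: np.ndarray
    soft: np.ndarray
    hard: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.hard is None:
            self.hard = hard_assign(self.soft)


@dataclass
class WLPartition:
    """Fixed point of WL color refinement, grouped into equivalence classes."""

    classes: list                      # list of sorted atom-index lists
    class_of: np.ndarray               # atom index -> class index
    labels_per_iteration: list         # color history, one int array per round

    @property
    def n_classes(self) -> int:
        return len(self.classes)


# ---------------------------------------------------------------- soft matching
def similarity(h_p, h_r):
    """Raw similarity: dot products of product and reactant embeddings."""
    dp = h_p.shape[1] if hasattr(h_p, "shape") else len(h_p[0])
    dr = h_r.shape[1] if hasattr(h_r, "shape") else len(h_r[0])
    if dp != dr:
        raise ValueError(f"embedding dims differ: {dp} vs {dr}")
    return h_p @ h_r.T


def sinkhorn(raw, iterations: int = 10, temperature: float = 0.1):
    """Sinkhorn scaling of exp(raw / temperature).

    Alternates row and column normalization `iterations` times and ends with
    a final row step, so every product atom carries a proper distribution
    over reactant candidates.  Square inputs converge to a doubly stochastic
    matrix.  Rectangular inputs (fewer product than reactant atoms) are
    padded with constant slack rows before scaling; surplus reactant atoms —
    leaving groups, reagents — send their column mass to the slack rows
    instead of being force-fed onto real product atoms, and after the slack
    rows are dropped the real column sums are <= 1 (up to the iteration
    tolerance).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    data = raw.data if isinstance(raw, ad.Tensor) else np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("sinkhorn input must be finite")
    # subtract the max before exponentiating for numerical stability; the
    # normalizations cancel any constant shift (shift invariance)
    n_p, n_r = data.shape
    if n_p < n_r:
        # slack logit at the scale of the strongest match, so unmatched
        # reactant columns prefer the slack rows over weak real affinities
        pad = ad.Tensor if isinstance(raw, ad.Tensor) else np.asarray
        slack = pad(np.full((n_r - n_p, n_r), float(data.max())))
        raw = ad.concat([raw, slack], axis=0) if isinstance(raw, ad.Tensor) \
            else np.concatenate([raw, slack], axis=0)
        data = raw.data if isinstance(raw, ad.Tensor) else raw
    shift = float(data.max()) if data.size else 0.0
    # the additive floor guards against exp underflow producing exactly-zero
    # rows/columns (and hence 0/0 in the normalizations); it is far below
    # any probability the scaling can resolve
    m = ad.exp((raw - shift) * (1.0 / temperature)) + 1e-30
    for _ in range(iterations):
        m = m / m.sum(axis=1, keepdims=True)
        m = m / m.sum(axis=0, keepdims=True)
    if n_p < n_r:
        m = (ad.gather_rows(m, np.arange(n_p)) if isinstance(m, ad.Tensor)
             else m[:n_p])
    m = m / m.sum(axis=1, keepdims=True)
    return m


def hard_assign(soft) -> np.ndarray:
    """Row-wise argmax; ties resolved to the lowest reactant index."""
    data = soft.data if isinstance(soft, ad.Tensor) else np.asarray(soft)
    return np.argmax(data, axis=1)


# --------------------------------------------------------------- WL refinement
def wl_partition(graph: MolGraph, max_iterations: int | None = None) -> WLPartition:
    """WL color refinement with initial colors (element, charge, aromatic).

    Refinement stops at the fixed point (the partition no longer splits) or
    after `max_iterations` rounds (default: number of atoms, which always
    reaches the fixed point).
    """
    n = graph.n_atoms
    if n == 0:
        raise ValueError("wl_partition requires a nonempty graph")
    if max_iterations is None:
        max_iterations = n
    neigh = [graph.neighbors(i) for i in range(n)]
    palette: dict = {}
    colors = np.empty(n, dtype=np.int64)
    for i, a in enumerate(graph.atoms):
        key = (a.element, a.formal_charge, a.aromatic)
        colors[i] = palette.setdefault(key, len(palette))
    history = [colors.copy()]
    for _ in range(max_iterations):
        palette = {}
        new = np.empty(n, dtype=np.int64)
        for i in range(n):
            key = (colors[i], tuple(sorted(colors[j] for j in neigh[i])))
            new[i] = palette.setdefault(key, len(palette))
        history.append(new.copy())
        if len(set(new)) == len(set(colors)):
            colors = new
            break
        colors = new
    # group by (final color, element); the initial coloring already separates
    # elements, so this matches "identical labels and matching atomic types"
    groups: dict = {}
    for i, a in enumerate(graph.atoms):
        groups.setdefault((colors[i], a.element), []).append(i)
    classes = sorted(groups.values(), key=lambda c: c[0])
    class_of = np.empty(n, dtype=np.int64)
    for ci, members in enumerate(classes):
        class_of[members] = ci
    return WLPartition(classes=classes, class_of=class_of,
                       labels_per_iteration=history)


def symmetry_refine(assignment, product_partition: WLPartition,
                    reactant_partition: WLPartition):
    """Repair assignment collisions among symmetry-equivalent product atoms.

    Within each product WL class, product atoms assigned to the same reactant
    atom are spread greedily (lowest index first) over unused members of that
    reactant atom's WL class.  Returns (refined assignment, list of product
    atoms left colliding because no equivalent reactant atom was free).
    """
    refined = np.asarray(assignment, dtype=np.int64).copy()
    unresolved: list[int] = []
    used = {}
    for r in refined:
        used[int(r)] = used.get(int(r), 0) + 1
    for members in product_partition.classes:
        targets: dict = {}
        for i in members:
            targets.setdefault(int(refined[i]), []).append(i)
        for r, atoms in targets.items():
            for i in atoms[1:]:           # lowest-index atom keeps r
                r_class = reactant_partition.classes[reactant_partition.class_of[r]]
                free = [c for c in r_class if used.get(c, 0) == 0]
                if free:
                    new_r = free[0]
                    used[r] -= 1
                    used[new_r] = used.get(new_r, 0) + 1
                    refined[i] = new_r
                else:
                    unresolved.append(i)
    return refined, unresolved


# ------------------------------------------------------------------- scoring
def consistency_score(m, a_p, a_r):
    """Structural consistency sum A_P(i,j) A_R(i',j') M(i,i') M(j,j')
    over ordered pairs, i.e. sum(A_P * (M A_R M^T))."""
    inner = (m @ a_r) @ m.T
    prod = inner * a_p
    total = ad.total_sum(prod)
    return total if isinstance(total, ad.Tensor) else float(total)


def symmetry_aware_accuracy(predicted, truth,
                            reactant_partition: WLPartition) -> float:
    """Fraction of product atoms whose predicted reactant atom falls in the
    same reactant WL class as the true one."""
    predicted = np.asarray(predicted, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if predicted.shape != truth.shape:
        raise ValueError("assignments must cover the same product atoms")
    cls = reactant_partition.class_of
    return float(np.mean(cls[predicted] == cls[truth]))
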