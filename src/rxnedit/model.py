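"""Multi-task graph model: shared edge-aware encoder, mapping-guided
cross-attention, dual-graph bond encoder, reactivity heads and classifier.

Architecture overview
---------------------
Reactant and product graphs pass through one *shared* GINE-style encoder:
each layer transforms ``(1 + eps) * h_i + sum_j relu(h_j + W_e e_ij)`` with a
two-layer MLP, followed by a dynamically weighted skip connection
``gate * update + (1 - gate) * input`` with a learnable per-layer gate.

Product embeddings are aligned to reactant embeddings by Sinkhorn soft
matching.  Mapping-guided cross-attention lets every product atom attend to
its single assigned reactant counterpart (ground-truth assignment during
training, predicted and symmetry-refined at inference); with one candidate
the softmax weight is identically 1, so each head returns the value
projection of the counterpart.  Head outputs are concatenated and appended to
the product embedding, giving enriched embeddings of twice the encoder width.

Atom reactivity is a per-atom MLP + sigmoid on the enriched embeddings.
Bond reactivity scores the concatenation of both enriched endpoints, the
bond's features, its dual-graph (line-graph) embedding, and both endpoint
atom scores; inputs for the two bond orientations are averaged so the score
is orientation invariant.  The reaction class is predicted from mean-pooled
enriched product embeddings.

In products-only mode the reactivity heads consume zero-padded enriched
embeddings (no reactant information); classification still uses the
cross-attention path when reactants are supplied.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, gather_rows, segment_sum, softmax
from .matching import (CorrespondenceMatrix, hard_assign, similarity, sinkhorn,
                       symmetry_refine, wl_partition)
from .reaction_io import (ATOM_FEATURE_DIM, BOND_FEATURE_DIM, DualGraph,
                          MolGraph, Reaction, build_dual_graph)

__all__ = ["EncoderConfig", "NodeEmbeddings", "AttentionParams", "EditScores",
           "ClassScores", "ForwardOutput", "ReactionModel"]


@dataclass
class EncoderConfig:
    num_layers: int = 5
    hidden_dim: int = 512
    num_heads: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.hidden_dim % self.num_heads != 0:
            raise ValueError("hidden_dim must be divisible by num_heads")

    @property
    def head_dim(self) -> int:
        return self.hidden_dim // self.num_heads


@dataclass
class NodeEmbeddings:
    h: np.ndarray
    enriched: np.ndarray | None = None
    pooled: np.ndarray | None = None


@dataclass
class AttentionParams:
    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    num_heads: int

    @property
    def d_k(self) -> int:
        return self.w_q.shape[1] // self.num_heads


@dataclass
class EditScores:
    atom_scores: np.ndarray
    bond_scores: np.ndarray
    dual_embeddings: np.ndarray


@dataclass
class ClassScores:
    probabilities: np.ndarray

    @property
    def predicted(self) -> int:
        """1-based class index of the argmax."""
        return int(np.argmax(self.probabilities)) + 1


@dataclass
class ForwardOutput:
    correspondence: CorrespondenceMatrix | None
    edit_scores: EditScores
    class_scores: ClassScores
    assignment: np.ndarray | None = None
    unresolved: list = field(default_factory=list)
    attention: np.ndarray | None = None
    # live autodiff tensors for loss computation (training use)
    tensors: dict = field(default_factory=dict)


def _l2_rows(t: Tensor) -> Tensor:
    norm = (t * t).sum(axis=1, keepdims=True) ** 0.5
    return t / (norm + 1e-8)


class ReactionModel:
    """Holds all trainable parameters and runs the multi-task forward pass."""

    def __init__(self, config: EncoderConfig | None = None, n_classes: int = 10,
                 d_x: int = ATOM_FEATURE_DIM, d_e: int = BOND_FEATURE_DIM,
                 sinkhorn_iterations: int = 10, temperature: float = 0.1,
                 similarity_norm: str = "cosine"):
        if similarity_norm not in ("cosine", "dot"):
            raise ValueError(f"unknown similarity_norm {similarity_norm!r}")
        self.config = config or EncoderConfig()
        self.n_classes = n_classes
        self.d_x = d_x
        self.d_e = d_e
        self.sinkhorn_iterations = sinkhorn_iterations
        self.temperature = temperature
        self.similarity_norm = similarity_norm
        self.params: dict[str, Tensor] = {}
        self._init_params()

    # ------------------------------------------------------------------ setup
    def _init_params(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        d, dx, de = self.config.hidden_dim, self.d_x, self.d_e
        p = self.params

        def lin(name, n_in, n_out):
            p[f"{name}_W"] = ad.parameter(rng, (n_in, n_out))
            p[f"{name}_b"] = Tensor(np.zeros(n_out), requires_grad=True)

        lin("in", dx, d)
        lin("dual_in", de, d)
        for l in range(self.config.num_layers):
            lin(f"enc{l}_edge", de, d)
            lin(f"enc{l}_mlp1", d, d)
            lin(f"enc{l}_mlp2", d, d)
            p[f"enc{l}_eps"] = Tensor(0.0, requires_grad=True)
            p[f"enc{l}_gate"] = Tensor(0.0, requires_grad=True)   # sigmoid -> 0.5
            lin(f"dual{l}_mlp1", d, d)
            lin(f"dual{l}_mlp2", d, d)
            p[f"dual{l}_eps"] = Tensor(0.0, requires_grad=True)
            p[f"dual{l}_gate"] = Tensor(0.0, requires_grad=True)
        for name in ("att_q", "att_k", "att_v"):
            p[f"{name}_W"] = ad.parameter(rng, (d, d))
        lin("atom1", 2 * d, d)
        lin("atom2", d, 1)
        lin("bond1", 4 * d + de + d + 2, d)
        lin("bond2", d, 1)
        lin("cls1", 2 * d, d)
        lin("cls2", d, self.n_classes)

    # ---------------------------------------------------------------- encoder
    def encode(self, graph: MolGraph) -> Tensor:
        """Shared GINE encoder; returns |V| x hidden_dim embeddings."""
        if graph.n_atoms == 0:
            raise ValueError("cannot encode an empty graph")
        if graph.atom_features is None:
            raise ValueError("graph must be featurized before encoding")
        p = self.params
        n = graph.n_atoms
        src = np.array([b.i for b in graph.bonds] + [b.j for b in graph.bonds],
                       dtype=np.intp)
        dst = np.array([b.j for b in graph.bonds] + [b.i for b in graph.bonds],
                       dtype=np.intp)
        e2 = (np.concatenate([graph.bond_features, graph.bond_features])
              if graph.n_bonds else np.zeros((0, self.d_e)))
        h = Tensor(graph.atom_features) @ p["in_W"] + p["in_b"]
        for l in range(self.config.num_layers):
            e_proj = Tensor(e2) @ p[f"enc{l}_edge_W"] + p[f"enc{l}_edge_b"]
            msg = (gather_rows(h, src) + e_proj).relu()
            agg = segment_sum(msg, dst, n)
            z = (1.0 + p[f"enc{l}_eps"]) * h + agg
            upd = (z @ p[f"enc{l}_mlp1_W"] + p[f"enc{l}_mlp1_b"]).relu()
            upd = upd @ p[f"enc{l}_mlp2_W"] + p[f"enc{l}_mlp2_b"]
            g = p[f"enc{l}_gate"].sigmoid()
            h = g * upd + (1.0 - g) * h
        return h

    # -------------------------------------------------------- cross-attention
    def cross_attend(self, h_p: Tensor, h_r: Tensor, assignment) -> Tensor:
        """Each product atom attends to its single assigned reactant atom.

        The softmax over one candidate is identically 1, so per head the
        output is the value projection of the counterpart; concatenating the
        heads equals the full value projection of the gathered rows.
        """
        assignment = np.asarray(assignment, dtype=np.intp)
        counterpart = gather_rows(h_r, assignment)
        return counterpart @ self.params["att_v_W"]

    def attention_matrix(self, h_p, h_r) -> np.ndarray:
        """Full product x reactant attention map (head-averaged softmax of
        scaled q.k), exported for interpretation only."""
        hp = h_p.data if isinstance(h_p, Tensor) else np.asarray(h_p)
        hr = h_r.data if isinstance(h_r, Tensor) else np.asarray(h_r)
        q = hp @ self.params["att_q_W"].data
        k = hr @ self.params["att_k_W"].data
        nh, dk = self.config.num_heads, self.config.head_dim
        maps = []
        for head in range(nh):
            sl = slice(head * dk, (head + 1) * dk)
            logits = q[:, sl] @ k[:, sl].T / np.sqrt(dk)
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            maps.append(e / e.sum(axis=1, keepdims=True))
        return np.mean(maps, axis=0)

    @staticmethod
    def enrich(h_p: Tensor, h_tilde: Tensor) -> Tensor:
        if h_p.shape[0] != h_tilde.shape[0]:
            raise ValueError("row counts differ in enrich")
        return concat([h_p, h_tilde], axis=1)

    # ------------------------------------------------------------ dual encoder
    def encode_dual(self, dual: DualGraph) -> Tensor:
        """GIN message passing over the bond-node (line) graph."""
        p = self.params
        n = dual.n_nodes
        if n == 0:
            return Tensor(np.zeros((0, self.config.hidden_dim)))
        src = np.array([u for u, v in dual.dual_edges]
                       + [v for u, v in dual.dual_edges], dtype=np.intp)
        dst = np.array([v for u, v in dual.dual_edges]
                       + [u for u, v in dual.dual_edges], dtype=np.intp)
        h = Tensor(dual.bond_node_features) @ p["dual_in_W"] + p["dual_in_b"]
        for l in range(self.config.num_layers):
            agg = segment_sum(gather_rows(h, src), dst, n)
            z = (1.0 + p[f"dual{l}_eps"]) * h + agg
            upd = (z @ p[f"dual{l}_mlp1_W"] + p[f"dual{l}_mlp1_b"]).relu()
            upd = upd @ p[f"dual{l}_mlp2_W"] + p[f"dual{l}_mlp2_b"]
            g = p[f"dual{l}_gate"].sigmoid()
            h = g * upd + (1.0 - g) * h
        return h

    # ----------------------------------------------------------------- heads
    def atom_head(self, enriched: Tensor) -> Tensor:
        p = self.params
        z = (enriched @ p["atom1_W"] + p["atom1_b"]).relu()
        return (z @ p["atom2_W"] + p["atom2_b"]).sigmoid()      # (n, 1)

    def bond_head(self, enriched: Tensor, bond_features: np.ndarray,
                  dual_embeddings: Tensor, atom_scores: Tensor,
                  bonds) -> Tensor:
        """Orientation-invariant bond scores: the (i,j) and (j,i) input
        concatenations are averaged before the MLP."""
        p = self.params
        idx_i = np.array([b.i for b in bonds], dtype=np.intp)
        idx_j = np.array([b.j for b in bonds], dtype=np.intp)
        e = Tensor(bond_features)
        hi, hj = gather_rows(enriched, idx_i), gather_rows(enriched, idx_j)
        yi, yj = gather_rows(atom_scores, idx_i), gather_rows(atom_scores, idx_j)
        fwd = concat([hi, hj, e, dual_embeddings, yi, yj], axis=1)
        rev = concat([hj, hi, e, dual_embeddings, yj, yi], axis=1)
        x = 0.5 * (fwd + rev)
        z = (x @ p["bond1_W"] + p["bond1_b"]).relu()
        return (z @ p["bond2_W"] + p["bond2_b"]).sigmoid()      # (m, 1)

    def classify(self, enriched: Tensor) -> Tensor:
        p = self.params
        pooled = enriched.mean(axis=0, keepdims=True)           # (1, 2d)
        z = (pooled @ p["cls1_W"] + p["cls1_b"]).relu()
        logits = z @ p["cls2_W"] + p["cls2_b"]
        return softmax(logits, axis=1)                          # (1, K)

    # --------------------------------------------------------------- forward
    def forward(self, reaction: Reaction, mode: str = "full",
                teacher_map: dict | None = None) -> ForwardOutput:
        """Run the multi-task pass.

        In full mode the cross-attention assignment is the ground-truth map
        when `teacher_map` is given (training-time teacher forcing) and the
        symmetry-refined hard Sinkhorn assignment otherwise.
        """
        if mode not in ("full", "products_only"):
            raise ValueError(f"unknown mode {mode!r}")
        has_reactants = reaction.reactants is not None and reaction.reactants.n_atoms > 0
        if mode == "full" and not has_reactants:
            raise ValueError("full mode requires reactant graphs")

        h_p = self.encode(reaction.product)
        n_p = reaction.product.n_atoms

        correspondence = None
        soft = None
        assignment = None
        unresolved: list = []
        attention = None
        h_tilde = None
        if has_reactants:
            h_r = self.encode(reaction.reactants)
            # cosine logits keep the Sinkhorn input bounded, which is what
            # makes the matching head trainable; "dot" is the unnormalized
            # printed form
            if self.similarity_norm == "cosine":
                raw = similarity(_l2_rows(h_p), _l2_rows(h_r))
            else:
                raw = similarity(h_p, h_r)
            soft = sinkhorn(raw, self.sinkhorn_iterations, self.temperature)
            if teacher_map is not None:
                assignment = np.array([teacher_map[i] for i in range(n_p)],
                                      dtype=np.intp)
            else:
                hard = hard_assign(soft)
                assignment, unresolved = symmetry_refine(
                    hard, wl_partition(reaction.product),
                    wl_partition(reaction.reactants))
            correspondence = CorrespondenceMatrix(
                raw=raw.data.copy(), soft=soft.data.copy(),
                hard=np.asarray(assignment).copy())
            attention = self.attention_matrix(h_p, h_r)
            h_tilde = self.cross_attend(h_p, h_r, assignment)

        zero_pad = Tensor(np.zeros((n_p, self.config.hidden_dim)))
        if mode == "full":
            react_enriched = self.enrich(h_p, h_tilde)
            cls_enriched = react_enriched
        else:
            react_enriched = self.enrich(h_p, zero_pad)
            cls_enriched = (self.enrich(h_p, h_tilde) if h_tilde is not None
                            else react_enriched)

        dual = build_dual_graph(reaction.product)
        hd = self.encode_dual(dual)
        atom = self.atom_head(react_enriched)
        bond = self.bond_head(react_enriched, dual.bond_node_features, hd,
                              atom, reaction.product.bonds)
        probs = self.classify(cls_enriched)

        out = ForwardOutput(
            correspondence=correspondence,
            edit_scores=EditScores(atom_scores=atom.data.ravel().copy(),
                                   bond_scores=bond.data.ravel().copy(),
                                   dual_embeddings=hd.data.copy()),
            class_scores=ClassScores(probabilities=probs.data.ravel().copy()),
            assignment=(np.asarray(assignment).copy()
                        if assignment is not None else None),
            unresolved=unresolved,
            attention=attention,
            tensors={"soft": soft, "atom": atom.reshape(-1),
                     "bond": bond.reshape(-1), "class_probs": probs},
        )
        return out

    # ------------------------------------------------------------ checkpoints
    def save(self, path) -> None:
        meta = {
            "config": {"num_layers": self.config.num_layers,
                       "hidden_dim": self.config.hidden_dim,
                       "num_heads": self.config.num_heads,
                       "seed": self.config.seed},
            "n_classes": self.n_classes,
            "d_x": self.d_x,
            "d_e": self.d_e,
            "sinkhorn_iterations": self.sinkhorn_iterations,
            "temperature": self.temperature,
            "similarity_norm": self.similarity_norm,
        }
        arrays = {k: p.data for k, p in self.params.items()}
        arrays["__meta__"] = np.array(json.dumps(meta))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ReactionModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            model = cls(config=EncoderConfig(**meta["config"]),
                        n_classes=meta["n_classes"], d_x=meta["d_x"],
                        d_e=meta["d_e"],
                        sinkhorn_iterations=meta["sinkhorn_iterations"],
                        temperature=meta["temperature"],
                        similarity_norm=meta.get("similarity_norm", "cosine"))
            for k in model.params:
                if k not in data.files:
                    raise ValueError(
                        f"checkpoint incompatible with model version: missing {k}")
                if model.params[k].data.shape != data[k].shape:
                    raise ValueError(
                        f"checkpoint parameter {k} has shape {data[k].shape}, "
                        f"expected {model.params[k].data.shape} "
                        "(feature vocabulary mismatch?)")
                model.params[k].data = data[k].astype(np.float64)
        return model
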