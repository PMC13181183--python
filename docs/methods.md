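# Methods

This note records the model, its assumptions, the tunable parameters, the
synthetic-data design, and the numerical choices that are not obvious from
the code.

## Graphs and features

Molecular graphs are heavy-atom graphs built with RDKit; hydrogens are
implicit and enter only through the per-atom total-H-count feature and the
labeling rules. A graph may contain several disconnected molecules
(multi-component reactant systems, reagents included); component membership
is recorded but not otherwise used by the model.

Atom features are concatenated one-hot blocks over closed vocabularies with a
reserved "other" bucket: element (C, N, O, S, P, F, Cl, Br, I, B, Si, Sn, Se,
Cu, Zn, Mg), formal charge (−2…+2), chirality tag, hybridization (sp…sp³d²),
degree (0–6), total H count (0–4), plus aromaticity and ring-membership
flags (d_x = 49). Bond features: bond type (single/double/triple/aromatic),
conjugation, stereo tag, ring flag (d_e = 11). The "other" buckets close the
vocabularies, so feature widths are constants and out-of-vocabulary input
never errors. These vocabularies are a documented stand-in: they cover the
elements common in organic reaction corpora, and anything rarer is treated as
"other".

Atom-map numbers are 1-based in SMILES; all internal indices are 0-based.
The ground-truth atom map is an index-based, injective, total function from
product atoms to reactant atoms, populated only when every product atom
carries a map number present on the reactant side.

## Reactivity labels

On the product graph, an atom is reactive when its total hydrogen count or
formal charge differs from its mapped reactant atom. A bond (i, j) is
reactive when the mapped reactant pair is not bonded — the bond was formed in
the forward direction, i.e. it is the retrosynthetic break — or is bonded
with a different type. Two deliberate choices:

* Reactant bonds with no product counterpart (retro "new bond formation")
  are not labeled; they have no home on the product graph and are excluded
  from the task.
* Bond types are compared after aromaticity perception, so Kekulé
  alternation within an aromatic ring never produces spurious labels.

## Encoder

Both graphs pass through one shared stack of GINE-style layers: the update
for atom i is `MLP((1 + ε)·h_i + Σ_{j∈N(i)} ReLU(h_j + W_e e_ij))` with a
learnable per-layer ε, followed by a dynamically weighted skip connection
`out = g·update + (1 − g)·input` where g is the sigmoid of a learnable
per-layer scalar (initialized to 0, i.e. g = ½). "Dynamically weighted" is
underspecified in the literature this follows; the scalar gate is the
simplest learnable realization. The dual-graph encoder uses the same update
family without edge features, with separate parameters. Parameters use
fan-in-scaled uniform initialization behind a single seed.

Reference configuration: 5 layers, 512 dims, 8 heads — the published
full-scale setting. Desk-scale runs use 3–4 layers and 64–96 dims; 4 layers
matter on aryl fixtures because two para-carbons of different rings differ
only at graph distance 3, the edge of a 3-layer receptive field.

## Atom mapping

Raw similarities are dot products of L2-normalized embeddings (cosine) by
default, divided by a fixed temperature τ = 0.1 inside Sinkhorn.
Unnormalized dot products (`similarity_norm="dot"`) reproduce the textbook
form `M̂ = H_P H_Rᵀ` but make training unstable: embedding norms grow during
optimization, the effective temperature collapses, and the matching loss
surface turns into a near-argmax with exploding gradients. Bounding the
logits is a numerical choice, not a modeling one.

Sinkhorn scaling exponentiates `raw/τ` (max-shifted; a 1e-30 additive floor
guards against exp underflow creating zero rows or columns) and alternates
row and column normalization, ending on a row step so each product atom
carries a proper distribution over reactant candidates. Rectangular
instances (|V_P| < |V_R|, the usual retro case) are padded with constant
slack rows at the strongest-match logit before scaling and the slack rows are
dropped afterwards. Without slack, plain column normalization force-feeds
leaving-group columns: the nucleophile's true-match probability is capped
near 0.5 because the leaving halogen's column must be filled by some real
row. With slack, surplus reactant atoms (leaving groups, reagents) send
their column mass to the dustbin, and real columns sum to at most ~1.

Hard assignments are the row-wise argmax (ties to the lowest reactant
index). Weisfeiler–Lehman refinement — initial color (element, charge,
aromatic flag), iterated neighborhood hashing to the fixed point (at most
|V| rounds) — partitions each graph into symmetry equivalence classes.
Collisions among symmetry-equivalent product atoms are repaired greedily
(lowest index first) within the targeted reactant class; infeasible
collisions are left in place and flagged. WL classes are unions of
automorphism orbits (tested against a brute-force VF2 oracle), so
symmetry-aware mapping accuracy — the fraction of product atoms mapped into
the correct reactant WL class — forgives exactly the rotations and
reflections that no structural method can distinguish.

The structural-consistency score
`Σ A_P(i,j)·A_R(i′,j′)·M(i,i′)·M(j,j′)` is exposed both as the brute-force
matching oracle in tests and as an optional (off by default) auxiliary
regularizer.

## Cross-attention and heads

Per head, each product atom builds a query from itself and key/value from its
single assigned reactant counterpart; the softmax over one candidate is
identically 1, so the head output is exactly the value projection of the
counterpart. This degenerate form is implemented as printed; the full
product × reactant attention map (head-averaged) is still computed for
export and interpretation. Ground-truth assignments are used during training
(teacher forcing) and predicted, symmetry-refined assignments at inference;
both paths share all parameters.

The bond head scores
`σ(MLP([Ĥ_P(i) ‖ Ĥ_P(j) ‖ E_ij ‖ HD_ij ‖ ŷ_i ‖ ŷ_j]))`; the two orientations
of the concatenation are averaged before the MLP, making scores exactly
orientation-invariant. Products-only mode zero-pads the enriched slot for
the reactivity heads, so one parameterization serves both modes;
classification still uses the cross-attention path when reactants are
supplied, as the products-only evaluation convention prescribes.

## Losses and task weighting

* Focal: mean of `−α_t(1−p_t)^γ log p_t`, γ = 2, with a positive-class
  weight α (default 5; the upweighting factor is not published, 5 is a
  conventional choice for ~10% positive rates).
* Dice: `1 − (2Σpy + s)/(Σp + Σy + s)`, smoothing s = 1, which also defines
  the degenerate all-negative case as zero loss.
* Reactivity = `λ_dice·Dice + (1−λ_dice)·Focal` per target, λ_dice = 0.4.
* Mapping = row-wise negative log-likelihood of the true reactant atom under
  the Sinkhorn matrix. The published work never defines its mapping loss;
  NLL is the direct choice when supervised maps exist.
* Classification = cross-entropy.
* Total = fixed λ-weighted sum, or homoscedastic uncertainty weighting
  `Σ_i L_i/(2σ_i²) + log σ_i` over three tasks (atom+bond reactivity is one
  task), with s_i = log σ_i² learned jointly. The two modes are mutually
  exclusive. All log/probability operations clamp at 1e-8.

## Training

AdamW (reference settings: lr 1e-4, weight decay 5e-5, batch 32, early
stopping patience 10 on the equal-weight mean of validation atom F1, bond F1
and class F1 — the scalarization weights are not published, equal weights
are the neutral choice). Gradients are clipped to global norm 5. Desk-scale
runs use lr 1e-3: the reference learning rate is tied to a 50k-reaction
corpus and is far too slow for 50-reaction overfitting.

The backing tensor library is a small reverse-mode autodiff engine on
float64 NumPy arrays (matmul, broadcasting arithmetic, gather/segment-sum
for message passing, softmax, clip); gradients are verified against central
differences to ~1e-9 through the entire forward pass.

## Synthetic data

Ten hand-coded templates (esterification, amide coupling, etherification,
amine alkylation, secondary-alcohol oxidation, alkene hydrogenation, acid
deprotonation, thioether formation, aryl esterification, N-methylation)
mirror the ten-class structure of standard reaction benchmarks and span the
label mechanisms: bond formation with a leaving group, bond-order change,
H-count change, and charge change. Templates are written directly as graph
edits on RDKit molecules, so the atom map, edit set and class index are
exact by construction rather than re-derived. R-groups are drawn from a
scaffold pool of alkyl chains and aromatic rings; `symmetric_fraction`
(default 0.3) controls how often an aryl scaffold with nontrivial WL classes
is used, and atom orders are randomly permuted by default to defeat
positional shortcuts.

One guardrail follows from the exact-ground-truth contract: an instance is
rejected when the product has a graph automorphism that moves reactive
atoms or bonds onto non-reactive ones, or relocates the truth map across
reactant WL classes. Example: benzyl bromide + propylamine can yield a
product whose two arms are exchangeable by symmetry, in which case "which
C–N bond was formed" is not decidable from the reaction — the declared truth
would not be a function of the observable input, and no permutation-
equivariant model (or human) could recover it.

What the generator does not emulate: realistic reagent/solvent context,
stereochemistry changes, multi-step or rearrangement chemistry, label noise,
and the heavy class imbalance of patent data. A green test on this substrate
establishes that the mechanisms are implemented correctly and can be learned
jointly; it does not establish benchmark-level accuracy on real corpora.

## Evaluation

Top-n edit accuracy pools each reaction's atoms and bonds into a single
ranked candidate list (descending score; deterministic tie-breaks) and
counts a reaction correct at level n when the full true edit set of size e
appears within the top n − 1 + e candidates — the edit set is recovered with
at most n − 1 intrusions. With e = 1 this reduces to the usual "true edit in
the top n" convention of retrosynthesis baselines, which is also available
directly (`single_edit=True`). Reactions with no true edit are excluded and
counted separately. Classification is exact-match accuracy; mapping is
symmetry-aware accuracy averaged per reaction; reactivity F1 uses thresholds
grid-searched to maximize F1 (ties to the lower threshold); consistency is
the fraction of reactions with both the class and the Top-1 edit set
correct.

## Known limitations

* No stereochemistry-aware matching beyond the stereo feature bits; no 3D.
* The classifier sees only ten template classes at desk scale; products-only
  classification can be ambiguous when different reactant sets yield the
  same product.
* WL classes are coarser than true "chemical equivalence": the two oxygens
  of a carboxyl group share a WL class under the (element, charge, aromatic)
  initial coloring because refinement ignores bond orders. This only makes
  symmetry-aware accuracy mildly more permissive.
* Uncertainty weighting and fixed λ weights cannot be combined.
* Checkpoints store raw parameter arrays plus config; no backward
  compatibility is attempted across feature-vocabulary changes (loading
  fails loudly on a width mismatch).
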