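# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `rnaqa`. It documents what the code does and why; every
number quoted as an outcome here is computed by the test suite or by
`scripts/acceptance.py`, not asserted from elsewhere.

## Scoring model

The scorer is a regression network that maps one RNA chain to a vector of
per-nucleotide quality estimates (pNuL) in (0, 1), interpreted as
predicted lDDT values, and reports their arithmetic mean as the
molecule-level score (pMoL). pMoL is computed, never predicted by a
separate head.

**Frames.** Each nucleotide gets a rigid frame by the three-point
Gram–Schmidt construction with the anchor order (P, C4′, glycosidic N)
and the translation at C4′. All coordinates entering frame construction
— and, by extension, every 3D point used inside the attention module —
are scaled by 0.1, so squared-distance attention penalties operate in
nm-like units while feature distances stay in Å. 5′-terminal residues
without a P atom fall back to O5′; if that is also absent, the frame is
completed deterministically from the C4′→N direction alone (such a frame
is not equivariant, which is acceptable only because the case is a rare
degenerate terminus). Triples with a Gram–Schmidt residual below 1e-8
are rejected as degenerate.

**Features.** Node: one-hot over (A, C, G, U, X) plus relative position
i/L — 6 values. Pair: a 5-bin sequence-separation one-hot (0, 1, 2–5,
6–24, >24) concatenated with Gaussian RBF encodings of the 9 anchor-atom
distances, i-atom-major over (P, C4′, N) × (P, C4′, N) — 149 values. The
16 RBF centers are linearly spaced on [0, 100] Å including both
endpoints; the Gaussian width σ equals the center spacing (100/15 Å).
That width is a package default (standard RBF practice) and is
configurable; nothing downstream depends on its exact value. RBF inputs
are raw Å distances — the 0.1 scaling never touches them, since a 100 Å
cap only makes sense unscaled.

**Locality.** Attention is restricted to the k = 20 nearest neighbours
by C4′–C4′ distance (self always first, within the budget). Ties are
broken by ascending index *after rounding distances to 1e-6 Å*: regular
helices contain exactly tied distances, and without the rounding a
global rotation perturbs them at the 1e-13 level and flips neighbourhood
membership, silently breaking rotation invariance. With it, the k-NN
graph — and the whole prediction — is invariant to machine precision.

**Attention.** Four IPA layers, 4 heads, hidden width 128 (per-head
scalar width c/H = 32), 8 query/key points and 4 value points per head,
with the AlphaFold2 weighting constants w_L = √(1/3), w_C = √(2/(9·Q)).
Pair embeddings are computed once from input features and held fixed
across layers; only the node embedding is updated (the alternative —
updating pair features between layers — is left unexplored). The
attention bias b_ij is a per-layer learned linear map from the pair
embedding to one scalar per head. The per-head point weight γ_h is a
plain learned scalar initialised at 1; it is *not* softplus-constrained,
so that an all-zero parameter set collapses exactly to uniform attention
over each neighbourhood — a property the test suite checks — and because
a sign-free γ loses nothing in a scorer. Layer outputs (scalar, pair,
point, point-norm, concatenated over heads) pass through a linear map,
dropout (p = 0.1, training only), a residual connection and layer
normalisation; the inter-layer wiring is a package choice in the spirit
of structure-module practice. Point norms add 1e-12 inside the square
root to keep the gradient finite at the origin. The head is a linear
layer, a 2-layer ReLU MLP and a logistic squashing to (0, 1).

Frames are fixed by the input structure; the network scores, it does not
fold, so there is no backbone update.

## lDDT labels

The label generator collects every unordered heavy-atom pair lying in
two different nucleotides closer than 15 Å in the native structure, and
scores each nucleotide as the fraction of its pairs preserved by the
model within 0.5/1/2/4 Å, averaged over the four tolerances. The global
score pools all pairs before averaging over tolerances (it is not the
mean of per-nucleotide scores). Same-nucleotide pairs are the only
exclusion; no stereochemical filtering is applied, matching the
"no-stereochecks" labelling convention. Atom matching is by (residue
position, atom name); model atoms without a native counterpart are
ignored, native atoms missing from the model count their pairs as not
preserved. Nucleotides touching no reference pair are reported as
undefined and masked out of training losses rather than scored zero —
undefined is not wrong. Hydrogens are dropped at parse time everywhere.
Both the per-nucleotide and the pooled scores are validated against an
independent brute-force O(n²·atoms²) enumeration to 1e-12.

## Synthetic decoys

The generator emulates what the training corpus needs to exercise —
valid anchor triples, realistic length scales and a controllable
accuracy gradient — without claiming biophysical realism. Natives are
either an A-form-like parametric helix (rise 2.8 Å, twist 32.7°/nt,
C4′ radius 9.22 Å, giving consecutive C4′–C4′ spacing of ~5.9 Å) or a
smooth self-avoiding coil with a 5.9 Å step; each nucleotide carries P,
O5′, C4′, the glycosidic N and three extra heavy pseudo-atoms at fixed
local offsets so the lDDT sees several atoms per residue. Decoys are
Gaussian perturbations (amplitude = per-atom noise SD in Å, grid 0,
0.25, 0.5, 1, 2, 4, 8 Å) or hinge motions (a contiguous 20–60 % segment
rotated 15°/Å of amplitude about an axis through its first C4′; the
segment is capped below the full chain because a whole-chain hinge is a
rigid motion and would carry label 1.0). The default grid makes realised
global lDDT labels span at least [0.3, 1.0]. Everything is reproducible
bit-exactly from the arguments and one seed.

What passing tests on these toys shows: the architecture is invariant,
trainable, and able to rank graded structural damage. What it does not
show: performance on real predictor decoys, whose error modes (register
shifts, non-native base pairing, compaction) the generator does not
emulate.

## Training protocol

L1 loss on pNuL against the per-nucleotide labels, pooled over all
unmasked nucleotides (not a per-structure mean of means); Adam with
β = (0.9, 0.999); dropout 0.1; one structure per step (variable lengths
make padding wasteful); global gradient-norm clipping at 1.0; no
learning-rate schedule and no early stopping. When a validation split is
given, the epoch with the best validation MAE supplies the returned
parameters. The default learning rate is 1e-4, the published value for
corpus-scale training; desk-scale runs (below) use 1e-3 because a few
thousand optimisation steps need proportionally larger steps. A fixed
seed makes the loss trace bit-reproducible on one machine; divergence
(non-finite loss) aborts with a diagnostic.

The package exposes this through a statsmodels-style pair:
`RNAQualityModel` (data + architecture) whose `fit()` returns
`RNAQualityResults` (parameters, trace, `summary()`, `predict()`,
`save()`/`load()`).

## Desk-scale study conditions

The validation experiments (test suite and `scripts/acceptance.py`) use:
10 synthetic natives of 16–32 nt (alternating helix/coil), 8 decoys each
over the default amplitude grid, a 20 % random held-out split, hidden
width reduced to 32 (every other architecture hyperparameter at its
published value), 30 epochs, learning rate 1e-3, everything seeded.
These sizes are chosen so a complete from-scratch run finishes in
minutes on one CPU while the decoy labels still span most of the lDDT
range. The network and its gradients are implemented directly in NumPy
on a small reverse-mode autodiff tape (float64 throughout), with
gradients verified against central finite differences.

## Evaluation metrics

Correlations (Pearson, Spearman, Kendall) at the global level pool all
(target, model) records; per-target values are averaged unweighted, and
targets with zero variance in either variable are skipped with a count.
diff is the pooled mean absolute difference between predicted and true
scores; top-1 loss the per-target quality gap between the top-ranked and
the truly best model (ties in predicted score break by model id);
ROC-AUC classifies good vs bad models at true lDDT ≥ 0.75 and equals the
normalised Mann–Whitney U with ties counted ½. Two formulas whose exact
published bodies were unavailable are implemented as documented,
configurable defaults: the RMSD length normalisation uses the TM-score
style 1/(1 + (RMSD/d0(L))²) with the RNA scale
d0(L) = max(0.6·√(L−0.5) − 2.5, 1), and the composite score is
Q_c = (r_g + (1 − diff) + r_a + (1 − loss) + AUC)/5, i.e. a five-term
average with loss-like terms complemented. Min–max energy recalibration
(1 − normalised energy) is pooled over the whole evaluated set, not per
target.

## Limitations

- Single chains only; no mmCIF, complexes, ligands, or symmetry-aware
  atom swapping in lDDT.
- The synthetic decoys do not reproduce the error structure of real
  structure predictors; trained weights from this package are a protocol
  demonstration, not a drop-in scorer for real models.
- Pair embeddings are frozen across layers; whether updating them helps
  is untested here.
- The per-head width c/H, the inter-layer residual + layer-norm wiring,
  the batch size of 1, gradient clipping, the RBF width and the Eq-style
  reconstructions above are package defaults where the published
  description is silent; all are configurable.
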