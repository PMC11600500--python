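# rnaqa

Reference-free quality assessment of RNA 3D structural models with a
locality-aware invariant point attention (IPA) network.

Given a single predicted RNA structure (a PDB file), `rnaqa` estimates how
accurate each nucleotide is — the **predicted nucleotide-wise lDDT**
(pNuL, in (0, 1)) — and averages those into a molecule-level score, the
**predicted molecular-level lDDT** (pMoL). It is aimed at people who
generate or consume RNA structure predictions and need to rank candidate
models or spot unreliable regions without knowing the experimental
structure.

## The model

Each nucleotide *i* gets a rigid local frame *T<sub>i</sub>* = (*R*, *t*)
built by Gram–Schmidt from its P, C4′ and glycosidic-N atoms (N9 in
purines, N1 in pyrimidines), with coordinates scaled by 0.1. Node features
are a 5-way one-hot (A, C, G, U, nonstandard) plus the relative position
*i*/*L*; pair features combine a 5-bin sequence-separation one-hot
(self, adjacent, 2–5, 6–24, >24) with Gaussian radial-basis encodings
(16 centers on [0, 100] Å) of the 9 distances between the anchor triples
of the two nucleotides. Attention is restricted to each nucleotide's
*k* = 20 nearest neighbours by C4′–C4′ distance, and for head *h* the
weight over *j* ∈ 𝒩(*i*) is

    a_ij = softmax_j  w_L ( qᵢᵀkⱼ/√(c/H) + b_ij − γₕ w_C/2 Σₚ ‖T_i∘q⃗ᵢᵖ − T_j∘k⃗ⱼᵖ‖² )

with *w<sub>L</sub>* = √(1/3), *w<sub>C</sub>* = √(2/9Q). Scalar, pair and
point outputs (the latter mapped back through *T<sub>i</sub>*⁻¹) are
concatenated, projected, and applied with a residual + layer-norm update;
four such layers feed a linear layer, a two-layer MLP and a logistic
output. Because every feature and every attention term depends only on
distances and frame-relative coordinates, the prediction is invariant
under global rotations and translations of the input — the test suite
verifies this to machine precision.

Training minimises the mean absolute error between pNuL and
per-nucleotide lDDT labels (Adam, β = (0.9, 0.999), dropout 0.1). The
label generator is included: a superposition-free lDDT with a 15 Å
inclusion radius, thresholds {0.5, 1, 2, 4} Å and no stereochemical
checks, validated against a brute-force pair-enumeration oracle. Since
the original multi-predictor decoy corpus is not shippable, the package
also includes a synthetic generator of toy RNA natives (A-form-like
helices and smooth coils) with graded Gaussian/hinge decoys spanning the
lDDT range, so the whole stack trains and tests at desk scale.

## Worked example

```python
from rnaqa.synthetic import make_decoy_set
from rnaqa.model import RNAQualityModel
from rnaqa.network import ModelConfig
from rnaqa.training import TrainConfig

manifest = make_decoy_set("demo", n_natives=4, decoys_per_native=6, seed=11)
model = RNAQualityModel.from_manifest(manifest, ModelConfig(hidden=32),
                                      validation_fraction=0.2, seed=11)
results = model.fit(TrainConfig(epochs=10, seed=11, learning_rate=1e-3))
print(results.summary())

ex = model.validation[0]
pred = results.predict(ex.decoy)
print(f"decoy {ex.decoy.id}: pMoL {pred.pmol:.4f}  true global lDDT {ex.truth_global:.4f}")
```

prints

```
RNA Quality Scorer (locality-aware IPA)
============================================
IPA layers         4
attention heads    4
hidden width c     32
query points       8
value points       4
neighbours K       20
parameters         79777
training examples  19
epochs             10
learning rate      0.001
seed               11
final train MAE    0.0508
final val MAE      0.1205

decoy native03_d05: pMoL 0.9494  true global lDDT 0.9052
```

The summary lists the architecture and the pooled mean absolute error of
pNuL against the lDDT labels on the training and held-out decoys; the
last line shows the fitted scorer ranking a held-out decoy close to its
true global lDDT. Ten epochs on 19 tiny decoys is deliberately small for
a quick demo — the desk-scale protocol below trains longer on more decoys.

The same pipeline is available from the shell:

```bash
rnaqa fixtures --out demo --natives 4 --decoys 6 --seed 11
rnaqa train --config train.yaml        # manifest, hyperparameters, seed
rnaqa score --pdb demo/native00_d03.pdb --weights weights.npz --out scores.txt
rnaqa lddt --model demo/native00_d03.pdb --native demo/native00.pdb
rnaqa eval --records records.csv --out report.json
```

`scores.txt` holds a `pMoL <value>` header and one
`chain resindex code pNuL` line per nucleotide. The `eval` command
computes the assessment battery for any scorer's records: global and
per-target Pearson/Spearman/Kendall correlations, the mean absolute
difference, top-1 loss, ROC-AUC at an lDDT threshold of 0.75 and the
composite quality score Q_c.

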