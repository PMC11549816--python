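# solugat

Graph-attention regression of protein solubility from 3D structure.

Protein solubility — operationally, the supernatant fraction of a protein
expressed in a cell-free assay, a continuous value in [0, 1] — is a key
screening quantity in recombinant protein production and antibody
engineering. Sequence-only predictors miss the spatial arrangement of
residues; this package predicts solubility from a *residue graph*: nodes are
amino acids, edges connect residue pairs whose Cα atoms lie within a
distance cutoff (default 10 Å) in the 3D structure (e.g. a predicted model),
and each node carries a 1280-dimensional protein-language-model embedding
concatenated with its 20-dimensional BLOSUM62 substitution profile
(F = 1300).

The model is a multi-head graph attention network. Per head $k$, with
shared projection $W_k$ and attention vector $\vec a_k \in \mathbb{R}^{2F'}$:

$$e_{ij} = \mathrm{LeakyReLU}_{0.2}\!\big(\vec a_k^{\,T} [W_k \vec h_i \,\|\, W_k \vec h_j]\big),\qquad
\alpha_{ij} = \mathrm{softmax}_{j \in \mathcal N_i}(e_{ij})$$

$$\vec h_i' = \big\Vert_{k=1}^{K} \sigma\Big(\sum_{j \in \mathcal N_i} \alpha^k_{ij} W_k \vec h_j\Big)$$

with neighborhoods $\mathcal N_i$ read off the adjacency (self-loops
included). After two such layers (K = 16 heads, 1024 hidden channels) node
vectors are mean-pooled and a perceptron emits
$S = \mathrm{ReLU}(w \cdot \bar h' + b)$. Training minimizes RMSE;
evaluation reports $R^2 = 1 - SS_{res}/SS_{tot}$ plus
accuracy/precision/recall/F1/AUC after binarizing at 0.5. The network —
forward pass and analytic gradients — is implemented directly in NumPy and
verified in the test suite against scalar-loop oracles and finite
differences.

Also included: greedy global-identity homology separation for dataset
curation (Needleman–Wunsch, BLOSUM62, affine gaps, 30% cutoff), five-fold
cross-validation, a deterministic stub embedding provider for offline runs,
and a synthetic fixture generator with known ground-truth signal.

## Worked example

Generate a small synthetic dataset and run the full pipeline with a reduced
model (the defaults — 16 heads, 1024 channels, lr 2e-6 — are sized for real
corpora of thousands of proteins):

```bash
solugat make-fixtures --n 96 --seed 11 --out fx96
cat > config96.yaml <<'EOF'
dataset: fx96/dataset.csv
out_dir: run96
test_fraction: 0.167
split_seed: 1
model: {in_features: 1300, num_layers: 2, heads: 4, hidden_channels: 64, seed: 0}
train: {learning_rate: 0.001, batch_size: 8, epochs: 220, seed: 0, patience: 1000, weight_decay: 5.0, lr_schedule: cosine}
EOF
solugat run --config config96.yaml
```

which prints (abridged; ~2 minutes on one CPU):

```
{
  "accuracy": 1.0,
  "auc": 1.0,
  "f1": 1.0,
  "n": 16,
  "precision": 1.0,
  "r2": 0.9206094981208043,
  "recall": 1.0,
  "test_rmse": 0.08544672051102443,
  "train_rmse": 0.03864605921741057,
  ...
}
```

i.e. on the 16 held-out proteins the model explains ~92% of the label
variance (R² = 0.92, RMSE 0.085 on a [0, 1] scale; the generating noise sd
is 0.05) and, after thresholding at 0.5, classifies all 16 correctly. A
single protein can then be scored with
`solugat predict --graph g.edges --features p.npy --checkpoint run/model.npz`.

Other subcommands: `build-graph` (PDB → edge list), `featurize`, `curate` /
`curate-cross` (homology separation), `train`, `cv`, `evaluate`.

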