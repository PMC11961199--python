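# screenkit

Graph-network prediction of **enzyme catalytic residues**, with
enzyme-class contrastive training, spatial-cohesion analysis of catalytic
sites, and mutation-tolerance triage from MAVE (multiplexed assay of
variant effects) data.

`screenkit` is for structural bioinformaticians who have enzyme
structures (PDB/mmCIF), evolutionary profiles (PSI-BLAST PSSM, profile
HMM) and optionally per-residue language-model embeddings, and want
per-residue catalytic propensities plus the downstream analyses those
propensities enable. A synthetic-data module generates complete
protein-like datasets with planted catalytic sites, so the whole pipeline
runs and is tested without any external database.

## Model

An enzyme chain is an attributed residue graph G = (V, A, X) with binary
Cα–Cα contact adjacency A (cutoff 10 Å) and features
X = (X_L, X_G, X_A): sigmoid-normalized PSSM + profile-HMM columns
(n×50), language-model embeddings (n×1024), and averaged atomic
properties with solvent accessibility (n×14). Three graph-convolution
layers with symmetric renormalized propagation
S = D̃^(−1/2)(A+I)D̃^(−1/2),

    H(0) = [X_L, X_A],   H(i) = ReLU(S H(i−1) W(i)),   i = 1..3,

are concatenated, fused by an MLP with the embedding branch into
XE ∈ R^(n×d), and reduced to an n×2 output whose softmax is the
catalytic propensity. Training mixes a contrastive phase — the pooled
representation z = mean(XE) is pulled toward its enzyme-class (EC
first-level) cluster center and pushed from a random other-class center
by the hinged Triplet Margin Loss max(0, ‖z_a−z_p‖₂ − ‖z_a−z_n‖₂ + α),
α = 1 — into class-weighted cross-entropy on the residue labels, with the
mixing weight λ decaying linearly to 0 over the first 30% of epochs.

MAVE triage fits a 3-component Gaussian mixture to variant scores, cuts
at the density intersection of the outer components to call residues
wild-type-like (WTL) vs functional-loss (FL), and predicts the call with
a shallow decision tree over distance-to-predicted-catalytic-site and
relative solvent accessibility.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```bash
python examples/02_train_and_evaluate.py
```

trains on 30 synthetic enzymes (60 residues, 5 planted catalytic
residues each) and evaluates on 10 held-out enzymes from the same
generated dataset:

```
held-out AUPR:    0.358  (prevalence 0.083)
held-out AUC:     0.888
best F1:          0.434 at threshold 0.07
final lambda:     0.0
```

AUPR 0.358 against a catalytic prevalence of 0.083 is a ~4-fold
enrichment over chance at this deliberately small training size; the
full 200/50-enzyme benchmark run by `scripts/acceptance.py` recovers the
planted signal far more strongly. The other examples build a
residue graph from a PDB file (`01`), reproduce the spatial cohesion of
catalytic sites (`03` — planted sites have median nearest-other-catalytic
distance ≈ 4.8 Å vs ≈ 12.8 Å for the rest of the chain), and run the MAVE
triage (`04`).

The `screen-kit` CLI wires the same library into shell workflows:

```bash
screen-kit end-to-end --out run1 --seed 7       # synth -> ... -> evaluate
screen-kit synth --out data --seed 1
screen-kit features --data data --out graphs
screen-kit train --graphs graphs --out model.npz --seed 1
screen-kit predict --model model.npz --graphs graphs --out pred.tsv
screen-kit evaluate --predictions pred.tsv --out metrics.json
```

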