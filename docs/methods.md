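# Methods

## Problem

Catalytic residues — the handful of amino acids that perform an enzyme's
chemical step — are expensive to identify experimentally, and curated
annotations cover a small fraction of known enzymes. `screenkit`
implements a structure-aware predictor of per-residue catalytic
propensity, together with two downstream analyses: the spatial cohesion
of catalytic sites, and mutation-tolerance triage from multiplexed
variant-effect (MAVE) scores.

## Residue graph representation

An enzyme chain of n residues becomes an attributed graph G = (V, A, X):

- **Adjacency** A ∈ {0,1}^(n×n): Cα–Cα contacts under a cutoff,
  default 10 Å. The cutoff is configurable; 10 Å gives a mean residue
  degree of ~13 on globular chains, spanning a typical active site whose
  internal distances concentrate below ~8 Å.
- **Evolutionary block** X_L (n×50): the 20 PSI-BLAST PSSM log-odds
  columns squashed elementwise by the logistic sigmoid x̄ = 1/(1+e^(−x)),
  concatenated with a 30-column profile-HMM block in [0,1]. HMM scores
  are integer negative-log values converted by 2^(−score/1000) ('*' → 0);
  the 30 columns are 20 match emissions, 7 state transitions and 3
  local-diversity fields. This conversion is the canonical
  score-to-probability map for that profile format.
- **Embedding block** X_G (n×1024): per-residue language-model
  embeddings consumed from file. When absent, the block is zero-filled
  and flagged; the forward pass remains defined.
- **Atomic block** X_A (n×14): per-residue means over heavy atoms of
  atom-type one-hot (C/N/O/S/other), atomic mass, B-factor, side-chain
  membership, bonded-hydrogen count, ring membership and van der Waals
  radius, plus broadcast residue-level relative SASA, absolute SASA and
  one reserved channel. Channel order is frozen
  (`structure.ATOMIC_CHANNELS`). Raw physical units are kept by
  `atomic_descriptor`; `build_graph` divides each channel by a fixed
  documented scale so all network inputs are O(1). SASA is computed by
  Shrake–Rupley (probe 1.4 Å, element radii) when not supplied.

Hydrogens, waters and hetero compounds are excluded on read. Residues
lacking a Cα are dropped with a warning; labels and profiles are joined
by author residue number (with insertion codes), so dropped residues
re-align the remaining blocks. Internal indices are 0-based.

## Network

With S = D̃^(−1/2)(A+I)D̃^(−1/2) (self-loops, symmetric renormalization):

    H(0) = [X_L, X_A]                        (width θ = 64)
    H(i) = ReLU(S H(i−1) W(i)),  i = 1..3
    XE   = ReLU(W_f [ReLU(W_g [H1,H2,H3]), ReLU(W_e X_G)])
    Y    = W_2 ReLU(W_1 XE)                  (n×2 logits)

Softmax over the two output channels gives the catalytic propensity.
Layer widths default to 256/256/256 with fusion width d = 512
(full-scale); the synthetic benchmark uses 64/64/64 with fusion 128 so a
full run takes about a minute per training on one CPU. The fusion bracketing
(concatenate the two branches, then one fused layer) is a design choice
among several reasonable nestings; it is fixed and documented here. The embedding block enters only at fusion, not in the propagation
layers. Biases are included in every linear map; initialization is the
uniform fan-based scheme U(±1/√fan_in) under a config seed; dropout is
off by default.

The model and its training loop are implemented directly on NumPy with a
small reverse-mode autodiff core (`autograd.py`) covering exactly the
operations the network needs; gradients are verified against brute-force
oracles in the test suite.

## Training

Total per-enzyme loss at epoch t:

    L(t) = λ(t) · L_TM + (1 − λ(t)) · L_sup

- **Contrastive phase.** The pooled sequence representation
  z = mean over rows of XE (width d) is pulled toward its enzyme-class
  (EC first level) cluster center z_p and pushed from a uniformly sampled
  other-class center z_n by the hinged Triplet Margin Loss
  max(0, ‖z_a−z_p‖₂ − ‖z_a−z_n‖₂ + α), margin α = 1 (the standard
  hinged form; an unhinged variant sits behind a flag). Cluster centers
  are the per-class means of cached pooled representations, recomputed
  each epoch and treated as constants in the gradient.
- **Schedule.** λ decays linearly from 1 at epoch 0 to 0 at 30% of the
  epochs (configurable), then training is pure supervised.
- **Supervised phase.** Class-weighted softmax cross-entropy on the n×2
  output; the positive-class weight defaults to the inverse catalytic
  prevalence of the training set (~19 at 5% prevalence).
- **Optimizer.** Adam (lr 1e-3) with decoupled weight decay 1e-2 on
  weight matrices. Updates are per-enzyme (one graph per step).
- **Model selection.** With `validation_fraction > 0` (0.2 in the
  benchmark) a deterministic slice of training enzymes is held out;
  after the contrastive phase the checkpoint with the best validation
  AUPR is kept. Without it, late training overfits residue identities
  and held-out performance decays.

Single-class datasets must set `use_contrastive=False`; the contrastive
sampler needs at least two classes. Training is bit-reproducible for a
fixed (seed, config, dataset) in a fixed environment.

## Evaluation

- Precision/recall/F1 at a threshold, pooled over residues of all
  enzymes (micro aggregation, labeled in every report); undefined ratios
  are reported as 0 with a flag.
- Best-F1: maximum over all observed propensity values plus endpoints,
  ties toward the lower threshold.
- AUC by the Mann–Whitney pairwise formulation with midrank tie
  correction; AUPR by step-interpolated precision–recall integration
  (equivalent to average precision). Both are cross-checked against
  scikit-learn in the tests.
- Distance analysis: each residue's Euclidean Cα distance to the nearest
  catalytic residue; catalytic residues use the nearest *other*
  catalytic residue so site cohesion is measurable. Summaries are pooled
  medians/quartiles with numpy's linear-interpolation convention.

## MAVE triage

Variant functional scores are fitted with a 3-component univariate
Gaussian mixture (EM, 10 seeded restarts, tol 1e-6); components are
ordered by mean and the cutoff is the root of
w₁N(x|μ₁,σ₁) = w₃N(x|μ₃,σ₃) between the outer means (bisection). A
variant is wild-type-like (WTL) iff its orientation-normalized score is
≥ the cutoff; a residue's class is the majority vote over its variants
with ties to functional-loss (FL), the conservative direction. The triage
model is a depth-≤3 axis-aligned decision tree on two features — distance
to the nearest *predicted* catalytic residue and relative solvent
accessibility — evaluated by stratified seeded 5-fold cross-validation.

## Synthetic data

The generator emulates the statistical signatures the predictor relies
on, not protein physics:

- **Geometry.** Self-avoiding random walks, Cα step 3.8 ± 0.05 Å,
  non-consecutive separation ≥ 4 Å, a mild centroid pull (0.25) keeping
  chains globular (Rg ≈ 14 Å at 100 residues; mean contact degree ≈ 13
  at 10 Å — both in the range of real globular proteins). Pseudo-atoms
  (4 backbone + residue-type side-chain counts) surround each Cα.
- **Catalytic sites.** A seed residue drawn with bias toward the chain
  centroid (burial), grown to k = 5 residues each within 8 Å of another
  planted residue. Default 100 residues/enzyme → 5% prevalence.
- **Signals.** PSSM log-odds ~ round(N(−1, 2)) with catalytic rows
  lifted by +2 (strong conservation); HMM match emissions correlated
  with the lift; B-factors depressed by 20 at catalytic residues;
  catalytic positions enriched for charged amino acids (D/E/H/K/R,
  p = 0.7); embeddings = enzyme-class direction + rank-16 shared basis
  + 0.05-std isotropic residual. The low-rank embedding mirrors the
  principal-subspace concentration of real language-model embeddings; a
  full-rank iid-noise embedding would let the network memorize every
  training residue and nothing would generalize.
- **Variant scores.** A 3-Gaussian mixture (means −2/0/+2, sd 0.3,
  weights 0.4/0.2/0.4, higher = more active); residues within 8 Å of
  the planted site draw from the loss component. The analytic
  density-intersection of the planted components is available as ground
  truth for the cutoff procedure.

What passing on this generator does **not** show: robustness to real
structural noise (crystal-packing artifacts, missing density, alternate
conformations), to profile quality varying with family depth, or to the
weaker and entangled feature correlations of real catalytic sites. The
benchmark measures whether the architecture and training machinery can
extract a planted multi-channel signal at realistic geometry and
prevalence — a necessary, not sufficient, condition.

## Benchmark conditions

200 training / 50 held-out enzymes split deterministically (every 5th
enzyme) from one 250-enzyme generated dataset so the two splits share the
embedding universe; 100 residues, 5 planted catalytic residues, 3 enzyme
classes; reduced model widths (above); 100 epochs with validation-based
selection. These sizes keep a full train+predict run around three
minutes on one CPU.

## Numerical choices and edge cases

- Symmetric normalization is exact (no epsilon): self-loops guarantee
  positive degrees.
- Softmax and the sigmoid are computed in overflow-safe forms; the
  cross-entropy clips probabilities at 1e-300 before the log.
- Triplet gradients guard zero norms with 1e-12.
- The EM cutoff raises on non-convergence, on degenerate (constant)
  scores, and when no density intersection exists between the outer
  component means.
- `best_f1` requires both classes; empty-denominator metrics are
  flagged, not silently NaN.
- All randomness flows from `numpy.random.default_rng(seed)`; no global
  state. Generator output is bit-identical under a fixed seed.

## Known limitations

- The GCN smooths features over ~13-neighbor neighborhoods; residues
  spatially adjacent to a catalytic site inherit much of its signal, so
  ranking residues *within* the site's neighborhood is intrinsically
  harder than separating site from non-site. Held-out AUPR saturates
  well below the in-sample value.
- Profile/embedding generation by external tools (PSI-BLAST, HMMER,
  language models) is consumed, not reproduced; the thin subprocess
  wrappers are untested conveniences.
- Single chain per record; no multi-chain active sites.
- CPU-sized problems only; no GPU path.
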