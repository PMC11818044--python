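# Methods

## The prediction problem

Given a protein's sequence and tertiary structure, classify every serine,
threonine and tyrosine residue as phosphorylated or not. The model treats
the protein as an undirected graph — nodes are residues, edges are
spatial contacts — so that the classifier can aggregate evidence from a
site's *structural* neighborhood rather than only its sequence window.

## Contact graph

The representative point of a residue is its β-carbon; glycine (which has
none) and residues with incomplete side chains fall back to the α-carbon,
the universal convention in the contact-map literature. Two residues are
in contact when their representative atoms lie within **8 Å, boundary
inclusive**. Residues with no resolved coordinates (crystallographic
gaps) are kept as isolated nodes so that node index *i* always equals
sequence index *i*; a warning reports their count. Sequence-adjacent
pairs (i, i±1) are contacts like any other pair; `min_seq_sep` can
exclude them. Multi-chain files default to the first chain, multi-model
files to model 0; altloc conformers resolve to the highest-occupancy one.
For AlphaFold models the B-factor column is read as per-residue pLDDT.

## Features

Each residue carries 57 handcrafted dimensions in fixed column order:

| block | cols | content |
|---|---|---|
| one-hot | 0–20 | 20 standard residues (alphabetical one-letter order) + catch-all column 20 for B/J/O/U/X/Z and anything else |
| physicochemical | 21–25 | 5-dim principal-component property summary; the packaged table is the Atchley five-factor solution, any published 5-dim set can be supplied as CSV |
| PSSM | 26–45 | PSI-BLAST log-odds, by default squashed through the logistic 1/(1+e⁻ˣ) to bound the dynamic range (raw mode available) |
| SS | 46–56 | 8 secondary-structure class probabilities (G,H,I,B,E,S,T,C), ASA, HSEu, HSEd; the three exposure columns min-max scaled to [0,1] per protein (off switchable) |

Disabled blocks (feature ablation) are zero-filled, so the matrix is
always L×57 and saved models stay shape-compatible across ablations.

## Network

**GraphSAGE branch** (two layers, full-neighborhood mean aggregation):

    a_v = mean of neighbor rows (zero vector if v is isolated)
    z_v = ReLU( concat(h_v, a_v) · W + b )
    h_v ← z_v / max(‖z_v‖₂, ε)        (norm = "l2_node", default)
         or per-channel batch standardization (norm = "batch")

Full-neighborhood aggregation is used rather than fixed-size neighbor
sampling: contact graphs are small (L ≲ 1300), so sampling would only add
variance. Keeping the node's own representation in the concatenation
means isolated nodes retain their signal, and an edgeless graph
degenerates the branch into a per-node MLP.

**Embedding-CNN branch**: per-residue pLM embeddings (L×p) pass through
two 1-D convolution blocks (conv → normalization → ReLU) with symmetric
zero padding, p → hidden → 57. Convolution is implemented as a sum of
row-shifted affine maps, which makes it a transparent composition of
autodiff primitives.

**Head**: branch outputs are concatenated at the S/T/Y rows only
(L′×114, or L′×57 under a single-branch ablation), then
W₁ (→ 64) → ReLU → W₂ (→ 1) → sigmoid. A site is called positive when
P ≥ 0.5; the tie goes to the positive class.

All parameters are trained jointly, including the embedding projection.
Defaults: `sage_hidden=57` (branch widths symmetric), `head_hidden=64`,
`cnn_hidden=128`, `cnn_kernels=(9,7)`, dropout off. Initialization is
seeded Glorot; forward passes are deterministic given parameters.

## Embedding providers

* `protbert` — wraps the pretrained ProtBERT encoder (1024-dim rows,
  special tokens stripped so row i ↔ residue i). Needs the
  `transformers` stack and downloaded weights; absent those it raises an
  error that names the alternative.
* `hashstub` — offline, deterministic: row i is a superposition of
  seeded-hash vectors for (residue, offset) pairs over a ±k window
  (default k=0, p=64), scaled by the window size. Rows depend only on
  their window and identical (seed, sequence) pairs are bitwise equal.
  The default k=0 keeps the stub's information strictly per-residue so
  the CNN kernels alone determine the receptive field. The whole test
  suite runs on this provider.

## Training and evaluation

Positives are the annotated sites; negatives are sampled globally from
the unannotated S/T/Y positions, without replacement, matched 1:1 to the
positives and stratified per residue type (S with S, T with T, Y with Y;
a shortage in one type is taken in full with a warning). Splits are at
the protein level: uniformly random; family-disjoint (families sorted by
size descending, greedily assigned to training without overshooting the
requested size, name-lexicographic tie break); or by mean pLDDT
(descending sort, upper half "high", median and ties to high).

The loss is binary cross-entropy on the balanced site set of one protein
per optimizer step (graph sizes vary, so no cross-protein batching), with
Adam at initial learning rate 10⁻³ halved four times over the run.
Two regularizers address the one-protein-per-step regime:

* **Input jitter** — per-step Gaussian noise on the feature matrix
  (σ = 0.1) and the embeddings (σ = 1.0), both configurable and off at 0.
  Without it the CNN branch interpolates the training residues within a
  few epochs on small corpora (training BCE → 0) and generalization
  collapses.
* **Checkpoint selection** — a seeded 10% protein carve-out from the
  training set; the epoch with the best validation F1 wins.

Metrics are micro-averaged: confusion counts pooled over all proteins
before computing Acc = (TP+TN)/N, Pre = TP/(TP+FP), Sn = TP/(TP+FN),
F1 = 2·Pre·Sn/(Pre+Sn), with zero-denominator guards.

Training is bitwise reproducible on one machine for fixed seeds. All
tensors are float64 numpy; the in-package reverse-mode autodiff core
(`graphphos.autodiff`) implements exactly the primitives the model needs
and every gradient is finite-difference-checked in the tests.

## Synthetic data generator

The generator emulates the *shape* of a real phosphosite corpus so the
entire pipeline is testable offline:

* **Chains** — self-avoiding random walks with exact 3.8 Å steps (the
  Cα–Cα virtual bond). Steps are uniform inside a globule of radius
  R = 3.3·L^⅓ Å (≈150 Å³ per residue, globular-protein packing); outside
  R the direction is biased back toward the running centroid with weight
  `compaction` (default 0.8). Non-bonded points keep ≥ 4.5 Å separation
  where possible. The defaults give mean contact degrees of ~8–12 at the
  8 Å threshold, matching real Cβ maps; compaction 0 is a free walk with
  few long-range contacts.
* **Sequences** — S/T/Y at 15% total (the natural frequency), other
  residues uniform. In `sequence_only` mode arginine is raised to 20% so
  the planted motif has workable prevalence (see below).
* **Labels** — three planting rules: `structural` (positive iff ≥ 2 of
  the site's contact-graph neighbors are K/R/H), `sequence_only`
  (positive iff "RR" occurs within the ±3 sequence window), `random`
  (fair coin). The first two are then flipped independently with
  probability `noise_rate` (default 0.05). The structural rule is
  deliberately legible through one-hot features alone, so a model that
  aggregates neighbor identities over the graph can recover it.
* **Side files** — PSSMs in the PSI-BLAST ASCII dialect with +5 log-odds
  on the true residue plus small integer noise; SS tables with Dirichlet
  class rows and ASA/HSE in realistic ranges; embeddings from the hash
  stub; PDB files with one representative atom per residue (CA for
  glycine, CB otherwise) and pLDDT-like B-factors. Every file is read
  back by the package's own parsers; raw-mode round trips are exact.

What the generator does **not** emulate: real fold topologies, kinase
recognition motifs, the long-tailed length distribution of real
proteins, evolutionary correlation between PSSM and structure, or the
semantic smoothness of real pLM embeddings (hash vectors of different
residues are near-orthogonal). Passing tests therefore demonstrate that
the machinery is correct and that structure-dependent signal is
recovered when present — not that real-data accuracy would reach any
particular level.

## The planted-signal ablation study

`graphphos.experiments.run_planted_signal_experiment` generates a
60-protein corpus (lengths 80–150, noise 0.05), splits 80/20 at the
protein level, and trains the full model against its structure-blind
("w/o SAGE") ablation under identical corpora, splits, balanced site
sets and seeds, averaging three seeds.

For this study the model uses `experiment_config()`: CNN branch at 8
hidden channels with kernels (5,3) — a ±3-residue receptive field, the
planted motif window — and batch normalization in the SAGE layers. The
general-purpose defaults are deliberately not used here: at sixty-protein
scale a 128–256-channel CNN memorizes the corpus outright, and row-L2
node normalization erases the aggregate-magnitude information discussed
next.

Observed behavior (recomputed by `scripts/acceptance.py`): on structural
corpora the full model reaches ~0.72–0.81 test accuracy while the
ablation stays near ~0.54–0.65, an absolute gap of ~0.15–0.19; on
sequence-motif corpora the gap vanishes (the ablation is equal or
slightly better); on random labels accuracy sits at chance.

**Known limitation — mean aggregation is degree-blind.** The structural
rule thresholds a neighbor *count*, but the mean aggregator sees only
the neighbor *fraction*: count = fraction × degree, and degree survives
only as a weak variance trace (under batch norm) or not at all (under
row-L2). Non-parametric oracles on these corpora quantify the ceiling:
classifiers given the full count and degree reach ~0.93, while
classifiers restricted to the fraction plus exact ±3-local counts — the
information a mean aggregator plus a ±3 CNN can access — reach only
~0.84 on average. The trained model's ~0.77 mean sits a few points below
that restricted ceiling, so most of the shortfall from the count-oracle
is representational, not an optimization failure. A sum aggregator would
remove the ceiling but is intentionally out of scope: mean aggregation
is the model family this package implements.

## Numerical and edge-case choices

* Distances to residues with no coordinates are +∞; they threshold to
  no contact and the residues stay isolated.
* Non-symmetric distance matrices are rejected, not symmetrized.
* L2 node normalization guards with ε = 10⁻¹²; rows of exact zeros stay
  zero.
* Batch statistics are per-protein (the "batch" is the protein's
  residues), identically at train and eval time.
* Metric guards: Pre := 0 when TP+FP = 0; F1 := 0 when Pre+Sn = 0.
* pLDDT split ties and the odd median go to the high group, ordered by
  protein id for determinism.
* PSSM rows are recognized by their layout (position, single-letter
  residue, ≥ 40 numeric fields), so header variants parse without
  special cases; malformed rows report their line number.
* NaN loss aborts training with the protein id and epoch in the message.
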