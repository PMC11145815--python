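# Methods

## Problem and scope

The package predicts protein–ligand binding affinity (PLA) on the pK
scale (−log10 Kd or Ki) from a cropped binding-pocket structure (PDB) and
a 3D ligand structure (SDF), following the early-fusion design in which
three modality-specific feature extractors feed a self-attention fusion
layer and a fully connected regression head. Everything runs on CPU on
top of a small reverse-mode autodiff engine written for this package;
gradient correctness is established against central finite differences
rather than assumed.

## Input representations

**Pocket CTD (147).** The pocket amino-acid sequence is summarized per
physicochemical property by Composition (3 class percentages), Transition
(3 adjacent-pair crossing frequencies, ordered T12/T13/T23) and
Distribution (per class, the 1-based sequence positions of the first,
25%, 50%, 75% and 100% occurrence, each as 100·pos/N). Seven properties
(hydrophobicity, normalized van der Waals volume, polarity,
polarizability, charge, secondary structure, solvent accessibility) ×
21 values = 147. The three-class partitions are the canonical tables used
by standard CTD toolkits, embedded literally in
`descriptors.CTD_GROUPINGS`; the distribution quantile index is
ceil(k·n_g/4) with the first occurrence prepended, and values are on the
0–100 percent scale. These conventions are frozen by golden tests because
several scales/quantile conventions circulate.

**Ligand descriptors (196).** A frozen, versioned registry
(`lig196-rdkit2024.09-v1`) of 196 two-dimensional RDKit descriptors:
the full 2D descriptor list of RDKit 2024.09 minus the eight BCUT2D
eigenvalue descriptors and the four min/max partial-charge descriptors
(both families require a charge model and fail on unusual valences) and
the two information-content indices Ipc/AvgIpc (numeric overflow on
larger molecules). Non-finite values are imputed to 0 and warned once per
name. The registry version is stamped into every trained model so that
feature/weight mismatches are detectable at load time.

**Interaction graph.** Nodes are the heavy atoms of ligand and pocket
(hydrogens excluded by default; PDBbind-style pockets rarely carry them).
Covalent edges come from the ligand bond block, typed by order
(single/double/triple/aromatic); inside the pocket, covalent edges are
inferred by the covalent-radius criterion d ≤ rᵢ + rⱼ + 0.4 Å because
pocket PDB files lack CONECT records. Non-covalent edges connect every
remaining atom pair (within and across molecules) with d ≤ 4.5 Å — the
PotentialNet convention; the threshold is a config field. A single
non-covalent edge type is used rather than distance bins. Node features
(19): one-hot element over {C,N,O,S,P,F,Cl,Br,I,H,other}, one-hot degree
0–5, formal charge, is-ligand flag (recipe id `atom19-v1`).

## Network

* **Descriptor towers** (ligand 196, pocket 147): the vector is treated
  as a single-channel 1D signal; three (conv → batch norm → PReLU) blocks
  with 'same' padding and stride 1, then mean pooling over positions and
  a linear projection to the token dimension. Mean pooling (rather than
  flattening) keeps the parameter count independent of the input length.
* **Graph stage**: node features are embedded linearly; K₁ gated steps
  propagate over covalent edge types only, then K₂ steps over all types
  (separate weights per stage and per edge type). The node update is the
  GRU-style gate h′ = (1−z)⊙h + z⊙n with update gate z, reset gate r and
  candidate n. The readout is gated and ligand-only:
  σ(W[h, h⁰])⊙(Uh) summed over ligand atoms (a mean-readout option
  exists), then projected to the token dimension.
* **Fusion**: the (2 or 3) modality tokens go through scaled dot-product
  self-attention (softmax rows sum to 1); the attended tokens are
  flattened and passed through fully connected layers
  (PReLU, dropout) to a single pK output.
* **Ablations**: DeepLI drops the pocket tower, DeepIP the ligand tower,
  DeepLP the graph stage; attention then runs over the remaining two
  tokens. Each ablation is a strict parameter subset of the full model.

Default sizes: tower channels (16, 32, 64) with kernel 3; graph hidden
32, K₁ = K₂ = 2, gather 64; token 64 with one attention head; head
(128, 32); dropout 0.1. These are deliberately compact so that the full
benchmark protocol (6 trainings on 500 complexes) runs in minutes on a
single CPU with the NumPy backend; all of them are `ModelConfig` fields,
and the hyperparameter search treats them as the search space.

## Training protocol

SmoothL1 loss (quadratic below β = 1 pK, linear above), Adam with
lr 1e-3, batch 64, at most 80 epochs with patience 30 on validation
loss. Descriptors are z-scored with training-set statistics (constant
columns get sd 1); labels stay in pK, with the output bias initialized to
the training-label mean. The returned model is always the snapshot with
minimum validation loss, never the last epoch unless it is the argmin.
Splits take floor(fraction·N) validation items from a seeded permutation
— 3,772 items at 20% give exactly 754/3,018. The repeat protocol retrains
across seeds (10 by default) and flags the best seed by validation error.
Runs are bitwise reproducible per seed on a fixed platform; across BLAS
builds/thread counts only near-equality is promised. Inference is
deterministic: dropout off, batch norm on running statistics.
Hyperparameter search is a seeded random search over declared ranges,
with a complete, replayable trial log.

## Synthetic data generator

Emulates a PDBbind-like collection at toy scale. Pockets are Cα traces
(one carbon per residue, consecutive atoms exactly 3.8 Å apart) along a
momentum random walk with mean reversion toward the origin, so the trace
coils around its own centroid; sequences are uniform over the 20-letter
alphabet. Ligands are random trees over {C,N,O,S} with valence-capped
degrees, bond lengths in 1.2–1.8 Å, occasional geometric cycle closures
and double-bond upgrades, grown within 6 Å of the pocket centroid.

The planted label is pK = 7 + a·(w·z) + ε with weights (1, 1, 2) on
z-scores of ligand heavy-atom count, pocket hydrophobic-class fraction
and ligand–pocket contact count (pairs ≤ 4.5 Å); the scale a maps ±3.3
population sd of the signal onto [2, 12] pK, with clipping as a rare
safety. Noise ε ~ 𝒩(0, 0.3 pK) is added after the scaling so its sd is
genuinely in pK units. The z-score statistics (and the signal sd,
including the covariance between ligand size and contact count) are
calibrated once by a fixed-seed simulation of the generator itself and
cached per spec; the calibration seed is a constant, part of the
generator definition. Defaults: n = 500, pockets 30–60 residues, ligands
10–30 heavy atoms, noise sd 0.3 pK — sized so that learnability and
ablation-separation checks complete in minutes on one CPU.

What the generator does **not** emulate: real chemistry (no valence
realism beyond degree caps, no aromatic systems in pockets, no docking
poses), realistic pocket side chains (Cα only), decoys, or any
label/structure correlation beyond the three planted terms. Passing
tests therefore demonstrate pipeline and optimization correctness and
the *relative* value of the interaction representation — not predictive
accuracy on real PDBbind complexes, which requires the real data and a
larger model/epoch budget.

## Structure I/O conventions

SDF is parsed with RDKit (sanitization deferred; record 0 of multi-record
files by default), PDB with Biopython. Nonstandard residues: MSE → M,
SEC → C; anything else (and waters) is dropped with a logged warning.
AltLoc: the first-seen variant of each atom is kept. Residues are ordered
by (chain, residue number, insertion code). SMILES strings are not
generated; an SDF property named SMILES is passed through if present.
A PDBbind-style index reader (`id resolution year pK ...`, `#` comments)
supports users with a local PDBbind copy; the native index is a simple
CSV (id, pocket_path, ligand_path, pK).

## Numerical choices and degenerate inputs

PCC on a constant vector is reported as an explicit None, not NaN.
PCA axes have their sign fixed so the largest-magnitude loading is
positive. Attention over identical tokens is exactly uniform. Graphs
with no ligand heavy atoms (or no pocket atoms) are construction errors;
a gated step on an edge-free graph reduces to GRU(h, 0). The SmoothL1
quadratic/linear mask is treated as locally constant in the backward
pass (the loss is C¹, so the gradient is exact away from the measure-zero
boundary). Unknown elements map to the 'other' node-feature slot; degrees
above 5 clamp to 5.

## Known limitations

* The exact descriptor identities and hyperparameter values of the
  original architecture are not published; the registry and defaults here
  are this package's own frozen reconstruction, versioned for
  reproducibility rather than archaeology.
* Real-data benchmark numbers (PDBbind refined/core sets) are out of
  desk-scale reach; the package supports them via the index loader but
  does not reproduce them in tests.
* Single non-covalent edge type (no distance binning, no typed
  interactions such as hydrogen bonds); no 3D ligand descriptors;
  CPU-only training.
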