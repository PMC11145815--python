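# deeplip

Multimodal deep learning for **protein–ligand binding affinity (PLA)**
prediction. Given a ligand structure (SDF) and a protein binding pocket
(PDB), the model predicts the affinity on the pK scale
(−log10 of the dissociation/inhibition constant; larger = tighter
binding), and a screening evaluator turns predictions into
inhibitor/non-inhibitor calls at an activity cutoff — the core loop of
structure-based virtual screening.

## The model

Three heterogeneous representations of one complex are fused early:

1. **Ligand descriptors** — a frozen registry of 196 two-dimensional
   physicochemical/topological descriptors (RDKit), processed by a tower
   of three (1D conv → batch norm → PReLU) blocks.
2. **Pocket CTD descriptors** — 147 Composition/Transition/Distribution
   statistics of the pocket amino-acid sequence (7 physicochemical
   properties × 21 values), processed by an identical tower.
3. **Interaction graph** — heavy atoms of the complex with typed covalent
   edges plus non-covalent edges between all atom pairs within 4.5 Å,
   processed by a gated graph sequence network (GRU-style node updates)
   staged as in PotentialNet: K₁ steps over covalent edges, K₂ steps over
   all edges, then a gated ligand-only gather readout

   &nbsp;&nbsp; mᵢ = Σₜ Σ_{j∈Nₜ(i)} Wₜ hⱼ,&nbsp;&nbsp; hᵢ ← GRU(hᵢ, mᵢ).

Each branch emits one token; scaled dot-product self-attention over the
(three) tokens balances the modalities, and fully connected layers map
the flattened attended tokens to the predicted pK. Training minimizes
SmoothL1 loss, keeps the minimum-validation-loss snapshot, and the
benchmark protocol repeats this over 10 seeds, flagging the best seed by
validation error. Ablation variants drop one branch: **DeepLI** (no
pocket), **DeepIP** (no ligand), **DeepLP** (no graph).

The network runs on a small NumPy reverse-mode autodiff engine included
in the package (`deeplip.autodiff` / `deeplip.nn`) — no GPU framework
required; gradients are verified against finite differences in the test
suite.

## Synthetic benchmark

Real PLA benchmarks require a PDBbind download (a loader for its index
format is included). For self-contained testing, `deeplip.synthetic_data`
generates PDBbind-like toy complexes — Cα-trace pockets and random small
molecules — with a *planted* affinity:

pK = squash(w_lig·z(ligand size) + w_poc·z(hydrophobic fraction) +
w_int·z(contact count)) + 𝒩(0, 0.3 pK), confined to [2, 12] pK.

Because the contact term depends on 3D geometry, a model without the
interaction graph (DeepLP) cannot recover the full signal — the planted
analogue of the ablation experiment.

## Worked example

```bash
python examples/04_train_and_screen.py
```

trains on 120 synthetic complexes for 25 epochs and prints:

```
trained 25 epochs; selected snapshot from epoch 12 (val loss 0.207)
held-out n=24: PCC 0.788  MAE 0.741  RMSE 0.948 (pK units)
screening at pK >= 6: accuracy 87.5%  (TP 18 FP 3 TN 3 FN 0)
screening at pK >= 7: accuracy 83.3%  (TP 13 FP 4 TN 7 FN 0)
screening at pK >= 8: accuracy 91.7%  (TP 7 FP 2 TN 15 FN 0)
```

PCC is the Pearson correlation between predicted and true pK on held-out
complexes; MAE/RMSE are the absolute and root-mean-square prediction
errors in pK units; the screening lines report confusion-matrix counts
and accuracy when predictions and labels are both thresholded at the
cutoff. The other scripts in `examples/` demonstrate dataset simulation,
descriptor computation, graph construction, and PCA projection of the
fused features.

A command-line interface wraps the same workflow:

```bash
deeplip simulate --n 100 --seed 0 --out data/
deeplip featurize --index data/index.csv --out features/
deeplip train --index data/index.csv --out run/ --seeds 0,1,2
deeplip predict --model run/model_seed0.npz --index data/index.csv \
    --out preds.csv --threshold 7.0
deeplip evaluate --predictions preds.csv --index data/index.csv
```

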