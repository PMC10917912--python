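# wfpn — weighted feature-pyramid classification of pressure injuries

Pressure injuries (PI) are staged 1–4 by depth of tissue loss (NPUAP
guideline). The stages look deceptively alike — every class is skin
tissue, and telling a stage-3 full-thickness wound from its neighbours
hinges on fine texture, colour and edge cues that deep CNN features
discard. `wfpn` implements a weighted feature-pyramid network for this
fine-grained setting: a dual-pathway fusion neck that re-combines
high-level semantics with low-level detail, with a learnable
non-negative weight on every fusion input, CBAM attention on the
top-down maps, and a weighted ensemble of per-level classifiers.

The package is aimed at researchers who want to train and evaluate the
architecture end-to-end — on their own class-per-folder image trees, or
entirely without clinical data via the built-in synthetic lesion-image
generator. The whole stack (including a compact NumPy reverse-mode
autodiff engine under `wfpn.nn`) runs on a plain CPU.

## The model

A backbone (ResNeXt-50 32x4d by default; any adapter exposing the same
contract plugs in) yields the feature hierarchy {B4, B5, B6} at strides
16/32/64. Every fusion site combines two same-shape maps by
*fast-normalised fusion* with learnable non-negative scalars w_i and
ε = 1e-4:

    O = Σ_i  w_i / (Σ_j w_j + ε) · I_i

The neck then runs:

* **top-down** — F6 = Conv1(GlobalAvgPool(B6) + GlobalMaxPool(B6)), a
  1×1 global-context seed; then
  F_n = Conv3( fuse( Conv1(B_n), Upsample(F_{n+1}) ) );
* **CBAM refinement** of each F_n: channel attention
  M_c(F) = σ(MLP(AvgPool F) + MLP(MaxPool F)) followed by spatial
  attention M_s(F′) = σ(f_{7×7}[AvgPool F′; MaxPool F′]);
* **bottom-up** — P4 = F″4, then
  P_n = Conv3( fuse( F″_n, Downsample(P_{n-1}) ) ).

All fused maps carry 256 channels. Each P level feeds a classifier
(global average pooling, two fully connected layers, K = 4 logits) and
the prediction is the weighted ensemble

    pred = Σ_k w_k · out_k / (ε + Σ_k w_k).

Evaluation reports the confusion matrix, one-vs-rest precision / recall
/ F1 with macro averages, overall accuracy, and one-vs-rest ROC curves
with trapezoidal AUC and macro AUC.

## Worked example

Generate a small synthetic 4-class dataset, train a compact
configuration, and inspect one prediction:

```bash
wfpn generate-data --out demo-data --per-class 25 --size 64 --seed 3
# -> wrote 100 images under demo-data

cat > demo.yaml <<EOF
backbone: tiny        # compact trunk for a quick run; default is resnext50_32x4d
channels: 32
hidden: 32
image_size: 64
epochs: 12
batch_size: 16
learning_rate: 0.002
seed: 3
EOF

wfpn train --data demo-data --config demo.yaml --out-dir demo-run
# -> {"best_accuracy": 1.0, "final_val_accuracy": 0.95,
#     "macro_f1": 0.9494949494949495, "macro_auc": 0.9166666666666666}
```

The run takes a few seconds on one CPU. `best_accuracy` is the best
validation accuracy seen during training (1.0 here: the 20-image
validation split was classified perfectly at some epoch);
`final_val_accuracy`, `macro_f1` and `macro_auc` describe the final
model on the validation split — 19/20 images correct, with the macro
averages taken unweighted over the four stages. `demo-run/` now holds
the config, per-epoch training log, best/last checkpoints, and under
`eval/` the prediction CSV, metric JSON, confusion matrices and ROC
point files.

```bash
wfpn predict --checkpoint demo-run/checkpoint_best.npz demo-data/stage3/img_0000.png
# -> [{"path": "demo-data/stage3/img_0000.png",
#      "predicted_stage": "stage3",
#      "scores": {"stage1": 0.302, "stage2": -1.136,
#                 "stage3": 0.977, "stage4": -1.001}}]
```

The scores are raw ensemble logits; the argmax (stage 3) is the
predicted label. `wfpn stats DIR` prints the per-channel mean/std of a
folder tree, for recomputing normalisation constants on new data.

## Layout

| module | role |
| --- | --- |
| `wfpn.nn` | NumPy autodiff engine, layers, AdamW + cosine annealing |
| `wfpn.backbone` | trunk adapters (`resnext50_32x4d`, `tiny`) and the hierarchy contract |
| `wfpn.neck` | fast-normalised fusion nodes, top-down/bottom-up pathways |
| `wfpn.attention` | CBAM channel + spatial attention |
| `wfpn.heads` | per-level classifiers and the weighted ensemble |
| `wfpn.metrics` | confusion matrix, P/R/F1, ROC/AUC, writers and plots |
| `wfpn.pipeline` | config, stratified split, training loop, evaluation driver |
| `wfpn.synthetic` | deterministic 4-class lesion-image generator |
| `wfpn.cli` | `wfpn` command-line entry point |

See `docs/methods.md` for the modelling choices, defaults and known
limitations.
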