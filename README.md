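# surgflow

Semi-supervised multimodal learning for **online recognition of surgical
workflow at multiple granularities** (phase ⊃ step ⊃ gesture) from
synchronized video and bimanual robot kinematics.

Annotating surgical recordings frame by frame is expensive, and most
recognition models need those labels for everything they learn. This
package takes a different route: the representation is learned **without
any labels**, and only small per-granularity classifiers consume
annotations — so a fraction of labeled demonstrations goes a long way.

The pipeline has three independently trained stages:

1. **Time-contrastive encoder.** Frames of the same demonstration are
   embedded so that temporal neighbors (within a positive range $r_p$) end
   up closer than distant frames (beyond a margin range $r_m$), via the
   triplet loss
   $\big[\lVert b_{t_a}-b_{t_p}\rVert_2^2-\lVert b_{t_a}-b_{t_n}\rVert_2^2+\alpha\big]_+$
   on L2-normalized projections $b$. The pre-projection features $v$ carry
   the learned spatiotemporal structure downstream.
2. **Multimodal VAE with product-of-experts fusion.** Per-modality Gaussian
   encoders for $v$ and the left/right arm kinematics are fused into a
   shared latent $z$ by multiplying the expert posteriors with a standard
   normal prior expert — precisions add, so each added modality sharpens
   the posterior. The loss combines per-modality ELBOs with a joint ELBO
   ($\beta$-weighted KLs, $\lambda_m$-weighted reconstructions).
3. **Online LSTM classifiers**, one per granularity, mapping $z_{1:t}$ to
   $p(y^g_t \mid z_{1:t})$ — strictly causal, suitable for intraoperative
   use.

Evaluation uses the field's standard metrics: frame-wise accuracy, the
segmental **edit score** (100-scaled complement of the normalized
Levenshtein distance between run-length-encoded label sequences), and
balanced **AD-accuracy** (macro recall with a 500 ms transition-delay
tolerance), under leave-one-user-out (LOUO) or leave-one-supertrial-out
(LOSO) cross-validation.

Because the public surgical datasets (JIGSAWS, MISAW) cannot be bundled,
the package ships a **synthetic benchmark generator**: a semi-Markov
phase→step→gesture state machine emitting spring-pull kinematics and
drifting visual features, with deliberately *complementary* modalities (one
gesture pair distinguishable only kinematically, another only visually) and
per-user skill variation. Every stage and experiment is testable end to end
against known ground truth.

## Worked example

```python
import surgflow as sf

cfg = sf.desk_config(seed=1)
cfg.max_folds = 1                      # evaluate the first LOUO fold only
report = sf.run_pipeline(cfg)

for g, agg in report["aggregate"].items():
    print(f"{g:8s} acc {agg['accuracy']['mean']:5.1f}   "
          f"edit {agg['edit_score']['mean']:5.1f}   "
          f"ad-acc {agg['ad_accuracy']['mean']:5.1f}")
```

prints (about a minute on one CPU core):

```
phase    acc  99.2   edit 100.0   ad-acc 100.0
step     acc 100.0   edit 100.0   ad-acc 100.0
gesture  acc  97.7   edit 100.0   ad-acc 100.0
```

Reading the numbers: the held-out user's demonstrations are recognized at
~98% of frames at the finest (gesture) level; an edit score of 100 means
the predicted *sequence* of segments matches the true workflow exactly (no
spurious or misordered segments); AD-accuracy of 100 means every residual
frame error lies within 500 ms of a true gesture boundary.

The same objects expose each stage individually — for example:

```python
from surgflow import MultimodalVAE, MVAEConfig
mvae = MultimodalVAE(train_demos, MVAEConfig(z_dim=32))
results = mvae.fit(seed=0)
print(results.summary())
z = results.infer_z(demo, modalities=("kin_left", "kin_right"))  # subset inference
```

There is also a CLI (`surgflow synth | run-all | ablate | label-sweep |
evaluate`) wrapping the same functions.

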