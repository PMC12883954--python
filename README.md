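# fatnet

Forecasting next-day wellbeing in older adults from wearable
heart-rate streams and music-listening behaviour.

`fatnet` implements a complete study harness around **FAT-Net**
(Fusion-Attentive Temporal Network), a dual-stream regressor that
fuses minute-resolution physiological/behavioural streams with daily
summary features to predict the next day's composite Health Score. It
is aimed at digital-health researchers who want a fully testable,
deposit-free reference implementation: every stage — cohort
simulation, QC, score construction, augmentation, model, baselines,
evaluation — is a library module with its own tests, and a synthetic
cohort generator with planted, analytically known structure stands in
for the (undeposited) real cohort.

## The model

Each participant-day *i* is represented by a minute-level stream
X<sub>i</sub><sup>TS</sup> ∈ ℝ<sup>T×2</sup> (heart rate, music
on/off) and a daily summary vector x<sub>i</sub><sup>DS</sup> ∈
ℝ<sup>d<sub>ds</sub></sup>. The temporal stream is encoded by three
Conv1D layers (32→64→128, kernels 5/3/3; LayerNorm + GELU + dropout
0.1), a BiLSTM (h/2 per direction) and multi-head self-attention with
mean pooling:

    H⁽⁰⁾ = Conv1D_stack(Xᵀˢ),  Hᵀˢ = BiLSTM(H⁽⁰⁾) ∈ ℝ^{T×h}
    U = MHAttn(Hᵀˢ),           vᵀˢ = (1/T) Σₜ U[t]

The summary stream is an MLP d_ds→64→128→h (BatchNorm + ReLU +
dropout 0.2). Cross-modal attention lets per-feature summary tokens
attend over U (giving a d_ds×T interpretability map) and the pooled
temporal vector attend over the tokens; the fused 2h vector passes a
512→512→2h feed-forward block and a 2h→256→1 head to produce
ŷ<sub>i+1</sub>. Training minimizes

    L(θ) = (1/N) Σ (ŷ_{i+1} − y_{i+1})² + λ‖θ‖²,  λ = 10⁻⁵

with AdamW (lr 3·10⁻⁴, batch 16) and early stopping on validation
MAE. The target is a composite Health Score: the equal-weight mean of
cohort-standardized PANAS positive affect, sleep efficiency and RMSSD
(a PCA-weighted variant is provided), validated by Cronbach's α,
PC1 variance share, distributional checks and responsiveness against
self-reported ratings.

The whole neural stack (autodiff, Conv1D, LSTM, attention, AdamW)
is implemented in numpy inside `fatnet.nn` and gradient-checked
against finite differences — no deep-learning framework is required.

## Worked example

```python
from fatnet.cohort import GeneratorConfig, generate_cohort
from fatnet.benchmark import prepare_run, compute_metrics
from fatnet.baselines import fit_tabular_baseline
from fatnet.model import FATNet, FatNetConfig

cohort = generate_cohort(GeneratorConfig(
    n_participants=48, days_mean=30, days_sd=6, T=96, seed=101))
train, val, test = prepare_run(cohort, seed=0)

fat = FATNet(train, val, FatNetConfig(
    T=train.T, d_ds=train.d_ds, h=32, batch_size=48, lr=1.2e-3,
    max_epochs=28, patience=6, min_epochs=14)).fit(seed=0)
print(fat.summary())

rf = fit_tabular_baseline("rf", train, seed=0)
print("FAT-Net:", compute_metrics(fat.predict(test), test.y))
print("RF     :", compute_metrics(rf.predict(test), test.y))
```

prints (numbers from this exact script on one CPU; a few minutes):

```
FAT-Net results
==============================================
temporal input        T=96 x d_ts=2
summary input         d_ds=19
embedding width h     32 (4 heads)
parameters            423,393
epochs run            19 (best 12)
best val MAE          0.5278
optimizer             AdamW lr=0.0012 wd=1e-05
batch size            48, patience 6
FAT-Net: {'rmse': 0.7179, 'mae': 0.5581, 'r2': 0.2237, 'pearson_r': 0.4898}
RF     : {'rmse': 0.7796, 'mae': 0.6044, 'r2': 0.0845, 'pearson_r': 0.3474}
```

The cohort plants a minute-level music→heart-rate interaction (brief
relaxation dips during high-tempo listening) that drives part of the
next day's latent wellness but is largely invisible to the daily
summary table; the fusion model's RMSE advantage over the Random
Forest baseline (≈8% on this particular split; several seeded runs
are averaged in the full protocol, where the margin varies by split)
measures how much of that planted minute-level signal it recovers.
An attention map for any test sample is one call away:
`fat.extract_attention(test, 0)`.

A command-line interface mirrors the pipeline:

```bash
fatnet generate --out data/ --seed 1
fatnet preprocess --in data/ --out refined/
fatnet score --in refined/ --out scores/
fatnet train --data data/ --out model.ckpt --seed 1
fatnet evaluate --data data/ --out report/ --runs 10
fatnet attn-export --model model.ckpt --data data/ --sample 0 --out attn/
```

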