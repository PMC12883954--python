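"""FAT-Net: dual-stream fusion-attentive temporal network.

Temporal stream: three Conv1D layers (filters 32→64→128, kernels
5/3/3, stride 1, same padding), each followed by LayerNorm, GELU and
dropout 0.1, then a BiLSTM with h/2 units per direction and multi-head
self-attention pooling (mean over time of the attended sequence).
Summary stream: a three-layer MLP (d_ds→64→128→h) with BatchNorm,
ReLU and dropout 0.2 after each layer.  Cross-modal fusion attends
per-feature summary tokens over the attended temporal sequence and the
pooled temporal vector over the summary tokens, concatenates with
residuals to a 2h vector, refines it with a feed-forward block and
predicts the next-day composite Health Score through a 2h→256→1 head
(linear output so negative z-scored targets are reachable).

Training minimizes mean squared error with decoupled weight decay
(AdamW) and early stopping on validation MAE; the reported objective
additionally evaluates the explicit penalized loss ``MSE + λ‖θ‖²``
for logging.

The module follows a statsmodels-like surface: ``FATNet(train, val,
config).fit()`` returns a :class:`FATNetResults` carrying the trained
parameters, history, predictions and attention maps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .datasets import SampleSet

__all__ = ["FatNetConfig", "FATNet", "FATNetResults", "FATNetModule",
           "AttentionMaps", "penalized_loss"]


@dataclass(frozen=True)
class FatNetConfig:
    """Architecture and optimization hyperparameters."""

    T: int = 240
    d_ts: int = 2
    d_ds: int = 19
    h: int = 64
    conv_filters: tuple = (32, 64, 128)
    conv_kernels: tuple = (5, 3, 3)
    conv_dropout: float = 0.1
    mlp_dims: tuple = (64, 128)
    mlp_dropout: float = 0.2
    n_heads: int = 4
    ffn_dims: tuple = (512, 512)
    head_dim: int = 256
    head_dropout: float = 0.2
    weight_decay: float = 1e-5
    lr: float = 3e-4
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    min_epochs: int = 0     # early stopping may not trigger before this epoch
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.h % 2 != 0:
            raise ValueError("h must be even (BiLSTM halves it per direction)")
        if self.h % self.n_heads != 0:
            raise ValueError("n_heads must divide h")
        dims = (self.T, self.d_ts, self.d_ds, self.h, self.head_dim,
                *self.conv_filters, *self.conv_kernels, *self.mlp_dims,
                *self.ffn_dims, self.batch_size, self.max_epochs, self.patience)
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ValueError("conv_filters and conv_kernels must align")
        if self.T < max(self.conv_kernels):
            raise ValueError("T is smaller than the largest conv kernel")
        for name in ("conv_dropout", "mlp_dropout", "head_dropout"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("lr must be > 0 and weight_decay >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AttentionMaps:
    """Attention weights for one sample (rows sum to 1).

    ``self_attention``: (n_heads, T, T) query-step × key-step weights.
    ``cross_attention``: (d_ds, T) summary-feature queries over time
    steps (head-averaged).  ``summary_attention``: (d_ds,) weights of
    the pooled temporal query over summary tokens (head-averaged).
    """

    self_attention: np.ndarray
    cross_attention: np.ndarray
    summary_attention: np.ndarray
    feature_names: list = field(default_factory=list)

    def export(self, directory, sample_id="sample") -> None:
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        T = self.self_attention.shape[-1]
        minutes = [f"min{t}" for t in range(T)]
        pd.DataFrame(self.self_attention.mean(axis=0), index=minutes,
                     columns=minutes).to_csv(directory / f"self_attn_{sample_id}.csv")
        rows = self.feature_names or [f"f{i}" for i in range(len(self.cross_attention))]
        pd.DataFrame(self.cross_attention, index=rows, columns=minutes) \
            .to_csv(directory / f"cross_attn_{sample_id}.csv")


class FATNetModule(nn.Module):
    """The dual-stream network (autodiff graph builder)."""

    def __init__(self, cfg: FatNetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.rng_ref = nn.RNGRef(rng)
        h = cfg.h

        self.convs, self.conv_norms, self.conv_drops = [], [], []
        c_in = cfg.d_ts
        for c_out, k in zip(cfg.conv_filters, cfg.conv_kernels):
            self.convs.append(nn.Conv1d(c_in, c_out, k, rng))
            self.conv_norms.append(nn.LayerNorm(c_out))
            self.conv_drops.append(nn.Dropout(cfg.conv_dropout, self.rng_ref))
            c_in = c_out
        self.bilstm = nn.BiLSTM(c_in, h, rng)
        self.self_attn = nn.MultiHeadAttention(h, cfg.n_heads, rng)

        self.mlp_layers, self.mlp_norms, self.mlp_drops = [], [], []
        d_in = cfg.d_ds
        for d_out in (*cfg.mlp_dims, h):
            self.mlp_layers.append(nn.Linear(d_in, d_out, rng))
            self.mlp_norms.append(nn.BatchNorm1d(d_out))
            self.mlp_drops.append(nn.Dropout(cfg.mlp_dropout, self.rng_ref))
            d_in = d_out

        # per-feature token embedding for cross-attention queries
        self.token_embed = nn.Tensor(
            (rng.standard_normal((cfg.d_ds, h)) / np.sqrt(h)).astype(nn.DTYPE),
            requires_grad=True)
        self.cross_ts2ds = nn.MultiHeadAttention(h, cfg.n_heads, rng)
        self.cross_ds2ts = nn.MultiHeadAttention(h, cfg.n_heads, rng)

        self.ffn = []
        d_in = 2 * h
        for d_out in (*cfg.ffn_dims, 2 * h):
            self.ffn.append(nn.Linear(d_in, d_out, rng))
            d_in = d_out

        self.head1 = nn.Linear(2 * h, cfg.head_dim, rng)
        self.head_drop = nn.Dropout(cfg.head_dropout, self.rng_ref)
        self.head2 = nn.Linear(cfg.head_dim, 1, rng)

    # exposed stages (each usable standalone, e.g. in tests) ------------

    def conv_stack(self, x: nn.Tensor) -> nn.Tensor:
        for conv, norm, drop in zip(self.convs, self.conv_norms, self.conv_drops):
            x = drop(nn.gelu(norm(conv(x))))
        return x

    def temporal_encode(self, h0: nn.Tensor) -> nn.Tensor:
        return self.bilstm(h0)

    def self_attention_pool(self, h_ts: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        u = self.self_attn(h_ts, h_ts, h_ts)
        return u.mean(axis=1), u

    def summary_encode(self, x_ds: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        v = x_ds
        for lin, norm, drop in zip(self.mlp_layers, self.mlp_norms, self.mlp_drops):
            v = drop(norm(lin(v)).relu())
        B, d_ds = x_ds.shape
        tokens = x_ds.reshape(B, d_ds, 1) * self.token_embed
        return v, tokens

    def cross_modal_fuse(self, v_ts: nn.Tensor, v_ds: nn.Tensor,
                         u: nn.Tensor, tokens: nn.Tensor) -> nn.Tensor:
        B = v_ts.shape[0]
        ctx_a = self.cross_ts2ds(tokens, u, u).mean(axis=1)     # (B, h)
        ctx_b = self.cross_ds2ts(v_ts.reshape(B, 1, -1), tokens, tokens) \
            .reshape(B, -1)                                      # (B, h)
        f = nn.concat([v_ts + ctx_b, v_ds + ctx_a], axis=-1)
        for i, lin in enumerate(self.ffn):
            f = lin(f)
            if i < len(self.ffn) - 1:
                f = f.relu()
        return f

    def predict_head(self, f: nn.Tensor) -> nn.Tensor:
        return self.head2(self.head_drop(self.head1(f).relu())).reshape(-1)

    def forward(self, X_ts: np.ndarray, X_ds: np.ndarray) -> nn.Tensor:
        x_ts = nn.Tensor(np.ascontiguousarray(X_ts, dtype=nn.DTYPE))
        x_ds = nn.Tensor(np.ascontiguousarray(X_ds, dtype=nn.DTYPE))
        h0 = self.conv_stack(x_ts)
        h_ts = self.temporal_encode(h0)
        v_ts, u = self.self_attention_pool(h_ts)
        v_ds, tokens = self.summary_encode(x_ds)
        f = self.cross_modal_fuse(v_ts, v_ds, u, tokens)
        return self.predict_head(f)

    __call__ = forward

    def attention_maps(self, feature_names=None) -> AttentionMaps:
        """Maps recorded by the most recent forward pass (first sample)."""
        return AttentionMaps(
            self_attention=self.self_attn.last_weights[0],
            cross_attention=self.cross_ts2ds.last_weights[0].mean(axis=0),
            summary_attention=self.cross_ds2ts.last_weights[0].mean(axis=0)[0],
            feature_names=list(feature_names or []),
        )


def penalized_loss(y_hat: np.ndarray, y: np.ndarray,
                   params: list | None = None, lam: float = 0.0) -> float:
    """Explicit objective: mean squared error + λ‖θ‖²."""
    y_hat = np.asarray(y_hat, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(y_hat) != len(y):
        raise ValueError("prediction/target length mismatch")
    if len(y) == 0:
        raise ValueError("empty batch")
    mse = float(np.mean((y_hat - y) ** 2))
    if params and lam:
        mse += lam * float(sum((p.data.astype(np.float64) ** 2).sum() for p in params))
    return mse


class FATNet:
    """Model object bound to training and validation sample sets."""

    def __init__(self, train: SampleSet, val: SampleSet,
                 config: FatNetConfig | None = None):
        if len(train) == 0 or len(val) == 0:
            raise ValueError("train and validation sets must be non-empty")
        if config is None:
            config = FatNetConfig(T=train.T, d_ds=train.d_ds)
        if config.T != train.T or config.d_ds != train.d_ds:
            config = dataclasses.replace(config, T=train.T, d_ds=train.d_ds)
        shared = set(np.unique(train.participant_id)) & set(np.unique(val.participant_id))
        shared = {p for p in shared if not str(p).startswith("synth-")}
        if shared:
            raise ValueError(f"participants span train and val: {sorted(shared)[:3]}")
        self.train_set = train
        self.val_set = val
        self.config = config

    def fit(self, seed: int | None = None, verbose: bool = False) -> "FATNetResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA7]))
        module = FATNetModule(cfg, rng)
        return _fit_loop(module, self.train_set, self.val_set, cfg, rng,
                         results_cls=FATNetResults, verbose=verbose)


def _fit_loop(module, train, val, cfg, rng, results_cls, verbose=False,
              forward=None):
    """Shared mini-batch AdamW loop with early stopping on val MAE."""
    fwd = forward or (lambda m, s, idx: m(s.X_ts[idx], s.X_ds[idx]))
    params = module.parameters()
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(train)
    history = []
    best = (np.inf, -1, None)  # (val MAE, epoch, state)
    for epoch in range(cfg.max_epochs):
        module.train()
        order = rng.permutation(n)
        sq_sum, seen = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            y = train.y[idx].astype(nn.DTYPE)
            y_hat = fwd(module, train, idx)
            err = y_hat - nn.Tensor(y)
            loss = (err * err).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}")
            opt.zero_grad()
            loss.backward()
            _clip_grads(params, cfg.grad_clip)
            opt.step()
            sq_sum += float(loss.data) * len(idx)
            seen += len(idx)
        train_mse = sq_sum / seen
        val_pred = _predict(module, val, cfg.batch_size * 8, fwd)
        val_mae = float(np.mean(np.abs(val_pred - val.y)))
        objective = train_mse + cfg.weight_decay * float(
            sum((p.data.astype(np.float64) ** 2).sum() for p in params))
        history.append({"epoch": epoch, "train_mse": train_mse,
                        "train_objective": objective, "val_mae": val_mae})
        if verbose:
            print(f"epoch {epoch:3d}  train_mse {train_mse:.4f}  val_mae {val_mae:.4f}")
        if val_mae < best[0]:
            best = (val_mae, epoch, module.state_dict())
        elif (epoch - best[1] >= cfg.patience
              and epoch + 1 >= getattr(cfg, "min_epochs", 0)):
            break
    if best[2] is not None:
        module.load_state_dict(best[2])
    module.eval()
    return results_cls(module=module, config=cfg,
                       history=pd.DataFrame(history), best_epoch=best[1],
                       val_mae=best[0],
                       feature_names=list(getattr(train, "feature_names", [])))


def _clip_grads(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale  # out of place: grads may be borrowed views


def _predict(module, samples, batch_size, fwd) -> np.ndarray:
    module.eval()
    out = np.empty(len(samples))
    for lo in range(0, len(samples), batch_size):
        idx = np.arange(lo, min(lo + batch_size, len(samples)))
        out[idx] = fwd(module, samples, idx).data.astype(np.float64)
    module.train()
    return out


@dataclass
class FATNetResults:
    """Trained-model results: parameters, history and diagnostics."""

    module: FATNetModule
    config: FatNetConfig
    history: pd.DataFrame
    best_epoch: int
    val_mae: float
    feature_names: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    def predict(self, samples: SampleSet, batch_size: int | None = None) -> np.ndarray:
        self.module.eval()
        bs = batch_size or self.config.batch_size * 8
        return _predict(self.module, samples, bs,
                        lambda m, s, idx: m(s.X_ts[idx], s.X_ds[idx]))

    def extract_attention(self, samples: SampleSet, index: int = 0) -> AttentionMaps:
        """Eval-mode attention maps for a single sample."""
        self.module.eval()
        self.module(samples.X_ts[index:index + 1], samples.X_ds[index:index + 1])
        return self.module.attention_maps(self.feature_names)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "FAT-Net results",
            "=" * 46,
            f"temporal input        T={cfg.T} x d_ts={cfg.d_ts}",
            f"summary input         d_ds={cfg.d_ds}",
            f"embedding width h     {cfg.h} ({cfg.n_heads} heads)",
            f"parameters            {self.module.n_parameters():,}",
            f"epochs run            {self.n_epochs} (best {self.best_epoch})",
            f"best val MAE          {self.val_mae:.4f}",
            f"optimizer             AdamW lr={cfg.lr} wd={cfg.weight_decay}",
            f"batch size            {cfg.batch_size}, patience {cfg.patience}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_mse"], label="train MSE")
        ax.plot(self.history["epoch"], self.history["val_mae"], label="val MAE")
        ax.axvline(self.best_epoch, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("epoch")
        ax.legend()
        return ax

    def save(self, path) -> None:
        """Single-file checkpoint: config + history JSON and parameter blob."""
        arrays = {f"p{i}": a for i, a in enumerate(self.module.state_dict())}
        meta = json.dumps({
            "config": self.config.to_dict(),
            "best_epoch": int(self.best_epoch),
            "val_mae": float(self.val_mae),
            "feature_names": list(self.feature_names),
            "history": self.history.to_dict(orient="list"),
        })
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                     **arrays)

    @classmethod
    def load(cls, path) -> "FATNetResults":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg = FatNetConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in meta["config"].items()})
            module = FATNetModule(cfg, np.random.default_rng(0))
            module.load_state_dict([z[f"p{i}"] for i in range(len(z.files) - 1)])
        module.eval()
        return cls(module=module, config=cfg,
                   history=pd.DataFrame(meta["history"]),
                   best_epoch=meta["best_epoch"], val_mae=meta["val_mae"],
                   feature_names=meta["feature_names"])
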