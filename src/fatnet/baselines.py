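"""Baseline regressors: Random Forest, XGBoost, LSTM and TCN.

Tabular baselines see the standardized daily features plus coarse
temporal aggregates (mean/sd heart rate, total music minutes); the
sequence baselines consume the minute stream with the daily summary
vector concatenated at the regression head.  All four share the
training contract of FAT-Net where applicable (AdamW, early stopping
on validation MAE) and return results objects with a ``predict``
method, mirroring the statsmodels-style model/results split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

from . import nn
from .datasets import SampleSet
from .model import _fit_loop, _predict

__all__ = ["BaselineConfig", "fit_tabular_baseline", "fit_sequence_baseline",
           "TabularResults", "SequenceResults", "tabular_features",
           "LSTMRegressorModule", "TCNModule"]


@dataclass(frozen=True)
class BaselineConfig:
    """Hyperparameters of the four baselines."""

    rf_estimators: int = 100
    rf_max_depth: int = 10
    xgb_trees: int = 100
    xgb_max_depth: int = 6
    xgb_lr: float = 0.1
    h: int = 64                       # LSTM hidden size
    tcn_channels: tuple = (32, 64, 128)
    tcn_kernel: int = 3
    lr: float = 3e-4
    weight_decay: float = 1e-5
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    min_epochs: int = 0
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if min(self.rf_estimators, self.rf_max_depth, self.xgb_trees,
               self.xgb_max_depth, self.h, self.tcn_kernel) <= 0:
            raise ValueError("counts/depths must be positive")
        if not (0.0 < self.xgb_lr <= 1.0):
            raise ValueError("xgb_lr must lie in (0, 1]")


def tabular_features(samples: SampleSet) -> np.ndarray:
    """Daily features + coarse raw-stream aggregates for tree models."""
    return np.column_stack([samples.X_ds, samples.ts_aggregates])


@dataclass
class TabularResults:
    kind: str
    model: object
    config: BaselineConfig

    def predict(self, samples: SampleSet) -> np.ndarray:
        return np.asarray(self.model.predict(tabular_features(samples)),
                          dtype=float)

    def summary(self) -> str:
        return f"{self.kind} baseline ({self.model.get_params()})"


def fit_tabular_baseline(kind: str, train: SampleSet,
                         config: BaselineConfig | None = None,
                         seed: int | None = None) -> TabularResults:
    """Fit Random Forest or XGBoost on day-level features."""
    config = config or BaselineConfig()
    seed = config.seed if seed is None else seed
    if len(train) == 0:
        raise ValueError("empty training set")
    X, y = tabular_features(train), train.y
    if kind in ("rf", "random_forest"):
        model = RandomForestRegressor(n_estimators=config.rf_estimators,
                                      max_depth=config.rf_max_depth,
                                      random_state=seed, n_jobs=1)
    elif kind in ("xgb", "xgboost"):
        model = XGBRegressor(n_estimators=config.xgb_trees,
                             max_depth=config.xgb_max_depth,
                             learning_rate=config.xgb_lr,
                             random_state=seed, n_jobs=1,
                             verbosity=0)
    else:
        raise ValueError(f"unknown tabular baseline kind {kind!r}")
    model.fit(X, y)
    return TabularResults(kind=kind, model=model, config=config)


class LSTMRegressorModule(nn.Module):
    """Single-stream recurrent regressor (hidden h) + summary head."""

    def __init__(self, d_ts: int, d_ds: int, h: int, rng: np.random.Generator):
        super().__init__()
        self.lstm = nn.LSTM(d_ts, h, rng)
        self.head1 = nn.Linear(h + d_ds, 64, rng)
        self.head2 = nn.Linear(64, 1, rng)

    def __call__(self, X_ts, X_ds) -> nn.Tensor:
        x_ts = nn.Tensor(np.ascontiguousarray(X_ts, dtype=nn.DTYPE))
        x_ds = nn.Tensor(np.ascontiguousarray(X_ds, dtype=nn.DTYPE))
        seq = self.lstm(x_ts).mean(axis=1)
        z = nn.concat([seq, x_ds], axis=-1)
        return self.head2(self.head1(z).relu()).reshape(-1)


class TCNModule(nn.Module):
    """Dilated causal convolution regressor + summary head.

    Dilations double per layer (channels mirror the Conv1D stack, the
    last width repeating) until the receptive field covers T.
    """

    def __init__(self, d_ts: int, d_ds: int, T: int, channels: tuple,
                 kernel: int, rng: np.random.Generator):
        super().__init__()
        self.convs = []
        c_in, dilation, rf = d_ts, 1, 1
        i = 0
        while rf < T:
            c_out = channels[min(i, len(channels) - 1)]
            self.convs.append(nn.Conv1d(c_in, c_out, kernel, rng,
                                        dilation=dilation, causal=True))
            rf += (kernel - 1) * dilation
            c_in, dilation, i = c_out, dilation * 2, i + 1
        self.receptive_field = rf
        self.head1 = nn.Linear(c_in + d_ds, 64, rng)
        self.head2 = nn.Linear(64, 1, rng)

    def __call__(self, X_ts, X_ds) -> nn.Tensor:
        x = nn.Tensor(np.ascontiguousarray(X_ts, dtype=nn.DTYPE))
        x_ds = nn.Tensor(np.ascontiguousarray(X_ds, dtype=nn.DTYPE))
        for conv in self.convs:
            x = conv(x).relu()
        z = nn.concat([x.mean(axis=1), x_ds], axis=-1)
        return self.head2(self.head1(z).relu()).reshape(-1)


@dataclass
class SequenceResults:
    """Results of a trained sequence baseline (LSTM or TCN)."""

    module: nn.Module
    config: BaselineConfig
    history: pd.DataFrame
    best_epoch: int
    val_mae: float
    feature_names: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    def predict(self, samples: SampleSet, batch_size: int | None = None) -> np.ndarray:
        bs = batch_size or self.config.batch_size * 8
        out = _predict(self.module, samples, bs,
                       lambda m, s, idx: m(s.X_ts[idx], s.X_ds[idx]))
        self.module.eval()
        return out

    def summary(self) -> str:
        return (f"{type(self.module).__name__}: {self.module.n_parameters():,} "
                f"params, best val MAE {self.val_mae:.4f} "
                f"at epoch {self.best_epoch}/{self.n_epochs}")


def fit_sequence_baseline(kind: str, train: SampleSet, val: SampleSet,
                          config: BaselineConfig | None = None,
                          seed: int | None = None) -> SequenceResults:
    """Train the LSTM or TCN baseline under the shared loop contract."""
    config = config or BaselineConfig()
    seed = config.seed if seed is None else seed
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA5E]))
    d_ts, d_ds = train.X_ts.shape[2], train.d_ds
    if kind == "lstm":
        module = LSTMRegressorModule(d_ts, d_ds, config.h, rng)
    elif kind == "tcn":
        module = TCNModule(d_ts, d_ds, train.T, config.tcn_channels,
                           config.tcn_kernel, rng)
    else:
        raise ValueError(f"unknown sequence baseline kind {kind!r}")
    return _fit_loop(module, train, val, config, rng,
                     results_cls=SequenceResults)
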