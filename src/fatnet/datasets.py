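"""Supervised sample assembly: (day-i inputs → day-(i+1) score) pairs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .preprocessing import CONTINUOUS_DAILY, Standardizer

__all__ = ["SampleSet", "build_samples", "FeatureScaler", "BINARY_DAILY"]

#: Binary / categorical day-level features (passed through unscaled).
BINARY_DAILY = ["gender_female", "hypertension", "diabetes"]


@dataclass
class SampleSet:
    """A batch of participant-day samples for next-day prediction.

    ``X_ts`` is (N, T, 2) with channels (heart rate bpm, music on/off);
    ``X_ds`` is (N, d_ds); ``y`` the next-day composite score.
    """

    X_ts: np.ndarray
    X_ds: np.ndarray
    y: np.ndarray
    participant_id: np.ndarray
    day_index: np.ndarray
    feature_names: list[str]
    split: str = "unspecified"
    provenance: np.ndarray = field(default=None)
    #: coarse raw-stream aggregates (mean HR, sd HR, music minutes) for
    #: the tabular baselines; computed before any stream normalization
    ts_aggregates: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.provenance is None:
            self.provenance = np.array(["original"] * len(self.y), dtype=object)
        if self.ts_aggregates is None:
            hr, mus = self.X_ts[:, :, 0], self.X_ts[:, :, 1]
            self.ts_aggregates = np.column_stack(
                [hr.mean(axis=1), hr.std(axis=1), mus.sum(axis=1)])

    def __len__(self) -> int:
        return len(self.y)

    @property
    def T(self) -> int:
        return self.X_ts.shape[1]

    @property
    def d_ds(self) -> int:
        return self.X_ds.shape[1]

    def subset(self, idx) -> "SampleSet":
        return SampleSet(self.X_ts[idx], self.X_ds[idx], self.y[idx],
                         self.participant_id[idx], self.day_index[idx],
                         list(self.feature_names), self.split,
                         self.provenance[idx], self.ts_aggregates[idx])

    def with_split(self, split: str) -> "SampleSet":
        return replace(self, split=split)

    @staticmethod
    def concatenate(parts: list["SampleSet"]) -> "SampleSet":
        first = parts[0]
        return SampleSet(
            np.concatenate([p.X_ts for p in parts]),
            np.concatenate([p.X_ds for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.participant_id for p in parts]),
            np.concatenate([p.day_index for p in parts]),
            list(first.feature_names), first.split,
            np.concatenate([p.provenance for p in parts]),
            np.concatenate([p.ts_aggregates for p in parts]),
        )


def build_samples(dataset: CohortDataset, engineered: pd.DataFrame,
                  scores: pd.DataFrame) -> SampleSet:
    """Pair each day's inputs with the following day's score.

    Only consecutive days of the same participant are paired (day i →
    day i+1); each participant's last day never serves as input and the
    first day never as target.  Gaps from QC-dropped days simply
    produce no pair.
    """
    eng = engineered.copy()
    if "gender_female" not in eng.columns:
        eng["gender_female"] = (eng["gender"] == "F").astype(float)
    feature_names = CONTINUOUS_DAILY + BINARY_DAILY

    score_map = scores.set_index(["participant_id", "day_index"])["equal_weight"] \
        if "equal_weight" in scores.columns else scores
    target_col = "target_score"
    eng = eng.sort_values(["participant_id", "day_index"]).reset_index(drop=True)
    key_next = pd.MultiIndex.from_arrays(
        [eng["participant_id"], eng["day_index"] + 1])
    eng[target_col] = score_map.reindex(key_next).to_numpy()
    eng = eng.dropna(subset=[target_col])

    T = dataset.config.T
    minutes = dataset.minutes
    hr = minutes["hr_bpm"].to_numpy()
    mus = minutes["music_on"].to_numpy()
    mkey = pd.MultiIndex.from_frame(minutes[["participant_id", "day_index"]])
    # minute rows are contiguous per day in generation order
    starts = pd.Series(np.arange(len(minutes)), index=mkey) \
               .groupby(level=[0, 1], sort=False).first()

    N = len(eng)
    X_ts = np.empty((N, T, 2), dtype=np.float64)
    for row, (pid, day) in enumerate(zip(eng["participant_id"], eng["day_index"])):
        s = starts.loc[(pid, day)]
        X_ts[row, :, 0] = hr[s:s + T]
        X_ts[row, :, 1] = mus[s:s + T]
    X_ds = eng[feature_names].to_numpy(dtype=np.float64)
    return SampleSet(
        X_ts=X_ts, X_ds=X_ds, y=eng[target_col].to_numpy(dtype=np.float64),
        participant_id=eng["participant_id"].to_numpy(),
        day_index=eng["day_index"].to_numpy(),
        feature_names=feature_names,
    )


class FeatureScaler:
    """Scales a SampleSet with statistics fitted on the training split.

    Daily continuous features are z-scored via :class:`Standardizer`
    (training-split statistics, never refit downstream).  The
    heart-rate channel is z-scored *within each day* — each day's
    minutes are centered and scaled by that day's own mean/sd, which
    removes inter-individual baseline offsets, requires no fitted
    statistics, and is computable at inference time without leakage.
    The raw-stream aggregates kept on ``ts_aggregates`` are untouched.
    """

    def __init__(self):
        self.daily = Standardizer()
        self.fitted = False

    def fit(self, train: SampleSet) -> "FeatureScaler":
        cont_idx = [train.feature_names.index(c) for c in CONTINUOUS_DAILY]
        table = pd.DataFrame(train.X_ds[:, cont_idx], columns=CONTINUOUS_DAILY)
        self.daily.fit(table, CONTINUOUS_DAILY, provenance=f"split:{train.split}")
        self.fitted = True
        return self

    def transform(self, samples: SampleSet) -> SampleSet:
        if not self.fitted:
            raise RuntimeError("FeatureScaler.transform called before fit")
        cont_idx = [samples.feature_names.index(c) for c in CONTINUOUS_DAILY]
        table = pd.DataFrame(samples.X_ds[:, cont_idx], columns=CONTINUOUS_DAILY)
        X_ds = samples.X_ds.copy()
        X_ds[:, cont_idx] = self.daily.transform(table).to_numpy()
        X_ts = samples.X_ts.copy()
        hr = X_ts[:, :, 0]
        mu = hr.mean(axis=1, keepdims=True)
        sd = hr.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X_ts[:, :, 0] = (hr - mu) / sd
        return replace(samples, X_ts=X_ts, X_ds=X_ds)
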