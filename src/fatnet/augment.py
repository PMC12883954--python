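"""Training-set augmentation: jitter, time-warp, magnitude-scale, SMOTE.

The fourfold expansion keeps the original samples and adds one
jittered copy, one time-warped + magnitude-scaled copy, and one
SMOTE copy synthesized in composite-score space, so |output| = 4·|input|.
Augmentation is restricted to the training split; applying it to any
other split raises, which protects evaluation integrity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .datasets import BINARY_DAILY, SampleSet
from .preprocessing import CONTINUOUS_DAILY

__all__ = [
    "AugmentationConfig", "jitter", "time_warp", "magnitude_scale",
    "smote_tail", "augment_fourfold",
]


@dataclass(frozen=True)
class AugmentationConfig:
    jitter_sigma_frac: float = 0.02       # Gaussian sd as fraction of feature range
    warp_factor_range: tuple = (0.9, 1.1)
    scale_factor_range: tuple = (0.9, 1.1)
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.jitter_sigma_frac < 1.0):
            raise ValueError("jitter_sigma_frac must lie in [0, 1)")
        for name in ("warp_factor_range", "scale_factor_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi):
                raise ValueError(f"{name} must be well-ordered and positive")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


def _continuous_idx(samples: SampleSet) -> list[int]:
    return [samples.feature_names.index(c) for c in CONTINUOUS_DAILY
            if c in samples.feature_names]


def jitter(samples: SampleSet, config: AugmentationConfig,
           rng: np.random.Generator) -> SampleSet:
    """Add Gaussian noise with sd = ``jitter_sigma_frac`` × feature range.

    Ranges are computed per continuous feature on the data being
    augmented (the training split).  The binary music channel, binary
    daily features and the target are untouched; a zero-range feature
    receives no noise.
    """
    frac = config.jitter_sigma_frac
    X_ts = samples.X_ts.copy()
    X_ds = samples.X_ds.copy()
    if frac > 0:
        hr = X_ts[:, :, 0]
        sd_hr = frac * np.ptp(hr)
        X_ts[:, :, 0] = hr + rng.normal(0.0, 1.0, size=hr.shape) * sd_hr
        idx = _continuous_idx(samples)
        rng_ds = np.ptp(X_ds[:, idx], axis=0)   # per-feature training range
        noise = rng.normal(0.0, 1.0, size=(len(samples), len(idx))) * (frac * rng_ds)
        X_ds[:, idx] = X_ds[:, idx] + noise
    return replace(samples, X_ts=X_ts, X_ds=X_ds,
                   provenance=np.array(["jitter"] * len(samples), dtype=object))


def time_warp(X_ts: np.ndarray, config: AugmentationConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Stretch/compress each sample's time axis and regrid to length T.

    With factor f, the warped series is v'(t) = v(t / f) linearly
    interpolated on the original grid (edge-clamped), so a ramp of
    slope 1 becomes a ramp of slope 1/f and the first sample is
    preserved exactly.  The binary music channel is re-thresholded at
    0.5 after interpolation.
    """
    if X_ts.ndim != 3 or X_ts.shape[1] < 2:
        raise ValueError("time_warp expects (N, T>=2, channels)")
    N, T, C = X_ts.shape
    lo, hi = config.warp_factor_range
    t = np.arange(T, dtype=float)
    out = np.empty_like(X_ts)
    for n in range(N):
        f = rng.uniform(lo, hi)
        src = t / f
        for c in range(C):
            out[n, :, c] = np.interp(src, t, X_ts[n, :, c])
    out[:, :, 1] = (out[:, :, 1] >= 0.5).astype(out.dtype)
    return out


def magnitude_scale(X_ds: np.ndarray, continuous_idx: list[int],
                    config: AugmentationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Scale each sample's continuous daily features by one factor s."""
    lo, hi = config.scale_factor_range
    out = X_ds.copy()
    s = rng.uniform(lo, hi, size=(len(X_ds), 1))
    out[:, continuous_idx] = out[:, continuous_idx] * s
    return out


def smote_tail(samples: SampleSet, scores: np.ndarray,
               config: AugmentationConfig, rng: np.random.Generator,
               n_out: int | None = None) -> SampleSet:
    """Synthesize samples in the tails of the composite-score distribution.

    Tail bins are score < Q1 and score > Q3.  Each synthetic sample
    interpolates a tail sample toward one of its k nearest neighbours
    within the same tail (Euclidean distance in internally
    standardized continuous-daily-feature + score space) with a single
    mixing weight u ~ U(0, 1) shared by the daily features, the minute
    series and the score.  Binary daily features keep the primary
    parent's value.  Synthetic samples carry fresh ids.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(samples):
        raise ValueError("scores and samples must align")
    n_out = len(samples) if n_out is None else n_out
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    tails = {"low": np.flatnonzero(scores < q1),
             "high": np.flatnonzero(scores > q3)}
    tails = {name: idx for name, idx in tails.items() if len(idx) >= 2}
    if not tails:
        raise ValueError("no usable tail bin (need >= 2 samples below Q1 or above Q3)")

    nn_models = {}
    cont = _continuous_idx(samples)
    space = np.column_stack([samples.X_ds[:, cont], scores])
    mu, sd = space.mean(axis=0), space.std(axis=0)
    sd[sd == 0] = 1.0
    space = (space - mu) / sd
    for name, idx in tails.items():
        k = config.smote_k
        if len(idx) < k + 1:
            warnings.warn(f"{name} tail has {len(idx)} samples < k+1; "
                          f"reducing k to {len(idx) - 1}")
            k = len(idx) - 1
        nn_models[name] = (NearestNeighbors(n_neighbors=k + 1).fit(space[idx]), idx, k)

    names = list(tails)
    pick_tail = rng.integers(0, len(names), size=n_out)
    new_ts = np.empty((n_out, samples.X_ts.shape[1], samples.X_ts.shape[2]),
                      dtype=samples.X_ts.dtype)
    new_ds = np.empty((n_out, samples.X_ds.shape[1]), dtype=samples.X_ds.dtype)
    new_agg = np.empty((n_out, samples.ts_aggregates.shape[1]))
    new_y = np.empty(n_out)
    pids = np.empty(n_out, dtype=object)
    bin_idx = [samples.feature_names.index(c) for c in BINARY_DAILY
               if c in samples.feature_names]
    for j in range(n_out):
        model, idx, k = nn_models[names[pick_tail[j]]]
        a_local = rng.integers(0, len(idx))
        a = idx[a_local]
        _, neigh = model.kneighbors(space[a][None, :])
        choices = [idx[c] for c in neigh[0] if idx[c] != a]
        b = choices[rng.integers(0, min(k, len(choices)))] if choices else a
        u = rng.uniform()
        new_ds[j] = samples.X_ds[a] + u * (samples.X_ds[b] - samples.X_ds[a])
        new_ds[j, bin_idx] = samples.X_ds[a, bin_idx]
        new_ts[j] = samples.X_ts[a] + u * (samples.X_ts[b] - samples.X_ts[a])
        new_agg[j] = samples.ts_aggregates[a] + u * (samples.ts_aggregates[b]
                                                     - samples.ts_aggregates[a])
        new_y[j] = scores[a] + u * (scores[b] - scores[a])
        pids[j] = f"synth-{j:05d}"
    new_ts[:, :, 1] = (new_ts[:, :, 1] >= 0.5).astype(new_ts.dtype)
    return SampleSet(
        X_ts=new_ts, X_ds=new_ds, y=new_y, participant_id=pids,
        day_index=np.full(n_out, -1), feature_names=list(samples.feature_names),
        split=samples.split,
        provenance=np.array(["smote"] * n_out, dtype=object),
        ts_aggregates=new_agg,
    )


def augment_fourfold(samples: SampleSet, config: AugmentationConfig
                     ) -> SampleSet:
    """Original ∪ jitter ∪ (time-warp ∘ magnitude-scale) ∪ SMOTE = 4N.

    Only the training split may be augmented; any other split raises.
    Deterministic given ``config.seed``.
    """
    if samples.split != "train":
        raise ValueError("augmentation is restricted to the training split "
                         f"(got split={samples.split!r})")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA46]))
    original = replace(samples,
                       provenance=np.array(["original"] * len(samples), dtype=object))
    jit = jitter(samples, config, rng)
    warped = replace(
        samples,
        X_ts=time_warp(samples.X_ts, config, rng),
        X_ds=magnitude_scale(samples.X_ds, _continuous_idx(samples), config, rng),
        provenance=np.array(["warp_scale"] * len(samples), dtype=object),
    )
    smote = smote_tail(samples, samples.y, config, rng)
    return SampleSet.concatenate([original, jit, warped, smote])
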