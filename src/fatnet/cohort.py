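"""Seeded synthetic cohort generator.

Emulates a wearable-music study cohort of older adults: each
participant contributes several weeks of participant-days, each with a
minute-resolution stream (heart rate in bpm, music on/off) and a daily
summary row (PANAS positive affect, sleep efficiency, RMSSD, resting
HR, music listening characteristics, demographics).

The statistical backbone is a latent daily wellness factor ``w`` with
AR(1) dynamics and unit stationary variance.  The three Health Score
components load equally on ``w``:

    Z_j = L·w + sqrt(1 − L²)·e_j,   e_j iid N(0, 1)

so that pairwise component correlation equals L².  A minute-level
music→heart-rate interaction is planted: during music blocks whose
tempo exceeds the participant's preferred tempo, heart rate first
rises and then dips below its local baseline.  The standardized count
of such "relaxation dip" minutes, ``g``, feeds the next day's
wellness:

    w_{i+1} = ρ·w_i + β·g_i + η,   η ~ N(0, 1 − ρ² − β²)

which keeps Var(w) = 1 and plants next-day predictive signal that the
daily summary table does not encode.  A self-reported global health
rating (ordinal 1–10) loads on ``w`` with loading ``rating_loading``
and is exported only in the truth table, never as a model feature.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "GeneratorConfig", "CohortDataset", "generate_cohort",
    "inject_missingness", "export_cohort", "import_cohort",
    "DAILY_COLUMNS", "MINUTE_COLUMNS", "TRUTH_COLUMNS",
]

# HR-stream constants (bpm unless noted): chosen to mimic wrist-worn
# minute data in adults ≥60 — see docs/methods.md for rationale.
_WAKING_OFFSET = 8.0          # waking HR sits above resting baseline
_CIRCADIAN_AMP = 2.5          # within-window circadian swing
_AR_NOISE_SD = 2.0            # stationary sd of minute-level AR(1) noise
_AR_NOISE_RHO = 0.9
_HIGH_RISE = 6.0              # rise during the arousal phase of a high-tempo block
_HIGH_DIP = 6.0               # dip below baseline in the relaxation phase
_LOW_TEMPO_DROP = 1.5         # mild relaxation during low-tempo music
_RESPONSE_PROB = 0.65         # chance a high-tempo block elicits the rise/dip response
_DIP_WINDOW = 61              # rolling-median window (minutes) for the local baseline
_DIP_MARGIN = 2.0             # bpm below local baseline that counts as a dip
_DAY_WANDER_SD = 2.5          # day-to-day wander of the whole-day HR level
_NOISE_SCALE_SD = 0.25        # lognormal sd of the per-day minute-noise scale


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the emulated study: 92 participants followed for
    45 ± 10 days, equal component loadings sqrt(0.5) (pairwise
    component correlation 0.5), rating loading sqrt(0.9), latent
    AR(1) coefficient 0.5, and a minute-level music effect whose
    weight beta satisfies beta² = 0.35 so that adding ``g`` to the
    previous day's wellness raises the population R² of next-day
    wellness by 0.35.
    """

    n_participants: int = 92
    days_mean: float = 45.0
    days_sd: float = 10.0
    T: int = 240
    ar_rho: float = 0.5
    component_loading: float = np.sqrt(0.5)
    rating_loading: float = np.sqrt(0.9)
    music_effect_beta: float = np.sqrt(0.35)
    missing_day_rate: float = 0.0
    missing_minute_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.n_participants, (int, np.integer)) and self.n_participants >= 1):
            raise ValueError("n_participants must be an integer >= 1")
        if not (0.0 <= self.ar_rho < 1.0):
            raise ValueError("ar_rho must satisfy 0 <= ar_rho < 1")
        if self.T < 10:
            raise ValueError("T must be >= 10 minutes")
        for name in ("missing_day_rate", "missing_minute_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("component_loading", "rating_loading"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.days_sd < 0:
            raise ValueError("days_sd must be >= 0")
        if self.music_effect_beta < 0:
            raise ValueError("music_effect_beta must be >= 0")
        if self.ar_rho ** 2 + self.music_effect_beta ** 2 >= 1.0:
            raise ValueError("ar_rho**2 + music_effect_beta**2 must be < 1 "
                             "to keep the latent wellness variance stationary")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


DAILY_COLUMNS = [
    "participant_id", "day_index", "panas", "sleep_efficiency", "rmssd",
    "sdnn", "resting_hr", "waso", "total_sleep_time",
    "listening_duration", "mean_tempo", "valence", "arousal",
    "age", "gender", "bmi", "hypertension", "diabetes", "missing_day",
]
MINUTE_COLUMNS = ["participant_id", "day_index", "minute_index", "hr_bpm",
                  "music_on", "missing"]
TRUTH_COLUMNS = ["participant_id", "day_index", "wellness", "g", "rating",
                 "baseline_rhr", "music_preference_tempo"]


@dataclass
class CohortDataset:
    """In-memory cohort: daily summaries, minute streams, latent truth.

    ``truth`` carries the latent wellness state, the minute-level
    interaction score ``g`` and the self-reported rating; it exists
    for diagnostics and tests only and is never used as model input.
    """

    daily: pd.DataFrame
    minutes: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig

    def copy(self) -> "CohortDataset":
        return CohortDataset(self.daily.copy(), self.minutes.copy(),
                             self.truth.copy(), self.config)

    @property
    def n_participants(self) -> int:
        return self.daily["participant_id"].nunique()

    @property
    def n_days(self) -> int:
        return len(self.daily)

    def equals(self, other: "CohortDataset") -> bool:
        return (self.daily.reset_index(drop=True).equals(other.daily.reset_index(drop=True))
                and self.minutes.reset_index(drop=True).equals(other.minutes.reset_index(drop=True))
                and self.truth.reset_index(drop=True).equals(other.truth.reset_index(drop=True)))


def _place_music_blocks(rng: np.random.Generator, T: int):
    """Sample 1–3 non-overlapping music blocks; returns (start, length) list."""
    n_blocks = int(rng.integers(1, 4))
    lmin, lmax = max(8, T // 12), max(10, T // 4)
    blocks: list[tuple[int, int]] = []
    for _ in range(n_blocks):
        for _attempt in range(25):
            length = int(rng.integers(lmin, lmax + 1))
            start = int(rng.integers(0, max(1, T - length)))
            if all(start + length <= s or start >= s + l for s, l in blocks):
                blocks.append((start, length))
                break
    return sorted(blocks)


def _simulate_minutes(rng: np.random.Generator, cfg: GeneratorConfig,
                      baseline_rhr: float, pref_tempo: float, phase: float,
                      n_days: int):
    """Simulate the exogenous minute streams for one participant.

    Returns (hr (n_days, T), music_on, g_raw, duration, mean_tempo).
    """
    T = cfg.T
    t = np.arange(T)
    circadian = _CIRCADIAN_AMP * np.sin(2 * np.pi * t / T + phase)

    hr = np.empty((n_days, T))
    music_on = np.zeros((n_days, T), dtype=np.int8)
    high_mask = np.zeros((n_days, T), dtype=bool)
    duration = np.zeros(n_days)
    mean_tempo = np.zeros(n_days)

    # AR(1) minute noise, simulated day by day (vectorized over days).
    # Each day additionally gets a level wander and a noise-scale draw:
    # resting heart rate and short-term variability genuinely fluctuate
    # from day to day, and without them the day-level HR moments would
    # betray the music response to any summary-level model.
    innov_sd = _AR_NOISE_SD * np.sqrt(1.0 - _AR_NOISE_RHO ** 2)
    noise = np.empty((n_days, T))
    noise[:, 0] = rng.normal(0.0, _AR_NOISE_SD, size=n_days)
    eps = rng.normal(0.0, innov_sd, size=(n_days, T))
    for k in range(1, T):
        noise[:, k] = _AR_NOISE_RHO * noise[:, k - 1] + eps[:, k]
    noise *= np.exp(rng.normal(0.0, _NOISE_SCALE_SD, size=(n_days, 1)))
    day_wander = rng.normal(0.0, _DAY_WANDER_SD, size=n_days)

    for d in range(n_days):
        effect = np.zeros(T)
        tempos, lengths = [], []
        for start, length in _place_music_blocks(rng, T):
            tempo = float(rng.normal(pref_tempo, 15.0))
            tempos.append(tempo)
            lengths.append(length)
            sl = slice(start, start + length)
            music_on[d, sl] = 1
            responds = rng.random() < _RESPONSE_PROB
            if tempo > pref_tempo and responds:
                rise_len = max(1, int(round(length * rng.uniform(0.15, 0.65))))
                effect[start:start + rise_len] += _HIGH_RISE
                effect[start + rise_len:start + length] -= _HIGH_DIP
                high_mask[d, start + rise_len:start + length] = True
                # only the relaxation (dip) phase counts toward g
            else:
                effect[sl] -= _LOW_TEMPO_DROP
        duration[d] = music_on[d].sum()
        mean_tempo[d] = float(np.average(tempos, weights=lengths))
        hr[d] = baseline_rhr + _WAKING_OFFSET + day_wander[d] + circadian \
            + noise[d] + effect

    np.clip(hr, 35.0, 185.0, out=hr)
    local_base = median_filter(hr, size=(1, _DIP_WINDOW), mode="nearest")
    dip = hr < (local_base - _DIP_MARGIN)
    g_raw = (dip & (music_on == 1) & high_mask).sum(axis=1).astype(float)
    return hr, music_on, g_raw, duration, mean_tempo


def generate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Generate a full synthetic cohort (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    P = config.n_participants

    # participant profiles
    ages = np.maximum(60, np.round(rng.normal(67.8, 5.1, size=P))).astype(int)
    genders = np.where(rng.random(P) < 0.58, "F", "M")
    bmis = np.clip(rng.normal(26.4, 3.8, size=P), 10.5, 59.5)
    hypert = (rng.random(P) < 0.45).astype(int)
    diab = (rng.random(P) < 0.22).astype(int)
    baseline_rhr = np.clip(rng.normal(65.0, 8.0, size=P), 45.0, 95.0)
    pref_tempo = rng.normal(110.0, 12.0, size=P)
    phases = rng.uniform(0, 2 * np.pi, size=P)
    n_days = np.maximum(7, np.round(rng.normal(config.days_mean, config.days_sd,
                                               size=P))).astype(int)

    per_part = []
    for p in range(P):
        per_part.append(_simulate_minutes(rng, config, baseline_rhr[p],
                                          pref_tempo[p], phases[p], n_days[p]))

    # Standardize g: center within participant (tempo preference and
    # baseline otherwise induce a persistent per-participant offset that
    # would inflate the stationary variance of w above 1), then scale to
    # unit variance across the cohort.
    g_centered = [pp[2] - pp[2].mean() for pp in per_part]
    g_sd = np.concatenate(g_centered).std()
    if g_sd <= 0:
        g_sd = 1.0

    rho, beta = config.ar_rho, config.music_effect_beta
    eta_sd = np.sqrt(1.0 - rho ** 2 - beta ** 2)
    L = config.component_loading
    comp_noise = np.sqrt(1.0 - L ** 2)
    RL = config.rating_loading
    rating_noise = np.sqrt(1.0 - RL ** 2)

    daily_rows, minute_frames, truth_rows = [], [], []
    for p in range(P):
        hr, music_on, g_raw, duration, tempo = per_part[p]
        nd = n_days[p]
        g = g_centered[p] / g_sd

        w = np.empty(nd)
        w[0] = rng.normal()
        eta = rng.normal(0.0, eta_sd, size=nd)
        for i in range(1, nd):
            w[i] = rho * w[i - 1] + beta * g[i - 1] + eta[i]

        e = rng.normal(size=(nd, 3))
        Z = L * w[:, None] + comp_noise * e
        M = np.clip(np.round(30.0 + 6.0 * Z[:, 0]), 10, 50).astype(int)
        S = np.clip(85.0 + 7.0 * Z[:, 1], 40.0, 100.0)
        H = np.clip(35.0 + 10.0 * Z[:, 2], 5.0, 199.0)

        rating_cont = RL * w + rating_noise * rng.normal(size=nd)
        rating = np.clip(np.round(5.5 + 2.0 * rating_cont), 1, 10).astype(int)

        resting = baseline_rhr[p] + rng.normal(0.0, 1.5, size=nd)
        sdnn = np.clip(1.3 * H + rng.normal(0.0, 5.0, size=nd), 5.0, 320.0)
        tst = np.clip(rng.normal(420.0, 35.0, size=nd), 240.0, 600.0)
        waso = np.clip(tst * (100.0 / S - 1.0) * np.exp(rng.normal(0.0, 0.15, size=nd)),
                       0.0, 400.0)
        valence = np.clip(rng.normal(6.0, 1.2, size=nd), 1.0, 9.0)
        arousal = np.clip(rng.normal(5.0, 1.5, size=nd), 1.0, 9.0)

        pid = f"P{p + 1:03d}"
        for i in range(nd):
            daily_rows.append((pid, i, M[i], S[i], H[i], sdnn[i], resting[i],
                               waso[i], tst[i], duration[i], tempo[i],
                               valence[i], arousal[i], ages[p], genders[p],
                               bmis[p], hypert[p], diab[p], False))
            truth_rows.append((pid, i, w[i], g[i], rating[i],
                               baseline_rhr[p], pref_tempo[p]))
        T = config.T
        minute_frames.append(pd.DataFrame({
            "participant_id": np.repeat(pid, nd * T),
            "day_index": np.repeat(np.arange(nd), T),
            "minute_index": np.tile(np.arange(T), nd),
            "hr_bpm": hr.ravel(),
            "music_on": music_on.ravel().astype(int),
            "missing": np.zeros(nd * T, dtype=bool),
        }))

    daily = pd.DataFrame(daily_rows, columns=DAILY_COLUMNS)
    minutes = pd.concat(minute_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return CohortDataset(daily=daily, minutes=minutes, truth=truth, config=config)


def inject_missingness(dataset: CohortDataset,
                       config: GeneratorConfig | None = None) -> CohortDataset:
    """Mark whole days and individual minutes missing at configured rates.

    Missing days blank every daily measurement and the day's heart-rate
    minutes; missing minutes blank individual ``hr_bpm`` samples.  The
    draw is seeded from ``config.seed`` so the corruption is
    reproducible and independent of generation order.
    """
    cfg = config if config is not None else dataset.config
    if not (0.0 <= cfg.missing_day_rate <= 1.0 and 0.0 <= cfg.missing_minute_rate <= 1.0):
        raise ValueError("missingness rates must lie in [0, 1]")
    if cfg.missing_day_rate == 0.0 and cfg.missing_minute_rate == 0.0:
        return dataset.copy()

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    out = dataset.copy()
    daily, minutes = out.daily, out.minutes

    day_missing = rng.random(len(daily)) < cfg.missing_day_rate
    daily["missing_day"] = day_missing
    measured = ["panas", "sleep_efficiency", "rmssd", "sdnn", "resting_hr",
                "waso", "total_sleep_time", "listening_duration",
                "mean_tempo", "valence", "arousal"]
    daily.loc[day_missing, measured] = np.nan

    key = pd.MultiIndex.from_frame(minutes[["participant_id", "day_index"]])
    missing_keys = pd.MultiIndex.from_frame(
        daily.loc[day_missing, ["participant_id", "day_index"]])
    minute_in_missing_day = key.isin(missing_keys)

    minute_missing = rng.random(len(minutes)) < cfg.missing_minute_rate
    mask = minute_missing | minute_in_missing_day
    minutes["missing"] = mask
    minutes.loc[mask, "hr_bpm"] = np.nan
    return out


# ---------------------------------------------------------------------------
# CSV round trip

_FILES = {"daily": "cohort_daily.csv", "minutes": "cohort_minutes.csv",
          "truth": "cohort_truth.csv"}


def export_cohort(dataset: CohortDataset, path: str | Path) -> Path:
    """Write cohort CSVs plus a JSON sidecar with the generator config."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.daily.to_csv(path / _FILES["daily"], index=False)
    dataset.minutes.to_csv(path / _FILES["minutes"], index=False)
    dataset.truth.to_csv(path / _FILES["truth"], index=False)
    with open(path / "generator_config.json", "w") as fh:
        json.dump(dataset.config.to_dict(), fh, indent=2)
    return path


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:  # pandas reports the offending line
        raise ValueError(f"malformed file {path.name}: {e}") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name} is missing required column(s): "
                         f"{', '.join(missing)}")
    return df


def import_cohort(path: str | Path) -> CohortDataset:
    """Read a cohort previously written by :func:`export_cohort`."""
    path = Path(path)
    daily = _read_csv(path / _FILES["daily"], DAILY_COLUMNS)
    minutes = _read_csv(path / _FILES["minutes"], MINUTE_COLUMNS)
    truth = _read_csv(path / _FILES["truth"], TRUTH_COLUMNS)
    with open(path / "generator_config.json") as fh:
        config = GeneratorConfig.from_dict(json.load(fh))
    for df, boolcol in ((daily, "missing_day"), (minutes, "missing")):
        df[boolcol] = df[boolcol].astype(bool)
    if len(minutes):
        minutes["music_on"] = minutes["music_on"].astype(int)
    return CohortDataset(daily=daily, minutes=minutes, truth=truth, config=config)
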