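"""Data refinement pipeline: plausibility QC, imputation, engineering.

Mirrors the refinement stages a wearable-cohort analysis applies before
modelling: (a) physiologically implausible records are flagged and
removed, (b) lightly missing days are linearly interpolated over time
while heavily missing participants are excluded, (c) derived day-level
features are computed (ΔHRV, listening intensity, sleep fragmentation)
and (d) continuous features are standardized with statistics fitted on
the training split only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortDataset

__all__ = [
    "QCConfig", "QCReport", "flag_outliers", "impute_and_exclude",
    "engineer_features", "Standardizer", "standardize", "CONTINUOUS_DAILY",
    "refine_cohort",
]


@dataclass(frozen=True)
class QCConfig:
    """Plausibility bounds and missingness thresholds.

    Bounds follow conventional wearable plausibility rules: resting
    heart rate outside [30, 120] bpm, RMSSD above 200 ms or sleep
    efficiency above 100% are physiologically implausible for this
    population.
    """

    rhr_min: float = 30.0
    rhr_max: float = 120.0
    hrv_max: float = 200.0
    sleep_eff_max: float = 100.0
    day_missing_threshold: float = 0.10
    participant_missing_threshold: float = 0.10

    def __post_init__(self):
        if not self.rhr_min < self.rhr_max:
            raise ValueError("rhr_min must be below rhr_max")
        for name in ("day_missing_threshold", "participant_missing_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class QCReport:
    n_total_records: int = 0
    n_flagged_records: int = 0
    n_imputed_days: int = 0
    n_dropped_days: int = 0
    excluded_participants: list = field(default_factory=list)
    exclusion_reasons: dict = field(default_factory=dict)

    @property
    def flagged_fraction(self) -> float:
        return self.n_flagged_records / self.n_total_records if self.n_total_records else 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flagged_fraction"] = self.flagged_fraction
        return d


_QC_REQUIRED = ["resting_hr", "rmssd", "sleep_efficiency"]


def flag_outliers(daily: pd.DataFrame, qc: QCConfig | None = None
                  ) -> tuple[pd.DataFrame, QCReport]:
    """Remove physiologically implausible daily records.

    A record is flagged when resting HR falls outside
    ``[rhr_min, rhr_max]``, RMSSD exceeds ``hrv_max`` or sleep
    efficiency exceeds ``sleep_eff_max``.  SDNN is deliberately not
    bounded.  Missing values do not trigger the flag (they belong to
    the imputation stage).
    """
    qc = qc or QCConfig()
    missing_cols = [c for c in _QC_REQUIRED if c not in daily.columns]
    if missing_cols:
        raise ValueError(f"daily table is missing required column(s): "
                         f"{', '.join(missing_cols)}")
    rhr = daily["resting_hr"]
    bad = (
        (rhr < qc.rhr_min) | (rhr > qc.rhr_max)
        | (daily["rmssd"] > qc.hrv_max)
        | (daily["sleep_efficiency"] > qc.sleep_eff_max)
    ).fillna(False)
    report = QCReport(n_total_records=len(daily),
                      n_flagged_records=int(bad.sum()))
    return daily.loc[~bad].copy(), report


def impute_and_exclude(dataset: CohortDataset, qc: QCConfig | None = None
                       ) -> tuple[CohortDataset, QCReport]:
    """Impute lightly missing days; drop heavy days and participants.

    Per participant-day the missing fraction pools the day's
    minute-level samples and its daily measurement fields.  Days at or
    below ``day_missing_threshold`` are linearly interpolated along
    time (minutes within the day, daily fields across days within the
    participant).  Days above the threshold count as missing days and
    are dropped; participants whose missing-day fraction exceeds
    ``participant_missing_threshold`` are excluded entirely.
    """
    qc = qc or QCConfig()
    out = dataset.copy()
    daily, minutes = out.daily, out.minutes
    report = QCReport(n_total_records=len(daily))

    measured = ["panas", "sleep_efficiency", "rmssd", "sdnn", "resting_hr",
                "waso", "total_sleep_time", "listening_duration",
                "mean_tempo", "valence", "arousal"]

    # per-day missing fraction over minutes + daily fields, counted jointly
    miss_min = minutes.groupby(["participant_id", "day_index"], sort=False)["missing"] \
                      .agg(["sum", "size"])
    daily_idx = daily.set_index(["participant_id", "day_index"]).index
    miss_min = miss_min.reindex(daily_idx, fill_value=0)
    n_daily_fields = len(measured)
    miss_daily = daily[measured].isna().sum(axis=1).to_numpy()
    frac = (miss_min["sum"].to_numpy() + miss_daily) \
        / (miss_min["size"].to_numpy() + n_daily_fields)

    heavy = frac > qc.day_missing_threshold
    light = (frac > 0) & ~heavy

    # participant exclusion on fraction of heavy ("missing") days
    daily = daily.assign(_heavy=heavy, _light=light)
    excluded: list[str] = []
    reasons: dict[str, str] = {}
    for pid, gdf in daily.groupby("participant_id", sort=False):
        n = len(gdf)
        h = gdf["_heavy"].sum()
        if n == 1 and (gdf["_heavy"].iloc[0] or gdf["_light"].iloc[0]):
            excluded.append(pid)
            reasons[pid] = "single day with missing values; interpolation impossible"
        elif h / n > qc.participant_missing_threshold:
            excluded.append(pid)
            reasons[pid] = f"{h}/{n} missing days exceeds threshold"
    keep = ~daily["participant_id"].isin(excluded)
    daily = daily.loc[keep]
    report.excluded_participants = excluded
    report.exclusion_reasons = reasons

    # drop heavy days, interpolate the light ones
    report.n_dropped_days = int(daily["_heavy"].sum())
    report.n_imputed_days = int(daily["_light"].sum())
    daily = daily.loc[~daily["_heavy"]].drop(columns=["_heavy", "_light"])

    # daily fields: linear interpolation over day_index within participant
    daily = daily.sort_values(["participant_id", "day_index"])
    for col in measured:
        daily[col] = (
            daily.groupby("participant_id", sort=False)[col]
                 .transform(lambda s: s.interpolate(method="linear",
                                                    limit_direction="both"))
        )

    # minute streams: keep only retained days, interpolate hr within day
    retained = pd.MultiIndex.from_frame(daily[["participant_id", "day_index"]])
    mkey = pd.MultiIndex.from_frame(minutes[["participant_id", "day_index"]])
    minutes = minutes.loc[mkey.isin(retained)].copy()
    if minutes["missing"].any():
        minutes["hr_bpm"] = (
            minutes.groupby(["participant_id", "day_index"], sort=False)["hr_bpm"]
                   .transform(lambda s: s.interpolate(method="linear",
                                                      limit_direction="both"))
        )
        minutes["missing"] = False
    daily["missing_day"] = False

    tkey = pd.MultiIndex.from_frame(out.truth[["participant_id", "day_index"]])
    out.daily = daily.reset_index(drop=True)
    out.minutes = minutes.reset_index(drop=True)
    out.truth = out.truth.loc[tkey.isin(retained)].reset_index(drop=True)
    return out, report


_ENGINEER_REQUIRED = ["rmssd", "listening_duration", "mean_tempo", "waso",
                      "total_sleep_time"]


def engineer_features(daily: pd.DataFrame) -> pd.DataFrame:
    """Add ΔHRV, listening intensity and sleep fragmentation columns.

    ΔHRV is the day-to-day RMSSD change (0 on each participant's first
    day — the no-change prior keeps the row usable).  Listening
    intensity is duration × mean tempo (min·BPM).  Sleep fragmentation
    is WASO / total sleep time; a zero TST leaves the value NaN and
    sets ``fragmentation_undefined`` instead of dividing.
    """
    missing = [c for c in _ENGINEER_REQUIRED if c not in daily.columns]
    if missing:
        raise ValueError(f"daily table is missing required column(s): "
                         f"{', '.join(missing)}")
    out = daily.sort_values(["participant_id", "day_index"]).copy()
    out["delta_hrv"] = (
        out.groupby("participant_id", sort=False)["rmssd"].diff().fillna(0.0)
    )
    out["listening_intensity"] = out["listening_duration"] * out["mean_tempo"]
    tst = out["total_sleep_time"]
    zero_tst = tst == 0
    out["sleep_fragmentation"] = np.where(zero_tst, np.nan, out["waso"] / tst)
    out["fragmentation_undefined"] = zero_tst
    return out


#: Continuous day-level model features (z-scored with training statistics).
CONTINUOUS_DAILY = [
    "panas", "sleep_efficiency", "rmssd", "sdnn", "resting_hr", "waso",
    "total_sleep_time", "listening_duration", "mean_tempo", "valence",
    "arousal", "age", "bmi", "delta_hrv", "listening_intensity",
    "sleep_fragmentation",
]


class Standardizer:
    """Column-wise z-scoring with stored (leakage-safe) statistics.

    ``fit`` records per-column mean and sample standard deviation
    (ddof=1) together with a provenance label; ``transform`` applies
    the stored statistics, so validation/test data are never refit.
    """

    def __init__(self):
        self.mean_: pd.Series | None = None
        self.std_: pd.Series | None = None
        self.columns_: list[str] | None = None
        self.provenance: str | None = None

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, table: pd.DataFrame, columns: list[str] | None = None,
            provenance: str = "fit") -> "Standardizer":
        cols = columns if columns is not None else [
            c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
        mean = table[cols].mean()
        std = table[cols].std(ddof=1)
        constant = [c for c in cols if not np.isfinite(std[c]) or std[c] == 0.0]
        if constant:
            raise ValueError(f"constant column(s) cannot be standardized: "
                             f"{', '.join(constant)}")
        self.mean_, self.std_, self.columns_ = mean, std, cols
        self.provenance = provenance
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not self.fitted:
            raise RuntimeError("Standardizer.transform called before fit")
        out = table.copy()
        out[self.columns_] = (table[self.columns_] - self.mean_) / self.std_
        return out

    def fit_transform(self, table: pd.DataFrame, columns: list[str] | None = None,
                      provenance: str = "fit") -> pd.DataFrame:
        return self.fit(table, columns, provenance).transform(table)


def refine_cohort(dataset: CohortDataset, qc: QCConfig | None = None
                  ) -> tuple[CohortDataset, pd.DataFrame, dict]:
    """Full refinement: outlier QC → imputation/exclusion → engineering.

    Returns the refined dataset, the engineered daily table, and a dict
    with both QC reports.  Standardization is *not* applied here — it
    must be fitted on the training split downstream.
    """
    qc = qc or QCConfig()
    clean_daily, outlier_report = flag_outliers(dataset.daily, qc)
    refined = dataset.copy()
    refined.daily = clean_daily.reset_index(drop=True)
    refined, missing_report = impute_and_exclude(refined, qc)
    engineered = engineer_features(refined.daily)
    reports = {"outliers": outlier_report.to_dict(),
               "missingness": missing_report.to_dict()}
    return refined, engineered, reports


def standardize(table: pd.DataFrame, stats_source: "Standardizer | str" = "fit",
                columns: list[str] | None = None
                ) -> tuple[pd.DataFrame, Standardizer]:
    """Standardize `table`; fit fresh stats or apply previously fitted ones."""
    if isinstance(stats_source, Standardizer):
        return stats_source.transform(table), stats_source
    if stats_source != "fit":
        raise ValueError("stats_source must be 'fit' or a fitted Standardizer")
    sc = Standardizer()
    return sc.fit_transform(table, columns), sc
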