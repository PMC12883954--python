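"""Composite Health Score construction and its validation checks.

The day-level composite integrates positive affect (PANAS sum M),
sleep efficiency (S, %) and resting HRV (RMSSD, H, ms).  Components
are z-scored across the cohort (the cohort-wide statistics *define*
the target, unlike model features which use training-split
statistics), then combined either as the equal-weight mean

    Health_i = (Z_M,i + Z_S,i + Z_H,i) / 3

or as the projection on the first principal component of
[Z_M, Z_S, Z_H].  Diagnostics cover internal consistency (Cronbach's
α), PC1 variance share, distributional shape, responsiveness of
day-to-day score changes against self-reported global ratings, and an
optional binary Good / Not-Good label at the 75th percentile.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HealthComponents", "ScoreDiagnostics", "standardize_components",
    "equal_weight_score", "pca_score", "cronbach_alpha",
    "distribution_checks", "responsiveness", "binary_label",
    "score_cohort",
]


@dataclass
class HealthComponents:
    """Raw components, their z-scores and the cohort statistics used."""

    M: np.ndarray
    S: np.ndarray
    H: np.ndarray
    Z: np.ndarray          # (n, 3) z-scored [Z_M, Z_S, Z_H]
    mean: np.ndarray       # (3,) cohort means (μ_M, μ_S, μ_H)
    std: np.ndarray        # (3,) cohort sds (sample convention)

    @property
    def n(self) -> int:
        return len(self.M)


@dataclass
class ScoreDiagnostics:
    cronbach_alpha: float = np.nan
    pc1_variance_fraction: float = np.nan   # percent
    shapiro_p: float = np.nan
    skewness: float = np.nan
    kurtosis: float = np.nan                # excess kurtosis
    responsiveness_rho: float = np.nan
    responsiveness_p: float = np.nan

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def standardize_components(M, S, H) -> HealthComponents:
    """Z-score the three components across the cohort (sample sd)."""
    M, S, H = (np.asarray(v, dtype=float) for v in (M, S, H))
    if not (len(M) == len(S) == len(H)):
        raise ValueError("component vectors must have equal length")
    if len(M) < 2:
        raise ValueError("at least two days are required to standardize")
    X = np.column_stack([M, S, H])
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    if np.any(std == 0):
        names = np.array(["M (PANAS)", "S (sleep efficiency)", "H (RMSSD)"])
        raise ValueError(f"constant component(s): {', '.join(names[std == 0])}")
    return HealthComponents(M=M, S=S, H=H, Z=(X - mean) / std, mean=mean, std=std)


def equal_weight_score(components: HealthComponents) -> np.ndarray:
    """Equal-weight composite: mean of the three z-scores."""
    return components.Z.mean(axis=1)


def pca_score(components: HealthComponents
              ) -> tuple[np.ndarray, float, np.ndarray]:
    """Project on PC1 of the component correlation matrix.

    Returns ``(score, pc1_variance_fraction_percent, weights)``.  The
    eigenvector sign is oriented so the PCA score correlates
    non-negatively with the equal-weight score ("higher = healthier").
    Degenerate (rank-deficient) inputs are handled by eigh directly;
    ties in the leading eigenvalue resolve to eigh's ordering.
    """
    Z = components.Z
    if Z.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows")
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    lead = evals[-1]
    weights = evecs[:, -1]
    score = Z @ weights
    ew = equal_weight_score(components)
    if np.dot(score, ew) < 0:
        weights = -weights
        score = -score
    return score, 100.0 * lead / R.shape[0], weights


def cronbach_alpha(components: HealthComponents | np.ndarray) -> float:
    """Internal consistency α = k/(k−1) · (1 − Σ item var / var of sum)."""
    X = components.Z if isinstance(components, HealthComponents) else np.asarray(components, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance; alpha undefined")
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def distribution_checks(score: np.ndarray) -> ScoreDiagnostics:
    """Shapiro–Wilk p, sample skewness and excess kurtosis of the score."""
    score = np.asarray(score, dtype=float)
    if len(score) < 3:
        raise ValueError("distribution checks require n >= 3")
    if np.ptp(score) == 0:
        raise ValueError("constant score; distribution checks undefined")
    sw = stats.shapiro(score)
    return ScoreDiagnostics(
        shapiro_p=float(sw.pvalue),
        skewness=float(stats.skew(score, bias=False)),
        kurtosis=float(stats.kurtosis(score, bias=False)),
    )


def responsiveness(score: pd.Series | np.ndarray,
                   rating: pd.Series | np.ndarray,
                   participant_id: pd.Series | np.ndarray,
                   day_index: pd.Series | np.ndarray,
                   ) -> tuple[float, float]:
    """Pooled Spearman ρ of within-participant day-to-day changes.

    Both the composite score and the global rating are first-differenced
    within participant (days sorted by index), the differences pooled
    across participants, and Spearman rank correlation computed on the
    pooled pairs.  Returns ``(rho, p_value)``.
    """
    df = pd.DataFrame({
        "pid": np.asarray(participant_id),
        "day": np.asarray(day_index),
        "score": np.asarray(score, dtype=float),
        "rating": np.asarray(rating, dtype=float),
    }).sort_values(["pid", "day"])
    d_score, d_rating = [], []
    for _, g in df.groupby("pid", sort=False):
        if len(g) < 2:
            continue
        d_score.append(np.diff(g["score"].to_numpy()))
        d_rating.append(np.diff(g["rating"].to_numpy()))
    if not d_score or sum(len(a) for a in d_score) < 3:
        raise ValueError("fewer than 3 pooled difference pairs")
    res = stats.spearmanr(np.concatenate(d_score), np.concatenate(d_rating))
    return float(res.statistic), float(res.pvalue)


def binary_label(score: np.ndarray) -> np.ndarray:
    """Good (1) ⇔ score strictly above the 75th percentile.

    The quantile uses linear interpolation between order statistics;
    scores exactly at the threshold count as Not-Good.
    """
    score = np.asarray(score, dtype=float)
    if len(score) < 4:
        raise ValueError("binary labelling requires n >= 4")
    thr = np.quantile(score, 0.75)  # default 'linear' interpolation
    return (score > thr).astype(int)


def score_cohort(daily: pd.DataFrame, method: str = "equal",
                 truth: pd.DataFrame | None = None
                 ) -> tuple[pd.DataFrame, ScoreDiagnostics]:
    """Score every participant-day of a daily table; attach diagnostics.

    Returns a frame with ``equal_weight``, ``pca_score`` and ``label``
    columns (label from the requested method) plus a
    :class:`ScoreDiagnostics`.  If a truth table with ratings is given,
    responsiveness is evaluated as well — ratings are diagnostics-only
    and never become features.
    """
    if method not in ("equal", "pca"):
        raise ValueError("method must be 'equal' or 'pca'")
    comp = standardize_components(daily["panas"], daily["sleep_efficiency"],
                                  daily["rmssd"])
    ew = equal_weight_score(comp)
    pca, pc1_frac, _ = pca_score(comp)
    target = ew if method == "equal" else pca
    out = daily[["participant_id", "day_index"]].copy()
    out["equal_weight"] = ew
    out["pca_score"] = pca
    out["label"] = binary_label(target)

    diag = distribution_checks(target)
    diag.cronbach_alpha = cronbach_alpha(comp)
    diag.pc1_variance_fraction = pc1_frac
    if truth is not None:
        merged = out.merge(truth[["participant_id", "day_index", "rating"]],
                           on=["participant_id", "day_index"], how="inner")
        rho, p = responsiveness(merged["equal_weight"] if method == "equal"
                                else merged["pca_score"],
                                merged["rating"], merged["participant_id"],
                                merged["day_index"])
        diag.responsiveness_rho = rho
        diag.responsiveness_p = p
    return out, diag
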