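"""Weekly-GDU forecasting skeleton.

Builds lag-``k`` same-week supervised datasets from historical 52-week
years, evaluates predictions with RMSE/MAE/Pearson correlation, and
rolls a pluggable regressor forward to produce a planning-horizon
scenario.  The climatology baseline (mean of the lagged values) stands
in for heavier sequence models; anything with ``fit``/``predict`` over
the lagged feature matrix slots in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Protocol, Sequence

import numpy as np

from .core import GduScenario

__all__ = [
    "LaggedDataset",
    "build_lagged_dataset",
    "ClimatologyRegressor",
    "climatology_predict",
    "evaluate_forecast",
    "rolling_forecast",
    "WEEKS_PER_YEAR",
]

WEEKS_PER_YEAR = 52


class Regressor(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Regressor": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class LaggedDataset:
    """Per-sample lagged features and targets with (year, week) labels."""

    X: np.ndarray  # (n_samples, k)
    y: np.ndarray  # (n_samples,)
    labels: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.y)


def _validated_years(weekly_gdu_by_year: Mapping[int, Sequence[float]]) -> list[int]:
    years = sorted(weekly_gdu_by_year)
    for y in years:
        if len(weekly_gdu_by_year[y]) != WEEKS_PER_YEAR:
            raise ValueError(
                f"year {y}: expected {WEEKS_PER_YEAR} weekly values, "
                f"got {len(weekly_gdu_by_year[y])}"
            )
    return years


def build_lagged_dataset(
    weekly_gdu_by_year: Mapping[int, Sequence[float]], k: int
) -> LaggedDataset:
    """One sample per (year, week) with the same week of the ``k`` prior years.

    Chronological order (year-major, then week) is preserved.  The first
    ``k`` years supply features only, so ``len == 52 · (n_years − k)``.
    """
    if k < 1:
        raise ValueError("lag k must be >= 1")
    years = _validated_years(weekly_gdu_by_year)
    if len(years) < k + 1:
        raise ValueError(f"need at least {k + 1} complete years for lag {k}")
    X, y, labels = [], [], []
    for year in years[k:]:
        for w in range(WEEKS_PER_YEAR):
            X.append([weekly_gdu_by_year[year - lag][w] for lag in range(k, 0, -1)])
            y.append(weekly_gdu_by_year[year][w])
            labels.append((year, w + 1))
    return LaggedDataset(X=np.asarray(X, float), y=np.asarray(y, float), labels=labels)


class ClimatologyRegressor:
    """Baseline predictor: mean of the lagged same-week values."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClimatologyRegressor":
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] == 0:
            raise ValueError("empty feature vectors")
        return X.mean(axis=1)


def climatology_predict(features: Sequence[float]) -> float:
    """Mean of the lagged values (the climatology baseline, one sample)."""
    features = np.asarray(features, float)
    if features.size == 0:
        raise ValueError("empty feature vector")
    return float(features.mean())


def evaluate_forecast(
    predictions: Sequence[float], actuals: Sequence[float]
) -> dict[str, Optional[float]]:
    """RMSE, MAE and Pearson correlation of a forecast.

    Correlation is reported as ``None`` when either series has zero
    variance (undefined rather than silently zero).
    """
    p = np.asarray(predictions, float)
    a = np.asarray(actuals, float)
    if p.shape != a.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("predictions and actuals must be equal-length 1-d, length >= 2")
    err = p - a
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.std(p) == 0 or np.std(a) == 0:
        corr: Optional[float] = None
    else:
        corr = float(np.corrcoef(p, a)[0, 1])
    return {"rmse": rmse, "mae": mae, "correlation": corr}


def rolling_forecast(
    weekly_gdu_by_year: Mapping[int, Sequence[float]],
    k: int,
    horizon_weeks: int,
    regressor: Optional[Regressor] = None,
    label: str = "forecast",
) -> GduScenario:
    """Forecast the next ``horizon_weeks`` weeks, rolling into a second year.

    The regressor is fit on the full lagged history, used to predict the
    first unseen year week by week, and — when the horizon exceeds 52
    weeks — the predicted year joins the history to predict the opening
    weeks of the year after (so second-year forecasts feed on first-year
    predictions).
    """
    if horizon_weeks < 1:
        raise ValueError("horizon_weeks must be >= 1")
    if horizon_weeks > 2 * WEEKS_PER_YEAR:
        raise ValueError(f"horizon_weeks > {2 * WEEKS_PER_YEAR} not supported")
    history = {y: list(map(float, v)) for y, v in weekly_gdu_by_year.items()}
    years = _validated_years(history)
    reg = regressor if regressor is not None else ClimatologyRegressor()
    train = build_lagged_dataset(history, k)
    reg.fit(train.X, train.y)

    def predict_year(hist: Mapping[int, Sequence[float]], target_year: int) -> list[float]:
        X = np.asarray(
            [
                [hist[target_year - lag][w] for lag in range(k, 0, -1)]
                for w in range(WEEKS_PER_YEAR)
            ],
            float,
        )
        return [float(v) for v in np.asarray(reg.predict(X)).ravel()]

    first_year = years[-1] + 1
    out = predict_year(history, first_year)
    if horizon_weeks > WEEKS_PER_YEAR:
        history[first_year] = out
        out = out + predict_year(history, first_year + 1)
    return GduScenario(label=label, weekly_gdu=[max(0.0, v) for v in out[:horizon_weeks]])
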