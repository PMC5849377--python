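"""Model validation: lagged Pearson correlation and ROC/AUC analysis.

The exposure–outcome convention throughout is that a predictor observed on
day ``t`` is compared against hospitalizations on day ``t + lag`` for lags
of 0–3 days, i.e. from the day of exposure up to three days later.

For discrimination, daily counts are dichotomized at a cutoff (default:
positive class = more than 2 hospitalizations) and each continuous
predictor (PM10, NO2 and the fuzzy model's prediction) is scored by the
area under the ROC curve, which equals the Mann–Whitney probability that a
randomly chosen positive day outranks a randomly chosen negative day (ties
counted one half). 95% confidence intervals use the closed-form
Hanley–McNeil standard error by default; the DeLong covariance estimator is
available as an option.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .model import predict_series

logger = logging.getLogger(__name__)

__all__ = [
    "lag_align",
    "pearson_with_p",
    "dichotomize",
    "roc_auc_ci",
    "validate",
    "ValidationReport",
    "LagCorrelation",
    "RocResult",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"


def lag_align(x: np.ndarray, y: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair ``x`` at day t with ``y`` at day t+lag, dropping missing pairs.

    Returns ``(x_pairs, y_pairs, n_dropped)`` where ``n_dropped`` counts
    pairs removed because either member was missing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays on the same calendar")
    if lag < 0:
        raise ValueError(f"lag must be non-negative, got {lag}")
    if lag >= len(x):
        raise ValueError(f"lag {lag} >= series length {len(x)}")
    xs = x[: len(x) - lag]
    ys = y[lag:]
    keep = ~(np.isnan(xs) | np.isnan(ys))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("lag_align(lag=%d): dropped %d incomplete pairs", lag, n_dropped)
    return xs[keep], ys[keep], n_dropped


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-test p-value.

    The p-value comes from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of
    freedom (scipy's default exact beta form, equivalent for finite r).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    for name, arr in (("x", x), ("y", y)):
        if np.ptp(arr) == 0.0:
            raise ValueError(f"correlation undefined: series {name!r} is constant")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def dichotomize(counts: np.ndarray, cutoff: int = 2, strict: bool = True) -> np.ndarray:
    """Binary outcome from daily counts: positive iff count > cutoff.

    ``strict=False`` switches to count >= cutoff. The default reads "up to
    ``cutoff`` hospitalizations" as delimiting the negative class. NaNs
    propagate.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be >= 0, got {cutoff}")
    counts = np.asarray(counts, dtype=float)
    out = np.where(np.isnan(counts), np.nan,
                   (counts > cutoff) if strict else (counts >= cutoff))
    pos = np.nansum(out)
    n = np.sum(~np.isnan(counts))
    logger.info("dichotomize(cutoff=%d): %d positive / %d days", cutoff, int(pos), int(n))
    return out


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form AUC standard error under the exponential approximation."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc)
           + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(predictor: np.ndarray, outcome: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong standard error via midrank placements."""
    pos = predictor[outcome == 1]
    neg = predictor[outcome == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    # placement values: V10_i = P(pos_i > random neg), V01_j = P(random pos > neg_j)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    var_pos = np.var(v10, ddof=1) / m if m > 1 else 0.0
    var_neg = np.var(v01, ddof=1) / n if n > 1 else 0.0
    var = var_pos + var_neg
    return auc, float(np.sqrt(max(var, 0.0)))


def roc_auc_ci(predictor: np.ndarray, outcome: np.ndarray,
               ci_method: str = "hanley", alpha: float = 0.05,
               ) -> tuple[float, float, float]:
    """AUC of a continuous predictor with a (1−alpha) confidence interval.

    The AUC is the trapezoidal ROC integral, identical to the Mann–Whitney
    U/(n₁·n₀) statistic with ties counted ½. The CI is clipped to [0, 1].
    """
    predictor = np.asarray(predictor, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    keep = ~(np.isnan(predictor) | np.isnan(outcome))
    predictor, outcome = predictor[keep], outcome[keep]
    if not np.all(np.isfinite(predictor)):
        raise ValueError("predictor contains non-finite values")
    n_pos = int((outcome == 1).sum())
    n_neg = int((outcome == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"need both outcome classes (got {n_pos} positive, {n_neg} negative)")

    if ci_method == "delong":
        auc, se = _delong_se(predictor, outcome)
    elif ci_method == "hanley":
        auc = float(roc_auc_score(outcome, predictor))
        se = _hanley_mcneil_se(auc, n_pos, n_neg)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r} (use 'hanley' or 'delong')")

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), float(lo), float(hi)


@dataclass
class LagCorrelation:
    lag: int
    pearson_r: float
    p_value: float
    n_pairs: int


@dataclass
class RocResult:
    predictor: str
    lag: int
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass
class ValidationReport:
    """Per-lag correlations and per-predictor ROC results at a count cutoff."""

    cutoff: int
    ci_method: str
    correlations: list = field(default_factory=list)
    roc: list = field(default_factory=list)
    schema_version: str = REPORT_SCHEMA_VERSION

    def correlation(self, lag: int) -> LagCorrelation:
        return next(c for c in self.correlations if c.lag == lag)

    def roc_result(self, predictor: str, lag: int) -> RocResult:
        return next(r for r in self.roc if r.predictor == predictor and r.lag == lag)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "cutoff": self.cutoff,
            "ci_method": self.ci_method,
            "correlations": [dataclasses.asdict(c) for c in self.correlations],
            "roc": [dataclasses.asdict(r) for r in self.roc],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, spec: dict) -> "ValidationReport":
        return cls(
            cutoff=int(spec["cutoff"]),
            ci_method=spec["ci_method"],
            correlations=[LagCorrelation(**c) for c in spec["correlations"]],
            roc=[RocResult(**r) for r in spec["roc"]],
            schema_version=spec.get("schema_version", REPORT_SCHEMA_VERSION),
        )

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls.from_dict(json.loads(text))

    def to_frame(self) -> pd.DataFrame:
        """ROC results as a tidy DataFrame (one row per predictor × lag)."""
        return pd.DataFrame([dataclasses.asdict(r) for r in self.roc])


def validate(series: pd.DataFrame, fis, lags=(0, 1, 2, 3), cutoff: int = 2,
             ci_method: str = "hanley",
             predictors=("pm10", "no2", "model_prediction")) -> ValidationReport:
    """Run the full validation on an observed daily series.

    Computes model predictions, then for each lag the Pearson correlation
    between prediction at day t and the observed count at day t+lag, and the
    ROC AUC (with CI) of each predictor against the dichotomized counts.
    Deterministic given its inputs.
    """
    if "hospitalizations" not in series.columns:
        raise ValueError("series lacks the observed 'hospitalizations' column")
    counts = series["hospitalizations"].to_numpy(dtype=float)
    finite = counts[~np.isnan(counts)]
    if np.any(finite < 0) or np.any(finite != np.round(finite)):
        raise ValueError("hospitalization counts must be non-negative integers")

    preds = predict_series(fis, series).to_numpy()
    outcome = dichotomize(counts, cutoff=cutoff)
    pos = np.nansum(outcome)
    if pos == 0 or pos == np.sum(~np.isnan(outcome)):
        warnings.warn("dichotomized outcome has a single class; ROC results omitted")

    columns = {"pm10": series["pm10"].to_numpy(dtype=float) if "pm10" in series else None,
               "no2": series["no2"].to_numpy(dtype=float) if "no2" in series else None,
               "model_prediction": preds}

    report = ValidationReport(cutoff=cutoff, ci_method=ci_method)
    for lag in lags:
        xp, yp, _ = lag_align(preds, counts, lag)
        r, p = pearson_with_p(xp, yp)
        report.correlations.append(LagCorrelation(lag=int(lag), pearson_r=r, p_value=p, n_pairs=len(xp)))
        for name in predictors:
            col = columns.get(name)
            if col is None:
                continue
            xs, ys, _ = lag_align(col, outcome, lag)
            n_pos, n_neg = int((ys == 1).sum()), int((ys == 0).sum())
            if n_pos == 0 or n_neg == 0:
                continue
            auc, lo, hi = roc_auc_ci(xs, ys, ci_method=ci_method)
            report.roc.append(RocResult(predictor=name, lag=int(lag), auc=auc,
                                        ci_low=lo, ci_high=hi, n_pos=n_pos, n_neg=n_neg))
    return report
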