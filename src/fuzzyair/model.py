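"""The pediatric respiratory-hospitalization fuzzy model.

Four daily inputs — PM10 and NO2 concentrations (µg/m³), air temperature
(°C) and wind speed (m/s) — each described by two complementary trapezoidal
terms, drive a five-term output (expected hospitalizations of children up
to 10 years, counts 0–9) through a 16-rule Mamdani base covering the full
2×2×2×2 factorial of input terms. High pollutant levels raise the predicted
count; higher temperature and stronger wind are protective (better
dispersion conditions).

The default membership breakpoints are a calibration choice, not measured
constants: they are fixed so that a PM10 reading of 24 µg/m³ is 0.55
"acceptable" / 0.45 "unacceptable" (the crossover midpoint sits at
25 µg/m³), so that each variable's two terms form a partition of unity
over the observed data ranges, and so that the five output terms have equal
mass, which keeps the defuzzified prediction monotone in each pollutant.
Every breakpoint can be overridden through configuration.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .fuzzy import (
    FuzzyInferenceSystem,
    FuzzyRule,
    LinguisticVariable,
    trapezoid,
    triangle,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BREAKPOINTS",
    "RULE_TABLE",
    "TERM_LABELS",
    "build_hospitalization_fis",
    "predict_series",
    "EXPOSURE_COLUMNS",
]

EXPOSURE_COLUMNS = ["pm10", "no2", "temperature", "wind"]

#: Default breakpoints: {variable: (domain, {term: breakpoints})}.
#: Two-term inputs share interior breakpoints so memberships sum to one.
DEFAULT_BREAKPOINTS: dict = {
    "pm10": ((0.0, 150.0), {
        "acceptable": (0.0, 0.0, 15.0, 35.0),
        "unacceptable": (15.0, 35.0, 150.0, 150.0),
    }),
    "no2": ((0.0, 130.0), {
        "acceptable": (0.0, 0.0, 40.0, 80.0),
        "unacceptable": (40.0, 80.0, 130.0, 130.0),
    }),
    "temperature": ((0.0, 45.0), {
        "low": (0.0, 0.0, 22.0, 32.0),
        "high": (22.0, 32.0, 45.0, 45.0),
    }),
    "wind": ((0.0, 5.0), {
        "weak": (0.0, 0.0, 1.8, 2.8),
        "strong": (1.8, 2.8, 5.0, 5.0),
    }),
    "hospitalizations": ((0.0, 9.0), {
        # equal-width, touching terms: with matched term masses the Mamdani
        # centroid is non-decreasing along pollutant sweeps at fixed
        # temperature/wind plateaus, which unequal-width terms break
        "L": (0.0, 0.9, 1.8),
        "ML": (1.8, 2.7, 3.6),
        "M": (3.6, 4.5, 5.4),
        "MH": (5.4, 6.3, 7.2),
        "H": (7.2, 8.1, 9.0, 9.0),
    }),
}

#: Printable legend for the output terms.
TERM_LABELS = {"L": "low", "ML": "medium-low", "M": "medium", "MH": "medium-high", "H": "high"}

#: The canonical 16-rule base: (pm10, temperature, no2, wind) -> consequent.
#: Rules enumerate the full factorial of the two terms per input; the
#: consequent severity rises along the acceptable -> unacceptable direction,
#: with high temperature and strong wind acting protectively.
RULE_TABLE: list = [
    (("acceptable", "high", "acceptable", "strong"), "L"),
    (("acceptable", "high", "acceptable", "weak"), "L"),
    (("acceptable", "low", "acceptable", "strong"), "L"),
    (("acceptable", "low", "acceptable", "weak"), "L"),
    (("acceptable", "high", "unacceptable", "strong"), "ML"),
    (("acceptable", "high", "unacceptable", "weak"), "M"),
    (("acceptable", "low", "unacceptable", "strong"), "M"),
    (("acceptable", "low", "unacceptable", "weak"), "M"),
    (("unacceptable", "high", "acceptable", "strong"), "ML"),
    (("unacceptable", "high", "acceptable", "weak"), "ML"),
    (("unacceptable", "low", "acceptable", "strong"), "M"),
    (("unacceptable", "low", "acceptable", "weak"), "M"),
    (("unacceptable", "high", "unacceptable", "strong"), "M"),
    (("unacceptable", "high", "unacceptable", "weak"), "MH"),
    (("unacceptable", "low", "unacceptable", "strong"), "MH"),
    (("unacceptable", "low", "unacceptable", "weak"), "H"),
]


def _make_mf(points):
    if len(points) == 3:
        return triangle(*points)
    return trapezoid(*points)


def build_hospitalization_fis(config: dict | None = None,
                              defuzz_resolution: int = 1001) -> FuzzyInferenceSystem:
    """Construct the 16-rule hospitalization model.

    Parameters
    ----------
    config
        Optional overrides, same nesting as :data:`DEFAULT_BREAKPOINTS`:
        ``{variable: {"domain": (lo, hi), "terms": {term: breakpoints}}}``.
        Only the entries present are overridden.
    defuzz_resolution
        Number of uniform output-grid points for centroid defuzzification.

    Returns
    -------
    FuzzyInferenceSystem
        Deterministically built system with 4 two-term inputs, a five-term
        output and the canonical 16 rules, each with weight 1.
    """
    config = config or {}
    variables: dict[str, LinguisticVariable] = {}
    for name, (domain, terms) in DEFAULT_BREAKPOINTS.items():
        override = config.get(name, {})
        domain = tuple(override.get("domain", domain))
        term_pts = {t: override.get("terms", {}).get(t, pts) for t, pts in terms.items()}
        try:
            mfs = {t: _make_mf(pts) for t, pts in term_pts.items()}
        except ValueError as err:
            raise ValueError(f"invalid breakpoints for variable {name!r}: {err}") from err
        variables[name] = LinguisticVariable(name=name, domain=domain, terms=mfs)

    rules = [
        FuzzyRule(
            antecedent={
                "pm10": pm, "temperature": temp, "no2": no2, "wind": wind,
            },
            consequent=cons,
            weight=1.0,
        )
        for (pm, temp, no2, wind), cons in RULE_TABLE
    ]
    return FuzzyInferenceSystem(
        inputs=[variables[n] for n in EXPOSURE_COLUMNS],
        output=variables["hospitalizations"],
        rules=rules,
        defuzz_resolution=defuzz_resolution,
    )


def predict_series(fis: FuzzyInferenceSystem, series: pd.DataFrame) -> pd.Series:
    """Predict one daily hospitalization count per row of ``series``.

    ``series`` must carry the four exposure columns. Rows with any missing
    exposure yield a missing (NaN) prediction — no imputation is attempted,
    so downstream validation sees only genuinely observed days.
    """
    if series.empty:
        raise ValueError("input series is empty")
    missing_cols = [c for c in EXPOSURE_COLUMNS if c not in series.columns]
    if missing_cols:
        raise ValueError(f"series is missing exposure columns: {missing_cols}")

    values = {c: series[c].to_numpy(dtype=float) for c in EXPOSURE_COLUMNS}
    preds = fis.infer_batch(values)
    n_missing = int(np.isnan(preds).sum())
    if n_missing:
        logger.info("predict_series: %d of %d rows had missing exposures", n_missing, len(preds))
    return pd.Series(preds, index=series.index, name="predicted")
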