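"""Generic Mamdani fuzzy-inference engine.

Implements the classical "maximum and minimum" Mamdani pipeline: crisp
inputs are fuzzified through piecewise-linear membership functions, rule
antecedents are combined with ``min``, consequents are clipped (min
implication) and aggregated with ``max``, and the aggregated fuzzy output
set is collapsed to a crisp value by its centroid.

All membership functions are trapezoids ``(a, b, c, d)`` — membership is 0
below ``a``, rises linearly on ``[a, b]``, is 1 on ``[b, c]``, falls
linearly on ``[c, d]`` and is 0 above ``d``. Triangles are degenerate
trapezoids with ``b == c``. Shoulder functions (saturating at a domain
edge) are trapezoids with ``a == b`` or ``c == d``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "MembershipFunction",
    "LinguisticVariable",
    "FuzzyRule",
    "FuzzyInferenceSystem",
    "NoRuleFiredWarning",
    "trapezoid",
    "triangle",
    "defuzzify_centroid",
]


class NoRuleFiredWarning(UserWarning):
    """Emitted when no rule activates and the midpoint fallback is used."""


@dataclass(frozen=True)
class MembershipFunction:
    """A trapezoidal (or triangular) fuzzy set over one variable's domain.

    Parameters
    ----------
    a, b, c, d
        Non-decreasing breakpoints in the variable's physical units.
        ``b == c`` yields a triangle.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        pts = (self.a, self.b, self.c, self.d)
        if not all(np.isfinite(pts)):
            raise ValueError(f"membership breakpoints must be finite, got {pts}")
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"membership breakpoints must be non-decreasing, got {pts}")

    @property
    def shape(self) -> str:
        return "triangle" if self.b == self.c else "trapezoid"

    @property
    def params(self) -> tuple[float, ...]:
        if self.shape == "triangle":
            return (self.a, self.b, self.d)
        return (self.a, self.b, self.c, self.d)

    def __call__(self, x):
        """Evaluate membership at ``x`` (scalar or array) -> degree in [0, 1]."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("membership evaluated at non-finite input")
        a, b, c, d = self.a, self.b, self.c, self.d
        rise = (x - a) / (b - a) if b > a else np.ones_like(x)
        fall = (d - x) / (d - c) if d > c else np.ones_like(x)
        mu = np.minimum(np.minimum(rise, 1.0), fall)
        mu = np.where((x < a) | (x > d), 0.0, np.clip(mu, 0.0, 1.0))
        return float(mu) if mu.ndim == 0 else mu

    def to_dict(self) -> dict:
        return {"shape": self.shape, "params": list(self.params)}

    @classmethod
    def from_dict(cls, spec: dict) -> "MembershipFunction":
        params = [float(p) for p in spec["params"]]
        shape = spec.get("shape", "trapezoid" if len(params) == 4 else "triangle")
        if shape == "triangle":
            if len(params) != 3:
                raise ValueError(f"triangle needs 3 breakpoints, got {params}")
            return triangle(*params)
        if len(params) != 4:
            raise ValueError(f"trapezoid needs 4 breakpoints, got {params}")
        return cls(*params)


def trapezoid(a: float, b: float, c: float, d: float) -> MembershipFunction:
    return MembershipFunction(a, b, c, d)


def triangle(a: float, b: float, c: float) -> MembershipFunction:
    """Triangle (a, b, c) as the degenerate trapezoid (a, b, b, c)."""
    return MembershipFunction(a, b, b, c)


@dataclass(frozen=True)
class LinguisticVariable:
    """A named variable with a closed physical domain and its fuzzy terms."""

    name: str
    domain: tuple[float, float]
    terms: dict[str, MembershipFunction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"{self.name}: invalid domain {self.domain}")
        if len(self.terms) != len(set(self.terms)):
            raise ValueError(f"{self.name}: duplicate term names")

    def clamp(self, x):
        """Clamp ``x`` into the domain, warning when clipping occurs.

        Sensor series legitimately exceed nominal scales, so out-of-domain
        values are pulled to the nearest edge rather than rejected.
        """
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"{self.name}: non-finite input value")
        lo, hi = self.domain
        if np.any((x < lo) | (x > hi)):
            logger.warning("%s: input outside domain [%g, %g]; clamped", self.name, lo, hi)
        out = np.clip(x, lo, hi)
        return float(out) if out.ndim == 0 else out

    def fuzzify(self, x) -> dict:
        """Map a crisp value (or array) to one membership degree per term."""
        x = self.clamp(x)
        return {t: mf(x) for t, mf in self.terms.items()}

    def grid(self, resolution: int) -> np.ndarray:
        return np.linspace(self.domain[0], self.domain[1], resolution)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "domain": list(self.domain),
            "terms": {t: mf.to_dict() for t, mf in self.terms.items()},
        }

    @classmethod
    def from_dict(cls, spec: dict) -> "LinguisticVariable":
        return cls(
            name=spec["name"],
            domain=tuple(float(v) for v in spec["domain"]),
            terms={t: MembershipFunction.from_dict(m) for t, m in spec["terms"].items()},
        )


@dataclass(frozen=True)
class FuzzyRule:
    """IF (var1 is term1) AND ... THEN (output is consequent), with a weight."""

    antecedent: dict  # input variable name -> term name
    consequent: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"rule weight must be in (0, 1], got {self.weight}")

    def activation(self, fuzzified: dict) -> float:
        """Firing degree: weight × min over antecedent term memberships."""
        degrees = []
        for var, term in self.antecedent.items():
            if var not in fuzzified:
                raise KeyError(f"rule references unknown variable {var!r}")
            if term not in fuzzified[var]:
                raise KeyError(f"rule references unknown term {term!r} of {var!r}")
            degrees.append(fuzzified[var][term])
        return self.weight * min(degrees)

    def to_dict(self) -> dict:
        return {"antecedent": dict(self.antecedent), "consequent": self.consequent, "weight": self.weight}

    @classmethod
    def from_dict(cls, spec: dict) -> "FuzzyRule":
        return cls(dict(spec["antecedent"]), spec["consequent"], float(spec.get("weight", 1.0)))


def defuzzify_centroid(grid: np.ndarray, curve: np.ndarray) -> float:
    """Centroid of an aggregated membership curve sampled on a uniform grid.

    Integrals are evaluated with the trapezoidal rule, which is exact for the
    piecewise-linear curves Mamdani aggregation produces (up to the cells
    containing kinks), so the result converges rapidly with grid resolution.

    Raises
    ------
    ValueError
        If the curve has zero total mass (no rule fired).
    """
    grid = np.asarray(grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if grid.shape != curve.shape or grid.size < 2:
        raise ValueError("grid and curve must be 1-D arrays of equal length >= 2")
    mass = np.trapezoid(curve, grid)
    if mass <= 0.0:
        raise ValueError("aggregated curve has zero mass: no rule fired")
    return float(np.trapezoid(grid * curve, grid) / mass)


@dataclass
class FuzzyInferenceSystem:
    """A complete Mamdani system: inputs, output, rule base, defuzzification grid."""

    inputs: list
    output: LinguisticVariable
    rules: list
    defuzz_resolution: int = 1001

    def __post_init__(self) -> None:
        if self.defuzz_resolution < 2:
            raise ValueError("defuzz_resolution must be >= 2")
        names = [v.name for v in self.inputs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate input variable names")
        self._validate_rules()

    def _validate_rules(self) -> None:
        by_name = {v.name: v for v in self.inputs}
        for i, rule in enumerate(self.rules):
            for var, term in rule.antecedent.items():
                if var not in by_name:
                    raise ValueError(f"rule {i}: unknown input variable {var!r}")
                if term not in by_name[var].terms:
                    raise ValueError(f"rule {i}: unknown term {term!r} of {var!r}")
            if rule.consequent not in self.output.terms:
                raise ValueError(f"rule {i}: unknown output term {rule.consequent!r}")

    @property
    def input_names(self) -> list:
        return [v.name for v in self.inputs]

    def fuzzify(self, values: dict) -> dict:
        """Fuzzify one crisp value per input variable."""
        missing = [v.name for v in self.inputs if v.name not in values]
        if missing:
            raise KeyError(f"missing input values for {missing}")
        return {v.name: v.fuzzify(values[v.name]) for v in self.inputs}

    def aggregate(self, activations, grid: np.ndarray) -> np.ndarray:
        """Pointwise max over rules of consequents clipped at their activation."""
        curve = np.zeros_like(grid, dtype=float)
        fired = False
        for term, degree in activations:
            if degree <= 0.0:
                continue
            fired = True
            curve = np.maximum(curve, np.minimum(degree, self.output.terms[term](grid)))
        if not fired:
            raise ValueError("no rule fired")
        return curve

    def infer(self, values: dict) -> float:
        """Crisp output for one input point (fuzzify → min/max → centroid)."""
        batch = self.infer_batch({k: np.asarray([v], dtype=float) for k, v in values.items()})
        return float(batch[0])

    def infer_batch(self, values: dict) -> np.ndarray:
        """Vectorized inference over aligned arrays of input values.

        Rows where any input is NaN yield NaN. Non-NaN inputs must be finite.
        """
        names = self.input_names
        missing = [n for n in names if n not in values]
        if missing:
            raise KeyError(f"missing input values for {missing}")
        cols = {n: np.asarray(values[n], dtype=float).ravel() for n in names}
        n = len(next(iter(cols.values())))
        if any(len(c) != n for c in cols.values()):
            raise ValueError("input arrays must have equal length")
        ok = np.ones(n, dtype=bool)
        for c in cols.values():
            ok &= ~np.isnan(c)
            if np.any(np.isinf(c)):
                raise ValueError("non-finite (infinite) input value")

        out = np.full(n, np.nan)
        if not np.any(ok):
            return out

        by_name = {v.name: v for v in self.inputs}
        fuzz = {
            name: {t: np.atleast_1d(d) for t, d in by_name[name].fuzzify(cols[name][ok]).items()}
            for name in names
        }
        # activation matrix: (n_ok, n_rules)
        act = np.empty((int(ok.sum()), len(self.rules)))
        for j, rule in enumerate(self.rules):
            deg = np.minimum.reduce([fuzz[var][term] for var, term in rule.antecedent.items()])
            act[:, j] = rule.weight * deg

        grid = self.output.grid(self.defuzz_resolution)
        cons = np.stack([self.output.terms[r.consequent](grid) for r in self.rules])  # (R, G)
        n_ok = act.shape[0]
        mass = np.empty(n_ok)
        moment = np.empty(n_ok)
        # chunked so the (rows, R, G) intermediate stays small
        chunk = max(1, 4_000_000 // (len(self.rules) * len(grid)))
        for start in range(0, n_ok, chunk):
            sl = slice(start, start + chunk)
            curves = np.max(np.minimum(act[sl, :, None], cons[None, :, :]), axis=1)
            mass[sl] = np.trapezoid(curves, grid, axis=1)
            moment[sl] = np.trapezoid(grid * curves, grid, axis=1)
        dead = mass <= 0.0
        centroids = np.empty(n_ok)
        if np.any(~dead):
            centroids[~dead] = moment[~dead] / mass[~dead]
        if np.any(dead):
            # Unreachable under partition-of-unity term sets; defensive fallback
            # for user-supplied configurations with coverage gaps.
            warnings.warn(
                "no rule fired for some inputs; returning output-domain midpoint",
                NoRuleFiredWarning,
                stacklevel=2,
            )
            centroids[dead] = 0.5 * (self.output.domain[0] + self.output.domain[1])
        out[ok] = centroids
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "inputs": [v.to_dict() for v in self.inputs],
            "output": self.output.to_dict(),
            "rules": [r.to_dict() for r in self.rules],
            "defuzz_resolution": self.defuzz_resolution,
        }

    @classmethod
    def from_dict(cls, spec: dict) -> "FuzzyInferenceSystem":
        return cls(
            inputs=[LinguisticVariable.from_dict(v) for v in spec["inputs"]],
            output=LinguisticVariable.from_dict(spec["output"]),
            rules=[FuzzyRule.from_dict(r) for r in spec["rules"]],
            defuzz_resolution=int(spec.get("defuzz_resolution", 1001)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FuzzyInferenceSystem":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FuzzyInferenceSystem":
        return cls.from_dict(json.loads(text))
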