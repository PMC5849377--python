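"""Independent brute-force/closed-form oracles used by the test suite.

Kept deliberately free of the package's numerical code paths: centroids are
piecewise-polynomial closed forms over explicit segment lists, and AUC is
literal Mann–Whitney pair counting.
"""

import numpy as np


def clipped_trapezoid_centroid(a, b, c, d, alpha):
    """Exact centroid of min(trapezoid(a,b,c,d), alpha) for alpha in (0, 1].

    The clipped set is itself a trapezoid with plateau height ``alpha``
    between ``a + alpha*(b-a)`` and ``d - alpha*(d-c)``; the centroid follows
    from exact segment-wise integrals of mu and x*mu (linear mu per segment).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    ap = a + alpha * (b - a)
    dp = d - alpha * (d - c)
    xs = [a, ap, dp, d]
    mus = [0.0 if b > a else alpha, alpha, alpha, 0.0 if d > c else alpha]
    mass = 0.0
    moment = 0.0
    for (x0, x1), (m0, m1) in zip(zip(xs, xs[1:]), zip(mus, mus[1:])):
        if x1 <= x0:
            continue
        slope = (m1 - m0) / (x1 - x0)
        intercept = m0 - slope * x0
        mass += 0.5 * (m0 + m1) * (x1 - x0)
        moment += slope * (x1**3 - x0**3) / 3.0 + intercept * (x1**2 - x0**2) / 2.0
    if mass <= 0:
        raise ValueError("degenerate clipped set")
    return moment / mass


def pairwise_auc(scores, labels):
    """Mann–Whitney AUC by explicit pair enumeration, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def max_union_centroid(term_fns, degrees, lo, hi, n=200_001):
    """Brute-force centroid of the max of clipped membership functions.

    Very fine midpoint grid, independent of the package's trapezoidal-rule
    defuzzifier.
    """
    x = np.linspace(lo, hi, n)
    x = 0.5 * (x[1:] + x[:-1])
    curve = np.zeros_like(x)
    for fn, deg in zip(term_fns, degrees):
        curve = np.maximum(curve, np.minimum(deg, fn(x)))
    return float(np.sum(x * curve) / np.sum(curve))
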