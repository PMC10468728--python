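"""Accuracy metrics, confidence intervals, and the true lethal fraction.

The "true proportion of lethals" of a gamma DFE is the upper tail mass
of the selection-coefficient distribution beyond a lethality threshold
``s_star`` (default 1: a homozygote is inviable).  With effects sampled
on the population scale ``S = 2*Ne*s`` from Gamma(shape beta,
mean s_mean) this is a regularised upper incomplete gamma function.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import special, stats

__all__ = ["lethal_fraction", "inaccuracy", "ci"]


def lethal_fraction(
    s_mean: float, beta: float, ne: float, s_star: float = 1.0
):
    """P(s >= s_star) for s ~ Gamma(shape beta, mean s_mean / (2 Ne)).

    ``s_star = 1`` means a homozygous carrier has fitness <= 0.  The
    threshold is exposed because "lethal" conventions differ (e.g.
    s >= 1 versus S >> 2 Ne); the value is a lower bound on the
    proportion of strongly deleterious mutations.
    """
    s_mean = np.asarray(s_mean, dtype=float)
    if np.any(s_mean <= 0) or beta <= 0 or ne <= 0 or s_star <= 0:
        raise ValueError("all parameters must be positive")
    out = special.gammaincc(beta, 2.0 * ne * beta * s_star / s_mean)
    return float(out) if out.ndim == 0 else out


def inaccuracy(estimate: float, truth: float) -> float:
    """log2(estimate / truth); zero means a perfectly accurate estimate."""
    if estimate <= 0 or truth <= 0:
        raise ValueError("estimate and truth must be positive")
    return math.log2(estimate / truth)


def ci(values: Sequence[float]) -> tuple[float, float]:
    """Mean and t-interval half-width of replicate values.

    Half-width is ``t_{0.975, n-1} * sd / sqrt(n)`` with the sample
    standard deviation (ddof = 1).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two values for a confidence interval")
    z = stats.t.ppf(0.975, n - 1)
    return float(values.mean()), float(z * values.std(ddof=1) / math.sqrt(n))
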