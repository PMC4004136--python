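"""Maximum-likelihood estimation of a discrete power-law exponent.

Degree sequences of follower graphs are modeled as a discrete power law,
P(k) = k^(-alpha) / zeta(alpha, xmin) for integer k >= xmin.  Two
estimators are provided: the exact discrete MLE (numerical maximization of
the zeta likelihood — use this one) and the closed-form continuous
approximation alpha = 1 + n / sum(ln(k / (xmin - 1/2))), which is cheap
but noticeably biased when xmin is 1 or 2.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

__all__ = ["fit_discrete_power_law", "fit_power_law_approx"]


def _prepare(values, xmin: int) -> np.ndarray:
    if xmin < 1:
        raise ValueError("xmin must be >= 1")
    data = np.asarray(values, dtype=float)
    tail = data[data >= xmin]
    if tail.size < 2:
        raise ValueError("need at least 2 observations at or above xmin")
    return tail


def fit_discrete_power_law(values, xmin: int = 1) -> float:
    """Exact discrete MLE of the power-law exponent, tail at ``xmin``.

    Maximizes the zeta-normalized log-likelihood
    ``-alpha * sum(ln k) - n * ln(zeta(alpha, xmin))`` over alpha in
    (1, 10].  Values below ``xmin`` are discarded before fitting.
    """
    tail = _prepare(values, xmin)
    log_sum = np.sum(np.log(tail))
    n = tail.size

    def negative_log_likelihood(alpha: float) -> float:
        return alpha * log_sum + n * np.log(zeta(alpha, xmin))

    result = minimize_scalar(negative_log_likelihood, bounds=(1.01, 10.0), method="bounded")
    return float(result.x)


def fit_power_law_approx(values, xmin: int = 1) -> float:
    """Closed-form continuous-approximation MLE; fast, biased at small xmin."""
    tail = _prepare(values, xmin)
    return 1.0 + tail.size / np.sum(np.log(tail / (xmin - 0.5)))
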