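"""Capture-recapture estimators of the number of genuine binding regions.

The observed merged regions are the *captured* part of an unknown
population of N genuine regions; the pivotal frequencies f_1..f_k play the
role of capture-count frequencies (f_i = regions captured by exactly i
datasets). Four frequency-based estimators of N are provided:

* Chao's lower-bound estimator         E_C  = n + f1^2 / (2 f2)
* Lanumteang-Bohning's estimator       E_LB = n + 3 f1^3 f3 / (4 f2^3)
* Zelterman's estimator                E_Z  = n / (1 - exp(-2 f2 / f1))
* Zero-truncated Poisson ML estimator  E_ML = n / (1 - exp(-lambda*))

where lambda* maximizes the zero-truncated Poisson log-likelihood

    L(lambda) = log(lambda) * sum_i i*f_i  -  n * log(e^lambda - 1) + const.

The two-sample Chapman (bias-corrected Lincoln-Petersen) estimator

    E_ij = (|D_i|+1)(|D_j|+1) / (|D_i ∩ D_j| + 1) - 1

serves the orphan-removal branch, together with a single-pass leave-one-out
3-sigma outlier filter over the sample of pairwise Chapman estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, DegenerateInputError, UndefinedEstimatorError
from .region_merge import PivotalFrequencies

__all__ = [
    "PopulationEstimate", "ZtpFit",
    "chao", "lanumteang_bohning", "zelterman", "ztp_mle", "chapman",
    "leave_one_out_outliers", "ztp_loglik",
]

# lambda cap: exp(700) is near the float64 overflow ceiling, and any
# realistic mean capture count (<= k datasets) corresponds to tiny lambda.
_LAMBDA_LO = 1e-8
_LAMBDA_HI = 700.0


@dataclass
class PopulationEstimate:
    """A named estimate of the genuine-region count with its inputs."""

    name: str
    value: float
    inputs: dict = field(default_factory=dict)
    flag: str | None = None

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class ZtpFit:
    """Result of the zero-truncated Poisson maximum-likelihood fit."""

    lambda_star: float
    log_likelihood: float
    converged: bool
    iterations: int


def chao(f1: int, f2: int, n: int) -> PopulationEstimate:
    """Chao's estimator: n + f1^2 / (2 f2).

    With no singletons (f1 = 0) the correction term vanishes and the
    estimate is n whatever f2 is; f2 = 0 with f1 > 0 is undefined.
    """
    if f1 == 0:
        return PopulationEstimate(
            "chao", float(n), {"f1": f1, "f2": f2, "n": n},
            flag="no_singletons" if f2 == 0 else None,
        )
    if f2 <= 0:
        raise UndefinedEstimatorError("chao", "f2 = 0 with f1 > 0")
    value = n + f1 ** 2 / (2.0 * f2)
    return PopulationEstimate("chao", value, {"f1": f1, "f2": f2, "n": n})


def lanumteang_bohning(f1: int, f2: int, f3: int, n: int) -> PopulationEstimate:
    """Lanumteang-Bohning's estimator: n + 3 f1^3 f3 / (4 f2^3).

    As with Chao, f1 = 0 (or f3 = 0) kills the correction term and the
    estimate is n; f2 = 0 with a live correction term is undefined.
    """
    inputs = {"f1": f1, "f2": f2, "f3": f3, "n": n}
    if f1 == 0 or f3 == 0:
        return PopulationEstimate(
            "lanumteang_bohning", float(n), inputs,
            flag="no_singletons" if f2 == 0 else None,
        )
    if f2 <= 0:
        raise UndefinedEstimatorError(
            "lanumteang_bohning", "f2 = 0 with f1, f3 > 0")
    value = n + 3.0 * f1 ** 3 * f3 / (4.0 * f2 ** 3)
    return PopulationEstimate("lanumteang_bohning", value, inputs)


def zelterman(f1: int, f2: int, n: int) -> PopulationEstimate:
    """Zelterman's estimator: n / (1 - exp(-2 f2 / f1)).

    At f1 = 0 the exponent diverges and the estimator tends to n; that
    limit is returned with a flag rather than raising.
    """
    if f1 == 0:
        return PopulationEstimate(
            "zelterman", float(n), {"f1": f1, "f2": f2, "n": n},
            flag="limit_f1_zero",
        )
    if f2 <= 0:
        raise UndefinedEstimatorError("zelterman", "f2 = 0 with f1 > 0")
    value = n / (1.0 - math.exp(-2.0 * f2 / f1))
    return PopulationEstimate("zelterman", value, {"f1": f1, "f2": f2, "n": n})


def ztp_loglik(lam: float, freqs: PivotalFrequencies) -> float:
    """Zero-truncated Poisson log-likelihood (up to an additive constant)."""
    if lam <= 0:
        return -np.inf
    # log(e^lam - 1) = lam + log1p(-exp(-lam)), stable for large lam
    log_em1 = lam + math.log1p(-math.exp(-lam)) if lam > 1e-8 else math.log(math.expm1(lam))
    return math.log(lam) * freqs.total_captures - freqs.n * log_em1


def ztp_mle(freqs: PivotalFrequencies,
            tol: float = 1e-10) -> tuple[ZtpFit, PopulationEstimate]:
    """Fit lambda* of the zero-truncated Poisson and estimate N = n/(1-e^-lambda*).

    The stationarity condition of the log-likelihood is the ZTP mean
    equation lambda/(1 - e^-lambda) = (sum_i i f_i)/n, whose left side is
    strictly increasing from 1; a safeguarded bracketing root-finder on
    lambda in [1e-8, 700] is therefore exact and robust. A sample mean
    <= 1 admits no interior maximum (lambda* -> 0) and raises.
    """
    if freqs.n <= 0:
        raise DegenerateInputError("ztp_mle requires n > 0")
    mean = freqs.mean_count
    if mean <= 1.0:
        raise DegenerateInputError(
            f"ztp_mle: sample mean of capture counts is {mean:.6g} <= 1; "
            "the zero-truncated Poisson likelihood has no interior maximum"
        )

    def mean_gap(lam: float) -> float:
        return lam / (-math.expm1(-lam)) - mean

    if mean_gap(_LAMBDA_HI) < 0:
        raise ConvergenceError(
            f"ztp_mle: sample mean {mean:.6g} exceeds the bracketed range"
        )
    sol = optimize.root_scalar(
        mean_gap, bracket=(_LAMBDA_LO, _LAMBDA_HI), method="brentq",
        xtol=tol,
    )
    if not sol.converged:
        raise ConvergenceError(
            "ztp_mle: root finding did not converge", best_iterate=sol.root
        )
    lam = sol.root
    fit = ZtpFit(
        lambda_star=lam,
        log_likelihood=ztp_loglik(lam, freqs),
        converged=True,
        iterations=sol.iterations,
    )
    value = freqs.n / (-math.expm1(-lam))
    est = PopulationEstimate(
        "ztp_ml", value,
        {"f": list(freqs.f), "n": freqs.n, "lambda_star": lam},
    )
    return fit, est


def chapman(size_i: int, size_j: int, overlap: int) -> PopulationEstimate:
    """Chapman's bias-corrected two-sample estimator.

    (|D_i|+1)(|D_j|+1)/(overlap+1) - 1; symmetric in the two samples.
    """
    if overlap > min(size_i, size_j):
        raise ValueError(
            f"overlap {overlap} exceeds the smaller sample size "
            f"{min(size_i, size_j)}"
        )
    if overlap < 0 or size_i < 0 or size_j < 0:
        raise ValueError("sizes and overlap must be non-negative")
    value = (size_i + 1) * (size_j + 1) / (overlap + 1) - 1
    return PopulationEstimate(
        "chapman", value,
        {"size_i": size_i, "size_j": size_j, "overlap": overlap},
    )


def leave_one_out_outliers(
    sample: Sequence[float],
) -> tuple[list[float], list[float]]:
    """Single-pass leave-one-out 3-sigma outlier screen.

    Each element X is tested once against the mean X0 and SAMPLE standard
    deviation (n-1 denominator) of the OTHER original elements; every
    element with |X - X0| > 3 sigma is removed simultaneously. The pass is
    not iterated: each test uses the original co-elements, so the result
    is permutation-invariant but re-running on the kept set may remove
    more. With sigma = 0 and X = X0 (constant sample) nothing is removed
    (0 > 0 is false).

    Returns ``(kept, removed)`` in input order.
    """
    values = [float(x) for x in sample]
    if len(values) < 3:
        raise DegenerateInputError(
            f"outlier screen needs >= 3 estimates, got {len(values)}"
        )
    arr = np.asarray(values)
    kept: list[float] = []
    removed: list[float] = []
    for idx, x in enumerate(values):
        others = np.delete(arr, idx)
        x0 = others.mean()
        sigma = others.std(ddof=1)
        (removed if abs(x - x0) > 3.0 * sigma else kept).append(x)
    return kept, removed
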