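"""ESS estimation, log-log regression and power-law predictions.

The quantitative backbone of the benchmark: computational performance (ESS
per hour, ESS per million MCMC states) and statistical accuracy (relative
species tree error) are each well described by power laws in the number of
loci.  The multiple regression

    ln(Y) = beta1 * ln(n_loci) + beta2 * n_species + beta3 * n_individuals + alpha

is fitted by OLS on the natural-log scale; single-predictor restrictions
give plain power laws whose (slope, intercept) pairs support point
prediction, extrapolation to larger locus counts, workload estimates
(states or hours to reach a target ESS) and expected error reductions when
a study is scaled up.

ESS uses the Tracer-style estimator: the autocorrelation time is the
initial-positive-sequence truncation of the empirical autocorrelation
function, and ESS = N / ACT, capped at N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "PowerLaw",
    "ess",
    "fit_loglog",
    "fit_powerlaw",
    "powerlaw_predict",
    "powerlaw_extrapolate",
    "workload",
    "error_reduction",
    "loess",
    "find_crossover",
]

#: Minimum locus counts entering the emulated regressions: the power-law
#: regime starts later for the smallest (5 species, 2 individuals) design.
REGRESSION_MIN_LOCI = {"5sp_2ind": 32, "default": 16}


@dataclass
class RegressionFit:
    """OLS fit of ln(Y) on ln(n_loci), n_species, n_individuals and 1."""

    beta1: float
    beta2: float
    beta3: float
    alpha: float
    se_beta1: float
    se_beta2: float
    se_beta3: float
    se_alpha: float
    response: str = ""

    def predict(self, n_loci: float, n_species: float, n_individuals: float) -> float:
        return float(
            np.exp(
                self.beta1 * np.log(n_loci)
                + self.beta2 * n_species
                + self.beta3 * n_individuals
                + self.alpha
            )
        )


@dataclass
class PowerLaw:
    """Y = exp(intercept) * n_loci**slope (natural-log scale intercept)."""

    slope: float
    intercept: float


def ess(series: Sequence[float]) -> float:
    """Effective sample size of an MCMC trace column.

    ACT is estimated from the empirical autocorrelation function, truncated
    at the first lag pair whose sum turns negative (Geyer's initial positive
    sequence rule), with a maximum lag of N/3.  Constant series have no
    defined autocorrelation and raise ValueError.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0.0:
        raise ValueError("constant series: ESS undefined")
    max_lag = n // 3
    # FFT autocovariance up to max_lag
    m = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, m)
    acov = np.fft.irfft(fx * np.conj(fx), m)[: max_lag + 1].real / n
    rho = acov / acov[0]
    # pair sums Gamma_m = rho_{2m} + rho_{2m+1}; keep while positive
    tau = 1.0
    lag = 1
    while lag + 1 <= max_lag:
        pair = rho[lag] + rho[lag + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        lag += 2
    tau = max(tau, 1.0)
    return float(min(n, n / tau))


def fit_loglog(table: pd.DataFrame, response: str = "") -> RegressionFit:
    """Fit ln(Y) = b1*ln(nl) + b2*n + b3*ni + a by ordinary least squares.

    ``table`` must have columns Y, nl, n, ni with Y > 0 and nl >= 1 and at
    least 5 rows.  Standard errors are the usual OLS ones.
    """
    required = {"Y", "nl", "n", "ni"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    if len(table) < 5:
        raise ValueError("need at least 5 rows")
    y = np.log(table["Y"].to_numpy(dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("all responses must be positive and finite")
    X = np.column_stack(
        [
            np.log(table["nl"].to_numpy(dtype=float)),
            table["n"].to_numpy(dtype=float),
            table["ni"].to_numpy(dtype=float),
        ]
    )
    X = sm.add_constant(X, prepend=False)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    b1, b2, b3, a = fit.params
    s1, s2, s3, sa = fit.bse
    return RegressionFit(b1, b2, b3, a, s1, s2, s3, sa, response=response)


def fit_powerlaw(n_loci: Sequence[float], y: Sequence[float]) -> PowerLaw:
    """Plain power-law fit: OLS of ln(y) on ln(n_loci)."""
    lx = np.log(np.asarray(n_loci, dtype=float))
    ly = np.log(np.asarray(y, dtype=float))
    slope, intercept = np.polyfit(lx, ly, 1)
    return PowerLaw(float(slope), float(intercept))


def powerlaw_predict(pl: PowerLaw, n_loci: float) -> float:
    """Point prediction exp(intercept + slope * ln n_loci)."""
    if n_loci < 1:
        raise ValueError("need n_loci >= 1")
    return float(np.exp(pl.intercept + pl.slope * np.log(n_loci)))


def powerlaw_extrapolate(
    value: float, n_loci_from: float, n_loci_to: float, slope: float
) -> float:
    """Carry a response from one locus count to another along a power law.

    value * (nl_to / nl_from)**slope.
    """
    if value <= 0 or n_loci_from < 1 or n_loci_to < 1:
        raise ValueError("need positive value and locus counts >= 1")
    return float(value * (n_loci_to / n_loci_from) ** slope)


def workload(target_ess: float, ess_rate: float) -> float:
    """Units of work (states, hours, ...) to reach a target ESS.

    With an ESS accrual rate per unit of work, the requirement is simply
    target / rate — e.g. 200 ESS at 0.047 ESS per million states needs about
    4.3e9 states.
    """
    if ess_rate <= 0:
        raise ValueError("ESS rate must be positive")
    return target_ess / ess_rate


def error_reduction(fold_increase: float, slope: float) -> float:
    """Percent error reduction from a fold increase in loci.

    100 * (1 - fold**slope) for a (negative) error power-law slope; a
    positive slope means error would grow and triggers a warning.
    """
    if fold_increase < 1:
        raise ValueError("fold increase must be >= 1")
    if slope > 0:
        warnings.warn("positive slope: error increases with more loci", stacklevel=2)
    return 100.0 * (1.0 - fold_increase**slope)


# -- local regression ------------------------------------------------------


def loess(
    x: Sequence[float], y: Sequence[float], span: float = 0.75
) -> Callable[[float], float]:
    """Degree-1 local regression with tricube weights.

    Returns a callable smoother evaluable at arbitrary abscissae; at each
    query point the nearest ceil(span * n) observations receive tricube
    weights scaled by the bandwidth and a weighted straight line is fitted.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need at least 3 matched points")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    k = max(2, int(np.ceil(span * xa.size)))

    def smooth(x0: float) -> float:
        d = np.abs(xa - x0)
        idx = np.argsort(d)[:k]
        h = d[idx].max()
        if h == 0:
            return float(ya[idx].mean())
        w = (1.0 - np.minimum(d[idx] / h, 1.0) ** 3) ** 3
        W = np.sqrt(w)
        A = np.column_stack([np.ones(k), xa[idx] - x0]) * W[:, None]
        coef, *_ = np.linalg.lstsq(A, ya[idx] * W, rcond=None)
        return float(coef[0])

    return smooth


def find_crossover(
    branch_lengths: Sequence[float],
    ratios: Sequence[float],
    span: float = 0.75,
) -> float | None:
    """Branch length (coalescent units) where the error ratio crosses 1.

    Smooths log(ratio) against log(branch length) with degree-1 tricube
    local regression, then locates the zero of the smoothed curve by
    bisection.  Returns None when the smoothed curve never crosses 1 (e.g.
    one method dominates everywhere).  The answer is invariant to the
    ordering of the input points.
    """
    b = np.asarray(branch_lengths, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if b.size != r.size:
        raise ValueError("branch lengths and ratios must be matched")
    if b.size < 20:
        raise ValueError("need at least 20 points to locate a crossover")
    if np.any(b <= 0) or np.any(r <= 0):
        raise ValueError("branch lengths and ratios must be positive")
    lx, ly = np.log(b), np.log(r)
    smooth = loess(lx, ly, span=span)
    grid = np.linspace(lx.min(), lx.max(), 201)
    vals = np.array([smooth(g) for g in grid])
    signs = np.sign(vals)
    cross = np.nonzero(np.diff(signs) != 0)[0]
    if len(cross) == 0:
        return None
    lo, hi = grid[cross[0]], grid[cross[0] + 1]
    flo = smooth(lo)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        fmid = smooth(mid)
        if fmid == 0:
            return float(np.exp(mid))
        if (flo < 0) != (fmid < 0):
            hi = mid
        else:
            lo, flo = mid, fmid
    return float(np.exp(0.5 * (lo + hi)))
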