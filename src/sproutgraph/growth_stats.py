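"""Growth-curve and length-distribution statistics.

Logistic fits Y(t) = Y_max / (1 + exp(−k(t−t1))) with derived onset
t0 = t1 − 2/k and maximal rate (dY/dt)_max = Y_max·k/4; exponential
segment-length fits via semi-log linear regression of the histogram; the
MAPE/WMAPE fit-quality metrics; the n-sigma comparison test; and the
Damköhler-number utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

DEFAULT_BIN_WIDTH_UM = 25.0
DEFAULT_MIN_LENGTH_UM = 62.5


class FitError(RuntimeError):
    """Raised for ill-posed fit inputs."""


# ---------------------------------------------------------------------------
# Logistic growth
# ---------------------------------------------------------------------------


def logistic(t, y_max, k, t1):
    """Y(t) = Y_max / (1 + exp(−k(t−t1)))."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow far below onset → Y = 0
        return y_max / (1.0 + np.exp(-k * (t - t1)))


@dataclass
class LogisticFit:
    y_max: float
    k: float
    t1: float
    se_y_max: float = math.nan
    se_k: float = math.nan
    se_t1: float = math.nan
    mape: float = math.nan
    wmape: float = math.nan
    converged: bool = True
    init: tuple[float, float, float] | None = None
    residuals: np.ndarray | None = field(default=None, repr=False)

    @property
    def t0(self) -> float:
        """Onset of growth: x-intercept of the tangent at the inflection."""
        return self.t1 - 2.0 / self.k

    @property
    def rate_max(self) -> float:
        """Maximal growth rate (dY/dt)_max = Y_max·k/4."""
        return self.y_max * self.k / 4.0

    def predict(self, t):
        return logistic(t, self.y_max, self.k, self.t1)

    def to_dict(self) -> dict:
        return {
            "Y_max": self.y_max,
            "k": self.k,
            "t1": self.t1,
            "t0": self.t0,
            "rate_max": self.rate_max,
            "se_Y_max": self.se_y_max,
            "se_k": self.se_k,
            "se_t1": self.se_t1,
            "mape": self.mape,
            "wmape": self.wmape,
            "converged": self.converged,
        }


def _logistic_init(days: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    y_max0 = 1.05 * float(values.max())
    half = values.max() / 2.0
    above = np.nonzero(values >= half)[0]
    i = int(above[0]) if above.size else len(values) // 2
    t10 = float(days[i])
    # slope at the crossing; logistic midpoint slope = Y_max·k/4
    if 0 < i < len(days):
        slope = (values[i] - values[i - 1]) / (days[i] - days[i - 1])
    elif len(days) > 1:
        slope = (values[1] - values[0]) / (days[1] - days[0])
    else:
        slope = 1.0
    k0 = 4.0 * slope / y_max0 if slope > 0 else 1.0
    return y_max0, max(k0, 1e-3), t10


def fit_logistic(series) -> LogisticFit:
    """Nonlinear least-squares logistic fit of a :class:`TimeSeries`.

    Requires ≥4 points that are not all equal; positivity bounds on Y_max
    and k.  Standard errors come from the linearized covariance at the
    optimum.  On non-convergence, returns a fit-failure result carrying the
    initializer and residuals.
    """
    days = np.asarray(series.days, dtype=float)
    values = np.asarray(series.values, dtype=float)
    if days.size < 4:
        raise FitError("need at least 4 points")
    if np.allclose(values, values[0]):
        raise FitError("values are all equal")
    if np.all(values == 0):
        raise FitError("all-zero series")
    init = _logistic_init(days, values)
    try:
        popt, pcov = curve_fit(
            logistic,
            days,
            values,
            p0=init,
            bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        resid = values - logistic(days, *init)
        return LogisticFit(*init, converged=False, init=init, residuals=resid)
    ses = np.sqrt(np.diag(pcov))
    fit = LogisticFit(
        y_max=float(popt[0]),
        k=float(popt[1]),
        t1=float(popt[2]),
        se_y_max=float(ses[0]),
        se_k=float(ses[1]),
        se_t1=float(ses[2]),
        init=init,
    )
    predicted = fit.predict(days)
    fit.residuals = values - predicted
    fit.wmape = wmape(values, predicted) if values.sum() > 0 else math.nan
    fit.mape = mape(values, predicted) if np.all(values > 0) else math.nan
    return fit


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, as a fraction: mean(|a−p|/a)."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be non-empty and equal-length")
    if np.any(a < 0):
        raise ValueError("negative actual values")
    zeros = np.nonzero(a == 0)[0]
    if zeros.size:
        raise ValueError(f"zero actual value at index {zeros[0]} would give infinite error")
    return float(np.mean(np.abs(a - p) / a))


def wmape(actual, predicted) -> float:
    """Weighted MAPE, as a fraction: Σ|a−p| / Σa."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be non-empty and equal-length")
    if np.any(a < 0):
        raise ValueError("negative actual values")
    total = a.sum()
    if total == 0:
        raise ValueError("sum of actual values is zero")
    return float(np.abs(a - p).sum() / total)


# ---------------------------------------------------------------------------
# Exponential segment-length distribution
# ---------------------------------------------------------------------------


@dataclass
class ExponentialFit:
    l_star: float
    se_l_star: float
    slope: float
    se_slope: float
    intercept: float
    n: int
    bin_width_um: float
    population: str = ""
    valid: bool = True


def fit_exponential_hist(centers, densities, bin_width_um: float, n: int = 0, population: str = "") -> ExponentialFit:
    """Ordinary least squares of ln(density) vs bin center; l* = −1/slope
    with its standard error propagated from the slope."""
    centers = np.asarray(centers, dtype=float)
    densities = np.asarray(densities, dtype=float)
    keep = densities > 0
    centers, densities = centers[keep], densities[keep]
    if centers.size < 2:
        raise FitError("fewer than 2 non-empty bins")
    y = np.log(densities)
    if centers.size == 2:
        slope = (y[1] - y[0]) / (centers[1] - centers[0])
        intercept = y[0] - slope * centers[0]
        se_slope = math.nan
    else:
        (slope, intercept), cov = np.polyfit(centers, y, 1, cov=True)
        se_slope = float(np.sqrt(cov[0, 0]))
    if slope >= 0:
        return ExponentialFit(
            l_star=math.nan,
            se_l_star=math.nan,
            slope=float(slope),
            se_slope=se_slope,
            intercept=float(intercept),
            n=n,
            bin_width_um=bin_width_um,
            population=population,
            valid=False,
        )
    l_star = -1.0 / slope
    se_l_star = se_slope / slope**2 if np.isfinite(se_slope) else math.nan
    return ExponentialFit(
        l_star=float(l_star),
        se_l_star=float(se_l_star),
        slope=float(slope),
        se_slope=se_slope,
        intercept=float(intercept),
        n=n,
        bin_width_um=bin_width_um,
        population=population,
    )


def fit_exponential_pdf(
    lengths,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    min_length_um: float = DEFAULT_MIN_LENGTH_UM,
    population: str = "",
) -> ExponentialFit:
    """Fit P(l) ~ exp(−l/l*) to segment lengths by semi-log regression.

    Lengths below ``min_length_um`` (default: the pruning length) are
    discarded; ≥30 remaining samples are required.  The histogram uses a
    fixed bin width starting at ``min_length_um`` and is density-normalized.
    The fit stops at the first empty bin: beyond that gap the histogram is a
    handful of singleton counts, not a density estimate, and keeping those
    bins flattens the unweighted semi-log slope (l* biased high by ~25% at
    n=1000).
    """
    lengths = np.asarray(lengths, dtype=float)
    lengths = lengths[lengths >= min_length_um]
    if lengths.size < 30:
        raise FitError(f"need at least 30 lengths above {min_length_um}, got {lengths.size}")
    n_bins = int(np.ceil((lengths.max() - min_length_um) / bin_width_um)) or 1
    edges = min_length_um + bin_width_um * np.arange(n_bins + 1)
    densities, _ = np.histogram(lengths, bins=edges, density=True)
    centers = (edges[:-1] + edges[1:]) / 2.0
    if (densities == 0).any():
        stop = int(np.argmax(densities == 0))
        densities, centers = densities[:stop], centers[:stop]
    return fit_exponential_hist(centers, densities, bin_width_um, n=int(lengths.size), population=population)


# ---------------------------------------------------------------------------
# Comparison test and transport utility
# ---------------------------------------------------------------------------


def n_sigma_test(x1: float, u1: float, x2: float, u2: float, n: int) -> bool:
    """True iff |x1 − x2| ≤ n·√(u1² + u2²): the two fitted values are
    consistent at n combined standard errors."""
    if u1 < 0 or u2 < 0:
        raise ValueError("uncertainties must be non-negative")
    if n < 1:
        raise ValueError("n must be ≥ 1")
    sigma = math.hypot(u1, u2)
    return abs(x1 - x2) <= n * sigma


def damkohler_number(uptake_rate: float, length_scale: float, diffusivity: float) -> float:
    """Da = uptake_rate × length_scale² / diffusivity (= τ_D/τ_R), the ratio
    of the diffusion timescale to the reaction timescale."""
    if uptake_rate <= 0 or length_scale <= 0 or diffusivity <= 0:
        raise ValueError("all inputs must be positive")
    return uptake_rate * length_scale**2 / diffusivity
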