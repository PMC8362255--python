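"""Structure-function correlation: rank correlation and OLS with
prediction bounds.

The central question the pipeline answers is whether functional
impairment (muscle function score, in [-2, 0]) tracks structural
disorganization (MDS, in [0, 15]).  Function scores are regressed on
MDS by ordinary least squares; 95% prediction intervals (not confidence
intervals for the mean) quantify where individual strains are expected
to fall.  Spearman rank correlation compares the two functional assays
to each other.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class ConstantInputError(ValueError):
    """Rank correlation is undefined for a constant vector."""


@dataclass
class RegressionResult:
    """Simple linear regression with per-point 95% prediction bounds."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n: int
    alpha: float = 0.05
    degenerate: bool = field(default=False)

    def predict(self, x_new) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x_new, dtype=float)


def spearman(z_a, z_b) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Raises :class:`ConstantInputError` when either vector is constant.
    """
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantInputError("rank correlation undefined for constant input")
    ranks_a = stats.rankdata(a, method="average")
    ranks_b = stats.rankdata(b, method="average")
    return float(np.corrcoef(ranks_a, ranks_b)[0, 1])


def fit_structure_function(x, y, alpha: float = 0.05) -> RegressionResult:
    """OLS of a function score on MDS with per-x prediction bounds.

    The prediction interval at observation i is

        yhat_i +/- t_{1-alpha/2, n-2} * s * sqrt(1 + 1/n + (x_i - xbar)^2 / Sxx)

    with s the residual standard deviation (n - 2 denominator).  Exactly
    collinear data give R^2 = 1 and zero-width bounds; the result is
    flagged ``degenerate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all x equal")

    n = x.size
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    fitted = intercept + slope * x
    resid = y - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    sigma2 = ss_res / (n - 2)
    residual_sd = float(np.sqrt(sigma2))
    degenerate = np.isclose(ss_res, 0.0, atol=1e-12 * max(ss_tot, 1.0))
    if degenerate:
        warnings.warn("zero residual variance: prediction bounds collapse "
                      "onto the fitted line", stacklevel=2)
    t_crit = stats.t.ppf(1 - alpha / 2, df=n - 2)
    half_width = t_crit * residual_sd * np.sqrt(1 + 1 / n + (x - xbar) ** 2 / sxx)

    return RegressionResult(
        slope=slope, intercept=intercept, r_squared=float(r_squared),
        residual_sd=residual_sd, x=x, y=y, fitted=fitted,
        lower=fitted - half_width, upper=fitted + half_width, n=n,
        alpha=alpha, degenerate=bool(degenerate))


def coverage_check(result: RegressionResult, points=None) -> float:
    """Fraction of points lying inside the prediction bounds at their x.

    By default the fit's own training points are checked; an explicit
    ``(x, y)`` pair of arrays can be supplied instead.
    """
    if points is None:
        x, y = result.x, result.y
    else:
        x = np.asarray(points[0], dtype=float)
        y = np.asarray(points[1], dtype=float)
    xbar = result.x.mean()
    sxx = float(np.sum((result.x - xbar) ** 2))
    t_crit = stats.t.ppf(1 - result.alpha / 2, df=result.n - 2)
    half = t_crit * result.residual_sd * np.sqrt(
        1 + 1 / result.n + (x - xbar) ** 2 / sxx)
    fitted = result.predict(x)
    inside = (y >= fitted - half) & (y <= fitted + half)
    return float(np.mean(inside))


def regression_to_json(result: RegressionResult, path=None) -> dict:
    """Serialize a fit (slope, intercept, r2, per-x bounds table)."""
    payload = {
        "slope": result.slope,
        "intercept": result.intercept,
        "r_squared": result.r_squared,
        "residual_sd": result.residual_sd,
        "n": result.n,
        "alpha": result.alpha,
        "degenerate": result.degenerate,
        "bounds": [
            {"x": float(xi), "y": float(yi), "fitted": float(fi),
             "lower": float(lo), "upper": float(hi)}
            for xi, yi, fi, lo, hi in zip(result.x, result.y, result.fitted,
                                          result.lower, result.upper)
        ],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    return payload


def plot_structure_function(result: RegressionResult, path,
                            xlabel: str = "Muscle disorganization score",
                            ylabel: str = "Muscle function score") -> None:
    """Scatter + fit + dotted 95% prediction bounds, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(result.x)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.x, result.y, color="tab:blue", zorder=3)
    ax.plot(result.x[order], result.fitted[order], "k-",
            label=f"fit (R$^2$={result.r_squared:.2f})")
    ax.plot(result.x[order], result.lower[order], "k:", label="95% prediction")
    ax.plot(result.x[order], result.upper[order], "k:")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
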