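"""Bivariate-normal ellipse outlier gate.

Outliers are points outside the probability contour of a bivariate
normal (fitted by plain sample moments) that encloses a stated mass,
99.9% by default. Contours of constant density are contours of constant
Mahalanobis distance, and for 2 degrees of freedom the squared-distance
cutoff has the closed form t = -2·ln(1 - p) (the chi-square(2) quantile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin

from .io import IntervalTable


def coverage_threshold(coverage: float) -> float:
    """Squared-Mahalanobis cutoff enclosing ``coverage`` probability mass."""
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    return -2.0 * math.log1p(-coverage)


class EllipseGate(BaseEstimator, OutlierMixin):
    """Outlier gate from the moments of a bivariate Gaussian fit.

    Parameters
    ----------
    coverage : float, default 0.999
        Probability mass enclosed by the gating ellipse.

    Attributes (after ``fit``)
    --------------------------
    mean_x_, mean_y_ : sample means on the fitted scale.
    sd_x_, sd_y_ : sample SDs (n-1 denominator).
    rho_ : Pearson correlation.
    threshold_ : squared Mahalanobis cutoff, ``-2 ln(1 - coverage)``.

    ``predict`` follows the scikit-learn outlier convention: +1 inlier,
    -1 outlier. Classification is invariant under affine rescaling of
    either axis.
    """

    def __init__(self, coverage: float = 0.999):
        self.coverage = coverage

    def fit(self, X, y=None) -> "EllipseGate":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n, 2)")
        n = X.shape[0]
        if n < 3:
            raise ValueError("degenerate gate: need at least 3 points")
        x, y_ = X[:, 0], X[:, 1]
        sd_x = float(np.std(x, ddof=1))
        sd_y = float(np.std(y_, ddof=1))
        if sd_x == 0 or sd_y == 0:
            raise ValueError("degenerate gate: zero variance on an axis")
        rho = float(np.corrcoef(x, y_)[0, 1])
        if not abs(rho) < 1:
            raise ValueError("degenerate gate: points are perfectly collinear")
        self.mean_x_ = float(np.mean(x))
        self.mean_y_ = float(np.mean(y_))
        self.sd_x_ = sd_x
        self.sd_y_ = sd_y
        self.rho_ = rho
        self.threshold_ = coverage_threshold(self.coverage)
        return self

    def mahalanobis_sq(self, X) -> np.ndarray:
        """Squared Mahalanobis distance of each point from the fitted mean."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        zx = (X[:, 0] - self.mean_x_) / self.sd_x_
        zy = (X[:, 1] - self.mean_y_) / self.sd_y_
        return (zx**2 - 2.0 * self.rho_ * zx * zy + zy**2) / (1.0 - self.rho_**2)

    def decision_function(self, X) -> np.ndarray:
        return self.threshold_ - self.mahalanobis_sq(X)

    def predict(self, X) -> np.ndarray:
        return np.where(self.mahalanobis_sq(X) <= self.threshold_, 1, -1)


def fit_gate(xs, ys, coverage: float = 0.999) -> EllipseGate:
    """Fit an :class:`EllipseGate` to paired observations."""
    return EllipseGate(coverage=coverage).fit(np.column_stack([xs, ys]))


def mahalanobis_sq(gate: EllipseGate, x, y) -> float | np.ndarray:
    d2 = gate.mahalanobis_sq(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
    return float(d2[0]) if np.isscalar(x) else d2


@dataclass(frozen=True)
class GateStratumResult:
    manufacturer: str
    sex: str
    n: int
    n_inliers: int
    n_outliers: int

    @property
    def outlier_pct(self) -> float:
        return 100.0 * self.n_outliers / self.n if self.n else 0.0


@dataclass
class OutlierSummary:
    """Per-stratum before/after bookkeeping of one gating pass."""

    scale: str
    coverage: float
    strata: list[GateStratumResult]

    @property
    def n_input(self) -> int:
        return sum(s.n for s in self.strata)

    @property
    def n_inliers(self) -> int:
        return sum(s.n_inliers for s in self.strata)

    def stratum(self, manufacturer: str, sex: str) -> GateStratumResult:
        for s in self.strata:
            if s.manufacturer == manufacturer and s.sex == sex:
                return s
        raise KeyError((manufacturer, sex))


def apply_gate(
    table: IntervalTable,
    scale: str = "log",
    coverage: float = 0.999,
    stratify: str = "stratum",
) -> tuple[IntervalTable, OutlierSummary]:
    """Gate a table on (RR, QT) pairs, log- or raw-scale, in one pass.

    The gate is fitted once per group (each manufacturer×sex stratum by
    default, or the pooled table) and never refitted after exclusion.
    Returns the inlier table (original row order) and the summary.
    """
    if scale not in ("log", "raw"):
        raise ValueError(f"scale must be 'log' or 'raw', got {scale!r}")
    if stratify not in ("stratum", "pooled"):
        raise ValueError(f"stratify must be 'stratum' or 'pooled', got {stratify!r}")
    df = table.data
    x = np.log(df["rr"].to_numpy()) if scale == "log" else df["rr"].to_numpy()
    y = np.log(df["qt"].to_numpy()) if scale == "log" else df["qt"].to_numpy()

    if stratify == "stratum":
        groups = [
            ((manu, sex), np.asarray((df["manufacturer"] == manu) & (df["sex"] == sex)))
            for manu in table.manufacturers()
            for sex in pd.unique(df.loc[df["manufacturer"] == manu, "sex"])
        ]
    else:
        groups = [(("pooled", "all"), np.ones(len(df), dtype=bool))]

    keep = np.zeros(len(df), dtype=bool)
    results = []
    for (manu, sex), mask in groups:
        try:
            gate = fit_gate(x[mask], y[mask], coverage=coverage)
        except ValueError as exc:
            raise ValueError(f"stratum ({manu}, {sex}): {exc}") from exc
        d2 = gate.mahalanobis_sq(np.column_stack([x[mask], y[mask]]))
        inlier = d2 <= gate.threshold_
        keep[np.flatnonzero(mask)[inlier]] = True
        results.append(GateStratumResult(
            manufacturer=manu, sex=sex, n=int(mask.sum()),
            n_inliers=int(inlier.sum()),
            n_outliers=int(mask.sum() - inlier.sum()),
        ))
    summary = OutlierSummary(scale=scale, coverage=coverage, strata=results)
    return table.subset(keep), summary
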