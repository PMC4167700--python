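"""QTc heart-rate correction formulas, fitting and validation.

Every correction is anchored so that QTc = QT exactly at RR = 1 s
(heart rate 60 bpm). Two families cover all supported methods:

* power:  QTc = QT · RR^(-alpha)   — Bazett (alpha = 1/2), Fridericia
  (alpha = 1/3), or a fitted exponent from log-log regression;
* linear: QTc = QT + s · (1 - RR)  — Framingham (s = 0.154), ECAPS12
  (s = 1/7), or a fitted slope from raw-scale regression.

A fitted correction is validated by regressing ln QTc on ln RR: the
residual slope beta is 0 when rate dependence has been fully removed;
beta = alpha_true - alpha_used for power corrections of power-law data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .io import IntervalTable

NAMED_METHODS = ("bazett", "fridericia", "framingham", "ecaps12")


@dataclass(frozen=True)
class CorrectionModel:
    """An RR=1-anchored QTc rule.

    ``kind`` is a named formula or one of the generic families
    ``power`` / ``linear``, which require ``parameter`` (the exponent
    alpha, resp. the slope s).
    """

    kind: str
    parameter: float | None = None

    def __post_init__(self) -> None:
        if self.kind in ("power", "linear"):
            if self.parameter is None:
                raise ValueError(f"{self.kind} correction requires a parameter")
        elif self.kind not in NAMED_METHODS:
            raise ValueError(f"unknown correction kind {self.kind!r}")

    @property
    def exponent(self) -> float | None:
        """RR exponent for power-family methods, else None."""
        return {"bazett": 0.5, "fridericia": 1.0 / 3.0,
                "power": self.parameter}.get(self.kind)

    @property
    def linear_slope(self) -> float | None:
        """(1 - RR) slope for linear-family methods, else None."""
        return {"framingham": 0.154, "ecaps12": 1.0 / 7.0,
                "linear": self.parameter}.get(self.kind)

    def qtc(self, qt, rr):
        return compute_qtc(self, qt, rr)

    def label(self) -> str:
        if self.kind == "power":
            return f"QT*RR^-{self.parameter:g}"
        if self.kind == "linear":
            return f"QT+{self.parameter:g}*(1-RR)"
        return self.kind


def compute_qtc(model: CorrectionModel, qt, rr):
    """Apply a correction model; qt, rr in seconds (scalars or arrays)."""
    qt = np.asarray(qt, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any(qt <= 0) or np.any(rr <= 0):
        raise ValueError("qt and rr must be positive (seconds)")
    alpha = model.exponent
    if alpha is not None:
        out = qt * rr ** (-alpha)
    else:
        out = qt + model.linear_slope * (1.0 - rr)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RegressionFit:
    """Simple-regression summary of a QT–RR relation on one scale."""

    scale: str            # 'log' or 'raw'
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    pvalue: float
    r_squared: float
    n: int
    resid_sd: float


class QTRateRegression(BaseEstimator, RegressorMixin):
    """OLS of QT on RR, on the log or raw scale.

    Log scale regresses ln QT on ln RR (slope = correction exponent);
    raw scale regresses QT on RR in seconds (slope = linear correction
    coefficient). 95% CI from the t distribution with n-2 df; two-sided
    slope p-value; R² equals the squared Pearson correlation.
    """

    def __init__(self, scale: str = "log"):
        self.scale = scale

    def fit(self, X, y) -> "QTRateRegression":
        if self.scale not in ("log", "raw"):
            raise ValueError(f"scale must be 'log' or 'raw', got {self.scale!r}")
        rr = np.asarray(X, dtype=float).reshape(-1)
        qt = np.asarray(y, dtype=float).reshape(-1)
        if rr.shape != qt.shape:
            raise ValueError("X and y must have the same length")
        if rr.size < 3:
            raise ValueError("degenerate regression: need n >= 3")
        if np.any(rr <= 0) or np.any(qt <= 0):
            raise ValueError("qt and rr must be positive (seconds)")
        if np.var(rr) == 0:
            raise ValueError("degenerate regression: RR has zero variance")
        x = np.log(rr) if self.scale == "log" else rr
        resp = np.log(qt) if self.scale == "log" else qt
        res = sm.OLS(resp, sm.add_constant(x)).fit()
        ci = res.conf_int(alpha=0.05)
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.ci_ = (float(ci[1][0]), float(ci[1][1]))
        self.pvalue_ = float(res.pvalues[1])
        self.r_squared_ = float(res.rsquared)
        self.n_ = int(res.nobs)
        self.resid_sd_ = float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0
        return self

    def predict(self, X) -> np.ndarray:
        rr = np.asarray(X, dtype=float).reshape(-1)
        if self.scale == "log":
            return np.exp(self.intercept_ + self.slope_ * np.log(rr))
        return self.intercept_ + self.slope_ * rr

    def result(self) -> RegressionFit:
        return RegressionFit(
            scale=self.scale, slope=self.slope_, intercept=self.intercept_,
            ci_low=self.ci_[0], ci_high=self.ci_[1], pvalue=self.pvalue_,
            r_squared=self.r_squared_, n=self.n_, resid_sd=self.resid_sd_,
        )


def fit_log_correction(table: IntervalTable) -> RegressionFit:
    """OLS of ln QT on ln RR over a table; slope is the exponent alpha."""
    df = table.data
    return QTRateRegression("log").fit(df["rr"], df["qt"]).result()


def fit_raw_correction(table: IntervalTable) -> RegressionFit:
    """OLS of raw QT on raw RR (seconds); slope is the linear coefficient."""
    df = table.data
    return QTRateRegression("raw").fit(df["rr"], df["qt"]).result()


def build_correction(fit: RegressionFit) -> CorrectionModel:
    """Turn a fitted QT–RR relation into an RR=1-anchored correction.

    The intercept is discarded: anchoring at RR = 1 s makes the rule
    QT·RR^(-slope) on the log scale and QT + slope·(1 - RR) on the raw
    scale.
    """
    kind = "power" if fit.scale == "log" else "linear"
    return CorrectionModel(kind, fit.slope)


def residual_slope(
    table: IntervalTable, model: CorrectionModel, scale: str = "log"
) -> RegressionFit:
    """Residual rate-dependence beta of a correction over a table.

    Regresses ln QTc on ln RR (default) or raw QTc on raw RR. beta = 0
    certifies a rate-independent QTc.
    """
    df = table.data
    qtc = compute_qtc(model, df["qt"].to_numpy(), df["rr"].to_numpy())
    return QTRateRegression(scale).fit(df["rr"], qtc).result()
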