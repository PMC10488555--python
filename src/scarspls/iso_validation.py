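"""Model validation statistics and ISO 12099:2017 acceptance limits.

For a prediction set of n_p samples with reference values x_i and NIR
predictions y_i, with residuals e_i = x_i - y_i:

    bias  = mean(e)
    SEP   = sqrt( sum((e - bias)^2) / (n_p - 1) )     (bias-corrected)
    RMSEP = sqrt( sum(e^2) / n_p )
    R^2   = squared Pearson correlation of x and y

which are tied together by the identity
RMSEP^2 = ((n_p - 1)/n_p) * SEP^2 + bias^2.

ISO 12099 accepts a calibration on an independent prediction set when

    SEP    < T_UE = SEC * sqrt(F(alpha; n_p - 1, n - LVs - 1))
    |bias| < T_b  = t(1 - alpha/2; n_p - 1) * SEP / sqrt(n_p)

with alpha = 0.05, n the calibration sample count and LVs the PLS
component count.  Both comparisons are strict: a statistic exactly at
its limit is not accepted.

SEC is implemented with the plain 1/n_c denominator (bias-corrected
calibration residuals); the ISO-style n - LVs - 1 denominator is
available via ``convention="dof"`` — the n - LVs - 1 in T_UE refers
only to the F-test degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PredictionStats", "IsoVerdict", "prediction_stats", "sec", "t_b", "t_ue", "iso_verdict"]


@dataclass
class PredictionStats:
    r2: float
    rmsep: float
    sep: float
    bias: float
    sec: float
    n: int  # calibration sample count
    n_p: int  # prediction sample count
    lvs: int


@dataclass
class IsoVerdict:
    t_ue: float
    t_b: float
    alpha: float
    nu: int  # n_p - 1, SEP degrees of freedom
    m_dof: int  # n - LVs - 1, SEC degrees of freedom
    sep_accepted: bool
    bias_accepted: bool


def prediction_stats(
    x_ref: np.ndarray,
    y_pred: np.ndarray,
    n: int,
    lvs: int,
    sec_value: float = np.nan,
) -> PredictionStats:
    """Validation statistics from reference/predicted value pairs.

    ``n`` is the calibration sample count (carried through for the
    F-test dof); ``sec_value`` may be filled in from the calibration
    residuals via :func:`sec`.  Zero variance in either vector leaves
    R^2 as NaN; the error statistics are still returned.
    """
    x = np.asarray(x_ref, dtype=float)
    y = np.asarray(y_pred, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x_ref and y_pred must be 1-D vectors of equal length")
    n_p = x.size
    if n_p < 2:
        raise ValueError("need at least 2 prediction samples")
    e = x - y
    bias = float(e.mean())
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (n_p - 1)))
    rmsep = float(np.sqrt(np.mean(e**2)))
    if x.std() == 0.0 or y.std() == 0.0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return PredictionStats(
        r2=r2, rmsep=rmsep, sep=sep, bias=bias, sec=float(sec_value), n=int(n), n_p=n_p, lvs=int(lvs)
    )


def sec(x_ref: np.ndarray, y_pred: np.ndarray, lvs: int | None = None, convention: str = "plain") -> float:
    """Standard error of calibration from bias-corrected residuals.

    ``convention="plain"`` divides by n_c; ``"dof"`` divides by
    n_c - LVs - 1 (requires ``lvs``).
    """
    x = np.asarray(x_ref, dtype=float)
    y = np.asarray(y_pred, dtype=float)
    e = x - y
    ss = float(np.sum((e - e.mean()) ** 2))
    if convention == "plain":
        return float(np.sqrt(ss / x.size))
    if convention == "dof":
        if lvs is None:
            raise ValueError("the dof convention needs lvs")
        dof = x.size - lvs - 1
        if dof < 1:
            raise ValueError("n - LVs - 1 must be >= 1")
        return float(np.sqrt(ss / dof))
    raise ValueError(f"unknown SEC convention {convention!r}")


def t_b(sep: float, n_p: int, alpha: float = 0.05) -> float:
    """Bias confidence limit t(1-alpha/2; n_p-1) * SEP / sqrt(n_p)."""
    if n_p < 2:
        raise ValueError("n_p must be >= 2")
    return float(sps.t.ppf(1 - alpha / 2, n_p - 1) * sep / np.sqrt(n_p))


def t_ue(sec: float, n_p: int, n: int, lvs: int, alpha: float = 0.05) -> float:
    """Unexplained-error limit SEC * sqrt(F(alpha; n_p-1, n-LVs-1))."""
    nu = n_p - 1
    m_dof = n - lvs - 1
    if nu < 1 or m_dof < 1:
        raise ValueError("invalid degrees of freedom for the F-test")
    return float(sec * np.sqrt(sps.f.ppf(1 - alpha, nu, m_dof)))


def iso_verdict(stats: PredictionStats, alpha: float = 0.05) -> IsoVerdict:
    """Apply the SEP < T_UE and |bias| < T_b acceptance tests."""
    tue = t_ue(stats.sec, stats.n_p, stats.n, stats.lvs, alpha)
    tb = t_b(stats.sep, stats.n_p, alpha)
    return IsoVerdict(
        t_ue=tue,
        t_b=tb,
        alpha=alpha,
        nu=stats.n_p - 1,
        m_dof=stats.n - stats.lvs - 1,
        sep_accepted=bool(stats.sep < tue),
        bias_accepted=bool(abs(stats.bias) < tb),
    )
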