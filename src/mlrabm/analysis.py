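"""Comparison toolkit for ex vivo vs in silico dose-response experiments.

Implements the analysis pipeline applied to MLR titrations: three-parameter
sigmoid fits (Bottom, Top, EC50; Hill slope fixed at 1), span/delta/
normalization transforms, RMS-based accuracy metrics, a classical RANSAC
screen of immunophenotype predictors, and Bland-Altman agreement between
paired measurement sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SigmoidFit",
    "AccuracyReport",
    "RansacResult",
    "BlandAltman",
    "sigmoid",
    "map_control_doses",
    "fit_sigmoid",
    "accuracy_metrics",
    "delta_response",
    "normalize_ifng",
    "ransac_screen",
    "bland_altman",
    "paired_ttest",
]


@dataclass(frozen=True)
class SigmoidFit:
    """Three-parameter log-dose sigmoid: Bottom, Top, EC50 (Hill slope 1)."""

    bottom: float
    top: float
    ec50: float  # M
    r_squared: float
    ec50_unidentifiable: bool = False
    ec50_extrapolated: bool = False

    @property
    def span(self) -> float:
        return self.top - self.bottom

    def predict(self, doses) -> np.ndarray:
        return sigmoid(np.asarray(doses, dtype=float), self.bottom, self.top, self.ec50)


@dataclass(frozen=True)
class AccuracyReport:
    """RMS-based agreement of points with a reference sigmoid."""

    rms: float
    pct_rms: float
    pct_accuracy: float  # 100 - pct_rms
    corrected_pct_accuracy: Optional[float] = None


@dataclass(frozen=True)
class RansacResult:
    slope: float
    intercept: float
    inlier_mask: np.ndarray
    inlier_r: float  # Pearson correlation of the inliers
    pct_errors: np.ndarray  # per-sample % error vs the estimator

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_mask.sum())

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    lower_limit: float
    upper_limit: float


def sigmoid(dose, bottom: float, top: float, ec50: float) -> np.ndarray:
    """response = bottom + (top - bottom) / (1 + 10^(log10 EC50 - log10 dose)).

    Equivalent to ``bottom + span * dose / (dose + ec50)`` for Hill slope 1.
    """
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) * dose / (dose + ec50)


def map_control_doses(doses, decades_below: float = 1.0) -> np.ndarray:
    """Map zero-dose controls to a pseudo-dose below the lowest tested dose.

    Standard log-dose plotting convention: controls enter the fit at
    ``decades_below`` decades under the smallest positive dose.
    """
    doses = np.asarray(doses, dtype=float)
    positive = doses[doses > 0]
    if len(positive) == 0:
        raise ValueError("need at least one positive dose")
    pseudo = positive.min() * 10.0 ** (-decades_below)
    return np.where(doses > 0, doses, pseudo)


def fit_sigmoid(doses, responses) -> SigmoidFit:
    """Least-squares fit of the 3-parameter sigmoid to (dose, response) data.

    Doses must be positive (map controls first with
    :func:`map_control_doses`).  The fit multi-starts over a log-EC50 grid
    spanning one decade beyond the dose range to avoid local minima.  When
    the span is statistically indistinguishable from zero the EC50 is
    flagged unidentifiable (a fit is still returned); an EC50 outside the
    tested dose range is flagged extrapolated.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be 1-D arrays of equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive; map controls with map_control_doses()")
    if len(np.unique(doses)) < 4:
        raise ValueError("need >= 4 distinct doses for a 3-parameter fit")

    logd = np.log10(doses)
    lo, hi = logd.min() - 1.0, logd.max() + 1.0

    def model(logdose, bottom, top, logec50):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (logec50 - logdose))

    rmin, rmax = responses.min(), responses.max()
    spread = max(rmax - rmin, 1e-12)
    best = None
    for logec50_start in np.linspace(lo, hi, 7):
        p0 = [rmin, rmax, logec50_start]
        try:
            popt, pcov = optimize.curve_fit(
                model, logd, responses, p0=p0,
                bounds=([rmin - 2 * spread, rmin - 2 * spread, lo],
                        [rmax + 2 * spread, rmax + 2 * spread, hi]),
                maxfev=5000, xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(logd, *popt) - responses) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError("sigmoid fit failed from every start")

    sse, popt, pcov = best
    bottom, top, logec50 = popt
    sst = float(np.sum((responses - responses.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    span = top - bottom
    span_var = pcov[0, 0] + pcov[1, 1] - 2.0 * pcov[0, 1]
    span_se = math.sqrt(max(span_var, 0.0)) if np.isfinite(span_var) else math.inf
    unidentifiable = bool(abs(span) < 1e-9 * max(1.0, abs(rmax)) or abs(span) <= 2.0 * span_se)
    extrapolated = bool(logec50 < logd.min() or logec50 > logd.max())
    return SigmoidFit(
        bottom=float(bottom),
        top=float(top),
        ec50=float(10.0 ** logec50),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        ec50_unidentifiable=unidentifiable,
        ec50_extrapolated=extrapolated,
    )


def accuracy_metrics(
    points: Sequence[tuple[float, float]],
    reference: SigmoidFit,
    reference_self_accuracy: Optional[float] = None,
) -> AccuracyReport:
    """RMS deviation of points from a reference sigmoid, as % of its span.

    ``rms`` is in response units; ``pct_rms = 100 * rms / span``;
    ``pct_accuracy = 100 - pct_rms``.  When the reference method's
    self-accuracy is supplied, the corrected accuracy is the ratio
    ``pct_accuracy / reference_self_accuracy * 100``.
    """
    if reference.span == 0:
        raise ValueError("reference span is zero; %RMS is undefined")
    pts = np.asarray(points, dtype=float)
    doses, responses = pts[:, 0], pts[:, 1]
    rms = float(np.sqrt(np.mean((responses - reference.predict(doses)) ** 2)))
    pct_rms = 100.0 * rms / abs(reference.span)
    pct_accuracy = 100.0 - pct_rms
    corrected = (
        pct_accuracy / reference_self_accuracy * 100.0
        if reference_self_accuracy is not None
        else None
    )
    return AccuracyReport(rms=rms, pct_rms=pct_rms, pct_accuracy=pct_accuracy,
                          corrected_pct_accuracy=corrected)


def delta_response(
    table,
    response_col: str = "pct_pd1_cd4",
) -> pd.DataFrame:
    """Per-dose replicate means minus the lowest-dose replicate mean.

    Accepts a :class:`~mlrabm.experiment.DoseResponseTable` or its
    DataFrame.  Only rows with a positive dose participate (controls have
    no dose on the titration grid).  Returns a frame with columns
    ``dose_M``, ``mean_response``, ``delta``.
    """
    df = getattr(table, "df", table)
    dosed = df[df["dose_M"] > 0]
    if dosed.empty:
        raise ValueError("table contains no dosed conditions")
    means = (
        dosed.groupby("dose_M", as_index=False)[response_col]
        .mean()
        .rename(columns={response_col: "mean_response"})
        .sort_values("dose_M", ignore_index=True)
    )
    baseline = means.loc[0, "mean_response"]  # lowest dose after sort
    means["delta"] = means["mean_response"] - baseline
    return means


def normalize_ifng(values) -> np.ndarray:
    """Scale cytokine values by their within-experiment maximum (max -> 1)."""
    values = np.asarray(values, dtype=float)
    vmax = values.max() if values.size else 0.0
    if vmax <= 0:
        raise ValueError("normalization requires at least one positive value")
    return values / vmax


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def ransac_screen(
    x,
    y,
    threshold: Optional[float] = None,
    min_samples: int = 2,
    seed: int = 0,
    n_trials: int = 500,
) -> RansacResult:
    """Classical RANSAC linear regression of a response difference on a
    phenotype statistic.

    Minimal sets of ``min_samples`` points are sampled ``n_trials`` times;
    each candidate line's consensus set is every point with absolute
    residual <= ``threshold``; the best consensus (most inliers, ties by
    residual sum of squares) is refit by ordinary least squares.  The
    default threshold is the MAD-scaled residual spread of a plain OLS fit
    (2.5 x 1.4826 x MAD); pass ``threshold=np.inf`` to force all points
    inliers, in which case the result is exactly OLS.

    Reports the inlier Pearson correlation and each sample's % error with
    respect to the estimator, ``100 * |y - y_hat| / |y_hat|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    if n < min_samples:
        raise ValueError(f"need at least min_samples = {min_samples} points, got {n}")

    if threshold is None:
        s0, i0 = _ols_line(x, y)
        resid = np.abs(y - (s0 * x + i0))
        mad = float(np.median(np.abs(resid - np.median(resid))))
        threshold = 2.5 * 1.4826 * mad if mad > 0 else 2.5 * float(resid.std() + 1e-12)
        # floor against numerically-zero residuals on exactly collinear data
        threshold = max(threshold, 1e-9 * max(1.0, float(np.max(np.abs(y)))))

    rng = np.random.default_rng(seed)
    best_mask = None
    best_key = (-1, math.inf)
    for _ in range(n_trials):
        idx = rng.choice(n, size=min_samples, replace=False)
        if np.ptp(x[idx]) == 0:
            continue
        slope, intercept = _ols_line(x[idx], y[idx])
        resid = np.abs(y - (slope * x + intercept))
        mask = resid <= threshold
        k = int(mask.sum())
        if k < min_samples:
            continue
        rss = float(np.sum(resid[mask] ** 2))
        if (k, -rss) > (best_key[0], -best_key[1]):
            best_key = (k, rss)
            best_mask = mask
    if best_mask is None:
        raise RuntimeError(
            f"RANSAC found no consensus set of size >= {min_samples}; "
            "raise the residual threshold"
        )

    slope, intercept = _ols_line(x[best_mask], y[best_mask])
    # Final inlier classification against the refit line.
    resid = np.abs(y - (slope * x + intercept))
    mask = resid <= threshold
    if mask.sum() >= min_samples and np.ptp(x[mask]) > 0:
        slope, intercept = _ols_line(x[mask], y[mask])
    else:
        mask = best_mask

    xin, yin = x[mask], y[mask]
    if len(xin) >= 2 and np.std(xin) > 0 and np.std(yin) > 0:
        inlier_r = float(np.corrcoef(xin, yin)[0, 1])
    else:
        inlier_r = 1.0 if len(xin) >= 2 else float("nan")
    yhat = slope * x + intercept
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_errors = 100.0 * np.abs(y - yhat) / np.abs(yhat)
    return RansacResult(
        slope=float(slope),
        intercept=float(intercept),
        inlier_mask=mask,
        inlier_r=inlier_r,
        pct_errors=pct_errors,
    )


def bland_altman(a, b) -> BlandAltman:
    """Agreement of two paired measurement sets.

    Differences ``d = a - b``; bias = mean(d); 95 % limits of agreement
    = bias +/- 1.96 * SD(d) with the sample (n-1) standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, lower_limit=bias - 1.96 * sd, upper_limit=bias + 1.96 * sd)


def paired_ttest(a, b) -> tuple[float, float]:
    """Paired t-test (standard two-sided test); returns (statistic, p-value)."""
    res = stats.ttest_rel(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return float(res.statistic), float(res.pvalue)
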