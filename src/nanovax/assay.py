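"""Assay post-processing: viability normalization, 4PL dose-response with
IC50, survival-normalized cathepsin-B activity, and the activity-vs-zeta
summary (binned means and an OLS trend line)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit


@dataclass
class DoseResponse:
    """Doses (pM) with replicate responses per dose.

    ``responses[i]`` holds the replicates measured at ``doses[i]``.
    ``control_mean`` is the zero-dose response level if measured separately.
    """

    doses: np.ndarray
    responses: np.ndarray  # shape (n_doses, n_replicates)
    control_mean: float | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[0] != self.doses.shape[0]:
            raise ValueError("responses must have one row per dose")
        if (self.doses < 0).any():
            raise ValueError("doses must be >= 0")
        if len(np.unique(self.doses)) < 4:
            raise ValueError("need >= 4 distinct doses for dose-response fitting")


@dataclass(frozen=True)
class FourPLFit:
    """Four-parameter logistic fit r(d) = lower + (upper-lower)/(1+(d/ic50)^hill)."""

    lower: float
    upper: float
    ic50: float
    hill: float
    se_lower: float
    se_upper: float
    se_ic50: float
    se_hill: float
    converged: bool


@dataclass(frozen=True)
class PercentOfControl:
    percent: float
    per_replicate: np.ndarray


@dataclass(frozen=True)
class NormalizedActivity:
    """Cathepsin-B activity divided by the survival fraction.

    A treatment killing half the cells but yielding the same raw
    fluorescence as an untreated well has twice the per-surviving-cell
    activity; dividing raw activity (AU) by survival/100 expresses that.
    """

    raw_activity: float
    survival_percent: float
    normalized: float


@dataclass(frozen=True)
class ChargeActivityPoint:
    pZ_mV: float
    normalized_activity: float
    group: str | None = None


@dataclass
class ChargeActivitySummary:
    bins: pd.DataFrame  # columns: bin, n, mean, sd
    slope: float
    intercept: float
    r_squared: float


def percent_of_control(
    values: Sequence[float], control: Sequence[float]
) -> PercentOfControl:
    """Express measurements as a percentage of the control mean."""
    values = np.asarray(values, dtype=float)
    control = np.asarray(control, dtype=float)
    cmean = control.mean()
    if cmean <= 0:
        raise ValueError("control mean must be > 0")
    return PercentOfControl(
        percent=float(100.0 * values.mean() / cmean),
        per_replicate=100.0 * values / cmean,
    )


def four_pl(d: np.ndarray, lower: float, upper: float, ic50: float, hill: float) -> np.ndarray:
    """4PL response; decreasing in dose for hill > 0 (inhibition curve)."""
    d = np.asarray(d, dtype=float)
    return lower + (upper - lower) / (1.0 + (d / ic50) ** hill)


def fit_4pl(dr: DoseResponse) -> FourPLFit:
    """Least-squares 4PL fit on the positive doses.

    Initialization: upper = max response, lower = min response, ic50 = dose
    whose mean response is nearest mid-range, hill = 1.  Standard errors come
    from the curvature (covariance) at the optimum.  Degenerate data (for
    example constant responses) yield ``converged=False``, never a silent
    number.
    """
    pos = dr.doses > 0
    doses = np.repeat(dr.doses[pos], dr.responses.shape[1])
    resp = dr.responses[pos].ravel()
    if len(np.unique(dr.doses[pos])) < 4:
        raise ValueError("need >= 4 distinct positive doses")
    if not np.isfinite(resp).all():
        raise ValueError("responses must be finite")

    upper0, lower0 = float(resp.max()), float(resp.min())
    mid = (upper0 + lower0) / 2.0
    dose_means = dr.responses[pos].mean(axis=1)
    ic50_0 = float(dr.doses[pos][np.argmin(np.abs(dose_means - mid))])
    p0 = [lower0, upper0, max(ic50_0, np.finfo(float).tiny), 1.0]

    if np.ptp(resp) == 0.0:
        return FourPLFit(lower0, upper0, p0[2], 1.0, *([np.inf] * 4), converged=False)

    bounds = ([-np.inf, -np.inf, np.finfo(float).tiny, -np.inf], [np.inf] * 4)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                four_pl, doses, resp, p0=p0, bounds=bounds, maxfev=20000
            )
    except (RuntimeError, ValueError):
        return FourPLFit(*p0, *([np.inf] * 4), converged=False)

    ses = np.sqrt(np.diag(pcov))
    lower, upper, ic50, hill = (float(v) for v in popt)
    converged = bool(
        np.isfinite(popt).all()
        and np.isfinite(ses).all()
        and ic50 > 0
        and upper > lower
    )
    return FourPLFit(
        lower, upper, ic50, hill,
        float(ses[0]), float(ses[1]), float(ses[2]), float(ses[3]),
        converged=converged,
    )


def normalize_activity(raw: float, survival_percent: float) -> NormalizedActivity:
    """Divide raw activity by the survival fraction (survival/100)."""
    if not (0.0 < survival_percent <= 100.0):
        raise ValueError(
            f"survival percent must lie in (0, 100], got {survival_percent}"
        )
    return NormalizedActivity(
        raw_activity=float(raw),
        survival_percent=float(survival_percent),
        normalized=float(raw) / (survival_percent / 100.0),
    )


def charge_activity_summary(
    points: Sequence[ChargeActivityPoint], bin_edges: Sequence[float]
) -> ChargeActivitySummary:
    """Per-zeta-bin mean +/- sample SD plus an OLS line of activity on zeta."""
    if len(points) < 2:
        raise ValueError("need >= 2 points")
    pz = np.array([p.pZ_mV for p in points], dtype=float)
    act = np.array([p.normalized_activity for p in points], dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if pz.min() < edges.min() or pz.max() > edges.max():
        raise ValueError("bin edges must cover all pZ values")

    labels = pd.cut(pz, edges, include_lowest=True)
    df = pd.DataFrame({"bin": labels, "activity": act})
    grouped = df.groupby("bin", observed=True)["activity"]
    bins = pd.DataFrame(
        {
            "bin": [str(b) for b in grouped.mean().index],
            "n": grouped.size().to_numpy(),
            "mean": grouped.mean().to_numpy(),
            "sd": grouped.std(ddof=1).to_numpy(),
        }
    )

    X = sm.add_constant(pz)
    with warnings.catch_warnings():
        # constant activities give zero centred TSS; r^2 mapped to 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.OLS(act, X).fit()
        intercept, slope = (float(v) for v in model.params)
        r2 = float(model.rsquared) if np.isfinite(model.rsquared) else 0.0
    return ChargeActivitySummary(
        bins=bins, slope=slope, intercept=intercept, r_squared=r2
    )
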