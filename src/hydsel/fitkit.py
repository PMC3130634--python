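"""Nonlinear fits for O2-tolerance phenotypes.

Two models:

* first-order inactivation kinetics, A(t) = A0 * exp(-k t).  Enzyme activity
  after t minutes of O2 exposure; the half-life t1/2 = ln 2 / k is the
  headline O2-tolerance number.
* sigmoid dose response, area = a / (1 + exp(b * (O2 - c))).  Mean colony
  area as a function of ambient O2 percentage; a is the zero-O2 plateau,
  b the steepness (per % O2, positive for decreasing response) and c the
  half-maximal inhibitory O2 level (the curve equals a/2 at O2 = c by
  construction).

Both fits are least squares in linear response space (log-linear regression
of the decay is available as a cross-check but biases noisy low activities).
Uncertainty comes from a seeded residual bootstrap: by default *relative*
residuals (residual / fitted value) are resampled with replacement, scaled
by the small-sample leverage inflation sqrt(n / (n - p)), reapplied
multiplicatively to the fitted curve and the model refit; 95% percentile
intervals are read from the bootstrap parameter distribution.  Relative
resampling matches the proportional error structure of activity assays and
colony-size data; ``residual_mode='additive'`` gives the classic
homoscedastic variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .seqcore import ValidationError

LN2 = float(np.log(2.0))
DEFAULT_N_BOOT = 1000


class FitError(RuntimeError):
    """Raised when a fit fails to converge; carries the initialization used."""


@dataclass
class TimeCourse:
    """One replicate's activity time course (minutes vs arbitrary activity)."""

    times: np.ndarray
    activities: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.times.size != self.activities.size:
            raise ValidationError("times and activities differ in length")
        if self.times.size < 3:
            raise ValidationError("a time course needs at least 3 points")
        if (self.times < 0).any() or not (np.diff(self.times) > 0).all():
            raise ValidationError("times must be nonnegative and strictly increasing")
        if (self.activities < 0).any():
            raise ValidationError("activities must be nonnegative")


@dataclass
class DecayFit:
    A0: float
    k: float
    half_life: float
    ci95_half_life: tuple[float, float]
    flagged: bool = False
    message: str = ""
    n_boot: int = 0
    seed: int = 0
    boot_half_lives: Optional[np.ndarray] = None


@dataclass
class DoseResponse:
    """Mean colony areas across an O2 gradient (one strain, one atmosphere)."""

    o2_levels: np.ndarray
    responses: np.ndarray
    sd: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.o2_levels = np.asarray(self.o2_levels, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.o2_levels.size != self.responses.size:
            raise ValidationError("o2_levels and responses differ in length")
        if (self.o2_levels < 0).any():
            raise ValidationError("O2 levels must be nonnegative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.n is not None:
            self.n = np.asarray(self.n)


@dataclass
class SigmoidFit:
    a: float
    b: float
    c: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    ci95_c: tuple[float, float]
    flagged: bool = False
    message: str = ""
    n_boot: int = 0
    seed: int = 0
    boot_params: Optional[np.ndarray] = None  # (n_boot, 3)

    def predict(self, o2: np.ndarray | float) -> np.ndarray | float:
        return sigmoid(np.asarray(o2, dtype=float), self.a, self.b, self.c)


def exp_decay(t: np.ndarray, A0: float, k: float) -> np.ndarray:
    return A0 * np.exp(-k * t)


def sigmoid(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a / (1.0 + np.exp(b * (x - c)))


def _pool(tc: Union[TimeCourse, Sequence[TimeCourse]]) -> tuple[np.ndarray, np.ndarray]:
    courses = [tc] if isinstance(tc, TimeCourse) else list(tc)
    t = np.concatenate([c.times for c in courses])
    y = np.concatenate([c.activities for c in courses])
    order = np.argsort(t, kind="stable")
    return t[order], y[order]


def _bootstrap_responses(
    yhat: np.ndarray,
    resid: np.ndarray,
    n_params: int,
    residual_mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """One resampled response vector for the residual bootstrap."""
    n = resid.size
    infl = np.sqrt(n / max(n - n_params, 1))
    if residual_mode == "relative":
        rel = resid / np.maximum(np.abs(yhat), 1e-12)
        draw = yhat * (1 + infl * rng.choice(rel, size=n, replace=True))
    elif residual_mode == "additive":
        draw = yhat + infl * rng.choice(resid, size=n, replace=True)
    else:
        raise ValidationError(f"unknown residual_mode {residual_mode!r}")
    return np.clip(draw, 0, None)


def fit_first_order(
    tc: Union[TimeCourse, Sequence[TimeCourse]],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    residual_mode: str = "relative",
) -> DecayFit:
    """Fit A(t) = A0 exp(-k t) by nonlinear least squares.

    Replicate time courses may be passed as a sequence and are pooled.
    Non-decaying data (optimal k <= 0) yields a flagged result with infinite
    half-life and a warning rather than an exception.
    """
    t, y = _pool(tc)
    if not (y > 0).any():
        raise ValidationError("at least one activity must be positive")
    A0_hat, k_hat = _fit_decay_core(t, y)
    # "no decay" includes k numerically indistinguishable from zero over the
    # observed time span
    if k_hat * (t.max() - t.min()) <= 1e-9:
        warnings.warn(
            "activities do not decay (k <= 0 at optimum); half-life is infinite",
            stacklevel=2,
        )
        return DecayFit(
            A0=A0_hat,
            k=k_hat,
            half_life=np.inf,
            ci95_half_life=(np.inf, np.inf),
            flagged=True,
            message="non-decaying data",
            seed=seed,
        )
    yhat = exp_decay(t, A0_hat, k_hat)
    resid = y - yhat
    rng = np.random.default_rng(seed)
    boot_hl = np.empty(n_boot)
    for b in range(n_boot):
        y_b = _bootstrap_responses(yhat, resid, 2, residual_mode, rng)
        try:
            _, k_b = _fit_decay_core(t, y_b, p0=(A0_hat, k_hat))
        except FitError:
            k_b = np.nan
        boot_hl[b] = LN2 / k_b if k_b > 0 else np.inf
    finite = boot_hl[np.isfinite(boot_hl)]
    if n_boot > 0 and finite.size >= max(10, 0.5 * n_boot):
        lo, hi = np.percentile(boot_hl[~np.isnan(boot_hl)], [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        ci = (np.nan, np.nan)
    return DecayFit(
        A0=A0_hat,
        k=k_hat,
        half_life=LN2 / k_hat,
        ci95_half_life=ci,
        n_boot=n_boot,
        seed=seed,
        boot_half_lives=boot_hl if n_boot else None,
    )


def _fit_decay_core(
    t: np.ndarray, y: np.ndarray, p0: Optional[tuple[float, float]] = None
) -> tuple[float, float]:
    if p0 is None:
        pos = y > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
            p0 = (float(np.exp(intercept)), float(-slope))
        else:
            p0 = (float(y.max()), 0.1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(exp_decay, t, y, p0=p0, maxfev=10_000)
    except RuntimeError as exc:
        raise FitError(f"decay fit failed to converge from p0={p0}: {exc}") from exc
    return float(popt[0]), float(popt[1])


def log_linear_half_life(tc: Union[TimeCourse, Sequence[TimeCourse]]) -> float:
    """Cross-check estimator: OLS of log activity on time (positive points)."""
    t, y = _pool(tc)
    pos = y > 0
    slope, _ = np.polyfit(t[pos], np.log(y[pos]), 1)
    return float(LN2 / -slope) if slope < 0 else np.inf


def fit_sigmoid(
    dr: DoseResponse,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    residual_mode: str = "relative",
) -> SigmoidFit:
    """Fit area = a / (1 + exp(b (O2 - c))) by nonlinear least squares.

    Initialization: a0 = max response, c0 = dose whose response is nearest
    a0/2, b0 = 1.  A flat response is non-identifiable and returns a flagged
    fit; failure to converge raises FitError carrying the initialization.
    """
    x, y = dr.o2_levels, dr.responses
    if x.size < 4:
        raise ValidationError("sigmoid fit needs at least 4 dose points")
    if np.ptp(y) <= 1e-12 * max(1.0, abs(float(np.mean(y)))):
        warnings.warn("flat dose response; sigmoid parameters are not identifiable",
                      stacklevel=2)
        return SigmoidFit(
            a=float(np.mean(y)), b=np.nan, c=np.nan,
            ci95_a=(np.nan, np.nan), ci95_b=(np.nan, np.nan), ci95_c=(np.nan, np.nan),
            flagged=True, message="flat response (non-identifiable)", seed=seed,
        )
    a0 = float(y.max())
    c0 = float(x[np.argmin(np.abs(y - a0 / 2))])
    p0 = (a0, 1.0, c0)
    popt = _fit_sigmoid_core(x, y, p0)
    yhat = sigmoid(x, *popt)
    resid = y - yhat
    rng = np.random.default_rng(seed)
    boot = np.full((n_boot, 3), np.nan)
    for b in range(n_boot):
        y_b = _bootstrap_responses(yhat, resid, 3, residual_mode, rng)
        try:
            boot[b] = _fit_sigmoid_core(x, y_b, popt)
        except FitError:
            pass
    ok = ~np.isnan(boot[:, 0])
    if n_boot > 0 and ok.sum() >= max(10, 0.5 * n_boot):
        los, his = np.nanpercentile(boot, [2.5, 97.5], axis=0)
        cis = [(float(l), float(h)) for l, h in zip(los, his)]
    else:
        cis = [(np.nan, np.nan)] * 3
    return SigmoidFit(
        a=popt[0], b=popt[1], c=popt[2],
        ci95_a=cis[0], ci95_b=cis[1], ci95_c=cis[2],
        n_boot=n_boot, seed=seed, boot_params=boot if n_boot else None,
    )


def _fit_sigmoid_core(
    x: np.ndarray, y: np.ndarray, p0: Sequence[float]
) -> tuple[float, float, float]:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(sigmoid, x, y, p0=p0, maxfev=10_000)
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit failed to converge from p0={tuple(p0)}: {exc}") from exc
    return float(popt[0]), float(popt[1]), float(popt[2])


@dataclass
class ConditionShift:
    """Difference in half-maximal inhibition between two atmospheres."""

    delta_c: float
    ci95: tuple[float, float]
    flagged: bool = False
    message: str = ""


def compare_conditions(
    fit_with_h2: SigmoidFit, fit_without_h2: SigmoidFit
) -> ConditionShift:
    """Report c_with - c_without and a bootstrap CI of the difference."""
    if fit_with_h2.flagged or fit_without_h2.flagged:
        return ConditionShift(
            delta_c=np.nan, ci95=(np.nan, np.nan), flagged=True,
            message="one or both fits are flagged non-identifiable",
        )
    delta = fit_with_h2.c - fit_without_h2.c
    b1, b2 = fit_with_h2.boot_params, fit_without_h2.boot_params
    if b1 is None or b2 is None:
        return ConditionShift(delta_c=delta, ci95=(np.nan, np.nan),
                              message="no bootstrap samples available")
    c1 = b1[~np.isnan(b1[:, 2]), 2]
    c2 = b2[~np.isnan(b2[:, 2]), 2]
    m = min(c1.size, c2.size)
    diffs = c1[:m] - c2[:m]
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return ConditionShift(delta_c=float(delta), ci95=(float(lo), float(hi)))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_timecourse_csv(path: str | Path) -> list[TimeCourse]:
    """CSV with columns time_min, activity and optional replicate."""
    df = pd.read_csv(path)
    for col in ("time_min", "activity"):
        if col not in df.columns:
            raise ValidationError(f"time-course CSV {path}: missing column {col!r}")
    if "replicate" in df.columns:
        groups = df.groupby("replicate", sort=True)
        return [
            TimeCourse(g["time_min"].to_numpy(), g["activity"].to_numpy(),
                       replicate_id=str(name))
            for name, g in groups
        ]
    return [TimeCourse(df["time_min"].to_numpy(), df["activity"].to_numpy())]


def read_dose_response_csv(path: str | Path) -> DoseResponse:
    """CSV with columns o2_percent, mean_area and optional sd, n."""
    df = pd.read_csv(path)
    for col in ("o2_percent", "mean_area"):
        if col not in df.columns:
            raise ValidationError(f"dose-response CSV {path}: missing column {col!r}")
    return DoseResponse(
        o2_levels=df["o2_percent"].to_numpy(),
        responses=df["mean_area"].to_numpy(),
        sd=df["sd"].to_numpy() if "sd" in df.columns else None,
        n=df["n"].to_numpy() if "n" in df.columns else None,
    )
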