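"""Sigmoidal growth-curve models, fitting, and inflection-point derivation.

Three classical three-parameter growth models are supported, each written
in terms of an asymptotic weight ``A`` (kg), a dimensionless shape constant
``B`` and a rate constant ``k`` (per day):

* logistic:        W(t) = A / (1 + B e^(-k t))
* Gompertz:        W(t) = A exp(-B e^(-k t))
* von Bertalanffy: W(t) = A (1 - B e^(-k t))^3

Each model has a closed-form inflection point — the age at which daily
gain is maximal:

===============  ==============  =================  =================
model            inflection age  inflection weight  maximum daily gain
===============  ==============  =================  =================
logistic         ln(B)/k         A/2                k·w/2
Gompertz         ln(B)/k         A/e                k·w
von Bertalanffy  ln(3B)/k        8A/27              3k·w/2
===============  ==============  =================  =================

where ``w`` is the inflection weight. Weights are kept in kg internally;
maximum daily gain is reported in g/day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MODELS",
    "GrowthModelParams",
    "GrowthCurveFit",
    "InflectionSummary",
    "evaluate_model",
    "inflection_summary",
    "goodness_of_fit",
    "fit_growth_curve",
    "rank_models",
    "read_weight_records",
    "fit_report",
]

MODELS = ("logistic", "gompertz", "von_bertalanffy")


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameter triple (A, B, k) for one named sigmoidal model."""

    model: str
    A: float  # asymptotic weight, kg
    B: float  # shape constant, dimensionless
    k: float  # rate, per day

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; expected one of {MODELS}"
            )
        if not (self.A > 0 and self.B > 0 and self.k > 0):
            raise ValueError(
                f"growth parameters must be positive, got "
                f"A={self.A}, B={self.B}, k={self.k}"
            )


@dataclass(frozen=True)
class InflectionSummary:
    """Closed-form inflection quantities for one fitted model.

    ``before_birth`` flags the degenerate case where the shape argument is
    ≤ 1 and the analytic inflection age is non-positive (i.e. precedes
    birth); the computed negative age is returned unclamped and the caller
    decides what to do with it.
    """

    age: float  # days
    weight: float  # kg
    max_daily_gain: float  # g/day
    before_birth: bool = False


@dataclass
class GrowthCurveFit:
    params: GrowthModelParams
    r_squared: float
    residuals: np.ndarray
    converged: bool


def evaluate_model(params: GrowthModelParams, t) -> np.ndarray | float:
    """Model weight (kg) at age ``t`` (days; scalar or array)."""
    t = np.asarray(t, dtype=float)
    A, B, k = params.A, params.B, params.k
    decay = np.exp(-k * t)
    if params.model == "logistic":
        w = A / (1.0 + B * decay)
    elif params.model == "gompertz":
        w = A * np.exp(-B * decay)
    else:  # von_bertalanffy
        w = A * (1.0 - B * decay) ** 3
    return w if w.ndim else float(w)


def inflection_summary(params: GrowthModelParams) -> InflectionSummary:
    """Closed-form inflection age (d), weight (kg) and maximum gain (g/d).

    The maximum daily gain equals the model's first derivative at the
    inflection age, converted from kg/day to g/day.
    """
    A, B, k = params.A, params.B, params.k
    if params.model == "logistic":
        age = np.log(B) / k
        weight = A / 2.0
        gain_kg = k * weight / 2.0
    elif params.model == "gompertz":
        age = np.log(B) / k
        weight = A / np.e
        gain_kg = k * weight
    else:  # von_bertalanffy: inflection where the cubic's curvature flips
        age = np.log(3.0 * B) / k
        weight = 8.0 * A / 27.0
        gain_kg = 3.0 * k * weight / 2.0
    before_birth = age <= 0.0
    if before_birth:
        warnings.warn(
            f"{params.model}: inflection age {age:.2f} d precedes birth "
            "(shape argument <= 1); returning it unclamped",
            stacklevel=2,
        )
    return InflectionSummary(
        age=float(age),
        weight=float(weight),
        max_daily_gain=float(gain_kg * 1000.0),
        before_birth=before_birth,
    )


def goodness_of_fit(observed, predicted) -> float:
    """R² = 1 − SSE/SST with SST taken about the mean of ``observed``."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length, n >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("total sum of squares is zero (constant observations)")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def _linearizing_transform(w: np.ndarray, a0: float, model: str) -> np.ndarray:
    # each model is linear in t after this transform: z = const - k t
    if model == "logistic":
        return np.log(a0 / w - 1.0)
    if model == "gompertz":
        return np.log(np.log(a0 / w))
    return np.log(1.0 - (w / a0) ** (1.0 / 3.0))


def _initial_params(t: np.ndarray, w: np.ndarray, model: str) -> np.ndarray:
    a0 = 1.05 * float(w.max())
    lo, hi = np.percentile(w, [25, 75])
    mask = (w >= lo) & (w <= hi) & (w < 0.999 * a0)
    if mask.sum() < 2:
        mask = w < 0.999 * a0
    z = _linearizing_transform(w[mask], a0, model)
    slope = np.polyfit(t[mask], z, 1)[0] if mask.sum() >= 2 else -1e-3
    k0 = max(-float(slope), 1e-4)
    # shape constant from the earliest observation
    i0 = int(np.argmin(t))
    t1, w1 = float(t[i0]), min(float(w[i0]), 0.999 * a0)
    if model == "logistic":
        b0 = (a0 / w1 - 1.0) * np.exp(k0 * t1)
    elif model == "gompertz":
        b0 = np.log(a0 / w1) * np.exp(k0 * t1)
    else:
        b0 = (1.0 - (w1 / a0) ** (1.0 / 3.0)) * np.exp(k0 * t1)
    b0 = max(float(b0), 1e-6)
    return np.log([a0, b0, k0])


def fit_growth_curve(
    records: pd.DataFrame,
    model: str,
    max_iter: int = 500,
) -> GrowthCurveFit:
    """Least-squares fit of one model to pooled (age, weight) observations.

    ``records`` needs columns ``age_days`` and ``weight_kg`` (an
    ``animal_id`` column is accepted and ignored: observations are pooled).
    Parameters are fitted on the log scale, which enforces positivity, with
    a Levenberg–Marquardt solver. A fit that fails to converge, or a
    degenerate input (constant weights), is returned flagged with
    ``converged=False`` rather than raising.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    t = np.asarray(records["age_days"], dtype=float)
    w = np.asarray(records["weight_kg"], dtype=float)
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct ages to fit 3 parameters")
    if not np.all(w > 0):
        raise ValueError("weights must be positive")

    def degenerate() -> GrowthCurveFit:
        params = GrowthModelParams(model, float(w.mean()), 1.0, 1e-4)
        return GrowthCurveFit(
            params=params,
            r_squared=float("nan"),
            residuals=w - evaluate_model(params, t),
            converged=False,
        )

    if np.ptp(w) == 0.0:
        return degenerate()

    def resid(theta: np.ndarray) -> np.ndarray:
        a, b, kk = np.exp(theta)
        p = GrowthModelParams(model, a, b, kk)
        return np.asarray(evaluate_model(p, t)) - w

    try:
        x0 = _initial_params(t, w, model)
        sol = least_squares(
            resid, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=max_iter * 4,
        )
    except (ValueError, FloatingPointError):
        return degenerate()

    a, b, kk = np.exp(sol.x)
    params = GrowthModelParams(model, float(a), float(b), float(kk))
    pred = np.asarray(evaluate_model(params, t))
    try:
        r2 = goodness_of_fit(w, pred)
    except ValueError:
        r2 = float("nan")
    return GrowthCurveFit(
        params=params,
        r_squared=r2,
        residuals=w - pred,
        converged=bool(sol.success),
    )


def rank_models(fits: list[GrowthCurveFit]) -> list[GrowthCurveFit]:
    """Order fits by descending R²; ties broken by model name (lexicographic).

    NaN R² (degenerate fits) sorts last.
    """
    if not fits:
        raise ValueError("need at least one fit to rank")

    def key(f: GrowthCurveFit):
        r2 = f.r_squared if np.isfinite(f.r_squared) else -np.inf
        return (-r2, f.params.model)

    return sorted(fits, key=key)


def read_weight_records(path) -> pd.DataFrame:
    """Read a weight-record CSV with columns animal_id, age_days, weight_kg."""
    df = pd.read_csv(path)
    required = {"animal_id", "age_days", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight file missing columns: {sorted(missing)}")
    if (df["age_days"] < 0).any():
        raise ValueError("ages must be non-negative")
    if (df["weight_kg"] <= 0).any():
        raise ValueError("weights must be positive")
    return df


def fit_report(fits: list[GrowthCurveFit]) -> pd.DataFrame:
    """Tabular fit summary: parameters, R² and inflection quantities."""
    rows = []
    for f in rank_models(fits):
        p = f.params
        infl = inflection_summary(p)
        rows.append(
            {
                "model": p.model,
                "A": p.A,
                "B": p.B,
                "k": p.k,
                "R2": f.r_squared,
                "inflection_day": infl.age,
                "inflection_weight_kg": infl.weight,
                "max_daily_gain_g": infl.max_daily_gain,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
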