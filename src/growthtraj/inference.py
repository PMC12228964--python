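"""Trajectory quantities from a fitted growth-curve model.

Every quantity here — the predicted outcome at an age, the pointwise curve,
the area under the trajectory, and between-group contrasts — is a linear
combination ``c @ beta`` of the fixed effects, so its exact sampling variance
is ``c @ V @ c`` (the delta method is exact for linear contrasts) and 95%
Wald intervals follow.  The AUC uses the analytic antiderivative of the
fitted polynomial, not a grid approximation.

A parametric bootstrap (draws of ``beta* ~ N(beta_hat, V)``) is exposed both
as a verification oracle and for users who prefer percentile intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_core import FittedModel, Z975

__all__ = [
    "PredictionResult",
    "AUCResult",
    "ExtrapolationWarning",
    "default_profile",
    "contrast_vector",
    "predict_at_time",
    "trajectory_grid",
    "auc",
    "difference_at_time",
    "auc_difference",
    "parametric_bootstrap_ci",
]


class ExtrapolationWarning(UserWarning):
    """Requested time lies outside the range of the modelled data."""


@dataclass
class PredictionResult:
    """A point on the trajectory with its delta-method uncertainty."""

    time: float
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    contrast: np.ndarray
    extrapolated: bool = False


@dataclass
class AUCResult:
    """Area under the fitted trajectory between ``a`` and ``b``."""

    a: float
    b: float
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    weights: np.ndarray


def default_profile(fm: FittedModel, group=None) -> dict:
    """The display profile: continuous covariates at their fit-sample mean,
    categoricals at the reference (lowest) level, interaction variable at
    ``group`` (default: reference level / standardized mean zero).

    Values are resolved from ``encoding_info`` recorded at fit time, never
    recomputed from data.
    """
    profile: dict = {}
    for name, enc in fm.encoding_info["covariates"].items():
        profile[name] = enc["mean"] if enc["kind"] == "continuous" else enc["reference"]
    enc = fm.encoding_info["interaction"]
    if enc is not None:
        iname = fm.encoding_info["interaction_name"]
        if group is not None:
            profile[iname] = group
        elif enc["kind"] == "continuous":
            profile[iname] = enc["mean"]
        else:
            profile[iname] = enc["reference"]
    return profile


def _interaction_codes(fm: FittedModel, value) -> np.ndarray:
    """Encode an interaction-variable value into its design code(s)."""
    enc = fm.encoding_info["interaction"]
    if enc is None:
        raise ValueError(
            "model has no interaction variable; refit with interaction=... "
            "to compare groups"
        )
    if enc["kind"] == "continuous":
        return np.array([(float(value) - enc["mean"]) / enc["sd"]])
    levels = enc["levels"]
    matches = [lev for lev in levels if lev == value or str(lev) == str(value)]
    if not matches:
        raise ValueError(
            f"unknown level {value!r} for interaction variable; known levels: {levels}"
        )
    return np.array([1.0 if lev == matches[0] else 0.0 for lev in levels[1:]])


def _covariate_entries(fm: FittedModel, profile: dict) -> list[float]:
    entries: list[float] = []
    for name, enc in fm.encoding_info["covariates"].items():
        value = profile.get(name)
        if enc["kind"] == "continuous":
            entries.append(float(enc["mean"] if value is None else value))
        else:
            levels = enc["levels"]
            value = enc["reference"] if value is None else value
            matches = [lev for lev in levels if lev == value or str(lev) == str(value)]
            if not matches:
                raise ValueError(
                    f"unknown level {value!r} for covariate {name!r}; known: {levels}"
                )
            entries.extend(1.0 if lev == matches[0] else 0.0 for lev in levels[1:])
    return entries


def _poly_block(fm: FittedModel, t: float) -> np.ndarray:
    tc = t - fm.encoding_info["time_center"]
    D = fm.spec.fixed_degree
    return tc ** np.arange(D + 1)


def _check_range(fm: FittedModel, *times) -> bool:
    lo, hi = fm.encoding_info["time_range"]
    out = any(t < lo or t > hi for t in times)
    if out:
        warnings.warn(
            f"time outside the modelled range [{lo:g}, {hi:g}]; "
            "prediction is an extrapolation",
            ExtrapolationWarning,
            stacklevel=3,
        )
    return out


def contrast_vector(fm: FittedModel, t: float, profile: dict | None = None) -> np.ndarray:
    """The vector ``c`` with ``c @ beta`` = predicted outcome at time ``t``.

    Entries follow the design layout: polynomial terms ``(t - center)^d``,
    covariates encoded exactly as at fit time, interaction entries equal to
    the group code times each polynomial entry.
    """
    profile = {**default_profile(fm), **(profile or {})}
    poly = _poly_block(fm, t)
    entries = list(poly) + _covariate_entries(fm, profile)
    enc = fm.encoding_info["interaction"]
    if enc is not None:
        iname = fm.encoding_info["interaction_name"]
        codes = _interaction_codes(fm, profile[iname])
        for code in codes:
            entries.extend(code * poly)
    c = np.asarray(entries, float)
    if c.size != fm.p:
        raise RuntimeError("contrast length does not match design width")
    return c


def _wald(estimate: float, var: float) -> tuple[float, float, float]:
    se = float(np.sqrt(max(var, 0.0)))
    return se, estimate - Z975 * se, estimate + Z975 * se


def predict_at_time(fm: FittedModel, t: float, profile: dict | None = None,
                    group=None) -> PredictionResult:
    """Predicted outcome at time ``t`` with exact delta-method 95% CI."""
    if group is not None:
        profile = {**(profile or {}), fm.encoding_info["interaction_name"]: group}
    extrapolated = _check_range(fm, t)
    c = contrast_vector(fm, t, profile)
    est = float(c @ fm.beta)
    se, lo, hi = _wald(est, float(c @ fm.V @ c))
    return PredictionResult(float(t), est, se, lo, hi, c, extrapolated)


def trajectory_grid(fm: FittedModel, t_min: float, t_max: float, n_points: int = 101,
                    profiles: dict | list[dict] | None = None) -> list[list[PredictionResult]]:
    """Pointwise predictions on an evenly spaced grid, per covariate profile.

    Returns one list of :class:`PredictionResult` per profile (a single
    default profile if none given), with both endpoints included.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if t_min >= t_max:
        raise ValueError("t_min must be strictly below t_max")
    if profiles is None:
        profiles = [None]
    elif isinstance(profiles, dict):
        profiles = [profiles]
    times = np.linspace(t_min, t_max, n_points)
    return [[predict_at_time(fm, float(t), prof) for t in times] for prof in profiles]


def _auc_weights(fm: FittedModel, a: float, b: float, profile: dict) -> np.ndarray:
    """Exact integral weights: AUC = w @ beta.

    Polynomial degree ``d`` contributes ``((b-c)^{d+1} - (a-c)^{d+1})/(d+1)``
    with ``c`` the time_center; constant (covariate) columns contribute their
    encoded value times ``b - a``; interaction columns are the group code
    times the matching polynomial integral.
    """
    c0 = fm.encoding_info["time_center"]
    D = fm.spec.fixed_degree
    d = np.arange(D + 1)
    poly_int = ((b - c0) ** (d + 1) - (a - c0) ** (d + 1)) / (d + 1)
    entries = list(poly_int)
    entries += [v * (b - a) for v in _covariate_entries(fm, profile)]
    enc = fm.encoding_info["interaction"]
    if enc is not None:
        iname = fm.encoding_info["interaction_name"]
        codes = _interaction_codes(fm, profile[iname])
        for code in codes:
            entries.extend(code * poly_int)
    return np.asarray(entries, float)


def auc(fm: FittedModel, a: float, b: float, profile: dict | None = None,
        group=None) -> AUCResult:
    """Analytic area under the fitted trajectory between ``a`` and ``b``.

    The AUC is linear in ``beta`` so the delta-method variance ``w @ V @ w``
    is exact.  The integral is signed: negative fitted values subtract.
    """
    if a >= b:
        raise ValueError("AUC bounds require a < b")
    if group is not None:
        profile = {**(profile or {}), fm.encoding_info["interaction_name"]: group}
    profile = {**default_profile(fm), **(profile or {})}
    _check_range(fm, a, b)
    w = _auc_weights(fm, a, b, profile)
    est = float(w @ fm.beta)
    se, lo, hi = _wald(est, float(w @ fm.V @ w))
    return AUCResult(float(a), float(b), est, se, lo, hi, w)


def difference_at_time(fm: FittedModel, t: float, level_a, level_b) -> PredictionResult:
    """Group difference (level_a minus level_b) in the predicted outcome at
    ``t``, with delta-method CI.  All non-interaction covariate entries
    cancel, so the profile is irrelevant."""
    if fm.encoding_info.get("interaction") is None:
        raise ValueError(
            "model has no interaction variable; refit with interaction=... "
            "to compare groups"
        )
    iname = fm.encoding_info["interaction_name"]
    base = default_profile(fm)
    ca = contrast_vector(fm, t, {**base, iname: level_a})
    cb = contrast_vector(fm, t, {**base, iname: level_b})
    c = ca - cb
    _check_range(fm, t)
    est = float(c @ fm.beta)
    se, lo, hi = _wald(est, float(c @ fm.V @ c))
    return PredictionResult(float(t), est, se, lo, hi, c)


def auc_difference(fm: FittedModel, a: float, b: float, level_a, level_b) -> AUCResult:
    """Difference in trajectory AUC between two interaction-variable levels
    (level_a minus level_b) over ``[a, b]``."""
    if fm.encoding_info.get("interaction") is None:
        raise ValueError(
            "model has no interaction variable; refit with interaction=... "
            "to compare groups"
        )
    if a >= b:
        raise ValueError("AUC bounds require a < b")
    iname = fm.encoding_info["interaction_name"]
    base = default_profile(fm)
    wa = _auc_weights(fm, a, b, {**base, iname: level_a})
    wb = _auc_weights(fm, a, b, {**base, iname: level_b})
    w = wa - wb
    est = float(w @ fm.beta)
    se, lo, hi = _wald(est, float(w @ fm.V @ w))
    return AUCResult(float(a), float(b), est, se, lo, hi, w)


def parametric_bootstrap_ci(fm: FittedModel, vector: np.ndarray, n_draws: int = 2000,
                            seed: int | None = None, level: float = 0.95
                            ) -> tuple[float, float]:
    """Percentile CI of ``vector @ beta`` under ``beta* ~ N(beta_hat, V)``.

    Seeded and reproducible; converges to the Wald interval as ``n_draws``
    grows (the contrast is linear, hence exactly normal).
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    vector = np.asarray(vector, float)
    Vs = (fm.V + fm.V.T) / 2
    eigval, eigvec = np.linalg.eigh(Vs)
    if eigval.min() < -1e-8 * max(eigval.max(), 1.0):
        raise ValueError("V is not positive semidefinite")
    var = float(vector @ Vs @ vector)
    est = float(vector @ fm.beta)
    if var <= 0:
        return (est, est)
    rng = np.random.default_rng(seed)
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    beta_star = fm.beta + rng.standard_normal((n_draws, fm.p)) @ root.T
    draws = beta_star @ vector
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)
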