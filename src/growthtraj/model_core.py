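"""Polynomial growth-curve design matrices and linear mixed-model fitting.

The model for subject *i* with observation times :math:`t_{ij}` is

.. math::

    y_{ij} = \\sum_{d=0}^{D} \\beta_d\\, t_{c,ij}^d
             + \\mathbf{x}_{ij}^\\top \\boldsymbol\\beta_{\\mathrm{cov}}
             + \\sum_{d=0}^{q-1} u_{id}\\, t_{c,ij}^d + \\varepsilon_{ij},
    \\qquad u_i \\sim N(0, G),\\ \\varepsilon_{ij} \\sim N(0, \\sigma^2/w_{ij}),

with :math:`t_c = t - \\text{time\\_center}`, fixed polynomial degree
``D = fixed_degree`` (1..4) and ``q = random_degree + 1`` random terms
(intercept, slope, quadratic).  An optional interaction variable multiplies
every polynomial term, yielding group-specific trajectories.  Weights are
precision (inverse-variance) weights scaling the residual covariance as
``sigma2 * diag(1/w)``.

Estimation maximizes the ML or REML log-likelihood, profiling out ``beta``
and ``sigma2`` analytically and optimizing only the relative random-effect
covariance factor ``Lambda`` (``G = sigma2 * Lambda @ Lambda.T``) through its
log-Cholesky parameterization, which keeps ``G`` positive semidefinite by
construction.  Internally the polynomial basis is centered at the mean
modelled time for conditioning; estimates are mapped back to the requested
``time_center`` basis by the exact polynomial change-of-basis matrix, so all
predictions are invariant to the centering choice.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataprep import LongDataset

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "FittedModel",
    "DesignError",
    "ConvergenceError",
    "build_design",
    "loglikelihood",
    "fit_lmm",
    "fixed_effect_table",
    "random_effect_table",
    "formula_string",
    "parse_formula",
    "save_model",
    "load_model",
]

Z975 = stats.norm.ppf(0.975)  # 1.959963984540054

_SIGMA2_FLOOR = 1e-12


class DesignError(ValueError):
    """Raised for unusable design matrices (missing columns, collinearity...)."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a growth-curve model.

    ``covariates`` and ``interaction`` entries are ``(name, kind)`` with kind
    ``"continuous"`` or ``"categorical"``.  ``time_center=None`` means
    "center at the mean modelled time".  Estimator is ``"ML"`` (default) or
    ``"REML"``.  ``fixed_degree=0`` fits an intercept-only mean (useful for
    variance-component models); user-facing trajectory models use 1-4.
    """

    fixed_degree: int = 1
    random_degree: int = 1
    covariates: tuple[tuple[str, str], ...] = ()
    interaction: tuple[str, str] | None = None
    estimator: str = "ML"
    weights_col: str | None = None
    time_center: float | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "covariates", tuple((str(n), str(k)) for n, k in self.covariates)
        )
        if self.interaction is not None:
            object.__setattr__(
                self, "interaction", (self.interaction[0], self.interaction[1])
            )
        if self.fixed_degree not in (0, 1, 2, 3, 4):
            raise ValueError("fixed_degree must be in {0,1,2,3,4} (0 = intercept only)")
        if self.random_degree not in (0, 1, 2):
            raise ValueError("random_degree must be in {0,1,2}")
        if self.random_degree > self.fixed_degree:
            raise ValueError("random_degree must not exceed fixed_degree")
        if self.estimator not in ("ML", "REML"):
            raise ValueError("estimator must be 'ML' or 'REML'")
        if self.interaction is not None and self.interaction[0] in (
            n for n, _ in self.covariates
        ):
            raise ValueError("interaction variable must not also be a covariate")

    @property
    def q(self) -> int:
        return self.random_degree + 1


@dataclass
class DesignMatrices:
    """Assembled fixed/random design for fitting.

    Rows with missing outcome, time, covariate, interaction or weight value
    are absent; ``n_dropped`` counts them.  ``subject_index`` maps each row
    to ``subjects``.  ``time`` holds raw (uncentered) times; ``X``/``Z`` are
    built in the ``time_center`` basis recorded in ``encoding_info``.
    """

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    w: np.ndarray
    time: np.ndarray
    subject_index: np.ndarray
    subjects: np.ndarray
    term_names: list[str]
    encoding_info: dict
    spec: ModelSpec
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_subjects(self) -> int:
        return self.subjects.size


@dataclass
class FittedModel:
    """Estimates and metadata from a mixed-model fit.

    ``beta``/``V`` are the fixed effects and their covariance, ``G`` the
    random-effect covariance, ``sigma2`` the residual variance, all in the
    ``time_center`` basis recorded in ``encoding_info``.  ``deviance`` is
    exactly ``-2 * loglik`` of the chosen estimator.
    """

    beta: np.ndarray
    V: np.ndarray
    G: np.ndarray
    sigma2: float
    loglik: float
    n_obs: int
    n_subjects: int
    converged: bool
    singular: bool
    spec: ModelSpec
    term_names: list[str]
    encoding_info: dict
    diagnostics: dict = field(default_factory=dict)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def p(self) -> int:
        return self.beta.size


# ---------------------------------------------------------------------------
# design construction


def _sorted_levels(values: pd.Series) -> list:
    """Levels of a categorical, numeric order when all parse as numbers,
    otherwise lexicographic; the first level is the reference."""
    levels = pd.unique(values.dropna())
    try:
        order = np.argsort([float(v) for v in levels], kind="stable")
    except (TypeError, ValueError):
        order = np.argsort([str(v) for v in levels], kind="stable")
    return [levels[i] for i in order]


def build_design(ds: LongDataset, spec: ModelSpec) -> DesignMatrices:
    """Build fixed (X) and random (Z) design matrices from a long dataset.

    X columns, in order: intercept, ``t_c .. t_c^D``, covariate main effects,
    interaction main effect(s), interaction x polynomial terms.  Continuous
    interaction variables are standardized (mean 0, sd 1, n-1 denominator);
    categorical variables are treatment-coded against their lowest level.
    Centering/standardization constants are recorded in ``encoding_info`` so
    that downstream contrasts reproduce the encoding exactly.
    """
    df = ds.data
    needed = [ds.outcome_col, ds.time_col]
    for name, _ in spec.covariates:
        if name not in df.columns:
            raise DesignError(f"covariate column {name!r} not in dataset")
        needed.append(name)
    if spec.interaction is not None:
        if spec.interaction[0] not in df.columns:
            raise DesignError(f"interaction column {spec.interaction[0]!r} not in dataset")
        needed.append(spec.interaction[0])
    if spec.weights_col is not None:
        if spec.weights_col not in df.columns:
            raise DesignError(f"weights column {spec.weights_col!r} not in dataset")
        needed.append(spec.weights_col)

    complete = np.ones(len(df), dtype=bool)
    for col in needed:
        complete &= df[col].notna().to_numpy()
    n_dropped = int((~complete).sum())
    sub = df.loc[complete]
    if sub.empty:
        raise DesignError("no complete rows left after removing missing data")

    y = pd.to_numeric(sub[ds.outcome_col]).to_numpy(float)
    t = pd.to_numeric(sub[ds.time_col]).to_numpy(float)
    if spec.weights_col is not None:
        w = pd.to_numeric(sub[spec.weights_col]).to_numpy(float)
        if np.any(w <= 0):
            raise DesignError("weights must be strictly positive")
    else:
        w = np.ones_like(y)

    subjects, subject_index = np.unique(sub[ds.subject_col].to_numpy(), return_inverse=True)
    if subjects.size < 2:
        raise DesignError("at least 2 subjects with complete rows are required")

    center = float(np.mean(t)) if spec.time_center is None else float(spec.time_center)
    tc = t - center

    D = spec.fixed_degree
    time_name = ds.time_col
    cols: list[np.ndarray] = [np.ones_like(tc)]
    names: list[str] = ["(Intercept)"]
    for d in range(1, D + 1):
        cols.append(tc**d)
        names.append(time_name if d == 1 else f"I({time_name}^{d})")

    enc_cov: dict[str, dict] = {}
    for name, kind in spec.covariates:
        vals = sub[name]
        if kind == "continuous":
            x = pd.to_numeric(vals).to_numpy(float)
            enc_cov[name] = {"kind": "continuous", "mean": float(np.mean(x))}
            cols.append(x)
            names.append(name)
        elif kind == "categorical":
            levels = _sorted_levels(vals)
            if len(levels) < 2:
                raise DesignError(f"categorical covariate {name!r} has a single level")
            enc_cov[name] = {
                "kind": "categorical",
                "levels": [_jsonable(l) for l in levels],
                "reference": _jsonable(levels[0]),
            }
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(float))
                names.append(f"{name}[{lev}]")
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")

    enc_inter = None
    if spec.interaction is not None:
        iname, ikind = spec.interaction
        vals = sub[iname]
        if ikind == "continuous":
            x = pd.to_numeric(vals).to_numpy(float)
            mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
            if sd == 0:
                raise DesignError(f"interaction variable {iname!r} is constant")
            g = (x - mu) / sd
            enc_inter = {"kind": "continuous", "mean": mu, "sd": sd}
            codes = [(iname, g)]
        elif ikind == "categorical":
            levels = _sorted_levels(vals)
            if len(levels) < 2:
                raise DesignError(f"interaction variable {iname!r} has a single level")
            enc_inter = {
                "kind": "categorical",
                "levels": [_jsonable(l) for l in levels],
                "reference": _jsonable(levels[0]),
            }
            codes = [(f"{iname}[{lev}]", (vals == lev).to_numpy(float)) for lev in levels[1:]]
        else:
            raise ValueError(f"unknown interaction kind {ikind!r}")
        for label, g in codes:
            cols.append(g)
            names.append(label)
            for d in range(1, D + 1):
                cols.append(g * tc**d)
                names.append(f"{label}:{names[d]}" if d > 1 else f"{label}:{time_name}")

    X = np.column_stack(cols)
    _check_rank(X, names)

    q = spec.q
    Z = np.column_stack([tc**d for d in range(q)])

    encoding_info = {
        "time_center": center,
        "time_name": time_name,
        "time_range": [float(t.min()), float(t.max())],
        "outcome_name": ds.outcome_col,
        "subject_name": ds.subject_col,
        "covariates": enc_cov,
        "interaction": enc_inter,
        "interaction_name": spec.interaction[0] if spec.interaction else None,
        "n_dropped": n_dropped,
    }
    return DesignMatrices(
        X=X, Z=Z, y=y, w=w, time=t,
        subject_index=subject_index, subjects=subjects,
        term_names=names, encoding_info=encoding_info, spec=spec,
        n_dropped=n_dropped,
    )


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Hard error naming (near-)collinear columns rather than silent drop."""
    # scale columns to unit norm so the tolerance is scale-free
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        bad = [names[j] for j in np.where(norms == 0)[0]]
        raise DesignError(f"design columns are identically zero: {bad}")
    _, R, piv = _qr_pivot(X / norms)
    diag = np.abs(np.diag(R))
    tol = X.shape[0] * np.finfo(float).eps * diag.max()
    deficient = np.where(diag < max(tol, 1e-10))[0]
    if deficient.size:
        bad = [names[piv[j]] for j in deficient]
        raise DesignError(f"rank-deficient design; collinear columns: {bad}")


def _qr_pivot(A):
    from scipy.linalg import qr

    Q, R, piv = qr(A, mode="economic", pivoting=True)
    return Q, R, piv


# ---------------------------------------------------------------------------
# likelihood


def _group_by_subject(dm: DesignMatrices):
    """Group rows by subject, batching subjects with equal cluster size into
    stacked 3-D arrays for vectorized linear algebra."""
    order = np.argsort(dm.subject_index, kind="stable")
    idx = dm.subject_index[order]
    X, Z, y, w = dm.X[order], dm.Z[order], dm.y[order], dm.w[order]
    starts = np.flatnonzero(np.r_[True, np.diff(idx) != 0])
    stops = np.r_[starts[1:], idx.size]
    sizes = stops - starts
    groups = []
    for size in np.unique(sizes):
        sel = np.flatnonzero(sizes == size)
        rows = np.concatenate([np.arange(starts[i], stops[i]) for i in sel])
        m = sel.size
        groups.append(
            (
                X[rows].reshape(m, size, -1),
                Z[rows].reshape(m, size, -1),
                y[rows].reshape(m, size),
                w[rows].reshape(m, size),
                idx[starts[sel]],
            )
        )
    return groups


def _profiled_pieces(groups, Lam: np.ndarray, p: int):
    """Accumulate sufficient statistics of the profiled deviance.

    Returns (logdet_sum, A, c, d) with A = sum X'V*^-1 X, c = sum X'V*^-1 y,
    d = sum y'V*^-1 y, logdet_sum = sum log|V*|, where V* is the residual-
    relative marginal covariance Z Lam Lam' Z' + diag(1/w).
    """
    A = np.zeros((p, p))
    c = np.zeros(p)
    d = 0.0
    ld = 0.0
    LamLamT = Lam @ Lam.T
    for X3, Z3, y2, w2, _ in groups:
        m, n, _ = X3.shape
        V = Z3 @ LamLamT @ np.swapaxes(Z3, 1, 2)
        V[:, np.arange(n), np.arange(n)] += 1.0 / w2
        L = np.linalg.cholesky(V)
        a = np.linalg.solve(L, X3)
        b = np.linalg.solve(L, y2[..., None])[..., 0]
        ld += 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)))
        A += np.einsum("mni,mnj->ij", a, a)
        c += np.einsum("mni,mn->i", a, b)
        d += float(np.sum(b * b))
    return ld, A, c, d


def _theta_to_lambda(theta: np.ndarray, q: int) -> np.ndarray:
    """Log-Cholesky: diagonal entries exp(theta), off-diagonals free."""
    Lam = np.zeros((q, q))
    Lam[np.diag_indices(q)] = np.exp(theta[:q])
    if q > 1:
        Lam[np.tril_indices(q, -1)] = theta[q:]
    return Lam


def _profiled_deviance(theta, groups, n, p, q, estimator):
    Lam = _theta_to_lambda(np.asarray(theta, float), q)
    ld, A, c, d = _profiled_pieces(groups, Lam, p)
    try:
        cho = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return 1e12
    beta = _cho_solve(cho, c)
    r2 = max(d - float(c @ beta), _SIGMA2_FLOOR)
    if estimator == "ML":
        sigma2 = r2 / n
        dev = ld + n * (math.log(2 * math.pi * sigma2) + 1.0)
    else:
        sigma2 = r2 / (n - p)
        ldA = 2.0 * np.sum(np.log(np.diag(cho)))
        dev = ld + ldA + (n - p) * (math.log(2 * math.pi * sigma2) + 1.0)
    return dev


def _cho_solve(cho, b):
    from scipy.linalg import cho_solve

    return cho_solve((cho, True), b)


def loglikelihood(dm: DesignMatrices, beta, G, sigma2, estimator: str = "ML") -> float:
    """Evaluate the (restricted) log-likelihood at given parameters.

    ML: the sum over subjects of the multivariate-normal log-density of
    ``y_i`` with mean ``X_i beta`` and covariance ``Z_i G Z_i' + sigma2/w``.
    REML: the ML value minus ``0.5*log|sum X_i' V_i^-1 X_i|`` plus
    ``(p/2)*log(2*pi)`` (the convention whose maximum equals the standard
    restricted-likelihood criterion).
    """
    beta = np.asarray(beta, float)
    G = np.asarray(G, float)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    eig = np.linalg.eigvalsh((G + G.T) / 2)
    if eig.min() < -1e-10 * max(eig.max(), 1.0):
        raise ValueError("G must be positive semidefinite")

    groups = _group_by_subject(dm)
    p = dm.X.shape[1]
    ll = 0.0
    Info = np.zeros((p, p))
    for X3, Z3, y2, w2, _ in groups:
        m, n, _ = X3.shape
        V = Z3 @ G @ np.swapaxes(Z3, 1, 2)
        V[:, np.arange(n), np.arange(n)] += sigma2 / w2
        L = np.linalg.cholesky(V)
        resid = y2 - np.einsum("mnp,p->mn", X3, beta)
        b = np.linalg.solve(L, resid[..., None])[..., 0]
        ll -= 0.5 * float(np.sum(b * b))
        ll -= float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
        ll -= 0.5 * m * n * math.log(2 * math.pi)
        if estimator == "REML":
            a = np.linalg.solve(L, X3)
            Info += np.einsum("mni,mnj->ij", a, a)
    if estimator == "REML":
        sign, ldet = np.linalg.slogdet(Info)
        ll -= 0.5 * ldet
        ll += 0.5 * p * math.log(2 * math.pi)
    return float(ll)


def _poly_shift_matrix(degree: int, delta: float) -> np.ndarray:
    """Matrix M with (t - c0)^d = sum_k M[k, d] (t - c)^k for delta = c - c0:
    re-expresses polynomial coefficients after shifting the center."""
    M = np.zeros((degree + 1, degree + 1))
    for d in range(degree + 1):
        for k in range(d + 1):
            M[k, d] = math.comb(d, k) * delta ** (d - k)
    return M


def _basis_transform(spec: ModelSpec, p: int, delta: float, n_inter_codes: int):
    """Block change-of-basis for beta (and its random-effect counterpart)."""
    D = spec.fixed_degree
    M = _poly_shift_matrix(D, delta)
    A = np.eye(p)
    A[: D + 1, : D + 1] = M
    if n_inter_codes:
        n_cov_cols = p - (D + 1) - n_inter_codes * (D + 1)
        off = D + 1 + n_cov_cols
        for j in range(n_inter_codes):
            s = off + j * (D + 1)
            A[s : s + D + 1, s : s + D + 1] = M
    Mq = _poly_shift_matrix(spec.random_degree, delta)
    return A, Mq


def _n_interaction_codes(dm: DesignMatrices) -> int:
    enc = dm.encoding_info.get("interaction")
    if enc is None:
        return 0
    if enc["kind"] == "continuous":
        return 1
    return len(enc["levels"]) - 1


def fit_lmm(dm: DesignMatrices, spec: ModelSpec | None = None) -> FittedModel:
    """Fit the linear mixed model by ML or REML.

    ``beta`` and ``sigma2`` are profiled out analytically; the optimizer
    works on the log-Cholesky factor of the relative covariance
    ``Lambda = chol(G / sigma2)``, guaranteeing a positive-semidefinite
    ``G`` by construction.  The fit is performed in a mean-centered
    polynomial basis for conditioning and mapped back exactly to the basis
    implied by the requested ``time_center``, so fitted values and all
    downstream predictions are invariant to centering.

    Raises :class:`ConvergenceError` with optimizer diagnostics on failure;
    near-zero random-effect variances set ``singular=True`` (a warning, not
    an error, mirroring boundary fits).
    """
    spec = spec or dm.spec
    n, p = dm.X.shape
    q = spec.q

    # refit design in the internally centered basis (exact change of basis)
    c_user = dm.encoding_info["time_center"]
    c0 = float(np.mean(dm.time))
    delta = c_user - c0
    if delta == 0.0:
        Ab, Mq = np.eye(p), np.eye(q)
        dm0 = dm
    else:
        Ab, Mq = _basis_transform(spec, p, delta, _n_interaction_codes(dm))
        # rebuild X and Z in the c0 basis directly from raw times so the
        # optimization is bit-identical whatever time_center was requested
        # (X_user beta_user = X0 beta0 with beta_user = Ab beta0)
        D = spec.fixed_degree
        tc0 = dm.time - c0
        X0 = dm.X.copy()
        for d in range(D + 1):
            X0[:, d] = tc0**d
        n_codes = _n_interaction_codes(dm)
        off = p - n_codes * (D + 1)
        for j in range(n_codes):
            g = dm.X[:, off + j * (D + 1)]  # interaction main-effect column
            for d in range(1, D + 1):
                X0[:, off + j * (D + 1) + d] = g * tc0**d
        Z0 = np.column_stack([tc0**d for d in range(q)])
        dm0 = DesignMatrices(
            X=X0, Z=Z0, y=dm.y, w=dm.w, time=dm.time,
            subject_index=dm.subject_index, subjects=dm.subjects,
            term_names=dm.term_names, encoding_info=dm.encoding_info, spec=spec,
            n_dropped=dm.n_dropped,
        )
    groups = _group_by_subject(dm0)

    ntheta = q * (q + 1) // 2
    theta0 = np.zeros(ntheta)
    bounds = [(-10.0, 8.0)] * q + [(-1e3, 1e3)] * (ntheta - q)

    def _minimize(start):
        return optimize.minimize(
            _profiled_deviance,
            start,
            args=(groups, n, p, q, spec.estimator),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )

    res = _minimize(theta0)
    if np.min(res.x[:q]) < -5.0:
        # a relative variance collapsed to the boundary, where the profile is
        # flat and a large first step can strand the line search; restart
        # from nearby interior points and keep the best optimum found
        for diag0 in (-1.5, 1.0):
            start = theta0.copy()
            start[:q] = diag0
            alt = _minimize(start)
            if alt.fun < res.fun:
                res = alt
    if not res.success:
        # quasi-Newton can abort on flat or kinked profiles (tiny or
        # boundary cases); a simplex restart is slower but far more robust
        for start in (res.x, theta0):
            alt = optimize.minimize(
                _profiled_deviance,
                start,
                args=(groups, n, p, q, spec.estimator),
                method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
            )
            if alt.fun <= res.fun or res.fun != res.fun:
                res = alt
            if res.success:
                break
    res.x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    diagnostics = {
        "iterations": int(res.nit),
        "n_evaluations": int(res.nfev),
        "gradient_norm": float(np.max(np.abs(res.jac)))
        if getattr(res, "jac", None) is not None
        else np.nan,
        "message": str(res.message),
        "estimator": spec.estimator,
    }
    if not res.success:
        raise ConvergenceError(
            f"mixed-model optimizer failed: {res.message}", diagnostics
        )

    Lam = _theta_to_lambda(res.x, q)
    ld, A, c, d = _profiled_pieces(groups, Lam, p)
    cho = np.linalg.cholesky(A)
    beta0 = _cho_solve(cho, c)
    r2 = max(d - float(c @ beta0), _SIGMA2_FLOOR)
    if spec.estimator == "ML":
        sigma2 = r2 / n
        loglik = -0.5 * (ld + n * (math.log(2 * math.pi * sigma2) + 1.0))
    else:
        sigma2 = r2 / (n - p)
        ldA = 2.0 * np.sum(np.log(np.diag(cho)))
        loglik = -0.5 * (ld + ldA + (n - p) * (math.log(2 * math.pi * sigma2) + 1.0))
    V0 = sigma2 * _cho_solve(cho, np.eye(p))
    G0 = sigma2 * (Lam @ Lam.T)

    # map back to the user-requested basis
    beta = Ab @ beta0
    V = Ab @ V0 @ Ab.T
    V = (V + V.T) / 2
    G = Mq @ G0 @ Mq.T
    G = (G + G.T) / 2

    eig = np.linalg.eigvalsh(G)
    singular = bool(eig.min() < 1e-8 * max(np.trace(G), 1.0))
    if singular:
        warnings.warn(
            "random-effect covariance is singular (boundary fit); "
            "some variance components are effectively zero",
            RuntimeWarning,
            stacklevel=2,
        )

    return FittedModel(
        beta=beta, V=V, G=G, sigma2=float(sigma2), loglik=float(loglik),
        n_obs=n, n_subjects=dm.n_subjects,
        converged=True, singular=singular,
        spec=spec, term_names=list(dm.term_names),
        encoding_info=dict(dm.encoding_info), diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# summaries


def fixed_effect_table(fm: FittedModel) -> pd.DataFrame:
    """Wald summary of the fixed effects: estimate, SE, 95% CI, z, p.

    The CI multiplier is the exact normal 97.5% quantile; p-values are
    two-sided Wald z tests.  A zero SE yields missing z/p with a warning.
    """
    se = np.sqrt(np.clip(np.diag(fm.V), 0, None))
    est = fm.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.nan)
    if np.any(se == 0):
        warnings.warn("zero standard error; z and p reported as missing", RuntimeWarning)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": fm.term_names,
            "estimate": est,
            "se": se,
            "ci_low": est - Z975 * se,
            "ci_high": est + Z975 * se,
            "z": z,
            "p": p,
        }
    )


def random_effect_table(fm: FittedModel) -> pd.DataFrame:
    """Variances, covariances and correlations of the random terms plus the
    residual variance, derived exactly from ``G`` and ``sigma2``."""
    q = fm.G.shape[0]
    labels = ["intercept", "slope", "quadratic"][:q]
    rows = []
    for i in range(q):
        rows.append(
            {
                "term": labels[i],
                "variance": fm.G[i, i],
                "sd": math.sqrt(max(fm.G[i, i], 0.0)),
                "covariance_with": None,
                "covariance": np.nan,
                "correlation": np.nan,
            }
        )
    for i in range(q):
        for j in range(i + 1, q):
            denom = math.sqrt(max(fm.G[i, i] * fm.G[j, j], 0.0))
            rows.append(
                {
                    "term": labels[i],
                    "variance": np.nan,
                    "sd": np.nan,
                    "covariance_with": labels[j],
                    "covariance": fm.G[i, j],
                    "correlation": fm.G[i, j] / denom if denom > 0 else np.nan,
                }
            )
    rows.append(
        {
            "term": "residual",
            "variance": fm.sigma2,
            "sd": math.sqrt(fm.sigma2),
            "covariance_with": None,
            "covariance": np.nan,
            "correlation": np.nan,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# formula round trip


def formula_string(
    spec: ModelSpec,
    outcome: str = "y",
    time: str = "t",
    subject: str = "id",
) -> str:
    """Render the model as a Wilkinson-notation formula, e.g.
    ``sdq ~ age + I(age^2) + I(age^3) + (1 + age + I(age^2) | subject)``."""

    def poly(d):
        return time if d == 1 else f"I({time}^{d})"

    fixed = [poly(d) for d in range(1, spec.fixed_degree + 1)]
    for name, _ in spec.covariates:
        fixed.append(name)
    if spec.interaction is not None:
        f = spec.interaction[0]
        fixed.append(f)
        fixed.extend(f"{f}:{poly(d)}" for d in range(1, spec.fixed_degree + 1))
    rand = ["1"] + [poly(d) for d in range(1, spec.random_degree + 1)]
    if not fixed:
        fixed = ["1"]
    return f"{outcome} ~ " + " + ".join(fixed) + f" + ({' + '.join(rand)} | {subject})"


def parse_formula(text: str) -> tuple[ModelSpec, dict]:
    """Parse a formula produced by :func:`formula_string` back into a
    :class:`ModelSpec` plus the outcome/time/subject names.

    Covariate/interaction kinds are not encoded in the formula; they come
    back as ``"continuous"`` unless the term reappears interacted with time,
    in which case it is the interaction variable (kind defaults continuous).
    """
    import re

    lhs, rhs = [s.strip() for s in text.split("~", 1)]
    bar = rhs.find("|")
    if bar < 0:
        raise ValueError("formula lacks a random-effects term '(... | subject)'")
    # match the parenthesis pair enclosing the '|', respecting nested I(...)
    depth = 0
    start = -1
    for i in range(bar - 1, -1, -1):
        if rhs[i] == ")":
            depth += 1
        elif rhs[i] == "(":
            if depth == 0:
                start = i
                break
            depth -= 1
    depth = 0
    stop = -1
    for i in range(bar + 1, len(rhs)):
        if rhs[i] == "(":
            depth += 1
        elif rhs[i] == ")":
            if depth == 0:
                stop = i
                break
            depth -= 1
    if start < 0 or stop < 0:
        raise ValueError("unbalanced parentheses around the random-effects term")
    rand_part = rhs[start + 1 : bar].strip()
    subject = rhs[bar + 1 : stop].strip()
    fixed_part = (rhs[:start] + rhs[stop + 1 :]).strip().strip("+").strip()

    def term_degree(term, time):
        if term == time:
            return 1
        dm_ = re.fullmatch(rf"I\({re.escape(time)}\^(\d+)\)", term)
        return int(dm_.group(1)) if dm_ else None

    fixed_terms = [s.strip() for s in fixed_part.split("+") if s.strip()]
    rand_terms = [s.strip() for s in rand_part.split("+") if s.strip()]

    # the time variable is the first bare fixed term that also appears as I(x^2)
    # or is the first term
    time = fixed_terms[0]
    fixed_degree = 1
    for term in fixed_terms:
        d = term_degree(term, time)
        if d:
            fixed_degree = max(fixed_degree, d)
    random_degree = 0
    for term in rand_terms:
        if term == "1":
            continue
        d = term_degree(term, time)
        if d is None:
            raise ValueError(f"unrecognized random term {term!r}")
        random_degree = max(random_degree, d)

    covariates = []
    interaction = None
    inter_names = set()
    for term in fixed_terms:
        if ":" in term:
            inter_names.add(term.split(":", 1)[0])
    for term in fixed_terms:
        if ":" in term or term_degree(term, time):
            continue
        if term in inter_names:
            interaction = (term, "continuous")
        else:
            covariates.append((term, "continuous"))

    spec = ModelSpec(
        fixed_degree=fixed_degree,
        random_degree=random_degree,
        covariates=tuple(covariates),
        interaction=interaction,
    )
    return spec, {"outcome": lhs, "time": time, "subject": subject}


# ---------------------------------------------------------------------------
# serialization


def save_model(fm: FittedModel, path) -> None:
    """Write a fitted model as versioned JSON with full-precision reals."""
    doc = {
        "schema": "growthtraj-model-v1",
        "spec": {
            "fixed_degree": fm.spec.fixed_degree,
            "random_degree": fm.spec.random_degree,
            "covariates": [list(c) for c in fm.spec.covariates],
            "interaction": list(fm.spec.interaction) if fm.spec.interaction else None,
            "estimator": fm.spec.estimator,
            "weights_col": fm.spec.weights_col,
            "time_center": fm.spec.time_center,
        },
        "beta": fm.beta.tolist(),
        "V": fm.V.tolist(),
        "G": fm.G.tolist(),
        "sigma2": fm.sigma2,
        "loglik": fm.loglik,
        "deviance": fm.deviance,
        "n_obs": fm.n_obs,
        "n_subjects": fm.n_subjects,
        "converged": fm.converged,
        "singular": fm.singular,
        "term_names": fm.term_names,
        "encoding_info": fm.encoding_info,
        "diagnostics": fm.diagnostics,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> FittedModel:
    """Load a fitted model written by :func:`save_model`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema") != "growthtraj-model-v1":
        raise ValueError(f"unrecognized model schema {doc.get('schema')!r}")
    s = doc["spec"]
    spec = ModelSpec(
        fixed_degree=s["fixed_degree"],
        random_degree=s["random_degree"],
        covariates=tuple((n, k) for n, k in s["covariates"]),
        interaction=tuple(s["interaction"]) if s["interaction"] else None,
        estimator=s["estimator"],
        weights_col=s["weights_col"],
        time_center=s["time_center"],
    )
    return FittedModel(
        beta=np.asarray(doc["beta"], float),
        V=np.asarray(doc["V"], float),
        G=np.asarray(doc["G"], float),
        sigma2=float(doc["sigma2"]),
        loglik=float(doc["loglik"]),
        n_obs=int(doc["n_obs"]),
        n_subjects=int(doc["n_subjects"]),
        converged=bool(doc["converged"]),
        singular=bool(doc["singular"]),
        spec=spec,
        term_names=list(doc["term_names"]),
        encoding_info=dict(doc["encoding_info"]),
        diagnostics=dict(doc.get("diagnostics", {})),
    )
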