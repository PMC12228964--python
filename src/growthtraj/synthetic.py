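"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the structure of a birth-cohort repeated-measures
study: each subject follows a polynomial mean trajectory in age plus
correlated subject-level deviations (random intercept/slope/quadratic),
measurement ages jitter around nominal occasion ages (real cohorts measure
children at varying ages around each sweep), residual noise is Gaussian, an
optional binary group shifts both the level and the shape of the trajectory,
and missingness can be completely-at-random per occasion and/or monotone
dropout.  Everything flows from a single seed.

The default configuration mimics the shape of a five-sweep childhood
emotional-symptoms cohort: nominal ages 3, 5, 7, 11, 14, a gently rising
cubic mean trend on a 0-10 score scale, and random intercept + linear +
quadratic subject deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataprep import WideSpec, reshape_wide_to_long
from .model_core import ModelSpec, build_design, fit_lmm, ConvergenceError, Z975

__all__ = [
    "SimConfig",
    "default_config",
    "simulate_cohort",
    "apply_missingness",
    "recovery_study",
    "analytic_auc_truth",
]


@dataclass(frozen=True)
class SimConfig:
    """True parameters for the cohort generator.

    ``beta_true`` are polynomial coefficients on the original age scale
    (constant first); ``G_true`` is the random-effect covariance for the
    ``q`` leading polynomial terms; ``group`` optionally adds a Bernoulli
    group with a main effect and per-degree interaction coefficients;
    ``mcar_rate`` deletes occasion cells completely at random and
    ``dropout_hazard`` is the per-occasion probability of permanent dropout.
    """

    n_subjects: int = 500
    occasions: tuple[tuple[float, float], ...] = (
        (3.0, 0.25), (5.0, 0.25), (7.0, 0.25), (11.0, 0.25), (14.0, 0.25),
    )
    beta_true: tuple[float, ...] = (0.6, 0.25, -0.02, 0.0006)
    G_true: tuple[tuple[float, ...], ...] = (
        (0.2, -0.01, 0.0),
        (-0.01, 0.005, 0.0),
        (0.0, 0.0, 2.5e-5),
    )
    sigma2_true: float = 0.25
    group_prevalence: float | None = None
    group_main: float = 0.0
    group_interactions: tuple[float, ...] = ()
    mcar_rate: float = 0.0
    dropout_hazard: float = 0.0
    seed: int = 0

    def __post_init__(self):
        G = np.asarray(self.G_true, float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("G_true must be square")
        if not np.allclose(G, G.T):
            raise ValueError("G_true must be symmetric")
        if np.linalg.eigvalsh(G).min() < -1e-12:
            raise ValueError("G_true must be positive semidefinite")
        if self.sigma2_true <= 0:
            raise ValueError("sigma2_true must be positive")
        if len(self.occasions) < 2:
            raise ValueError("at least 2 occasions required")
        if not 0.0 <= self.mcar_rate < 1.0:
            raise ValueError("mcar_rate must be in [0, 1)")
        if not 0.0 <= self.dropout_hazard < 1.0:
            raise ValueError("dropout_hazard must be in [0, 1)")
        if self.group_prevalence is not None and not 0.0 < self.group_prevalence < 1.0:
            raise ValueError("group_prevalence must be in (0, 1)")

    @property
    def degree(self) -> int:
        return len(self.beta_true) - 1

    @property
    def q(self) -> int:
        return len(self.G_true)

    def wide_spec(self) -> WideSpec:
        k = len(self.occasions)
        return WideSpec(
            subject_col="subject",
            age_cols=tuple(f"age_t{j+1}" for j in range(k)),
            outcome_cols=tuple(f"score_t{j+1}" for j in range(k)),
            occasion_name="occ",
            outcome_name="score",
            age_name="age",
        )


def default_config(**overrides) -> SimConfig:
    """The default five-occasion cubic demo cohort, optionally overridden."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


def simulate_cohort(cfg: SimConfig, seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Draw one wide-format cohort; returns ``(wide_table, truth)``.

    For subject *i*: ``u_i ~ N(0, G_true)``; occasion age = nominal age +
    jitter; outcome = fixed polynomial (plus group terms when the subject is
    in the group) + random-effect polynomial + residual noise.  ``truth``
    records every generating parameter and the seed actually used.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = cfg.n_subjects
    k = len(cfg.occasions)
    beta = np.asarray(cfg.beta_true, float)
    G = np.asarray(cfg.G_true, float)
    q = G.shape[0]

    u = rng.multivariate_normal(np.zeros(q), G, size=n, method="eigh")
    nominal = np.array([a for a, _ in cfg.occasions])
    jitter_sd = np.array([s for _, s in cfg.occasions])
    ages = nominal[None, :] + rng.normal(0.0, 1.0, size=(n, k)) * jitter_sd[None, :]

    if cfg.group_prevalence is not None:
        grp = (rng.random(n) < cfg.group_prevalence).astype(int)
        gamma = np.zeros(cfg.degree + 1)
        gamma[0] = cfg.group_main
        gi = np.asarray(cfg.group_interactions, float)
        gamma[1 : 1 + gi.size] = gi
    else:
        grp = None
        gamma = np.zeros(cfg.degree + 1)

    powers_f = ages[..., None] ** np.arange(cfg.degree + 1)  # (n, k, D+1)
    mean = powers_f @ beta
    if grp is not None:
        mean = mean + (powers_f @ gamma) * grp[:, None]
    re_part = np.einsum("nkq,nq->nk", ages[..., None] ** np.arange(q), u)
    eps = rng.normal(0.0, np.sqrt(cfg.sigma2_true), size=(n, k))
    y = mean + re_part + eps

    data = {"subject": np.arange(1, n + 1)}
    for j in range(k):
        data[f"age_t{j+1}"] = ages[:, j]
    for j in range(k):
        data[f"score_t{j+1}"] = y[:, j]
    if grp is not None:
        data["group"] = grp
    wide = pd.DataFrame(data)

    if cfg.mcar_rate > 0 or cfg.dropout_hazard > 0:
        wide = apply_missingness(wide, cfg, seed=rng.integers(2**31))

    truth = {
        "beta_true": beta.tolist(),
        "G_true": G.tolist(),
        "sigma2_true": cfg.sigma2_true,
        "gamma_true": gamma.tolist(),
        "group_prevalence": cfg.group_prevalence,
        "nominal_ages": nominal.tolist(),
        "jitter_sd": jitter_sd.tolist(),
        "mcar_rate": cfg.mcar_rate,
        "dropout_hazard": cfg.dropout_hazard,
        "seed": int(seed),
    }
    return wide, truth


def apply_missingness(wide: pd.DataFrame, cfg: SimConfig, seed: int | None = None
                      ) -> pd.DataFrame:
    """Blank out (age, outcome) occasion cell-pairs.

    MCAR: each occasion pair is deleted independently with ``mcar_rate``.
    Dropout: at each occasion a still-enrolled subject drops with
    ``dropout_hazard``; from then on every later occasion is missing.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    wide = wide.copy()
    n = len(wide)
    k = len(cfg.occasions)

    miss = np.zeros((n, k), dtype=bool)
    if cfg.mcar_rate > 0:
        miss |= rng.random((n, k)) < cfg.mcar_rate
    if cfg.dropout_hazard > 0:
        drop = rng.random((n, k)) < cfg.dropout_hazard
        dropped = np.cumsum(drop, axis=1) > 0
        miss |= dropped

    for j in range(k):
        col_age, col_y = f"age_t{j+1}", f"score_t{j+1}"
        wide.loc[miss[:, j], [col_age, col_y]] = np.nan
    return wide


def analytic_auc_truth(cfg: SimConfig, a: float, b: float) -> float:
    """Exact population AUC of the generating mean polynomial over [a, b]."""
    beta = np.asarray(cfg.beta_true, float)
    d = np.arange(beta.size)
    return float(np.sum(beta * (b ** (d + 1) - a ** (d + 1)) / (d + 1)))


def recovery_study(cfg: SimConfig, n_replicates: int, model: ModelSpec,
                   seed: int | None = None, auc_bounds: tuple[float, float] | None = None
                   ) -> pd.DataFrame:
    """Simulate-reshape-fit repeatedly and summarize fixed-effect recovery.

    Each replicate draws a fresh cohort, pivots it to long format, fits
    ``model`` and records the fixed-effect estimates, their SEs, and 95% CI
    coverage of the generating values; optionally also the trajectory AUC
    over ``auc_bounds`` against its analytic truth.  Replicate-level fit
    failures are recorded (``convergence_rate``), not fatal.

    Returns one row per parameter: true value, mean estimate, bias,
    Monte-Carlo SE of the bias, empirical SE, mean model SE, coverage.
    """
    if model.fixed_degree != cfg.degree:
        raise ValueError("model fixed_degree must match the generating degree")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    spec_wide = cfg.wide_spec()

    truth_beta = np.asarray(cfg.beta_true, float)
    # the model is fit with time_center=0 so coefficients are on the raw age
    # scale, directly comparable to beta_true
    model = replace_center_zero(model)

    estimates, ses, aucs = [], [], []
    n_fail = 0
    from .inference import auc as auc_fn

    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        wide, _ = simulate_cohort(cfg, seed=rep_seed)
        ds = reshape_wide_to_long(wide, spec_wide)
        try:
            dm = build_design(ds, model)
            fm = fit_lmm(dm, model)
        except (ConvergenceError, np.linalg.LinAlgError):
            n_fail += 1
            continue
        npoly = cfg.degree + 1
        estimates.append(fm.beta[:npoly])
        ses.append(np.sqrt(np.diag(fm.V))[:npoly])
        if auc_bounds is not None:
            aucs.append(auc_fn(fm, *auc_bounds).estimate)

    est = np.asarray(estimates)
    se = np.asarray(ses)
    R = est.shape[0]
    rows = []
    for j in range(truth_beta.size):
        bias = est[:, j].mean() - truth_beta[j]
        emp_se = est[:, j].std(ddof=1)
        covered = (
            (est[:, j] - Z975 * se[:, j] <= truth_beta[j])
            & (truth_beta[j] <= est[:, j] + Z975 * se[:, j])
        ).mean()
        rows.append(
            {
                "parameter": f"beta_{j}",
                "true": truth_beta[j],
                "mean_estimate": est[:, j].mean(),
                "bias": bias,
                "mc_se": emp_se / np.sqrt(R),
                "empirical_se": emp_se,
                "mean_model_se": se[:, j].mean(),
                "coverage": covered,
            }
        )
    if auc_bounds is not None:
        av = np.asarray(aucs)
        truth_auc = analytic_auc_truth(cfg, *auc_bounds)
        rows.append(
            {
                "parameter": f"auc_{auc_bounds[0]:g}_{auc_bounds[1]:g}",
                "true": truth_auc,
                "mean_estimate": av.mean(),
                "bias": av.mean() - truth_auc,
                "mc_se": av.std(ddof=1) / np.sqrt(R),
                "empirical_se": av.std(ddof=1),
                "mean_model_se": np.nan,
                "coverage": np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_replicates"] = n_replicates
    out.attrs["n_converged"] = R
    out.attrs["convergence_rate"] = R / n_replicates
    return out


def replace_center_zero(model: ModelSpec) -> ModelSpec:
    """Copy of ``model`` with time_center pinned at 0 (raw-age coefficients)."""
    from dataclasses import replace as dc_replace

    return dc_replace(model, time_center=0.0)
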