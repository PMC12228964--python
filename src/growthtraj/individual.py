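"""Individual-level trajectories: BLUPs, predicted-vs-observed curves,
shrinkage diagnostics, and reproducible subsampling.

The random effects for subject *i* are predicted by their conditional mean
under the fitted parameters (the BLUP),

.. math::

    \\hat u_i = G Z_i^\\top (Z_i G Z_i^\\top + \\sigma^2 W_i^{-1})^{-1}
               (y_i - X_i \\hat\\beta),

which shrinks each subject's raw deviation toward zero by an amount that
grows as the residual noise dominates the between-subject variance.  BLUPs
are computed at the plug-in parameter estimates; no extra uncertainty for
estimating ``G`` and ``sigma2`` is propagated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import DesignMatrices, FittedModel
from .inference import predict_at_time

__all__ = [
    "SubjectEffects",
    "IndividualCurve",
    "blups",
    "individual_curve",
    "sample_individuals",
    "shrinkage_table",
]


@dataclass
class SubjectEffects:
    subject: object
    u_hat: np.ndarray
    n_obs_used: int


@dataclass
class IndividualCurve:
    """Population and subject-specific predictions on a time grid, plus the
    subject's observed (time, outcome) pairs."""

    subject: object
    times: np.ndarray
    population: np.ndarray
    individual: np.ndarray
    observed_times: np.ndarray
    observed_outcomes: np.ndarray


def _subject_rows(dm: DesignMatrices) -> dict:
    rows: dict = {}
    for pos, code in enumerate(dm.subject_index):
        rows.setdefault(dm.subjects[code], []).append(pos)
    return rows


def blups(fm: FittedModel, dm: DesignMatrices) -> list[SubjectEffects]:
    """Conditional modes of the random effects for every modelled subject.

    ``dm`` must be the design used to fit ``fm`` (same basis).  Subjects
    with no modelled rows are absent, never zero-filled.
    """
    out = []
    for subject, pos in _subject_rows(dm).items():
        pos = np.asarray(pos)
        Zi = dm.Z[pos]
        Xi = dm.X[pos]
        yi = dm.y[pos]
        wi = dm.w[pos]
        Vi = Zi @ fm.G @ Zi.T + np.diag(fm.sigma2 / wi)
        resid = yi - Xi @ fm.beta
        u = fm.G @ Zi.T @ np.linalg.solve(Vi, resid)
        out.append(SubjectEffects(subject, u, pos.size))
    return out


def _blup_for(fm: FittedModel, dm: DesignMatrices, pos: np.ndarray) -> np.ndarray:
    Zi, Xi, yi, wi = dm.Z[pos], dm.X[pos], dm.y[pos], dm.w[pos]
    Vi = Zi @ fm.G @ Zi.T + np.diag(fm.sigma2 / wi)
    return fm.G @ Zi.T @ np.linalg.solve(Vi, yi - Xi @ fm.beta)


def individual_curve(fm: FittedModel, dm: DesignMatrices, subject,
                     grid: np.ndarray | None = None,
                     profile: dict | None = None) -> IndividualCurve:
    """Predicted population and subject-specific trajectory for one subject.

    The default grid spans the subject's own observed time range (individual
    curves are not extrapolated beyond the subject's data).  The individual
    curve is the population curve plus the subject's random-effect polynomial
    ``sum_d u_hat[d] * (t - center)^d``.
    """
    rows = _subject_rows(dm)
    if subject not in rows:
        raise KeyError(f"subject {subject!r} has no modelled rows")
    pos = np.asarray(rows[subject])
    t_obs = dm.time[pos]
    if grid is None:
        lo, hi = float(t_obs.min()), float(t_obs.max())
        grid = np.linspace(lo, hi, 25) if hi > lo else np.array([lo])
    grid = np.asarray(grid, float)

    if profile is None:
        profile = _observed_profile(fm, dm, pos)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # subject grids may nudge past range
        population = np.array(
            [predict_at_time(fm, float(t), profile).estimate for t in grid]
        )
    u = _blup_for(fm, dm, pos)
    tc = grid - fm.encoding_info["time_center"]
    re_poly = sum(u[d] * tc**d for d in range(u.size))
    return IndividualCurve(
        subject=subject,
        times=grid,
        population=population,
        individual=population + re_poly,
        observed_times=t_obs,
        observed_outcomes=dm.y[pos],
    )


def _observed_profile(fm: FittedModel, dm: DesignMatrices, pos: np.ndarray) -> dict:
    """Profile matching the subject's own covariate/interaction row values,
    reconstructed from the design columns so curves pass near the data."""
    profile: dict = {}
    enc = fm.encoding_info.get("interaction")
    if enc is not None:
        iname = fm.encoding_info["interaction_name"]
        code_cols = [
            j
            for j, name in enumerate(fm.term_names)
            if ":" not in name and (name == iname or name.startswith(iname + "["))
        ]
        codes = dm.X[pos[0], code_cols]
        if enc["kind"] == "continuous":
            profile[iname] = enc["mean"] + codes[0] * enc["sd"]
        else:
            levels = enc["levels"]
            hit = next((k for k, v in enumerate(codes) if v == 1.0), None)
            profile[iname] = levels[hit + 1] if hit is not None else enc["reference"]
    return profile


def sample_individuals(fm: FittedModel, dm: DesignMatrices, n: int = 30,
                       group=None, subjects=None, seed: int | None = None,
                       grid: np.ndarray | None = None) -> list[IndividualCurve]:
    """Up to ``n`` individual curves, sampled without replacement.

    ``group`` filters to subjects at that interaction-variable level before
    sampling; an explicit ``subjects`` list bypasses sampling entirely.  If
    fewer than ``n`` subjects are available all are returned (with a notice
    via the returned length, not an error).  Sampling uses numpy's seeded
    PCG64 generator, so the same seed reproduces the same subject set.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rows = _subject_rows(dm)
    if subjects is not None:
        chosen = list(subjects)
    else:
        pool = list(rows)
        if group is not None:
            enc = fm.encoding_info.get("interaction")
            if enc is None:
                raise ValueError("model has no interaction variable to group by")
            iname = fm.encoding_info["interaction_name"]
            pool = [
                s
                for s in pool
                if _observed_profile(fm, dm, np.asarray(rows[s])).get(iname) == group
                or str(_observed_profile(fm, dm, np.asarray(rows[s])).get(iname))
                == str(group)
            ]
        rng = np.random.default_rng(seed)
        if len(pool) <= n:
            chosen = pool
        else:
            chosen = list(rng.choice(np.asarray(pool, dtype=object), size=n, replace=False))
    return [individual_curve(fm, dm, s, grid=grid) for s in chosen]


def shrinkage_table(fm: FittedModel, dm: DesignMatrices):
    """Compare each subject's BLUP with their ordinary least-squares
    deviation (OLS of the subject's residuals on their random design).

    Subjects without enough rows for a full-rank per-subject OLS keep their
    BLUP but get missing OLS entries.  The ratio BLUP/OLS is the empirical
    shrinkage factor; it approaches 1 as the subject contributes more data.
    """
    import pandas as pd

    q = fm.G.shape[0]
    records = []
    for subject, pos in _subject_rows(dm).items():
        pos = np.asarray(pos)
        u = _blup_for(fm, dm, pos)
        rec = {"subject": subject, "n_obs": pos.size}
        for d in range(q):
            rec[f"blup_{d}"] = u[d]
        Zi = dm.Z[pos]
        resid = dm.y[pos] - dm.X[pos] @ fm.beta
        if pos.size >= q and np.linalg.matrix_rank(Zi) == q:
            ols, *_ = np.linalg.lstsq(Zi, resid, rcond=None)
            for d in range(q):
                rec[f"ols_{d}"] = ols[d]
                rec[f"ratio_{d}"] = u[d] / ols[d] if ols[d] != 0 else np.nan
        else:
            for d in range(q):
                rec[f"ols_{d}"] = np.nan
                rec[f"ratio_{d}"] = np.nan
        records.append(rec)
    return pd.DataFrame(records)
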