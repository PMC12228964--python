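import numpy as np
import pandas as pd
import pytest

from growthtraj import (
    FittedModel,
    LongDataset,
    ModelSpec,
    build_design,
    default_config,
    fit_lmm,
    reshape_wide_to_long,
    simulate_cohort,
)


def make_long(subjects, times, outcomes, covariates=None):
    """Assemble a LongDataset from parallel arrays (occasion = index within
    subject)."""
    df = pd.DataFrame({"id": subjects, "t": times, "y": outcomes})
    df["occ"] = df.groupby("id").cumcount() + 1
    if covariates:
        for name, vals in covariates.items():
            df[name] = vals
    return LongDataset(
        data=df,
        subject_col="id",
        occasion_col="occ",
        time_col="t",
        outcome_col="y",
        covariate_cols=tuple(covariates) if covariates else (),
    )


def random_long(rng, n_subjects=5, max_obs=6, degree=1):
    """A small random mixed-model dataset for likelihood oracles."""
    rows = []
    for i in range(n_subjects):
        k = rng.integers(1, max_obs + 1)
        t = np.sort(rng.uniform(0, 10, size=k))
        y = rng.normal(size=k) + 0.3 * t
        for tt, yy in zip(t, y):
            rows.append((i, tt, yy))
    s, t, y = map(np.asarray, zip(*rows))
    return make_long(s, t, y)


def synthetic_model(beta, V, *, time_center=0.0, fixed_degree=None, G=None,
                    sigma2=0.25, time_range=(0.0, 10.0), interaction=None,
                    encoding_extra=None):
    """A FittedModel built directly from given estimates (synthetic stand-in
    for a fit; used to test inference algebra on known numbers)."""
    beta = np.asarray(beta, float)
    V = np.asarray(V, float)
    if fixed_degree is None:
        fixed_degree = beta.size - 1
    spec = ModelSpec(
        fixed_degree=fixed_degree,
        random_degree=0,
        interaction=interaction,
        time_center=time_center,
    )
    q = 1
    names = ["(Intercept)"] + [
        "t" if d == 1 else f"I(t^{d})" for d in range(1, fixed_degree + 1)
    ]
    enc = {
        "time_center": time_center,
        "time_name": "t",
        "time_range": list(time_range),
        "outcome_name": "y",
        "subject_name": "id",
        "covariates": {},
        "interaction": None,
        "interaction_name": None,
        "n_dropped": 0,
    }
    if encoding_extra:
        enc.update(encoding_extra)
    return FittedModel(
        beta=beta,
        V=V,
        G=np.eye(q) * 0.1 if G is None else np.asarray(G, float),
        sigma2=sigma2,
        loglik=0.0,
        n_obs=100,
        n_subjects=50,
        converged=True,
        singular=False,
        spec=spec,
        term_names=names[: beta.size],
        encoding_info=enc,
    )


@pytest.fixture(scope="session")
def demo_fit():
    """One moderately sized fitted cubic model shared across tests."""
    cfg = default_config(n_subjects=300)
    wide, truth = simulate_cohort(cfg, seed=42)
    ds = reshape_wide_to_long(wide, cfg.wide_spec())
    spec = ModelSpec(fixed_degree=3, random_degree=2, estimator="ML")
    dm = build_design(ds, spec)
    fm = fit_lmm(dm, spec)
    return {"cfg": cfg, "wide": wide, "truth": truth, "ds": ds, "spec": spec,
            "dm": dm, "fm": fm}


@pytest.fixture(scope="session")
def group_fit():
    """A fitted model with a binary group interaction."""
    cfg = default_config(
        n_subjects=400,
        group_prevalence=0.5,
        group_main=0.3,
        group_interactions=(0.05, -0.004, 0.0),
    )
    wide, truth = simulate_cohort(cfg, seed=7)
    ds = reshape_wide_to_long(wide, cfg.wide_spec())
    spec = ModelSpec(
        fixed_degree=3, random_degree=2,
        interaction=("group", "categorical"), estimator="ML",
    )
    dm = build_design(ds, spec)
    fm = fit_lmm(dm, spec)
    return {"cfg": cfg, "wide": wide, "truth": truth, "ds": ds, "spec": spec,
            "dm": dm, "fm": fm}
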