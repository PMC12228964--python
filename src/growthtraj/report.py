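"""Summary-report assembly: collect every fitted quantity into one bundle,
render it as text/markdown/CSVs, and generate plain-language interpretation.

The bundle is the single source of numbers; the template layer only formats
(half-even rounding to 2 decimals, matching the display style of growth-curve
reports) and never recomputes anything.
"""

from __future__ import annotations

import datetime
import hashlib
import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import templates as T
from .model_core import (
    FittedModel,
    fixed_effect_table,
    formula_string,
    random_effect_table,
)
from .inference import AUCResult, PredictionResult

__all__ = ["ReportBundle", "build_bundle", "interpret", "render_report"]

_SECTIONS = (
    "formula",
    "sample",
    "fixed_effects",
    "random_effects",
    "deviance",
    "predictions",
    "auc",
    "interactions",
    "interpretation",
    "provenance",
)


@dataclass
class ReportBundle:
    formula: str
    n_obs: int
    n_subjects: int
    n_dropped: int
    fixed_effects: pd.DataFrame
    random_effects: pd.DataFrame
    deviance: float
    estimator: str
    singular: bool
    outcome_name: str
    time_name: str
    predictions: list[PredictionResult] = field(default_factory=list)
    auc_results: list[AUCResult] = field(default_factory=list)
    difference_results: list[tuple[object, object, PredictionResult]] = field(
        default_factory=list
    )
    auc_difference_results: list[tuple[object, object, AUCResult]] = field(
        default_factory=list
    )
    provenance: dict = field(default_factory=dict)


def build_bundle(
    fm: FittedModel,
    predictions: list[PredictionResult] | None = None,
    auc_results: list[AUCResult] | None = None,
    difference_results=None,
    auc_difference_results=None,
    input_path: str | None = None,
    seed: int | None = None,
) -> ReportBundle:
    """Assemble a report bundle from a fitted model and requested results."""
    enc = fm.encoding_info
    provenance = {
        "package": "growthtraj",
        "version": _version(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
    }
    if input_path is not None and os.path.exists(input_path):
        with open(input_path, "rb") as fh:
            provenance["input_sha256"] = hashlib.sha256(fh.read()).hexdigest()
        provenance["input_path"] = str(input_path)
    return ReportBundle(
        formula=formula_string(
            fm.spec,
            outcome=enc.get("outcome_name", "y"),
            time=enc.get("time_name", "t"),
            subject=enc.get("subject_name", "id"),
        ),
        n_obs=fm.n_obs,
        n_subjects=fm.n_subjects,
        n_dropped=enc.get("n_dropped", 0),
        fixed_effects=fixed_effect_table(fm),
        random_effects=random_effect_table(fm),
        deviance=fm.deviance,
        estimator=fm.spec.estimator,
        singular=fm.singular,
        outcome_name=enc.get("outcome_name", "outcome"),
        time_name=enc.get("time_name", "time"),
        predictions=list(predictions or []),
        auc_results=list(auc_results or []),
        difference_results=list(difference_results or []),
        auc_difference_results=list(auc_difference_results or []),
        provenance=provenance,
    )


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("growthtraj")
    except Exception:
        return "unknown"


def _fmt(x) -> str:
    """Half-even rounding to 2 decimals, the bundle-wide display convention."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return format(_round2(x), ".2f")


def _round2(x: float) -> float:
    import decimal

    return float(
        decimal.Decimal(repr(float(x))).quantize(
            decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_EVEN
        )
    )


def _ci_excludes_zero(lo: float, hi: float) -> bool:
    return lo > 0 or hi < 0


def interpret(bundle: ReportBundle) -> list[str]:
    """Deterministic plain-language paragraphs describing the results.

    Direction words are chosen by coefficient sign, and "statistically
    distinguishable from zero at the 95% level" strictly by whether the CI
    excludes zero; every number comes from the bundle's tables.
    """
    out: list[str] = []
    fe = bundle.fixed_effects
    time, outcome = bundle.time_name, bundle.outcome_name

    dropped_clause = (
        T.SAMPLE_DROPPED.format(n_dropped=bundle.n_dropped) if bundle.n_dropped else ""
    )
    out.append(
        T.SAMPLE.format(
            n_obs=bundle.n_obs,
            n_subjects=bundle.n_subjects,
            dropped_clause=dropped_clause,
        )
    )

    lin = fe[fe["term"] == time]
    if len(lin):
        row = lin.iloc[0]
        clear = _ci_excludes_zero(row["ci_low"], row["ci_high"])
        tmpl = (
            (T.TREND_UP if row["estimate"] > 0 else T.TREND_DOWN) if clear else T.TREND_FLAT
        )
        out.append(
            tmpl.format(estimate=_fmt(row["estimate"]), time=time, outcome=outcome)
        )

    higher = fe[
        fe["term"].str.fullmatch(rf"I\({time}\^\d+\)", na=False)
    ]
    sig_terms = [
        r["term"]
        for _, r in higher.iterrows()
        if _ci_excludes_zero(r["ci_low"], r["ci_high"])
    ]
    if len(higher):
        out.append(
            T.NONLINEAR.format(terms=", ".join(sig_terms), time=time)
            if sig_terms
            else T.LINEAR_OK
        )

    for pr in bundle.predictions:
        out.append(
            T.PREDICTION.format(
                outcome=outcome, time=time, t=f"{pr.time:g}",
                estimate=_fmt(pr.estimate), ci_low=_fmt(pr.ci_low),
                ci_high=_fmt(pr.ci_high),
            )
        )
    for ar in bundle.auc_results:
        out.append(
            T.AUC.format(
                time=time, a=f"{ar.a:g}", b=f"{ar.b:g}", estimate=_fmt(ar.estimate),
                ci_low=_fmt(ar.ci_low), ci_high=_fmt(ar.ci_high), outcome=outcome,
            )
        )
    for level_a, level_b, pr in bundle.difference_results:
        tmpl = (
            T.DIFF_CLEAR if _ci_excludes_zero(pr.ci_low, pr.ci_high) else T.DIFF_UNCLEAR
        )
        out.append(
            tmpl.format(
                time=time, t=f"{pr.time:g}", outcome=outcome,
                level_a=level_a, level_b=level_b,
                estimate=_fmt(pr.estimate), ci_low=_fmt(pr.ci_low),
                ci_high=_fmt(pr.ci_high),
            )
        )
    for level_a, level_b, ar in bundle.auc_difference_results:
        tmpl = (
            T.AUC_DIFF_CLEAR
            if _ci_excludes_zero(ar.ci_low, ar.ci_high)
            else T.AUC_DIFF_UNCLEAR
        )
        out.append(
            tmpl.format(
                time=time, a=f"{ar.a:g}", b=f"{ar.b:g}", outcome=outcome,
                level_a=level_a, level_b=level_b,
                estimate=_fmt(ar.estimate), ci_low=_fmt(ar.ci_low),
                ci_high=_fmt(ar.ci_high),
            )
        )

    re_tab = bundle.random_effects
    sd_int = re_tab.loc[re_tab["term"] == "intercept", "sd"]
    sd_res = re_tab.loc[re_tab["term"] == "residual", "sd"]
    if len(sd_int) and len(sd_res):
        out.append(
            T.RANDOM_EFFECTS.format(
                sd_intercept=_fmt(sd_int.iloc[0]), sd_residual=_fmt(sd_res.iloc[0])
            )
        )
    out.append(
        T.DEVIANCE.format(estimator=bundle.estimator, deviance=_fmt(bundle.deviance))
    )
    if bundle.singular:
        out.append(T.SINGULAR_NOTE)
    return out


def _result_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        if isinstance(r, tuple):
            level_a, level_b, res = r
            rec = {"level_a": level_a, "level_b": level_b}
        else:
            res, rec = r, {}
        if isinstance(res, PredictionResult):
            rec.update(time=res.time)
        else:
            rec.update(a=res.a, b=res.b)
        rec.update(
            estimate=res.estimate, se=res.se, ci_low=res.ci_low, ci_high=res.ci_high
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def render_report(bundle: ReportBundle, path, format: str = "text") -> list[str]:
    """Write the report; returns the list of files written.

    ``format``: ``"text"`` (one .txt), ``"markdown"`` (one .md), or
    ``"csv-bundle"`` (a directory of CSVs, one per table, round-trippable).
    Sections are always ordered: formula, sample, fixed effects, random
    effects, deviance, predictions, AUC, interactions, interpretation,
    provenance.
    """
    if format not in ("text", "markdown", "csv-bundle"):
        raise ValueError(f"unknown report format {format!r}")

    if format == "csv-bundle":
        os.makedirs(path, exist_ok=True)
        written = []

        def emit(name, df):
            f = os.path.join(path, f"{name}.csv")
            df.to_csv(f, index=False, na_rep="NA")
            written.append(f)

        emit("fixed_effects", bundle.fixed_effects)
        emit("random_effects", bundle.random_effects)
        meta = pd.DataFrame(
            [
                {
                    "formula": bundle.formula,
                    "n_obs": bundle.n_obs,
                    "n_subjects": bundle.n_subjects,
                    "n_dropped": bundle.n_dropped,
                    "deviance": bundle.deviance,
                    "estimator": bundle.estimator,
                    "singular": bundle.singular,
                }
            ]
        )
        emit("model", meta)
        if bundle.predictions:
            emit("predictions", _result_frame(bundle.predictions))
        if bundle.auc_results:
            emit("auc", _result_frame(bundle.auc_results))
        if bundle.difference_results:
            emit("differences", _result_frame(bundle.difference_results))
        if bundle.auc_difference_results:
            emit("auc_differences", _result_frame(bundle.auc_difference_results))
        with open(os.path.join(path, "interpretation.txt"), "w", encoding="utf-8") as fh:
            fh.write("\n\n".join(interpret(bundle)) + "\n")
        written.append(os.path.join(path, "interpretation.txt"))
        return written

    md = format == "markdown"
    buf = io.StringIO()

    def heading(txt):
        buf.write((f"## {txt}\n\n") if md else (txt + "\n" + "-" * len(txt) + "\n"))

    def table(df):
        buf.write(df.to_markdown(index=False) if md else df.to_string(index=False))
        buf.write("\n\n")

    heading("Model formula")
    buf.write(bundle.formula + "\n\n")
    heading("Sample")
    buf.write(
        f"{bundle.n_obs} observations, {bundle.n_subjects} individuals, "
        f"{bundle.n_dropped} rows dropped for missing data\n\n"
    )
    heading("Fixed effects")
    table(bundle.fixed_effects)
    heading("Random effects")
    table(bundle.random_effects)
    heading("Deviance")
    buf.write(f"{bundle.deviance!r} ({bundle.estimator})\n\n")
    heading("Predictions")
    if bundle.predictions:
        table(_result_frame(bundle.predictions))
    else:
        buf.write("none requested\n\n")
    heading("Area under the curve")
    if bundle.auc_results:
        table(_result_frame(bundle.auc_results))
    else:
        buf.write("none requested\n\n")
    heading("Interaction contrasts")
    if bundle.difference_results or bundle.auc_difference_results:
        if bundle.difference_results:
            table(_result_frame(bundle.difference_results))
        if bundle.auc_difference_results:
            table(_result_frame(bundle.auc_difference_results))
    else:
        buf.write("none requested\n\n")
    heading("Interpretation")
    buf.write("\n\n".join(interpret(bundle)) + "\n\n")
    heading("Provenance")
    for k, v in bundle.provenance.items():
        buf.write(f"{k}: {v}\n")
    buf.write("\n")

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
    return [str(path)]
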