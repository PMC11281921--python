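"""Cox proportional-hazards estimation at tiered adjustment levels.

Hazard ratios with Wald 95% CIs and p-values are estimated by maximizing
the Cox partial likelihood (Efron tie handling, via lifelines), with
categorical exposures dummy-coded against their referent level.  Three
nested covariate tiers mirror a typical epidemiological adjustment ladder:
demographics; plus socioeconomic position; plus lifestyle factors.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

logger = logging.getLogger(__name__)

#: Covariate columns added at each adjustment tier (tier 3 ⊇ 2 ⊇ 1).
TIER_COVARIATES = {
    0: [],
    1: ["age", "sex", "ethnicity"],
    2: ["age", "sex", "ethnicity", "income", "deprivation", "education", "employment"],
    3: [
        "age",
        "sex",
        "ethnicity",
        "income",
        "deprivation",
        "education",
        "employment",
        "smoking",
        "alcohol",
        "diet_healthy",
        "physical_activity",
        "urbanicity",
    ],
}


class CoxFittingError(RuntimeError):
    """Model could not be fitted (non-convergence, separation, empty levels)."""


@dataclass
class ModelSpec:
    """What to fit: exposure predictors plus a covariate adjustment tier.

    ``referents`` overrides the referent level for categorical predictors
    (default: the lexically first level).  ``interactions`` are pairs of
    design columns whose encoded products are added to the model.
    """

    predictors: list
    tier: int = 1
    covariates: list | None = None
    referents: dict = field(default_factory=dict)
    interactions: list = field(default_factory=list)

    def resolved_covariates(self) -> list:
        if self.covariates is not None:
            return list(self.covariates)
        if self.tier not in TIER_COVARIATES:
            raise ValueError(f"unknown adjustment tier {self.tier}")
        return list(TIER_COVARIATES[self.tier])


@dataclass
class CoxFitResult:
    """Fitted model: the hazard-ratio table plus the underlying fitter."""

    table: pd.DataFrame  # per-level HR, CI, p, n, events
    cph: CoxPHFitter | None
    design: pd.DataFrame
    spec: ModelSpec
    n: int
    events: int


def _encode_column(df: pd.DataFrame, col: str, referent: str | None) -> tuple[pd.DataFrame, list]:
    """Dummy-code a categorical column against its referent; pass floats through.

    Returns (encoded columns, ordered non-referent levels) — levels is empty
    for continuous columns.
    """
    s = df[col]
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        levels = sorted(s.astype(str).unique())
        ref = referent if referent is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"referent {ref!r} not a level of {col!r}")
        others = [lv for lv in levels if lv != ref]
        out = pd.DataFrame(
            {f"{col}[{lv}]": (s.astype(str) == lv).astype(float) for lv in others},
            index=df.index,
        )
        return out, others
    return pd.DataFrame({col: s.astype(float)}), []


def build_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, dict]:
    """Complete-case design matrix for the spec; returns (design, level map)."""
    cols = list(spec.predictors) + spec.resolved_covariates()
    needed = cols + ["time", "status"]
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks columns: {missing_cols}")
    cc = table[needed].dropna()
    pieces, levels = [], {}
    for col in cols:
        enc, lv = _encode_column(cc, col, spec.referents.get(col))
        pieces.append(enc)
        if lv:
            levels[col] = lv
    design = pd.concat(pieces + [cc[["time", "status"]]], axis=1) if pieces else cc[["time", "status"]].copy()
    for a, b in spec.interactions:
        a_cols = [c for c in design.columns if c == a or c.startswith(f"{a}[")]
        b_cols = [c for c in design.columns if c == b or c.startswith(f"{b}[")]
        for ca in a_cols:
            for cb in b_cols:
                design[f"{ca}*{cb}"] = design[ca] * design[cb]
    return design, levels


def fit_cox(table: pd.DataFrame, spec: ModelSpec) -> CoxFitResult:
    """Fit a Cox PH model and tabulate hazard ratios per predictor level.

    Categorical predictors are dummy-coded against their referent; the
    referent row appears in the output with HR fixed at 1.  Raises
    :class:`CoxFittingError` if any predictor level has zero events or the
    partial-likelihood maximization fails.
    """
    design, levels = build_design(table, spec)
    cc = table.loc[design.index]
    n, events = len(design), int(design["status"].sum())
    for col in spec.predictors:
        if col in levels or col in spec.referents:
            ev = cc.groupby(cc[col].astype(str))["status"].sum()
            empty = ev[ev == 0]
            if len(empty):
                raise CoxFittingError(
                    f"zero events in level(s) {list(empty.index)} of {col!r}"
                )
    covariate_cols = [c for c in design.columns if c not in ("time", "status")]
    if not covariate_cols:
        return CoxFitResult(
            table=pd.DataFrame(), cph=None, design=design, spec=spec, n=n, events=events
        )
    cph = CoxPHFitter()
    try:
        # tight Newton precision so coefficients are optimizer-grade, not
        # merely inference-grade
        cph.fit(design, duration_col="time", event_col="status",
                fit_options={"precision": 1e-10})
    except Exception as exc:
        raise CoxFittingError(f"Cox fit failed: {exc}") from exc

    summ = cph.summary
    rows = []
    for col in spec.predictors:
        if col in levels:
            ref = spec.referents.get(col, sorted(cc[col].astype(str).unique())[0])
            by_level = cc.groupby(cc[col].astype(str))
            rows.append(
                {
                    "predictor": col,
                    "level": ref,
                    "is_ref": True,
                    "HR": 1.0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "n": int(by_level.size().get(ref, 0)),
                    "events": int(by_level["status"].sum().get(ref, 0)),
                }
            )
            for lv in levels[col]:
                name = f"{col}[{lv}]"
                rows.append(
                    {
                        "predictor": col,
                        "level": lv,
                        "is_ref": False,
                        "HR": float(np.exp(summ.loc[name, "coef"])),
                        "ci_low": float(np.exp(summ.loc[name, "coef lower 95%"])),
                        "ci_high": float(np.exp(summ.loc[name, "coef upper 95%"])),
                        "p": float(summ.loc[name, "p"]),
                        "n": int(by_level.size().get(lv, 0)),
                        "events": int(by_level["status"].sum().get(lv, 0)),
                    }
                )
        else:
            rows.append(
                {
                    "predictor": col,
                    "level": "(per unit)",
                    "is_ref": False,
                    "HR": float(np.exp(summ.loc[col, "coef"])),
                    "ci_low": float(np.exp(summ.loc[col, "coef lower 95%"])),
                    "ci_high": float(np.exp(summ.loc[col, "coef upper 95%"])),
                    "p": float(summ.loc[col, "p"]),
                    "n": n,
                    "events": events,
                }
            )
    out = pd.DataFrame(rows)
    out.insert(0, "tier", spec.tier)
    return CoxFitResult(table=out, cph=cph, design=design, spec=spec, n=n, events=events)


def incidence_rate(cases: int, person_years: float) -> float:
    """Crude incidence rate per 1000 person-years, rounded to 2 decimals."""
    if person_years <= 0:
        raise ValueError("person_years must be > 0")
    return round(1000.0 * cases / person_years, 2)


def ph_check(fit: CoxFitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Scaled Schoenfeld-residual test of proportional hazards per covariate.

    Returns a table of test statistics and p-values (rank time transform),
    flagging covariates with p < ``alpha``; a Bonferroni-combined global
    p-value is included as row ``GLOBAL``.
    """
    if fit.cph is None:
        return pd.DataFrame(columns=["test_statistic", "p", "flagged"])
    res = proportional_hazard_test(fit.cph, fit.design, time_transform="rank")
    out = res.summary[["test_statistic", "p"]].copy()
    out.index = [ix[0] if isinstance(ix, tuple) else ix for ix in out.index]
    out["flagged"] = out["p"] < alpha
    global_p = min(1.0, out["p"].min() * len(out))
    out.loc["GLOBAL"] = [np.nan, global_p, global_p < alpha]
    return out


def build_cohort_table(
    exposures: pd.DataFrame,
    circadian: pd.DataFrame | None = None,
    prs: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    outcomes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Inner-join the pipeline stages into one analysis table.

    Every input must carry ``participant_id`` (unique).  Participants
    failing light QC (``qc_pass`` False) or with prevalent disease
    (``prevalent`` truthy in the covariate table) are excluded; exclusion
    counts are logged at each step.
    """
    tables = {"exposures": exposures}
    if circadian is not None:
        tables["circadian"] = circadian
    if prs is not None:
        tables["prs"] = prs
    if covariates is not None:
        tables["covariates"] = covariates
    if outcomes is not None:
        tables["outcomes"] = outcomes

    merged = None
    for name, tab in tables.items():
        if "participant_id" not in tab.columns:
            raise ValueError(f"{name} table lacks participant_id")
        if tab["participant_id"].duplicated().any():
            raise ValueError(f"duplicate participant_id in {name} table")
        merged = tab if merged is None else merged.merge(tab, on="participant_id", how="inner")
        logger.info("after joining %s: %d participants", name, len(merged))
    if len(merged) == 0:
        logger.warning("cohort table is empty: no participant_id overlap across inputs")
        return merged
    if "qc_pass" in merged.columns:
        n0 = len(merged)
        merged = merged[merged["qc_pass"].astype(bool)]
        logger.info("light QC excluded %d participants", n0 - len(merged))
    if "prevalent" in merged.columns:
        n0 = len(merged)
        merged = merged[~merged["prevalent"].astype(bool)].drop(columns=["prevalent"])
        logger.info("prevalent-disease exclusion removed %d participants", n0 - len(merged))
    return merged.reset_index(drop=True)


def _fmt_row(r) -> str:
    if r["is_ref"]:
        return f"  {r['level']:<12} {'-':>20} {'-':>8}   cases {100*r['events']/max(r['n'],1):.2f}% ({r['events']})"
    return (
        f"  {r['level']:<12} {r['HR']:.2f} [{r['ci_low']:.2f}-{r['ci_high']:.2f}]"
        f"{'':>4} p={r['p']:.2g}   cases {100*r['events']/max(r['n'],1):.2f}% ({r['events']})"
    )


def render_hazard_report(fits: list) -> str:
    """Plain-text report, one block per model tier (referent rows as '-')."""
    if not fits:
        raise ValueError("need >= 1 fitted model")
    buf = io.StringIO()
    for fit in fits:
        buf.write(f"Model {fit.spec.tier} (N = {fit.n:,}; events = {fit.events:,})\n")
        for pred, sub in fit.table.groupby("predictor", sort=False):
            buf.write(f" {pred}\n")
            for _, r in sub.iterrows():
                buf.write(_fmt_row(r) + "\n")
        buf.write("\n")
    return buf.getvalue()


def hazard_tables_to_csv(fits: list, path) -> pd.DataFrame:
    """Concatenate hazard tables across model tiers and write CSV."""
    out = pd.concat([f.table for f in fits], ignore_index=True)
    out.to_csv(path, index=False)
    return out


def plot_cumulative_incidence(table: pd.DataFrame, group_col: str, path=None):
    """Basic cumulative-incidence (1 - Kaplan-Meier) curves by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(6, 4))
    for level, sub in table.groupby(group_col):
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["status"], label=str(level))
        ci = 1.0 - km.survival_function_
        ax.plot(ci.index, ci.iloc[:, 0], label=str(level))
    ax.set_xlabel("years of follow-up")
    ax.set_ylabel("cumulative incidence")
    ax.legend(title=group_col)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax
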