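"""Bivariate tables and clustered logistic (GEE) odds-ratio estimation.

Because the same physician receives many alerts over the year, alert-level
binary outcomes are correlated within provider.  Effects are therefore
estimated with generalized estimating equations: a marginal logistic model
(logit link, binomial variance) with an exchangeable working correlation and
robust (sandwich) standard errors, clustered on the provider.  Exchangeable
is the standard working structure for repeated alerts within a PCP, and the
sandwich variance makes inference insensitive to that choice.  Odds ratios
are exponentiated coefficients with Wald 95% intervals formed on the linear
predictor scale.

No multiple-testing adjustment is applied; report footers say so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .immediate import ImmediateActionResult
from .openings import OpeningRecord
from .subsequent import SubsequentActionResult

OUTCOMES = ("immediate_relevant", "general", "medication_specific", "laboratory_specific")

#: Reference level per covariate, mirroring the published tables.
DEFAULT_REFERENCES = {
    "alert_type": "information_only",
    "delay_category": "<=24h",
    "opened_by_pcp": False,
    "provider_age_group": "<50",
    "provider_gender": "female",
    "patient_gender": "female",
}


class DegenerateOutcomeError(ValueError):
    """The outcome is constant on the analysis rows; no model can be fit."""


@dataclass(frozen=True)
class TermEstimate:
    covariate: str
    level: str
    reference: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    robust_se: float

    @property
    def log_odds_ratio(self) -> float:
        return float(np.log(self.odds_ratio))


@dataclass(frozen=True)
class FitResult:
    outcome: str
    terms: list[TermEstimate]
    n_rows: int
    n_clusters: int
    converged: bool
    intercept: float = field(default=float("nan"))

    def term(self, covariate: str, level: str) -> TermEstimate:
        for t in self.terms:
            if t.covariate == covariate and t.level == level:
                return t
        raise KeyError(f"no term for {covariate}={level}")


def build_analysis_table(
    alerts: Sequence,
    openings: Sequence[OpeningRecord],
    immediate: Sequence[ImmediateActionResult],
    subsequent: Sequence[SubsequentActionResult],
    context: Optional[Sequence[dict]] = None,
) -> pd.DataFrame:
    """Join the per-stage outputs into one analysis row per opened alert.

    The immediate outcome is populated only for evaluable, PCP-first-opened
    alerts; the two-day outcomes for every opened alert.  Never-opened alerts
    are excluded (their count is available from the opening records).
    Duplicate alert ids in any input are an error.
    """
    def _frame(records, name, columns):
        df = pd.DataFrame(records, columns=columns if not records else None)
        if not df.empty and df["alert_id"].duplicated().any():
            raise ValueError(f"duplicate alert_id in {name}")
        return df

    alerts_df = _frame(
        [
            {
                "alert_id": a.alert_id,
                "pcp_id": a.pcp_id,
                "patient_id": a.patient_id,
                "alert_type": a.alert_type.value,
            }
            for a in alerts
        ],
        "alerts",
        ["alert_id", "pcp_id", "patient_id", "alert_type"],
    )
    open_df = _frame(
        [
            {
                "alert_id": o.alert_id,
                "opened": not o.never_opened,
                "opened_by_pcp": o.opened_by_pcp,
                "delay_category": o.delay_category.value if o.delay_category else None,
                "delay_category_coarse": (
                    o.delay_category_coarse.value if o.delay_category_coarse else None
                ),
                "within_office_hours": o.within_office_hours,
                "saturday_delivery": o.saturday_delivery,
            }
            for o in openings
        ],
        "openings",
        ["alert_id", "opened", "opened_by_pcp", "delay_category",
         "delay_category_coarse", "within_office_hours", "saturday_delivery"],
    )
    imm_df = _frame(
        [
            {
                "alert_id": r.alert_id,
                "immediate_evaluable": r.evaluable,
                "immediate_relevant": r.relevant if r.evaluable else None,
                "total_seconds": r.total_seconds,
            }
            for r in immediate
        ],
        "immediate",
        ["alert_id", "immediate_evaluable", "immediate_relevant", "total_seconds"],
    )
    sub_df = _frame(
        [
            {
                "alert_id": r.alert_id,
                "general": r.general,
                "medication_specific": r.medication_specific,
                "laboratory_specific": r.laboratory_specific,
            }
            for r in subsequent
        ],
        "subsequent",
        ["alert_id", "general", "medication_specific", "laboratory_specific"],
    )

    df = alerts_df.merge(open_df, on="alert_id", how="inner")
    df = df[df["opened"]].drop(columns=["opened"])
    df = df.merge(imm_df, on="alert_id", how="left")
    df = df.merge(sub_df, on="alert_id", how="inner")
    if context is not None:
        ctx_df = _frame(list(context), "context", ["alert_id"])
        df = df.merge(ctx_df, on="alert_id", how="left")
    if df.empty:
        warnings.warn("analysis table is empty: no alert ids in common")
    df["immediate_evaluable"] = (df["immediate_evaluable"] == True)  # noqa: E712
    return df.reset_index(drop=True)


def bivariate_table(
    rows: pd.DataFrame, outcome: str, stratifier: str
) -> pd.DataFrame:
    """Cross-tabulate a binary outcome by a categorical stratifier.

    Returns per-level totals, counts and column percentages (percent of all
    positives / negatives falling in each level, as the published tables
    format them).
    """
    if rows.empty:
        raise ValueError("no rows to tabulate")
    sub = rows.dropna(subset=[outcome])
    y = sub[outcome].astype(bool)
    out = []
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    for level, grp in sub.groupby(stratifier, sort=True, observed=True):
        gy = grp[outcome].astype(bool)
        pos = int(gy.sum())
        neg = int((~gy).sum())
        out.append(
            {
                stratifier: level,
                "n": len(grp),
                "action_n": pos,
                "action_col_pct": 100.0 * pos / n_pos if n_pos else 0.0,
                "no_action_n": neg,
                "no_action_col_pct": 100.0 * neg / n_neg if n_neg else 0.0,
            }
        )
    return pd.DataFrame(out)


def fit_clustered_logit(
    rows: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    cluster_key: str = "pcp_id",
    references: Optional[dict] = None,
    maxiter: int = 100,
) -> FitResult:
    """Marginal logistic GEE with exchangeable working correlation.

    Rows with a missing outcome are dropped (complete-case).  Covariate
    levels with zero rows are dropped with a warning.  A constant outcome
    raises :class:`DegenerateOutcomeError`; non-convergence is reported in
    the result, never silently ignored.
    """
    refs = {**DEFAULT_REFERENCES, **(references or {})}
    df = rows.dropna(subset=[outcome]).copy()
    if df.empty or df[outcome].astype(bool).nunique() < 2:
        raise DegenerateOutcomeError(f"outcome {outcome!r} is constant or empty")
    if df[cluster_key].nunique() < 2:
        raise ValueError("need at least 2 clusters")

    y = df[outcome].astype(bool).astype(float).to_numpy()
    X_parts = [pd.Series(1.0, index=df.index, name="Intercept")]
    term_meta: list[tuple[str, str, str]] = []  # (covariate, level, reference)
    for cov in covariates:
        col = df[cov]
        levels = sorted(col.astype(str).unique())
        ref = str(refs.get(cov, levels[0]))
        if ref not in levels:
            ref = levels[0]
        for lev in levels:
            if lev == ref:
                continue
            ind = (col.astype(str) == lev).astype(float)
            if ind.sum() == 0:
                warnings.warn(f"covariate {cov}: level {lev} has no rows; dropped")
                continue
            ind.name = f"{cov}[{lev}]"
            X_parts.append(ind)
            term_meta.append((cov, lev, ref))
    X = pd.concat(X_parts, axis=1)

    model = sm.GEE(
        y,
        X,
        groups=df[cluster_key].to_numpy(),
        family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter)
    params = np.asarray(res.params)
    ses = np.asarray(res.bse)  # robust by default for GEE
    converged = bool(
        getattr(res, "converged", True)
        and np.isfinite(params).all()
        and np.isfinite(ses).all()
    )

    terms = []
    for j, (cov, lev, ref) in enumerate(term_meta, start=1):
        coef, se = float(params[j]), float(ses[j])
        terms.append(
            TermEstimate(
                covariate=cov,
                level=lev,
                reference=ref,
                odds_ratio=float(np.exp(coef)),
                ci_low=float(np.exp(coef - 1.96 * se)),
                ci_high=float(np.exp(coef + 1.96 * se)),
                robust_se=se,
            )
        )
    return FitResult(
        outcome=outcome,
        terms=terms,
        n_rows=len(df),
        n_clusters=int(df[cluster_key].nunique()),
        converged=converged,
        intercept=float(params[0]),
    )


def _accounting_block(rows: pd.DataFrame) -> str:
    n = len(rows)
    by_pcp = int(rows["opened_by_pcp"].sum())
    evaluable = int(rows["immediate_evaluable"].sum())
    imm = int((rows["immediate_relevant"] == True).sum())  # noqa: E712
    gen = int(rows["general"].sum())
    lines = [
        "Alert opening and action accounting",
        f"  alerts opened:                 {n}",
        f"  first opened by addressed PCP: {by_pcp} ({100 * by_pcp / n:.1f}%)",
        f"  opened by staff/other:         {n - by_pcp} ({100 * (n - by_pcp) / n:.1f}%)",
        f"  immediate-action evaluable:    {evaluable}"
        f" ({by_pcp - evaluable} without window data)",
        f"  immediate relevant action:     {imm}"
        f" ({100 * imm / evaluable:.1f}% of evaluable)" if evaluable else
        "  immediate relevant action:     0",
        f"  action by end of next day:     {gen} ({100 * gen / n:.1f}%)",
        f"  no timely PCP action:          {n - gen}",
    ]
    return "\n".join(lines)


def report_tables(
    rows: pd.DataFrame,
    fits: dict[str, FitResult],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Render the three standard reports plus the accounting block.

    ``fits`` maps outcome name to its converged :class:`FitResult`; the
    subsequent-outcome report requires all three two-day outcomes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    for outcome in ("general", "medication_specific", "laboratory_specific"):
        if outcome not in fits:
            raise ValueError(f"missing fit for outcome {outcome!r}")
        if not fits[outcome].converged:
            raise ValueError(f"fit for outcome {outcome!r} did not converge")

    imm_rows = rows[rows["immediate_evaluable"]]
    t1 = bivariate_table(imm_rows, "immediate_relevant", "alert_type")
    p = out_dir / "immediate_bivariate.csv"
    t1.to_csv(p, index=False)
    written["immediate_bivariate"] = p

    def _time_summary(sub: pd.DataFrame, label: str) -> dict:
        secs = sub["total_seconds"].dropna()
        return {
            "group": label,
            "n": len(secs),
            "mean_seconds": round(float(secs.mean()), 1) if len(secs) else float("nan"),
            "median_seconds": float(secs.median()) if len(secs) else float("nan"),
        }

    t2 = pd.DataFrame(
        [_time_summary(imm_rows, "all_evaluable")]
        + [
            _time_summary(
                imm_rows[imm_rows["immediate_relevant"].astype(bool) == flag],
                "immediate_action" if flag else "no_immediate_action",
            )
            for flag in (True, False)
        ]
        + [
            _time_summary(imm_rows[imm_rows["alert_type"] == t], t)
            for t in sorted(imm_rows["alert_type"].unique())
        ]
    )
    p = out_dir / "time_summary.csv"
    t2.to_csv(p, index=False)
    written["time_summary"] = p

    t3_rows = []
    for outcome in ("general", "medication_specific", "laboratory_specific"):
        fit = fits[outcome]
        for t in fit.terms:
            t3_rows.append(
                {
                    "outcome": outcome,
                    "covariate": t.covariate,
                    "level": t.level,
                    "reference": t.reference,
                    "odds_ratio": round(t.odds_ratio, 2),
                    "ci_low": round(t.ci_low, 2),
                    "ci_high": round(t.ci_high, 2),
                }
            )
    p = out_dir / "subsequent_odds_ratios.csv"
    pd.DataFrame(t3_rows).to_csv(p, index=False)
    written["subsequent_odds_ratios"] = p

    footer = (
        "\n\nNote: odds ratios from logistic GEE with exchangeable working\n"
        "correlation, robust SEs clustered on provider. No multiple-testing\n"
        "adjustment is applied; interpret secondary contrasts accordingly.\n"
    )
    p = out_dir / "accounting.txt"
    p.write_text(_accounting_block(rows) + footer, encoding="utf-8")
    written["accounting"] = p
    return written


__all__ = [
    "OUTCOMES",
    "DEFAULT_REFERENCES",
    "DegenerateOutcomeError",
    "TermEstimate",
    "FitResult",
    "build_analysis_table",
    "bivariate_table",
    "fit_clustered_logit",
    "report_tables",
]
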