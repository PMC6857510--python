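"""The six-approach validation suite for EHR-derived phenotypes.

A phenotype algorithm cannot be validated against a single gold standard;
instead evidence is triangulated across six complementary approaches:

1. **Cross-source concordance** — in what pattern do the linked sources
   (primary care, hospital, registry, death) capture the same event,
   optionally within a day-count window of the earliest record?
2. **Case-note / registry review** — diagnostic accuracy (PPV, NPV,
   sensitivity, specificity with 95% CIs) of the algorithm against a
   reviewed gold standard.
3. **Etiology** — do hazard ratios of known risk factors, adjusted for age
   and sex, match prior research?  (Estimation plus a comparison table
   against user-supplied reference estimates; CI-overlap flags only.)
4. **Prognosis** — Kaplan–Meier cumulative incidence of subsequent outcomes.
5. **Genetic replication** — previously reported variants re-tested under a
   Bonferroni threshold with a direction-of-effect concordance requirement.
6. **External populations** — the same definition re-run on a second
   population (here: a second generator configuration) and reported side by
   side.

Survival machinery (product-limit estimator; Cox partial likelihood with
Breslow tie handling) is provided through lifelines; proportion CIs through
statsmodels (Wilson score by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LifelinesConvergenceError
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    InvalidArgumentError,
    NoDataError,
)
from .synth import SOURCES, GeneratorConfig, generate_cohort, pattern_key

# ---------------------------------------------------------------------------
# 1. Cross-source concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    """Capture-pattern summary over the case population.

    Percentages are reported to one decimal place, as 100 x count / total.
    """

    total: int
    window_days: float
    pattern_counts: dict[str, int]
    source_counts: dict[str, int]
    k_or_more_counts: dict[int, int]

    def percentage(self, count: int) -> float:
        return round(100.0 * count / self.total, 1)

    @property
    def pattern_percentages(self) -> dict[str, float]:
        return {k: self.percentage(v) for k, v in self.pattern_counts.items()}

    @property
    def source_percentages(self) -> dict[str, float]:
        return {k: self.percentage(v) for k, v in self.source_counts.items()}

    @property
    def k_or_more_percentages(self) -> dict[int, float]:
        return {k: self.percentage(v) for k, v in self.k_or_more_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "pattern", "key": k, "count": v, "percent": self.percentage(v)}
            for k, v in sorted(self.pattern_counts.items())
        ]
        rows += [
            {"kind": "source", "key": k, "count": v, "percent": self.percentage(v)}
            for k, v in self.source_counts.items()
        ]
        rows += [
            {"kind": "k_or_more", "key": str(k), "count": v, "percent": self.percentage(v)}
            for k, v in sorted(self.k_or_more_counts.items())
        ]
        return pd.DataFrame(rows)


def cross_source_concordance(
    events: pd.DataFrame, window_days: float = np.inf
) -> ConcordanceResult:
    """Summarize which sources captured each case within a window.

    Parameters
    ----------
    events : DataFrame with columns patient_id, source, date
        qualifying records per case across sources (one row per record or
        per source; duplicates are fine).
    window_days : float
        a case's pattern is the set of sources having a record within this
        many days of the case's earliest record; ``inf`` means ever.

    The pattern counts partition the case set, so they sum to the total.
    """
    if window_days < 0:
        raise InvalidArgumentError("window_days must be >= 0")
    if events.empty:
        raise NoDataError("no cases to summarize")
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"], errors="coerce")
    ev = ev.dropna(subset=["date"])
    if ev.empty:
        raise NoDataError("no dated records to summarize")

    anchor = ev.groupby("patient_id")["date"].transform("min")
    delta = (ev["date"] - anchor).dt.days
    in_window = ev if np.isinf(window_days) else ev[delta <= window_days]

    src_rank = {s: i for i, s in enumerate(SOURCES)}
    per_case = in_window.groupby("patient_id")["source"].agg(
        lambda s: pattern_key(sorted(set(s), key=src_rank.__getitem__))
    )
    total = int(per_case.size)
    pattern_counts = per_case.value_counts().to_dict()
    n_sources = per_case.map(lambda k: len(k.split("+")))
    source_counts = {
        s: int(per_case.map(lambda k, s=s: s in k.split("+")).sum()) for s in SOURCES
    }
    k_or_more = {
        k: int((n_sources >= k).sum()) for k in range(1, len(SOURCES) + 1)
    }
    return ConcordanceResult(
        total=total,
        window_days=window_days,
        pattern_counts={k: int(v) for k, v in pattern_counts.items()},
        source_counts=source_counts,
        k_or_more_counts=k_or_more,
    )


def concordance_from_result(result, window_days: float = np.inf) -> ConcordanceResult:
    """Concordance over a :class:`~ehrphen.engine.PhenotypeResult`'s cases."""
    ev = result.qualifying_events[["patient_id", "source", "date"]]
    return cross_source_concordance(ev, window_days=window_days)


# ---------------------------------------------------------------------------
# 2. Diagnostic accuracy
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidArgumentError("contingency counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise InvalidArgumentError("contingency table is empty")


@dataclass
class MetricEstimate:
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int | None = None
    denominator: int | None = None
    reason: str | None = None

    def percent(self) -> tuple[float, float, float] | None:
        """(point, lo, hi) at one-decimal percent, the conventional report."""
        if self.estimate is None:
            return None
        return (
            round(100 * self.estimate, 1),
            round(100 * self.ci_low, 1),
            round(100 * self.ci_high, 1),
        )


@dataclass
class AccuracyReport:
    ppv: MetricEstimate
    npv: MetricEstimate
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ci_method: str = "wilson"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("ppv", "npv", "sensitivity", "specificity"):
            m: MetricEstimate = getattr(self, name)
            rows.append(
                {
                    "metric": name,
                    "estimate": m.estimate,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "numerator": m.numerator,
                    "denominator": m.denominator,
                    "reason": m.reason,
                }
            )
        return pd.DataFrame(rows)


def _proportion(numer: int, denom: int, ci_method: str) -> MetricEstimate:
    if denom == 0:
        return MetricEstimate(
            None, None, None, numer, denom, reason="zero denominator"
        )
    method = {"wilson": "wilson", "wald": "normal"}[ci_method]
    lo, hi = proportion_confint(numer, denom, alpha=0.05, method=method)
    return MetricEstimate(
        estimate=numer / denom,
        ci_low=float(np.clip(lo, 0, 1)),
        ci_high=float(np.clip(hi, 0, 1)),
        numerator=numer,
        denominator=denom,
    )


def diagnostic_accuracy(
    table: ContingencyTable, ci_method: str = "wilson"
) -> AccuracyReport:
    """PPV, NPV, sensitivity, specificity with 95% CIs from a 2x2 table.

    Wilson score intervals by default (they behave near 0 and 1); Wald
    available for comparison with older reports.  Metrics with a zero
    denominator are reported absent with a reason rather than raising.
    """
    if ci_method not in ("wilson", "wald"):
        raise InvalidArgumentError("ci_method must be 'wilson' or 'wald'")
    t = table
    return AccuracyReport(
        ppv=_proportion(t.tp, t.tp + t.fp, ci_method),
        npv=_proportion(t.tn, t.tn + t.fn, ci_method),
        sensitivity=_proportion(t.tp, t.tp + t.fn, ci_method),
        specificity=_proportion(t.tn, t.tn + t.fp, ci_method),
        ci_method=ci_method,
    )


# ---------------------------------------------------------------------------
# 4. Prognosis: Kaplan–Meier
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    @property
    def cumulative_incidence(self) -> np.ndarray:
        return 1.0 - self.survival

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(durations, event_observed) -> SurvivalCurve:
    """Product-limit (Kaplan–Meier) survival estimate.

    Returns the curve evaluated at the distinct observed event times, with
    the number at risk just before each.
    """
    durations = np.asarray(list(durations), dtype=float)
    events = np.asarray(list(event_observed), dtype=bool)
    if durations.size == 0:
        raise NoDataError("no observations")
    if (durations < 0).any():
        raise InvalidArgumentError("durations must be >= 0")
    if not events.any():
        if (durations == 0).all():
            raise DegenerateInputError("all observations censored at time 0")
        # no events: survival is identically 1
        return SurvivalCurve(
            event_times=np.array([]), at_risk=np.array([]), survival=np.array([])
        )

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    event_times = np.unique(durations[events])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(durations >= t).sum() for t in event_times])
    return SurvivalCurve(event_times=event_times, at_risk=at_risk, survival=surv)


# ---------------------------------------------------------------------------
# 3. Etiology: Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    coefficients: pd.Series
    standard_errors: pd.Series
    hazard_ratios: pd.Series
    hr_ci_low: pd.Series
    hr_ci_high: pd.Series
    n: int
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "hr": self.hazard_ratios,
                "hr_ci_low": self.hr_ci_low,
                "hr_ci_high": self.hr_ci_high,
            }
        )


def cox_fit(durations, event_observed, covariates: pd.DataFrame) -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Breslow ties).

    HR = exp(coef); 95% CI = exp(coef +- 1.96 se).  Raises
    :class:`~ehrphen.errors.ConvergenceError` on non-convergence or
    detected complete separation (monotone likelihood).
    """
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    df = covariates.copy()
    df["_T"] = np.asarray(list(durations), dtype=float)
    df["_E"] = np.asarray(list(event_observed), dtype=int)
    if df["_E"].sum() < 1:
        raise DegenerateInputError("Cox model requires at least one event")
    rank = np.linalg.matrix_rank(covariates.to_numpy(dtype=float))
    if rank < covariates.shape[1]:
        raise InvalidArgumentError("covariate matrix is rank deficient")

    fitter = CoxPHFitter(baseline_estimation_method="breslow")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="_T", event_col="_E")
    except _LifelinesConvergenceError as exc:
        raise ConvergenceError(
            f"Cox partial-likelihood maximization failed: {exc}",
            diagnostics={"message": str(exc)},
        ) from exc
    coef = fitter.params_
    se = fitter.standard_errors_
    if (se > 50).any() or coef.abs().max() > 50:
        raise ConvergenceError(
            "monotone partial likelihood (complete separation) suspected",
            diagnostics={"coef": coef.to_dict(), "se": se.to_dict()},
        )
    return CoxResult(
        coefficients=coef,
        standard_errors=se,
        hazard_ratios=np.exp(coef),
        hr_ci_low=np.exp(coef - 1.96 * se),
        hr_ci_high=np.exp(coef + 1.96 * se),
        n=len(df),
        n_events=int(df["_E"].sum()),
    )


def etiology_comparison(
    fit: CoxResult, reference: dict[str, tuple[float, float, float]]
) -> pd.DataFrame:
    """Compare fitted HRs with user-supplied reference estimates.

    ``reference`` maps covariate -> (hr, ci_low, ci_high) from prior
    research.  Emits a table with a CI-overlap flag per covariate; judging
    consistency beyond overlap is left to the reader.
    """
    rows = []
    for cov, (hr, lo, hi) in reference.items():
        if cov not in fit.hazard_ratios.index:
            continue
        f_lo, f_hi = fit.hr_ci_low[cov], fit.hr_ci_high[cov]
        rows.append(
            {
                "covariate": cov,
                "hr_fitted": fit.hazard_ratios[cov],
                "hr_fitted_ci_low": f_lo,
                "hr_fitted_ci_high": f_hi,
                "hr_reference": hr,
                "hr_reference_ci_low": lo,
                "hr_reference_ci_high": hi,
                "ci_overlap": bool(max(f_lo, lo) <= min(f_hi, hi)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 5. Genetic replication
# ---------------------------------------------------------------------------


@dataclass
class ReplicationResult:
    m: int
    alpha: float
    bonferroni_threshold: float
    n_nominal_concordant: int
    n_bonferroni_replicated: int
    n_direction_undefined: int
    per_variant: pd.DataFrame = field(repr=False, default=None)


def genetic_replication(variants: pd.DataFrame, alpha: float = 0.05) -> ReplicationResult:
    """Apply the Bonferroni + direction-concordance replication rule.

    ``variants`` needs columns ``effect_discovery``, ``effect_replication``
    and ``p_replication``.  A variant replicates when its replication p-value
    beats alpha/m *and* the effect directions agree; nominal concordance uses
    p < alpha.  Variants with a zero effect in either column have undefined
    direction and are flagged, never counted as replicated.
    """
    m = len(variants)
    if m < 1:
        raise NoDataError("variant table is empty")
    required = {"effect_discovery", "effect_replication", "p_replication"}
    missing = required - set(variants.columns)
    if missing:
        raise InvalidArgumentError(f"variant table missing columns {sorted(missing)}")
    threshold = alpha / m
    df = variants.copy().reset_index(drop=True)
    sign_d = np.sign(df["effect_discovery"].to_numpy(dtype=float))
    sign_r = np.sign(df["effect_replication"].to_numpy(dtype=float))
    undefined = (sign_d == 0) | (sign_r == 0)
    concordant = (sign_d == sign_r) & ~undefined
    p = df["p_replication"].to_numpy(dtype=float)
    df["direction_undefined"] = undefined
    df["nominal_concordant"] = concordant & (p < alpha)
    df["bonferroni_replicated"] = concordant & (p < threshold)
    return ReplicationResult(
        m=m,
        alpha=alpha,
        bonferroni_threshold=threshold,
        n_nominal_concordant=int(df["nominal_concordant"].sum()),
        n_bonferroni_replicated=int(df["bonferroni_replicated"].sum()),
        n_direction_undefined=int(undefined.sum()),
        per_variant=df,
    )


# ---------------------------------------------------------------------------
# Report container + 6. external populations
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Collected evidence across the validation approaches for one cohort."""

    label: str
    concordance: ConcordanceResult | None = None
    accuracy: AccuracyReport | None = None
    survival_summary: dict | None = None
    etiology: pd.DataFrame | None = None
    replication: ReplicationResult | None = None

    def summary_text(self) -> str:
        lines = [f"cohort: {self.label}"]
        if self.concordance is not None:
            c = self.concordance
            pats = ", ".join(
                f"{k}: {v}%" for k, v in sorted(c.pattern_percentages.items())
            )
            lines.append(
                f"  concordance (window={c.window_days}): total={c.total}; {pats}"
            )
            lines.append(
                "  captured in >=2 sources: "
                f"{c.k_or_more_percentages.get(2, 0.0)}%"
            )
        if self.accuracy is not None:
            for name in ("ppv", "npv", "sensitivity", "specificity"):
                m = getattr(self.accuracy, name)
                p = m.percent()
                lines.append(
                    f"  {name}: absent ({m.reason})"
                    if p is None
                    else f"  {name}: {p[0]}% (95% CI {p[1]}%-{p[2]}%)"
                )
        if self.survival_summary:
            for k, v in self.survival_summary.items():
                lines.append(f"  survival {k}: {v:.3f}")
        if self.replication is not None:
            r = self.replication
            lines.append(
                f"  replication: {r.n_bonferroni_replicated}/{r.m} at "
                f"P<{r.bonferroni_threshold:.4f}, {r.n_nominal_concordant} nominal"
            )
        return "\n".join(lines)


def validate_cohort(
    config: GeneratorConfig,
    definition,
    label: str,
    window_days: float = np.inf,
    measurement_policies=None,
    followup_days: float = 365.0,
) -> ValidationReport:
    """Run generate -> phenotype -> concordance/accuracy/survival once."""
    from .engine import apply_phenotype  # local import to avoid a cycle

    cohort = generate_cohort(config)
    result = apply_phenotype(cohort, definition, measurement_policies)
    concordance = concordance_from_result(result, window_days=window_days)

    # accuracy against the generator's planted truth
    truth = cohort.truth.set_index("patient_id")["is_case"]
    called = result.case_records.set_index("patient_id")["is_case"].reindex(
        truth.index, fill_value=False
    )
    table = ContingencyTable(
        tp=int((called & truth).sum()),
        fp=int((called & ~truth).sum()),
        fn=int((~called & truth).sum()),
        tn=int((~called & ~truth).sum()),
    )
    accuracy = diagnostic_accuracy(table)

    # all-cause mortality after the index date among cases
    cases = result.cases()
    deaths = cohort.deaths.set_index("patient_id")["death_date"]
    idx = pd.to_datetime(cases["index_date"])
    ddate = pd.to_datetime(
        cases["patient_id"].map(deaths), errors="coerce"
    ).reset_index(drop=True)
    idx = idx.reset_index(drop=True)
    t_death = (ddate - idx).dt.days
    event = t_death.notna() & (t_death >= 0)
    duration = np.where(event, t_death, followup_days)
    duration = np.clip(duration, 0, followup_days)
    event = event & (t_death <= followup_days)
    survival_summary = {}
    if event.any():
        curve = km_curve(duration, event)
        survival_summary = {
            f"S({int(followup_days)}d)": curve.survival_at(followup_days)
        }
    return ValidationReport(
        label=label,
        concordance=concordance,
        accuracy=accuracy,
        survival_summary=survival_summary,
    )


@dataclass
class ExternalComparison:
    report_a: ValidationReport
    report_b: ValidationReport

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for report in (self.report_a, self.report_b):
            row = {"cohort": report.label}
            if report.concordance:
                row.update(
                    {
                        f"pct_{k}": v
                        for k, v in report.concordance.pattern_percentages.items()
                    }
                )
                row["pct_2_or_more"] = report.concordance.k_or_more_percentages.get(2)
            if report.accuracy and report.accuracy.ppv.estimate is not None:
                row["ppv"] = round(report.accuracy.ppv.estimate, 4)
                row["sensitivity"] = round(
                    report.accuracy.sensitivity.estimate, 4
                )
            if report.survival_summary:
                row.update({k: round(v, 4) for k, v in report.survival_summary.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        return (
            self.report_a.summary_text() + "\n" + self.report_b.summary_text()
        )


def external_population_run(
    config_a: GeneratorConfig,
    config_b: GeneratorConfig,
    definition_a,
    definition_b=None,
    labels=("population A", "population B"),
    window_days: float = np.inf,
    measurement_policies=None,
) -> ExternalComparison:
    """Re-run the full pipeline on two generator configs, side by side.

    The same phenotype definition must drive both runs; supplying a second,
    different definition is a mismatch error.
    """
    definition_b = definition_b if definition_b is not None else definition_a
    if (definition_a.name, definition_a.version, definition_a.logic) != (
        definition_b.name,
        definition_b.version,
        definition_b.logic,
    ):
        raise InvalidArgumentError(
            "external-population comparison requires the same phenotype "
            f"definition; got {definition_a.name!r} v{definition_a.version} "
            f"vs {definition_b.name!r} v{definition_b.version}"
        )
    report_a = validate_cohort(
        config_a, definition_a, labels[0], window_days, measurement_policies
    )
    report_b = validate_cohort(
        config_b, definition_a, labels[1], window_days, measurement_policies
    )
    return ExternalComparison(report_a=report_a, report_b=report_b)
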