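"""Biomarker-outcome statistics for physician vs digital PD-L1 calls.

Implements the cohort-level analysis layer: rater concordance on the
binary >=5% calls, the three-level combined classification, response
tables with a chi-square test, Pearson correlation of the raw
percentages, Kaplan-Meier survival curves, the log-rank test, and
multivariable Cox proportional-hazards fits.  Survival machinery is
backed by ``lifelines``; contingency and correlation tests by
``scipy.stats``.

Conventions used throughout: all p-values are two-sided; the median
survival time is the smallest ``t`` with ``S(t) <= 0.5`` and is
reported as ``None`` ("not reached") when the curve never gets there;
Cox ties are handled with the Efron approximation; rows with missing
covariates are dropped per model (complete case) with the exclusion
count reported, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "PatientRecord",
    "ConcordanceTable",
    "SurvivalCurve",
    "CoxFit",
    "ResponseTable",
    "COVARIATE_FIELDS",
    "concordance",
    "positivity_rate",
    "combined_class",
    "response_table",
    "pearson_r",
    "km_curve",
    "logrank",
    "cox_fit",
    "records_to_frame",
    "frame_to_records",
]

#: Binary prognostic covariates carried by each patient record, in the
#: order they enter the multivariable Cox model.
COVARIATE_FIELDS = (
    "age_gt65",
    "sex_male",
    "stage_iv",
    "primary_skin",
    "m_cat_high",
    "ldh_elevated",
    "combo_therapy",
    "braf_mutant",
)


@dataclass
class PatientRecord:
    """One patient's PD-L1 calls, therapy response and survival data.

    ``physician_call`` / ``digital_call`` are ``"positive"`` or
    ``"negative"``; percentages are optional.  ``bor_responder`` is true
    for complete or partial response.  Survival times are months from
    therapy start; an event flag of ``False`` marks censoring at last
    contact.  Covariates are booleans and may be ``None`` (missing).
    """

    id: str
    physician_call: str
    digital_call: str
    physician_pct: float | None = None
    digital_pct: float | None = None
    bor_responder: bool | None = None
    pfs_months: float = 0.0
    os_months: float = 0.0
    pfs_event: bool = False
    os_event: bool = False
    age_gt65: bool | None = None
    sex_male: bool | None = None
    stage_iv: bool | None = None
    primary_skin: bool | None = None
    m_cat_high: bool | None = None
    ldh_elevated: bool | None = None
    combo_therapy: bool | None = None
    braf_mutant: bool | None = None

    def __post_init__(self) -> None:
        for name in ("physician_call", "digital_call"):
            if getattr(self, name) not in ("positive", "negative"):
                raise ValueError(f"{name} must be 'positive' or 'negative'")
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be non-negative")


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into a DataFrame (one row per patient)."""
    return pd.DataFrame([vars(r) for r in records])


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`records_to_frame`; NaNs become ``None``."""
    recs = []
    for _, row in df.iterrows():
        kw = {k: row[k] for k in df.columns if k in PatientRecord.__dataclass_fields__}
        for k, v in kw.items():
            if isinstance(v, float) and np.isnan(v):
                kw[k] = None
        kw["id"] = str(kw["id"])
        recs.append(PatientRecord(**kw))
    return recs


# ---------------------------------------------------------------------------
# Concordance and classification
# ---------------------------------------------------------------------------


def _as_calls(calls: Iterable, name: str) -> np.ndarray:
    arr = []
    for c in calls:
        if isinstance(c, (bool, np.bool_)):
            arr.append("positive" if c else "negative")
        elif c in ("positive", "negative"):
            arr.append(c)
        else:
            raise ValueError(f"{name}: missing or invalid call {c!r}")
    if not arr:
        raise ValueError(f"{name}: empty call list")
    return np.array(arr)


@dataclass
class ConcordanceTable:
    """2x2 cross-classification of physician vs digital binary calls."""

    n_pos_pos: int
    n_neg_neg: int
    n_pos_digital_only: int
    n_pos_physician_only: int

    @property
    def n_total(self) -> int:
        return (
            self.n_pos_pos
            + self.n_neg_neg
            + self.n_pos_digital_only
            + self.n_pos_physician_only
        )

    @property
    def percent_agreement(self) -> float:
        """Agreement (both-positive plus both-negative), one decimal."""
        return round(100.0 * (self.n_pos_pos + self.n_neg_neg) / self.n_total, 1)

    @property
    def percent_discordance(self) -> float:
        """Complement of agreement; the two always sum to exactly 100."""
        return 100.0 - self.percent_agreement


def concordance(
    physician_calls: Iterable, digital_calls: Iterable
) -> ConcordanceTable:
    """Cross-classify two call vectors into a 2x2 concordance table.

    Raises on length mismatch or any missing call.
    """
    phys = _as_calls(physician_calls, "physician_calls")
    dig = _as_calls(digital_calls, "digital_calls")
    if phys.size != dig.size:
        raise ValueError("call vectors must have equal length")
    p = phys == "positive"
    d = dig == "positive"
    return ConcordanceTable(
        n_pos_pos=int(np.sum(p & d)),
        n_neg_neg=int(np.sum(~p & ~d)),
        n_pos_digital_only=int(np.sum(~p & d)),
        n_pos_physician_only=int(np.sum(p & ~d)),
    )


def positivity_rate(calls: Iterable) -> float:
    """Percentage of positive calls, reported to one decimal."""
    arr = _as_calls(calls, "calls")
    return round(100.0 * float(np.mean(arr == "positive")), 1)


def combined_class(physician_call: str, digital_call: str) -> str:
    """Three-level combined classification of the two binary calls.

    ``both_positive`` / ``both_negative`` when the raters agree;
    ``single_positive`` pools the two discordant patterns (positive by
    exactly one rater).
    """
    calls = _as_calls([physician_call], "physician_call")[0], _as_calls(
        [digital_call], "digital_call"
    )[0]
    pos = [c == "positive" for c in calls]
    if all(pos):
        return "both_positive"
    if not any(pos):
        return "both_negative"
    return "single_positive"


# ---------------------------------------------------------------------------
# Response tables and correlation
# ---------------------------------------------------------------------------


@dataclass
class ResponseTable:
    """Per-group best-overall-response rates with a chi-square test."""

    table: pd.DataFrame  # columns: group, n, n_responders, bor_percent
    chi_square: float
    p_value: float
    df: int


def response_table(
    records: Sequence[PatientRecord],
    grouping: str | Callable[[PatientRecord], str],
    yates: bool = False,
) -> ResponseTable:
    """Best-overall-response rates by group, with a Pearson chi-square.

    ``grouping`` is either a record attribute name or a callable mapping
    a record to its group label.  Records with a missing
    ``bor_responder`` are excluded (response not evaluable).  The
    chi-square is computed without continuity correction by default
    (``yates=True`` enables it) on the responders/non-responders by
    group contingency table; any zero expected cell raises.
    """
    group_of = (lambda r: getattr(r, grouping)) if isinstance(grouping, str) else grouping
    rows: dict[str, list[int]] = {}
    for r in records:
        if r.bor_responder is None:
            continue
        g = str(group_of(r))
        rows.setdefault(g, [0, 0])
        rows[g][0] += int(bool(r.bor_responder))
        rows[g][1] += 1
    if len(rows) < 2:
        raise ValueError("response_table needs at least two non-empty groups")
    groups = sorted(rows)
    resp = np.array([rows[g][0] for g in groups])
    total = np.array([rows[g][1] for g in groups])
    contingency = np.stack([resp, total - resp])
    try:
        chi2, p, dof, _ = sps.chi2_contingency(contingency, correction=yates)
    except ValueError as exc:
        raise ValueError(f"chi-square undefined: {exc}") from exc
    table = pd.DataFrame(
        {
            "group": groups,
            "n": total,
            "n_responders": resp,
            "bor_percent": np.round(100.0 * resp / total, 1),
        }
    )
    return ResponseTable(table=table, chi_square=float(chi2), p_value=float(p), df=int(dof))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r needs at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier product-limit estimate.

    ``event_times`` are the distinct times with at least one observed
    event, ascending; ``survival_probs`` the estimate just after each;
    ``n_at_risk`` the risk-set size at each.  ``median`` is ``None``
    when the curve never drops to 0.5 ("not reached").
    """

    event_times: np.ndarray
    survival_probs: np.ndarray
    n_at_risk: np.ndarray
    median: float | None
    n: int
    n_events: int


def km_curve(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier estimator for right-censored failure times."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("km_curve needs at least one observation")
    if t.size != e.size or (t < 0).any():
        raise ValueError("times and events must match and be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times_out = ev.index.to_numpy(dtype=float)
    probs = kmf.survival_function_.loc[times_out, kmf.survival_function_.columns[0]].to_numpy()
    at_risk = ev["at_risk"].to_numpy(dtype=np.int64)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return SurvivalCurve(
        event_times=times_out,
        survival_probs=probs,
        n_at_risk=at_risk,
        median=median,
        n=int(t.size),
        n_events=int(e.sum()),
    )


def logrank(groups: Sequence[tuple[Sequence[float], Sequence[bool]]]) -> tuple[float, float]:
    """Two-sided log-rank test across two or more groups.

    Returns ``(chi_square_statistic, p_value)`` with ``len(groups) - 1``
    degrees of freedom.  Raises if any group is empty or no events were
    observed anywhere ("test undefined").
    """
    if len(groups) < 2:
        raise ValueError("logrank needs at least two groups")
    durations, labels, observed = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"logrank group {i} is empty")
        durations.append(t)
        observed.append(e)
        labels.append(np.full(t.size, i))
    durations = np.concatenate(durations)
    observed = np.concatenate(observed)
    labels = np.concatenate(labels)
    if not observed.any():
        raise ValueError("log-rank test undefined: no events in any group")
    res = multivariate_logrank_test(durations, labels, observed)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """A multivariable Cox proportional-hazards fit.

    ``summary`` has one row per covariate with columns ``hazard_ratio``,
    ``ci_lower``, ``ci_upper`` (Wald 95%) and ``p_value``.
    """

    summary: pd.DataFrame
    n_used: int
    n_excluded: int
    n_events: int
    ties_method: str = "efron"

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_lower"]), float(row["ci_upper"])

    def p_value(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p_value"])


def cox_fit(
    records: Sequence[PatientRecord] | pd.DataFrame,
    endpoint: str,
    covariates: Sequence[str],
) -> CoxFit:
    """Multivariable Cox model for PFS or OS.

    ``endpoint`` is ``"pfs"`` or ``"os"``; ``covariates`` are column
    names holding binary (or numeric) regressors.  Rows with any missing
    requested covariate are dropped (complete case) and counted in
    ``n_excluded``.  Ties use the Efron approximation; confidence
    intervals and p-values are Wald-based.

    Raises
    ------
    ValueError
        If no events remain, a covariate is constant (separation /
        degenerate), or the partial-likelihood maximization fails.
    """
    if endpoint not in ("pfs", "os"):
        raise ValueError("endpoint must be 'pfs' or 'os'")
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    duration_col, event_col = f"{endpoint}_months", f"{endpoint}_event"
    cols = [duration_col, event_col, *covariates]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = df[cols].copy()
    n_before = len(sub)
    sub = sub.dropna()
    n_used = len(sub)
    if n_used == 0:
        raise ValueError("no complete-case rows left for the Cox model")
    sub = sub.astype(float)
    if sub[event_col].sum() < 1:
        raise ValueError("Cox model needs at least one event")
    for c in covariates:
        if sub[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant across patients; model degenerate")
    fitter = CoxPHFitter()
    try:
        fitter.fit(sub, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise ValueError(f"Cox model failed to converge: {exc}") from exc
    s = fitter.summary
    summary = pd.DataFrame(
        {
            "hazard_ratio": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p_value": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        n_used=n_used,
        n_excluded=n_before - n_used,
        n_events=int(sub[event_col].sum()),
    )
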