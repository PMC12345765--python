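"""Univariate Cox proportional-hazards screening of candidate genes.

Candidates emerging from the presence/absence cascade are prioritized by
clinical relevance: for each gene, expression in a tumor cohort (RNA-seq,
genes × patients) is regressed as a continuous covariate against overall
survival (OS: surgery to any-cause death) and disease-free survival (DFS:
surgery to recurrence or death) in a univariate Cox model.  The hazard ratio
exp(beta), its Wald 95% CI and p-value, a Benjamini–Hochberg q across the
screened set, and a Schoenfeld-residual proportionality check are reported
per gene.

Expression is transformed log2(x+1) and z-scored per gene before fitting, so
hazard ratios are per standard deviation and comparable across genes; the
transform is recorded in the output.  Ties are handled with Efron's
approximation, appropriate for month-resolution follow-up.  Fitting stands
on lifelines (CoxPHFitter, proportional_hazard_test, KaplanMeierFitter).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from statsmodels.stats.multitest import multipletests

from .setalgebra import ProteinSet

logger = logging.getLogger(__name__)

#: columns a clinical table must provide (dfs_* may be missing per record)
CLINICAL_COLUMNS = ("patient_id", "sample_type", "os_time", "os_event", "dfs_time", "dfs_event")

DEFAULT_TRANSFORM = "log2(x+1), z-score"


class Endpoint(str, Enum):
    OS = "OS"
    DFS = "DFS"

    @property
    def time_col(self) -> str:
        return "os_time" if self is Endpoint.OS else "dfs_time"

    @property
    def event_col(self) -> str:
        return "os_event" if self is Endpoint.OS else "dfs_event"


class NoOverlappingGenesError(ValueError):
    """No screened candidate is present in the expression matrix."""


@dataclass
class CoxScreenResult:
    """Per-gene univariate Cox fit for one endpoint.

    ``degenerate`` marks zero-information fits (constant covariate or fewer
    than two events): beta is reported as 0 with undefined CI/p, never as an
    exception, so a screen over many genes survives pathological columns.
    """

    gene: str
    endpoint: Endpoint
    n: int
    n_events: int
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    q: float = float("nan")
    prop_p: float = float("nan")
    prop_violation: bool = False
    degenerate: bool = False
    reason: str = ""


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-table contract and coerce dtypes.

    Times must be >= 0, events in {0, 1}; dfs_time and dfs_event must be
    jointly present or jointly missing per record.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df = clinical.copy()
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient ids in clinical table")
    for tcol, ecol in (("os_time", "os_event"), ("dfs_time", "dfs_event")):
        t = pd.to_numeric(df[tcol], errors="coerce")
        e = pd.to_numeric(df[ecol], errors="coerce")
        if t.isna().ne(e.isna()).any():
            raise ValueError(f"{tcol}/{ecol} must be jointly present or missing")
        if (t.dropna() < 0).any():
            raise ValueError(f"negative values in {tcol}")
        if not e.dropna().isin([0, 1]).all():
            raise ValueError(f"{ecol} values must be 0/1")
        df[tcol], df[ecol] = t, e
    if df["os_time"].isna().any():
        raise ValueError("os_time/os_event are required for every record")
    return df


def filter_cohort(clinical: pd.DataFrame, sample_type: str) -> pd.DataFrame:
    """Restrict the clinical table to one sample-type tag (e.g. primary)."""
    out = clinical[clinical["sample_type"] == sample_type].copy()
    if out.empty:
        logger.warning("no clinical records with sample_type=%r", sample_type)
    logger.info("cohort filter %r: %d of %d records", sample_type, len(out), len(clinical))
    return out


def transform_expression(values: np.ndarray) -> np.ndarray:
    """log2(x+1) then z-score; returns NaN-variance columns untouched."""
    logged = np.log2(np.asarray(values, dtype=float) + 1.0)
    sd = logged.std(ddof=1)
    # guard against float noise on (near-)constant columns: report them as
    # exactly zero-variance so the Cox fit takes the degenerate path
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.abs(logged).max())):
        return np.zeros_like(logged)
    return (logged - logged.mean()) / sd


def cox_univariate(
    values: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    gene: str = "gene",
    endpoint: Endpoint = Endpoint.OS,
    check_proportionality: bool = True,
) -> CoxScreenResult:
    """Fit a univariate Cox model of one covariate against survival.

    beta maximizes the Cox partial likelihood with Efron tie handling; the
    CI and p are Wald-based.  A constant covariate or < 2 events yields a
    degenerate result (beta 0, CI/p undefined) rather than an error, and the
    Schoenfeld check is skipped with the reason recorded.
    """
    endpoint = Endpoint(endpoint)
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    n = len(values)
    n_events = int(events.sum())

    def _degenerate(reason: str) -> CoxScreenResult:
        return CoxScreenResult(
            gene=gene, endpoint=endpoint, n=n, n_events=n_events,
            beta=0.0, hr=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            p=float("nan"), degenerate=True, reason=reason,
        )

    if n_events < 2:
        return _degenerate(f"fewer than 2 events ({n_events})")
    if not np.all(np.isfinite(values)):
        return _degenerate("non-finite covariate values")
    if np.var(values) == 0:
        return _degenerate("constant covariate (zero variance)")

    df = pd.DataFrame({"time": times, "event": events, "z": values})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # monotone-likelihood etc.
        return _degenerate(f"fit failed: {exc}")

    summary = cph.summary.loc["z"]
    beta = float(summary["coef"])
    result = CoxScreenResult(
        gene=gene,
        endpoint=endpoint,
        n=n,
        n_events=n_events,
        beta=beta,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(summary["coef lower 95%"])),
        ci_high=float(np.exp(summary["coef upper 95%"])),
        p=float(summary["p"]),
    )
    if check_proportionality:
        p = schoenfeld_check(cph, df)
        result.prop_p = p
        result.prop_violation = bool(np.isfinite(p) and p < 0.05)
    return result


def schoenfeld_check(fitted: CoxPHFitter, df: pd.DataFrame) -> float:
    """Proportional-hazards p-value from scaled Schoenfeld residuals.

    Correlation test of the scaled residuals against event-time rank; small
    p flags a time-varying effect.  Returns NaN (check skipped) when the fit
    cannot support residuals (e.g. a single event).
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            test = proportional_hazard_test(fitted, df, time_transform="rank")
        return float(np.asarray(test.p_value).ravel()[0])
    except Exception as exc:
        logger.info("Schoenfeld check skipped: %s", exc)
        return float("nan")


def km_median(times: np.ndarray, events: np.ndarray) -> float | None:
    """Kaplan–Meier median survival time, or ``None`` when not reached.

    The median is the smallest observed time at which the KM curve drops
    strictly below one half.  A curve that only ever *touches* 0.5 has not
    crossed it: the median is treated as not reached (returns ``None``).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if len(times) == 0:
        raise ValueError("km_median requires at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_.iloc[:, 0]
    below = surv[surv < 0.5]
    if below.empty:
        return None
    return float(below.index[0])


@dataclass
class ScreenOutput:
    """A Cox screen over a candidate set: results plus bookkeeping."""

    results: list[CoxScreenResult]
    unavailable: list[str]  # candidates absent from the expression matrix
    endpoint: Endpoint
    transform: str = DEFAULT_TRANSFORM

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "endpoint": r.endpoint.value,
                    "n": r.n,
                    "n_events": r.n_events,
                    "beta": r.beta,
                    "hr": r.hr,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p,
                    "q": r.q,
                    "prop_p": r.prop_p,
                    "prop_violation": r.prop_violation,
                    "degenerate": r.degenerate,
                    "reason": r.reason,
                }
                for r in self.results
            ]
        )


def screen(
    candidates: ProteinSet,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoint: Endpoint = Endpoint.OS,
    transform: bool = True,
) -> ScreenOutput:
    """Cox-screen every candidate gene against one survival endpoint.

    ``expression`` is genes (index) × patients (columns), non-negative.
    Records lacking the endpoint's time/event are dropped pairwise.
    Results carry BH-adjusted q-values across the screened set and are
    sorted by ascending p (degenerate fits last).

    Raises
    ------
    NoOverlappingGenesError
        If no candidate gene appears in the expression index.
    """
    endpoint = Endpoint(endpoint)
    clinical = validate_clinical(clinical)

    wanted = candidates.values()
    present = [g for g in wanted if g in expression.index]
    unavailable = [g for g in wanted if g not in expression.index]
    if not present:
        raise NoOverlappingGenesError(
            "no candidate gene overlaps the expression matrix index"
        )
    if unavailable:
        logger.info("%d candidate(s) unavailable in expression: %s",
                    len(unavailable), unavailable)

    cohort = clinical.dropna(subset=[endpoint.time_col, endpoint.event_col])
    patients = [p for p in expression.columns if p in set(cohort["patient_id"])]
    cohort = cohort.set_index("patient_id").loc[patients]
    times = cohort[endpoint.time_col].to_numpy()
    events = cohort[endpoint.event_col].to_numpy()

    results = []
    for gene in present:
        raw = expression.loc[gene, patients].to_numpy(dtype=float)
        vals = transform_expression(raw) if transform else raw
        results.append(
            cox_univariate(vals, times, events, gene=gene, endpoint=endpoint)
        )

    usable = [r for r in results if not r.degenerate]
    if usable:
        qvals = multipletests([r.p for r in usable], method="fdr_bh")[1]
        for r, q in zip(usable, qvals):
            r.q = float(q)
    results.sort(key=lambda r: (r.degenerate, r.p if np.isfinite(r.p) else np.inf))
    return ScreenOutput(
        results=results,
        unavailable=unavailable,
        endpoint=endpoint,
        transform=DEFAULT_TRANSFORM if transform else "none",
    )
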