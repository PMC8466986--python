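"""Clinical association and survival analysis.

Association of marker status with clinicopathological features uses
Pearson's chi-square (no continuity correction) with an automatic switch
to an exact conditional test when expected counts fall below 5.  Survival
comparisons use Kaplan-Meier product-limit curves with the log-rank test,
and multivariable Cox proportional-hazards regression (Efron ties) with
constant or collinear covariates dropped and flagged.  All computations
use pairwise deletion of missing clinical fields and report the n used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "ClinicalRecord",
    "SurvivalResult",
    "CoxResult",
    "read_clinical_table",
    "contingency_test",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "marker_outcome_scan",
]

CLINICAL_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "smoking",
    "drinking",
    "tnm_stage",
    "path_type",
    "location",
    "lymph_node",
    "chemotherapy",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
)

TNM_STAGES = ("I", "II", "III", "IV")
PATH_TYPES = ("adenocarcinoma", "mucinous", "signet_ring", "other")
LOCATIONS = ("colon", "rectum")


@dataclass
class ClinicalRecord:
    """One patient's clinical covariates and survival endpoints.

    Any field but ``patient_id`` may be None (missing); times are months.
    """

    patient_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    smoking: Optional[bool] = None
    drinking: Optional[bool] = None
    tnm_stage: Optional[str] = None
    path_type: Optional[str] = None
    location: Optional[str] = None
    lymph_node: Optional[bool] = None
    chemotherapy: Optional[bool] = None
    os_months: Optional[float] = None
    os_event: Optional[bool] = None
    pfs_months: Optional[float] = None
    pfs_event: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("os_months", "pfs_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.tnm_stage is not None and self.tnm_stage not in TNM_STAGES:
            raise ValueError(f"unknown TNM stage {self.tnm_stage!r}")


def records_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    rows = [vars(r).copy() for r in records]
    return pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS))


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical CSV (missing values as empty cells) into a frame
    indexed like :data:`CLINICAL_COLUMNS`."""
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    for col in ("smoking", "drinking", "lymph_node", "chemotherapy", "os_event", "pfs_event"):
        df[col] = df[col].map(
            lambda v: None if pd.isna(v) else bool(int(v)), na_action=None
        )
    return df[list(CLINICAL_COLUMNS)]


# ---------------------------------------------------------------------------
# Contingency tests


def _exact_2xk_p(table: np.ndarray) -> float:
    """Exact conditional p for a 2xK table: sum of probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (probability-based two-sided definition)."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())
    r1 = int(row[0])

    def log_table_prob(top: Sequence[int]) -> float:
        # P(table | margins) under the multivariate hypergeometric null
        lp = (
            math.lgamma(row[0] + 1)
            + math.lgamma(row[1] + 1)
            - math.lgamma(n + 1)
        )
        for cj, tj in zip(col, top):
            lp += math.lgamma(cj + 1) - math.lgamma(tj + 1) - math.lgamma(cj - tj + 1)
        return lp

    obs_lp = log_table_prob(table[0])
    total = 0.0
    p_le = 0.0
    k = len(col)

    def recurse(j: int, remaining: int, top: list[int], lp_partial: float) -> None:
        nonlocal total, p_le
        if j == k - 1:
            tj = remaining
            if 0 <= tj <= col[j]:
                lp = lp_partial + log_table_prob(top + [tj])
                # log_table_prob recomputes fully; lp_partial kept at 0
                p = math.exp(lp)
                total += p
                if lp <= obs_lp + 1e-9:
                    p_le += p
            return
        for tj in range(0, min(int(col[j]), remaining) + 1):
            recurse(j + 1, remaining - tj, top + [tj], lp_partial)

    recurse(0, r1, [], 0.0)
    return min(1.0, p_le / total) if total > 0 else 1.0


def contingency_test(table, method: str = "auto") -> tuple[Optional[float], float, str]:
    """Association test for a 2xK count table.

    With ``method="auto"``: Pearson chi-square without continuity
    correction, switching to an exact test when any expected count is
    below 5 — Fisher's exact for 2x2, exact conditional enumeration for
    small 2xK tables (falls back to chi-square on large sparse tables).
    ``method="chi2"`` or ``"fisher"`` forces one route.  Returns
    (statistic, p, method used); the statistic is None for exact tests.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError(f"expected a 2xK table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: a margin is zero")

    def chi2():
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return (float(stat), float(p), "chi-square")

    def exact():
        if table.shape[1] == 2:
            _, p = stats.fisher_exact(table, alternative="two-sided")
            return (None, float(p), "fisher")
        if table.sum() <= 500:
            return (None, _exact_2xk_p(table), "exact-2xK")
        stat, p, meth = chi2()
        return (stat, p, "chi-square-lowexp")

    if method == "chi2":
        return chi2()
    if method == "fisher":
        return exact()
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    expected = stats.contingency.expected_freq(table)
    return chi2() if (expected >= 5).all() else exact()


# ---------------------------------------------------------------------------
# Survival


@dataclass
class SurvivalResult:
    """Kaplan-Meier curves per group plus the log-rank comparison."""

    groups: list[str]
    curves: dict[str, pd.DataFrame]  # columns: time, survival, at_risk
    n_per_group: dict[str, int]
    logrank_statistic: Optional[float] = None
    logrank_p: Optional[float] = None


@dataclass
class CoxResult:
    """Proportional-hazards fit: per-covariate HR, 95% CI and p-value."""

    covariates: dict[str, dict] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)
    n: int = 0
    n_events: int = 0
    warnings: list[str] = field(default_factory=list)


def km_fit(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence | None = None,
) -> SurvivalResult:
    """Product-limit survival estimate per group (ties: events first)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    if not (len(times) == len(events) == len(groups)):
        raise ValueError("times, events and groups must have equal length")
    if len(times) == 0:
        raise ValueError("empty survival data")
    if (times < 0).any():
        raise ValueError("times must be >= 0")

    labels = [str(g) for g in pd.unique(groups)]
    curves = {}
    n_per_group = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tbl = kmf.event_table
        surv = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(),
                "survival": surv.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(surv.index).to_numpy(),
            }
        )
        n_per_group[str(g)] = int(mask.sum())

    result = SurvivalResult(groups=labels, curves=curves, n_per_group=n_per_group)
    if len(labels) >= 2:
        stat, p = logrank_test(times, events, groups)
        result.logrank_statistic = stat
        result.logrank_p = p
    return result


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> tuple[float, float]:
    """Two-sided log-rank chi-square test with K-1 degrees of freedom."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank test needs at least two groups")
    for g in uniq:
        if (groups == g).sum() == 0:
            raise ValueError(f"empty group {g!r}")
    res = multivariate_logrank_test(times, groups, events)
    return (float(res.test_statistic), float(res.p_value))


def _design_matrix(
    records: pd.DataFrame, covariates: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Numeric design matrix with constant/collinear covariates dropped."""
    dropped: dict[str, str] = {}
    cols = {}
    for cov in covariates:
        if cov not in records.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        series = records[cov]
        if series.dtype == object or series.dtype.name == "category":
            # binary-encode: reference level = first sorted level
            levels = sorted(x for x in series.dropna().unique())
            if len(levels) <= 1:
                dropped[cov] = "constant"
                continue
            if len(levels) == 2:
                cols[cov] = series.map({levels[0]: 0.0, levels[1]: 1.0})
            else:
                for lev in levels[1:]:
                    cols[f"{cov}[{lev}]"] = (series == lev).astype(float).where(
                        series.notna()
                    )
        else:
            cols[cov] = pd.to_numeric(series, errors="coerce")
    X = pd.DataFrame(cols)

    for name in list(X.columns):
        vals = X[name].dropna()
        if vals.nunique() <= 1:
            dropped[name] = "constant"
            X = X.drop(columns=[name])
    # collinearity: drop columns that add no rank
    kept: list[str] = []
    for name in X.columns:
        sub = X[kept + [name]].dropna()
        if len(sub) and np.linalg.matrix_rank(sub.to_numpy()) > len(kept):
            kept.append(name)
        else:
            dropped[name] = "linearly dependent"
    return X[kept], dropped


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    endpoint: str = "OS",
) -> CoxResult:
    """Cox proportional-hazards regression (Efron tie handling).

    ``endpoint`` selects the (os_months, os_event) or (pfs_months,
    pfs_event) columns.  Rows missing the endpoint or any covariate are
    dropped listwise for the fit; constant or linearly dependent
    covariates are removed beforehand and flagged, mirroring how standard
    survival software reduces the degrees of freedom.
    """
    endpoint = endpoint.upper()
    if endpoint not in ("OS", "PFS"):
        raise ValueError("endpoint must be OS or PFS")
    tcol, ecol = (
        ("os_months", "os_event") if endpoint == "OS" else ("pfs_months", "pfs_event")
    )
    X, dropped = _design_matrix(records, covariates)
    df = X.copy()
    df["_time"] = pd.to_numeric(records[tcol], errors="coerce")
    df["_event"] = records[ecol].map(
        lambda v: np.nan if v is None or (isinstance(v, float) and np.isnan(v)) else int(v)
    )
    df = df.dropna()
    if df.empty or int(df["_event"].sum()) == 0:
        raise ValueError("no events in the analysis set")

    result = CoxResult(dropped=dropped, n=len(df), n_events=int(df["_event"].sum()))
    if df.shape[1] == 2:  # every covariate dropped
        return result

    cph = CoxPHFitter()
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        cph.fit(df, duration_col="_time", event_col="_event")
        for w in caught:
            result.warnings.append(str(w.message))

    summary = cph.summary
    for name in summary.index:
        row = summary.loc[name]
        result.covariates[str(name)] = {
            "hr": float(row["exp(coef)"]),
            "ci_low": float(row["exp(coef) lower 95%"]),
            "ci_high": float(row["exp(coef) upper 95%"]),
            "p": float(row["p"]),
            "coef": float(row["coef"]),
            "se": float(row["se(coef)"]),
        }
    return result


# ---------------------------------------------------------------------------
# Marker survival scans


def truncate_followup(
    times: np.ndarray, events: np.ndarray, horizon: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """Administratively censor follow-up at a horizon (60 months = 5 y)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    over = times > horizon
    return np.where(over, horizon, times), np.where(over, 0, events)


def marker_outcome_scan(
    profiles,
    records: pd.DataFrame,
    markers: Sequence[str],
    endpoint: str = "OS",
    strata: Sequence[str] = ("all", "stage_II", "stage_III", "chemotherapy"),
    truncate_months: Optional[float] = 60.0,
    event_type: str = "MSI",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Log-rank scan of per-marker survival differences across strata.

    A marker is a locus id (patients dichotomized by event vs no event of
    ``event_type`` at that locus) or one of the panel classes
    ``b5_msi_class`` / ``b5_loh_class`` (dichotomized H vs L+negative).
    Strata with fewer than two patients per arm are skipped with a flag.
    Raw p-values are reported; Benjamini-Hochberg adjustment is opt-in.
    """
    endpoint = endpoint.upper()
    tcol, ecol = (
        ("os_months", "os_event") if endpoint == "OS" else ("pfs_months", "pfs_event")
    )
    prof_by_id = {p.patient_id: p for p in profiles}
    rows = []
    for marker in markers:
        for stratum in strata:
            sub = _stratum_mask(records, stratum)
            times, events, arms, n_pos, n_neg = [], [], [], 0, 0
            for _, rec in records[sub].iterrows():
                prof = prof_by_id.get(rec["patient_id"])
                if prof is None:
                    continue
                arm = _dichotomize(prof, marker, event_type)
                t, e = rec[tcol], rec[ecol]
                if arm is None or pd.isna(t) or e is None:
                    continue
                times.append(float(t))
                events.append(int(e))
                arms.append(arm)
                n_pos += arm
                n_neg += 1 - arm
            if n_pos < 2 or n_neg < 2:
                rows.append(
                    dict(marker=marker, stratum=stratum, endpoint=endpoint,
                         n=n_pos + n_neg, n_positive=n_pos, p=np.nan,
                         statistic=np.nan, skipped="arm with <2 patients")
                )
                continue
            t_arr, e_arr = np.asarray(times), np.asarray(events)
            if truncate_months is not None:
                t_arr, e_arr = truncate_followup(t_arr, e_arr, truncate_months)
            stat, p = logrank_test(t_arr, e_arr, np.asarray(arms))
            rows.append(
                dict(marker=marker, stratum=stratum, endpoint=endpoint,
                     n=n_pos + n_neg, n_positive=n_pos, p=p, statistic=stat,
                     skipped="")
            )
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _stratum_mask(records: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=records.index)
    if stratum == "stage_II":
        return records["tnm_stage"] == "II"
    if stratum == "stage_III":
        return records["tnm_stage"] == "III"
    if stratum == "chemotherapy":
        return records["chemotherapy"] == True  # noqa: E712 — None-aware
    raise ValueError(f"unknown stratum {stratum!r}")


def _dichotomize(profile, marker: str, event_type: str) -> Optional[int]:
    if marker == "b5_msi_class":
        cls = profile.b5_msi_class
        return None if cls is None else int(cls == "MSI_H")
    if marker == "b5_loh_class":
        cls = profile.b5_loh_class
        return None if cls is None else int(cls == "LOH_H")
    call = profile.calls.get(marker)
    if call is None or call.status == "FAILED":
        return None
    return int(call.status == event_type)


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = ok.sum()
    if m == 0:
        return adj
    order = np.argsort(p[ok])
    ranked = p[ok][order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(ranked, 1.0)
    adj[ok] = vals
    return adj
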