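"""Cohort-level evaluation of MRGlu results.

Covers the population side of the workflow: descriptive summaries per
group/condition, single-patient and group pre/post treatment deltas,
baseline-adjusted group comparison (ANCOVA: post ~ pre + group, group effect
tested by a partial F-test), and multiple linear regression of MRGlu on the
13 cardiovascular risk factors, reported through the multiple correlation
coefficient R = sqrt(R^2).

Conventions chosen where the field offers several: quartiles by linear
interpolation of order statistics, skewness as the adjusted Fisher-Pearson
standardized third moment, sample SDs with n-1 denominators.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    EmptyInput,
    GroupEmpty,
    PairingError,
    SchemaError,
    SingularDesign,
)

__all__ = [
    "RISK_FACTORS",
    "GROUPS",
    "PatientRecord",
    "DescriptiveSummary",
    "AncovaResult",
    "RegressionResult",
    "describe",
    "paired_delta",
    "ancova",
    "multiple_regression",
    "records_to_dataframe",
    "dataframe_to_records",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: The 13 cardiovascular risk factors, in cohort-table column order.
RISK_FACTORS = (
    "age_years", "leanM", "bmi", "waist_cm", "sbp", "dbp", "pp",
    "fpg", "fpins", "esr", "pcr", "pwv", "ao",
)

GROUPS = ("Group1", "Group2")

_DISTRICT_COLUMNS = {
    "aorta": ("mrglu_aorta_pre", "mrglu_aorta_post"),
    "myoc": ("mrglu_myoc_pre", "mrglu_myoc_post"),
}


@dataclass
class PatientRecord:
    """One patient row: group, pre/post MRGlu per district, risk factors.

    Missing values are ``None`` (NaN in table form).
    """

    id: str
    group: str
    mrglu_aorta_pre: float | None = None
    mrglu_aorta_post: float | None = None
    mrglu_myoc_pre: float | None = None
    mrglu_myoc_post: float | None = None
    age_years: float | None = None
    leanM: float | None = None
    bmi: float | None = None
    waist_cm: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    pp: float | None = None
    fpg: float | None = None
    fpins: float | None = None
    esr: float | None = None
    pcr: float | None = None
    pwv: float | None = None
    ao: float | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise SchemaError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class DescriptiveSummary:
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float
    skewness: float | None  # None (absent) when n < 3

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "min", "q1", "median", "q3", "max", "mean", "skewness")}


@dataclass
class GroupDelta:
    group: str
    n: int
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    delta_mean: float
    delta_sd: float
    paired_t_p: float | None


@dataclass
class AncovaResult:
    district: str
    group_f: float
    group_p: float
    baseline_slope: float
    group_effect: float          # Group2 minus Group1, baseline-adjusted
    group_effect_se: float
    per_group: dict[str, GroupDelta] = field(default_factory=dict)


@dataclass
class RegressionResult:
    response: str
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    coef_p_values: dict[str, float]
    f_statistic: float
    p_value: float
    multiple_r: float
    r_squared: float
    n: int
    condition_number: float


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_COLUMNS = [f.name for f in dc_fields(PatientRecord)]


def records_to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    df = pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records])
    return df


def dataframe_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in ("id", "group") if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing required column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {"id": str(row["id"]), "group": str(row["group"])}
        for c in _COLUMNS[2:]:
            if c in df.columns:
                v = row[c]
                try:
                    kwargs[c] = None if pd.isna(v) else float(v)
                except (TypeError, ValueError):
                    raise SchemaError(f"non-numeric value {v!r} in column '{c}'")
        records.append(PatientRecord(**kwargs))
    return records


def read_cohort_csv(path) -> list[PatientRecord]:
    return dataframe_to_records(pd.read_csv(path))


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def describe(values: Sequence[float]) -> DescriptiveSummary:
    """Descriptive summary: order statistics, mean, adjusted Fisher-Pearson
    skewness (absent for n < 3)."""
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], dtype=float)
    if v.size == 0:
        raise EmptyInput("describe() needs at least one finite value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    if v.size >= 3 and np.std(v) > 0:
        skew = float(stats.skew(v, bias=False))
    elif v.size >= 3:
        skew = 0.0
    else:
        skew = None
    return DescriptiveSummary(
        n=int(v.size),
        min=float(v.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(v.max()),
        mean=float(v.mean()),
        skewness=skew,
    )


def paired_delta(
    pre: Sequence[float], post: Sequence[float]
) -> tuple[float, float, np.ndarray]:
    """Per-patient post-minus-pre deltas with their mean and sample SD."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise PairingError(f"pre ({pre.size}) and post ({post.size}) differ in length")
    if pre.size == 0:
        raise EmptyInput("paired_delta() needs at least one pair")
    deltas = post - pre
    sd = float(np.std(deltas, ddof=1)) if deltas.size > 1 else math.nan
    return float(deltas.mean()), sd, deltas


def _district_frame(records, district, filter_negatives):
    if district not in _DISTRICT_COLUMNS:
        raise SchemaError(f"district must be one of {tuple(_DISTRICT_COLUMNS)}")
    pre_col, post_col = _DISTRICT_COLUMNS[district]
    df = records_to_dataframe(records)[["id", "group", pre_col, post_col]].dropna()
    if filter_negatives:
        df = df[(df[pre_col] >= 0) & (df[post_col] >= 0)]
    return df.rename(columns={pre_col: "pre", post_col: "post"})


def ancova(
    records: Sequence[PatientRecord],
    district: str = "aorta",
    filter_negatives: bool = False,
) -> AncovaResult:
    """Baseline-adjusted treatment comparison for one district.

    Fits ``post = b0 + b1*pre + b2*I(Group2)`` by OLS; the group effect is
    tested with the partial F-test of the group term.  Per-group pre, post
    and delta summaries (and within-group paired t-tests, the other common
    reading of pre/post p-values) are attached.
    """
    df = _district_frame(records, district, filter_negatives)
    per_group: dict[str, GroupDelta] = {}
    for g in GROUPS:
        sub = df[df["group"] == g]
        if len(sub) < 2:
            raise GroupEmpty(
                f"group {g} has {len(sub)} usable record(s) for district "
                f"'{district}' (needs >= 2)"
            )
        dmean, dsd, deltas = paired_delta(sub["pre"].to_numpy(), sub["post"].to_numpy())
        if np.std(deltas) > 0:
            t_p = float(stats.ttest_rel(sub["post"], sub["pre"]).pvalue)
        else:
            t_p = None if np.allclose(deltas, 0) else 0.0
        per_group[g] = GroupDelta(
            group=g,
            n=len(sub),
            pre_mean=float(sub["pre"].mean()),
            pre_sd=float(sub["pre"].std(ddof=1)),
            post_mean=float(sub["post"].mean()),
            post_sd=float(sub["post"].std(ddof=1)),
            delta_mean=dmean,
            delta_sd=dsd,
            paired_t_p=t_p,
        )

    group_ind = (df["group"] == GROUPS[1]).astype(float).to_numpy()
    x_full = np.column_stack([np.ones(len(df)), df["pre"].to_numpy(), group_ind])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise SingularDesign("ANCOVA design matrix is rank-deficient")
    y = df["post"].to_numpy()
    full = sm.OLS(y, x_full).fit()
    restricted = sm.OLS(y, x_full[:, :2]).fit()
    df_num = 1.0
    df_den = float(full.df_resid)
    if full.ssr <= 0:
        f_stat = 0.0 if restricted.ssr <= 0 else math.inf
    else:
        f_stat = (restricted.ssr - full.ssr) / df_num / (full.ssr / df_den)
    f_stat = max(float(f_stat), 0.0)
    p = float(stats.f.sf(f_stat, df_num, df_den)) if math.isfinite(f_stat) else 0.0
    return AncovaResult(
        district=district,
        group_f=f_stat,
        group_p=p,
        baseline_slope=float(full.params[1]),
        group_effect=float(full.params[2]),
        group_effect_se=float(full.bse[2]),
        per_group=per_group,
    )


def multiple_regression(
    records: Sequence[PatientRecord],
    response: str = "mrglu_aorta",
    predictors: Sequence[str] = RISK_FACTORS,
    condition: str = "pre",
) -> RegressionResult:
    """OLS of an MRGlu response on the risk factors, with intercept.

    ``response`` is ``mrglu_aorta`` or ``mrglu_myoc`` (the ``condition``
    column, default pre-treatment).  Reports the overall F-statistic, its
    p-value, and the multiple correlation coefficient R = sqrt(R^2).
    """
    col = f"{response}_{condition}"
    df = records_to_dataframe(records)
    if col not in df.columns:
        raise SchemaError(f"unknown response column '{col}'")
    cols = [col, *predictors]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s): {missing}")
    df = df[cols].dropna()
    n, p = len(df), len(predictors)
    if n <= p + 1:
        raise SingularDesign(
            f"n={n} records cannot identify {p} predictors plus intercept"
        )
    x = np.column_stack([np.ones(n), df[list(predictors)].to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = []
        for j, name in enumerate(predictors, start=1):
            reduced = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(name)
        raise SingularDesign(f"rank-deficient design; involved columns: {bad}")
    y = df[col].to_numpy(dtype=float)
    fit = sm.OLS(y, x).fit()
    names = ["intercept", *predictors]
    r2 = float(np.clip(fit.rsquared, 0.0, 1.0))
    return RegressionResult(
        response=col,
        coefficients=dict(zip(names, map(float, fit.params))),
        std_errors=dict(zip(names, map(float, fit.bse))),
        coef_p_values=dict(zip(names, map(float, fit.pvalues))),
        f_statistic=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        multiple_r=math.sqrt(r2),
        r_squared=r2,
        n=n,
        condition_number=float(np.linalg.cond(x)),
    )
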