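"""Group comparison of demographic and clinical variables.

Reproduces the usual cohort-description table: per-group mean +- SD with an
equal-variance two-sample t-test for continuous variables and a chi-square
test for the sex distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparisonRow", "summarize", "build_table1", "TABLE1_VARIABLES"]

#: variables of the standard cohort table, in report order
TABLE1_VARIABLES = (
    "age",
    "sex",
    "education_years",
    "cias",
    "sas",
    "sds",
    "bis_total",
)

_LABELS = {
    "age": "Age (years)",
    "sex": "Gender (M/F)",
    "education_years": "Education (years)",
    "cias": "Chen Internet Addiction Scale (CIAS)",
    "sas": "Self-Rating Anxiety Scale (SAS)",
    "sds": "Self-rating depression scale (SDS)",
    "bis_total": "Barratt Impulsiveness Scale-11 (BIS-11)",
}


@dataclass
class GroupComparisonRow:
    """One row of the cohort table.

    For continuous variables ``mean_a/sd_a`` and ``mean_b/sd_b`` are the
    group moments (sample SD, n-1 denominator); for sex they hold the male
    and female counts.  ``p`` is two-tailed; NaN when the test is undefined
    (e.g. zero pooled variance).
    """

    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    test: str
    statistic: float
    p: float
    n_excluded: int = 0


def _split_groups(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    groups = table["group"].unique()
    patient_label = "IGA" if "IGA" in groups else groups[0]
    a = table[table["group"] == patient_label]
    b = table[table["group"] != patient_label]
    if a.empty or b.empty:
        raise ValueError("both groups must be nonempty")
    return a, b


def summarize(
    table: pd.DataFrame, variable: str, welch: bool = False, yates: bool = False
) -> GroupComparisonRow:
    """Compare one variable between the two groups.

    Continuous variables get a pooled-variance two-sample t-test (Welch
    behind a flag); ``sex`` gets a Pearson chi-square on the 2x2 table
    (Yates continuity correction behind a flag).  Missing values are
    excluded row-wise and counted.
    """
    if variable not in table.columns:
        raise KeyError(variable)
    a, b = _split_groups(table)

    if variable == "sex":
        counts = np.array(
            [
                [(a["sex"] == "M").sum(), (a["sex"] == "F").sum()],
                [(b["sex"] == "M").sum(), (b["sex"] == "F").sum()],
            ]
        )
        if counts.min() == 0 and (counts.sum(axis=0) == 0).any():
            chi2, p = np.nan, np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(counts, correction=yates)
        return GroupComparisonRow(
            variable=variable,
            mean_a=float(counts[0, 0]), sd_a=float(counts[0, 1]),
            mean_b=float(counts[1, 0]), sd_b=float(counts[1, 1]),
            test="chi-square", statistic=float(chi2), p=float(p),
        )

    xa = pd.to_numeric(a[variable], errors="coerce")
    xb = pd.to_numeric(b[variable], errors="coerce")
    n_excluded = int(xa.isna().sum() + xb.isna().sum())
    xa, xb = xa.dropna().to_numpy(float), xb.dropna().to_numpy(float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError(f"{variable}: need >= 2 observations per group")
    mean_a, sd_a = xa.mean(), xa.std(ddof=1)
    mean_b, sd_b = xb.mean(), xb.std(ddof=1)
    if sd_a == 0 and sd_b == 0:
        t, p = np.nan, np.nan  # degenerate variance: test undefined
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
    return GroupComparisonRow(
        variable=variable,
        mean_a=float(mean_a), sd_a=float(sd_a),
        mean_b=float(mean_b), sd_b=float(sd_b),
        test="welch-t" if welch else "two-sample t",
        statistic=float(t), p=float(p), n_excluded=n_excluded,
    )


def build_table1(table: pd.DataFrame, welch: bool = False) -> list[GroupComparisonRow]:
    """All rows of the cohort-description table, in report order."""
    return [summarize(table, v, welch=welch) for v in TABLE1_VARIABLES]


def table1_dataframe(rows: list[GroupComparisonRow]) -> pd.DataFrame:
    """Human-readable rendering of the cohort table."""
    out = []
    for r in rows:
        if r.variable == "sex":
            out.append(
                {
                    "variable": _LABELS.get(r.variable, r.variable),
                    "patients": f"{int(r.mean_a)}/{int(r.sd_a)}",
                    "controls": f"{int(r.mean_b)}/{int(r.sd_b)}",
                    "test": r.test,
                    "p": round(r.p, 4) if np.isfinite(r.p) else r.p,
                }
            )
        else:
            out.append(
                {
                    "variable": _LABELS.get(r.variable, r.variable),
                    "patients": f"{r.mean_a:.2f} ± {r.sd_a:.2f}",
                    "controls": f"{r.mean_b:.2f} ± {r.sd_b:.2f}",
                    "test": r.test,
                    "p": round(r.p, 4) if np.isfinite(r.p) else r.p,
                }
            )
    return pd.DataFrame(out)
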