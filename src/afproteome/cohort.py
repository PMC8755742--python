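"""Cohort demographics: Welch's t, Fisher's exact test, median/IQR summaries.

Continuous clinical variables are compared between gestational-age groups
with Welch's unequal-variance t-test and summarized as median
(interquartile range); categorical variables are compared with the
two-sided Fisher's exact test (point-probability rule) and summarized as
count/denominator (percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GROUP_MIDTRIMESTER, GROUP_TERM, SampleMetadata, ValidationError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValidationError("contingency counts must be nonnegative integers")
        if sum(counts) == 0:
            raise ValidationError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value, point-probability rule.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table.
    """
    if not isinstance(table, ContingencyTable2x2):
        arr = np.asarray(table)
        table = ContingencyTable2x2(*arr.ravel().tolist())
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("Welch's t-test needs n >= 2 in each group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValidationError("both groups have zero variance")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


#: Default Table-1-style variable spec: (column, kind) with kind in
#: {"continuous", "binary"}; binary variables give (positive_value, label).
DEFAULT_VARIABLES = (
    ("maternal_age_years", "continuous", None),
    ("bmi_kg_m2", "continuous", None),
    ("gestational_age_weeks", "continuous", None),
    ("fetal_sex", "binary", "F"),
)


def summarize_cohort(
    metadata: SampleMetadata,
    variables=DEFAULT_VARIABLES,
    groups=(GROUP_TERM, GROUP_MIDTRIMESTER),
) -> pd.DataFrame:
    """Per-variable group summaries and tests, one row per variable.

    Continuous rows report median (IQR) per group and the Welch p-value;
    binary rows report count/denominator (percent) and the Fisher p-value.
    Missing values are excluded per variable and counted in ``n_missing``.
    """
    df = metadata.table
    rows = []
    for spec in variables:
        name, kind, positive = spec
        if name not in df.columns:
            raise ValidationError(f"unknown metadata variable {name!r}")
        values = df[name]
        rec: dict[str, object] = {
            "variable": name,
            "kind": kind,
            "n_missing": int(values.isna().sum()),
        }
        per_group = {g: values[df["group"] == g].dropna() for g in groups}
        if kind == "continuous":
            for g, v in per_group.items():
                v = v.astype(float)
                q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
                rec[f"{g}_summary"] = f"{med:g} ({q1:g}–{q3:g})"
            try:
                _, _, p = welch_t_test(*[per_group[g].astype(float) for g in groups])
            except ValidationError:
                p = np.nan
            rec["test"] = "welch_t"
        elif kind == "binary":
            counts = []
            for g, v in per_group.items():
                k, n = int((v == positive).sum()), int(len(v))
                pct = 100.0 * k / n if n else np.nan
                rec[f"{g}_summary"] = f"{k}/{n} ({pct:.1f}%)"
                counts.append((k, n - k))
            p = fisher_exact_2x2(
                ContingencyTable2x2(
                    counts[0][0], counts[0][1], counts[1][0], counts[1][1]
                )
            )
            rec["test"] = "fisher_exact"
        else:
            raise ValidationError(f"unknown variable kind {kind!r}")
        rec["p_value"] = float(p) if p == p else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("variable")
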