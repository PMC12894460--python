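"""Demographic and clinical cohort comparisons.

Covers the descriptive table machinery for a two-cohort cross-sectional
study: per-cohort category counts with half-up rounded percentages, the
pooled two-proportion z-test for category frequencies, and the Welch
t-test computed from summary statistics (mean, SD, n) when raw ages are
not available.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

METASTASIS_TIMES = ("at_diagnosis", "at_relapse", "not_reported")


@dataclass(frozen=True)
class PatientRecord:
    sample_id: str
    cohort: str  # AAM | CM
    age: float | None = None
    metastasis_site: str = "not_reported"
    metastasis_time: str = "not_reported"

    def __post_init__(self) -> None:
        if self.cohort not in ("AAM", "CM"):
            raise ValidationError(f"unknown cohort {self.cohort!r} for {self.sample_id}")
        if self.age is not None and self.age <= 0:
            raise ValidationError(f"non-positive age for {self.sample_id}")


def records_from_metadata(metadata: pd.DataFrame) -> list[PatientRecord]:
    """Build PatientRecords from the metadata TSV frame.

    Missing metastasis_time / metastasis_site values default to
    "not_reported"; age may be absent (NaN -> None).
    """
    records = []
    for row in metadata.itertuples(index=False):
        age = getattr(row, "age", None)
        if age is not None and (age != age):  # NaN
            age = None
        records.append(
            PatientRecord(
                sample_id=str(row.sample_id),
                cohort=str(row.race),
                age=float(age) if age is not None else None,
                metastasis_site=_field_or_default(row, "metastasis_site"),
                metastasis_time=_field_or_default(row, "metastasis_time"),
            )
        )
    return records


def _field_or_default(row, name: str) -> str:
    val = getattr(row, name, None)
    if val is None or (isinstance(val, float) and val != val) or str(val) == "":
        return "not_reported"
    return str(val)


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with the pooled
    phat = (k1 + k2) / (n1 + n2). When phat is degenerate (0 or 1) the two
    sample proportions are necessarily equal and (z, p) = (0, 1).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValidationError(f"invalid counts k={k}, n={n}")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def welch_ttest_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics: (t, df, two-sided p).

    Welch (unequal variance) with Satterthwaite degrees of freedom by
    default; ``equal_var=True`` gives the pooled-variance test.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("insufficient data: each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("negative standard deviation")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        if v1 + v2 == 0:
            df = float(n1 + n2 - 2)
        else:
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as printed tables use."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def categorical_summary(records: list[PatientRecord], fld: str) -> pd.DataFrame:
    """Per-cohort counts and percentages for one categorical patient field.

    Percentages use the full cohort size as denominator (not-reported
    included) and half-up rounding to one decimal. Categories are ordered
    by descending total count, then name; every category observed in either
    cohort appears in both cohorts' rows (count 0 where absent).
    """
    if fld not in ("metastasis_site", "metastasis_time"):
        raise ValidationError(f"unsupported field {fld!r}")
    values = pd.DataFrame(
        {"cohort": [r.cohort for r in records], "value": [getattr(r, fld) for r in records]}
    )
    sizes = values["cohort"].value_counts().to_dict()
    counts = values.groupby(["value", "cohort"]).size()
    totals = values.groupby("value").size()
    categories = sorted(totals.index, key=lambda v: (-int(totals[v]), v))
    rows = []
    for cat in categories:
        for cohort in ("AAM", "CM"):
            n = sizes.get(cohort, 0)
            k = int(counts.get((cat, cohort), 0))
            pct = round_half_up(100.0 * k / n) if n else 0.0
            rows.append({"field": fld, "category": cat, "cohort": cohort, "count": k,
                         "cohort_size": n, "percent": pct})
    return pd.DataFrame(rows)


def compare_category_frequency(
    records: list[PatientRecord], fld: str, category: str
) -> dict[str, float]:
    """Pooled z-test of one category's frequency between the two cohorts."""
    k = {"AAM": 0, "CM": 0}
    n = {"AAM": 0, "CM": 0}
    for r in records:
        n[r.cohort] += 1
        if getattr(r, fld) == category:
            k[r.cohort] += 1
    z, p = two_proportion_ztest(k["AAM"], n["AAM"], k["CM"], n["CM"])
    return {"test": "two_proportion_z", "statistic": z, "p": p,
            "k_aam": k["AAM"], "n_aam": n["AAM"], "k_cm": k["CM"], "n_cm": n["CM"]}


def compare_ages(records: list[PatientRecord], equal_var: bool = False) -> dict[str, float]:
    """Welch (default) t-test on ages between cohorts, from the raw values."""
    ages = {"AAM": [], "CM": []}
    for r in records:
        if r.age is not None:
            ages[r.cohort].append(r.age)
    a, c = np.asarray(ages["AAM"]), np.asarray(ages["CM"])
    if len(a) < 2 or len(c) < 2:
        raise ValidationError("insufficient age data")
    t, df, p = welch_ttest_from_summary(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(c.mean()), float(c.std(ddof=1)), len(c),
        equal_var=equal_var,
    )
    return {"test": "welch_t" if not equal_var else "pooled_t",
            "statistic": t, "df": df, "p": p,
            "mean_aam": float(a.mean()), "sd_aam": float(a.std(ddof=1)), "n_aam": len(a),
            "mean_cm": float(c.mean()), "sd_cm": float(c.std(ddof=1)), "n_cm": len(c)}
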