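"""Descriptive summaries of a target-event case series.

Percentages are computed on the total case count (unknowns included) and
rounded to one decimal with half-up rounding, the convention used in
published FAERS case-series tables.  Age statistics use known ages only;
the median/IQR quantile rule is linear interpolation.  A case may carry
several outcome codes and contributes to each, so outcome percentages need
not sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .pipeline import CaseSet

OUTCOME_LABELS = {
    "DE": "Death", "LT": "Life-Threatening", "HO": "Hospitalization",
    "DS": "Disability", "CA": "Congenital Anomaly",
    "RI": "Required Intervention", "OT": "Other Serious",
}
REPORTER_LABELS = {
    "MD": "Physician", "PH": "Pharmacist", "OT": "Other health-professional",
    "CN": "Consumer", "LW": "Lawyer",
}


def percent(count: int, total: int, decimals: int = 1) -> float:
    """count/total as a percentage, half-up rounded to ``decimals``."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, ROUND_HALF_UP))


@dataclass
class DescriptiveSummary:
    total: int
    sex: dict[str, tuple[int, float]]            # label -> (count, pct)
    age_mean: float | None
    age_sd: float | None
    age_median: float | None
    age_iqr: tuple[float, float] | None
    age_unknown: int
    outcomes: dict[str, tuple[int, float]]
    reporters: dict[str, tuple[int, float]]
    top_countries: list[tuple[str, int, float]]
    annual: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        """Flat two-column table mirroring a published characteristics table."""
        rows = [("Number of total cases", f"{self.total:,}")]
        for label, (n, p) in self.sex.items():
            rows.append((f"Gender: {label}", f"{n} ({p}%)"))
        if self.age_mean is not None:
            rows.append(("Age mean ± SD", f"{self.age_mean:.1f} ± {self.age_sd:.1f}"))
            lo, hi = self.age_iqr
            rows.append(("Age median (IQR)", f"{self.age_median:.1f} ({lo:.1f}-{hi:.1f})"))
        rows.append(("Age unknown", f"{self.age_unknown} ({percent(self.age_unknown, self.total)}%)"))
        for label, (n, p) in self.outcomes.items():
            rows.append((f"Outcome: {label}", f"{n} ({p}%)"))
        for label, (n, p) in self.reporters.items():
            rows.append((f"Reporter: {label}", f"{n} ({p}%)"))
        for country, n, p in self.top_countries:
            rows.append((f"Country: {country}", f"{n} ({p}%)"))
        return pd.DataFrame(rows, columns=["characteristic", "value"])

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "sex": {k: {"count": n, "pct": p} for k, (n, p) in self.sex.items()},
            "age": {"mean": self.age_mean, "sd": self.age_sd,
                    "median": self.age_median,
                    "iqr": list(self.age_iqr) if self.age_iqr else None,
                    "unknown": self.age_unknown},
            "outcomes": {k: {"count": n, "pct": p} for k, (n, p) in self.outcomes.items()},
            "reporters": {k: {"count": n, "pct": p} for k, (n, p) in self.reporters.items()},
            "top_countries": [{"country": c, "count": n, "pct": p}
                              for c, n, p in self.top_countries],
            "annual": {str(y): n for y, n in sorted(self.annual.items())},
        }


def summarize(caseset: CaseSet, k_countries: int = 5) -> DescriptiveSummary:
    """Tally demographics, outcomes, reporters, countries and annual trend."""
    df = caseset.cases
    total = len(df)

    sex_counts = {"Female": 0, "Male": 0, "Unknown": 0}
    for s in df["sex"]:
        if s == "F":
            sex_counts["Female"] += 1
        elif s == "M":
            sex_counts["Male"] += 1
        else:
            sex_counts["Unknown"] += 1
    sex = {k: (n, percent(n, total)) for k, n in sex_counts.items()}

    ages = df["age_years"].dropna().astype(float)
    if len(ages):
        age_mean = float(ages.mean())
        age_sd = float(ages.std(ddof=1)) if len(ages) > 1 else 0.0
        age_median = float(np.quantile(ages, 0.5))
        age_iqr = (float(np.quantile(ages, 0.25)), float(np.quantile(ages, 0.75)))
    else:
        age_mean = age_sd = age_median = None
        age_iqr = None
    age_unknown = int(df["age_years"].isna().sum())

    out_counts = {label: 0 for label in OUTCOME_LABELS.values()}
    unknown_outcome = 0
    for pid in df["primaryid"]:
        codes = set(caseset.outcomes.get(int(pid), []))
        if not codes:
            unknown_outcome += 1
            continue
        for code in codes:
            if code in OUTCOME_LABELS:
                out_counts[OUTCOME_LABELS[code]] += 1
    out_counts["Unknown"] = unknown_outcome
    outcomes = {k: (n, percent(n, total)) for k, n in out_counts.items()}

    rep_counts = {label: 0 for label in REPORTER_LABELS.values()}
    rep_counts["Unknown"] = 0
    for occ in df["occp_cod"]:
        label = REPORTER_LABELS.get(occ if isinstance(occ, str) else "", "Unknown")
        rep_counts[label] += 1
    reporters = {k: (n, percent(n, total)) for k, n in rep_counts.items()}

    cc = df["country"].dropna().value_counts()
    top = [(str(c), int(n), percent(int(n), total))
           for c, n in cc.head(k_countries).items()]

    return DescriptiveSummary(
        total=total, sex=sex, age_mean=age_mean, age_sd=age_sd,
        age_median=age_median, age_iqr=age_iqr, age_unknown=age_unknown,
        outcomes=outcomes, reporters=reporters, top_countries=top,
        annual=annual_counts(caseset),
    )


def annual_counts(caseset: CaseSet) -> dict[int, int]:
    """Cases per report year (receipt-date year; missing years excluded)."""
    years = caseset.cases["year"].dropna().astype(int)
    return {int(y): int(n) for y, n in years.value_counts().sort_index().items()}


def top_drugs(caseset: CaseSet, k: int) -> list[tuple[str, int]]:
    """Top-k PS drugs by case count; ties broken alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for drugs in caseset.ps_drugs.values():
        for name in drugs:
            counts[name] = counts.get(name, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
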