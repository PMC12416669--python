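"""Disproportionality statistics for spontaneous-report 2x2 tables.

For one drug D and one adverse event E over a universe of N deduplicated
reports the contingency table is::

                      event E      other events
    drug D (PS)          a              b
    other drugs          c              d

Two complementary statistics are computed:

* the frequentist reporting odds ratio, ROR = (a*d)/(b*c), with the Wald
  95% interval exp(ln ROR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d));
* the Bayesian information component of the BCPNN,
  IC = log2 P(D,E) / (P(D) P(E)), shrunk toward 0 by conjugate priors.
  The default is the classical moment approximation of the posterior mean
  and variance with priors gamma11 = 1, alpha1 = beta1 = 1,
  alpha = beta = 2, and IC025 = E[IC] - 2*SD[IC]; a seeded Monte-Carlo
  posterior-quantile method (literal 2.5th percentile under independent
  conjugate Beta posteriors) is available for comparison.

A drug is flagged as a signal only when both criteria hold: at least three
cases (a >= 3), ROR lower 95% bound > 1, and IC025 > 0.  Shrinkage makes
the IC criterion conservative for small a, which is the point of pairing it
with the more sensitive ROR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

Z95 = 1.959963984540054  # two-sided 95% normal quantile
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Exact 2x2 cell counts for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def with_haldane(self) -> "HaldaneTable":
        return HaldaneTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class HaldaneTable:
    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    n_cases: int
    defined: bool

    def __post_init__(self) -> None:
        if self.defined:
            # geometric-mean identity of the log-symmetric Wald interval
            gm = math.sqrt(self.ci_low * self.ci_high)
            assert abs(gm - self.ror) <= 1e-6 * self.ror, \
                f"geometric-mean identity violated: {gm} vs {self.ror}"


@dataclass(frozen=True)
class BcpnnPriors:
    """Prior constants of the BCPNN moment approximation.

    gamma is data-dependent, chosen so that the prior expectation of IC is 0
    under independence: gamma = gamma11*(N+alpha)(N+beta) /
    ((a+b+alpha1)(a+c+beta1)).
    """

    gamma11: float = 1.0
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        for v in (self.gamma11, self.alpha1, self.beta1, self.alpha, self.beta):
            if v <= 0:
                raise ValueError("BCPNN prior constants must be positive")

    def gamma(self, a: int, b: int, c: int, n: int) -> float:
        return (self.gamma11 * (n + self.alpha) * (n + self.beta)
                / ((a + b + self.alpha1) * (a + c + self.beta1)))


@dataclass(frozen=True)
class IcResult:
    ic_mle: float          # nan when a == 0
    e_ic: float
    ic025: float
    method: str            # "moment" | "posterior-quantile"


@dataclass(frozen=True)
class ScreenCriteria:
    """The dual signal criterion (conjunction)."""

    min_cases: int = 3
    ror_low_gt: float = 1.0
    ic025_gt: float = 0.0


@dataclass(frozen=True)
class SignalRecord:
    drug: str
    table: ContingencyTable
    ror: RorResult
    ic: IcResult
    is_signal: bool
    atc_group: str = "Unclassified"
    atc_code: str | None = None
    label_warning: bool | None = None  # None = unknown annotation


def build_contingency(case_ids: set[int], exposures: dict[int, list[str]],
                      drug: str) -> ContingencyTable:
    """Exact 2x2 cells for one drug over the deduplicated universe.

    ``exposures`` must cover ALL deduplicated reports (empty list where the
    report has no PS drug); its domain defines N.  ``case_ids`` are the
    target-event reports, a subset of that domain.
    """
    n = len(exposures)
    n_cases = len(case_ids)
    a = 0
    exposed = 0
    for pid, drugs in exposures.items():
        if drug in drugs:
            exposed += 1
            if pid in case_ids:
                a += 1
    b = exposed - a
    c = n_cases - a
    d = n - a - b - c
    return ContingencyTable(a, b, c, d)


def ror(table: ContingencyTable, haldane: bool = False) -> RorResult:
    """Reporting odds ratio with log-scale Wald 95% CI.

    With a zero cell the ROR is undefined (``defined=False``, nan outputs)
    unless ``haldane`` adds 0.5 to every cell.
    """
    t = table.with_haldane() if haldane else table
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) <= 0:
        return RorResult(math.nan, math.nan, math.nan, int(table.a), defined=False)
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(point)
    return RorResult(
        ror=point,
        ci_low=math.exp(log_ror - Z95 * se),
        ci_high=math.exp(log_ror + Z95 * se),
        n_cases=int(table.a),
        defined=True,
    )


def bcpnn_ic(table: ContingencyTable, priors: BcpnnPriors | None = None,
             method: str = "moment", rng: np.random.Generator | None = None,
             n_draws: int = 100_000) -> IcResult:
    """Information component with Bayesian shrinkage.

    moment: closed-form posterior mean/variance expansion; IC025 is
    E[IC] - 2*SD[IC] (the conventional label, coverage ~97.7% one-sided).
    posterior-quantile: the literal 2.5th percentile of IC under independent
    conjugate Beta posteriors for P(D,E), P(D), P(E) (seeded Monte Carlo).
    """
    priors = priors or BcpnnPriors()
    a, b, c, n = table.a, table.b, table.c, table.n
    if a > 0 and (a + b) > 0 and (a + c) > 0 and n > 0:
        ic_mle = math.log2(a * n / ((a + b) * (a + c)))
    else:
        ic_mle = math.nan

    g = priors.gamma(a, b, c, n)
    e_ic = math.log2(
        (a + priors.gamma11) * (n + priors.alpha) * (n + priors.beta)
        / ((n + g) * (a + b + priors.alpha1) * (a + c + priors.beta1)))

    if method == "moment":
        var = (1 / _LN2) ** 2 * (
            (n - a + g - priors.gamma11) / ((a + priors.gamma11) * (1 + n + g))
            + (n - a - b + priors.alpha - priors.alpha1)
            / ((a + b + priors.alpha1) * (1 + n + priors.alpha))
            + (n - a - c + priors.beta - priors.beta1)
            / ((a + c + priors.beta1) * (1 + n + priors.beta)))
        ic025 = e_ic - 2.0 * math.sqrt(var)
    elif method == "posterior-quantile":
        rng = rng or np.random.default_rng(0)
        p11 = rng.beta(a + priors.gamma11, n - a + g - priors.gamma11, size=n_draws)
        p1 = rng.beta(a + b + priors.alpha1, n - a - b + priors.alpha - priors.alpha1,
                      size=n_draws)
        p2 = rng.beta(a + c + priors.beta1, n - a - c + priors.beta - priors.beta1,
                      size=n_draws)
        ic_draws = np.log2(p11 / (p1 * p2))
        ic025 = float(np.quantile(ic_draws, 0.025))
    else:
        raise ValueError(f"unknown BCPNN method: {method!r}")
    return IcResult(ic_mle=ic_mle, e_ic=e_ic, ic025=ic025, method=method)


def screen(case_ids: set[int], exposures: dict[int, list[str]],
           drugs: list[str] | None = None,
           criteria: ScreenCriteria | None = None,
           priors: BcpnnPriors | None = None,
           ic_method: str = "moment",
           rng: np.random.Generator | None = None,
           atcmap=None,
           label_warnings: dict[str, bool] | None = None,
           haldane: bool = False) -> list[SignalRecord]:
    """Screen every drug (or a given list) against the dual criterion.

    Emits one SignalRecord per drug with a >= 1, sorted by descending ROR
    (signals therefore lead, in descending-ROR order); undefined RORs sort
    last.
    """
    criteria = criteria or ScreenCriteria()
    if drugs is None:
        seen: dict[str, None] = {}
        for pid in case_ids:
            for name in exposures.get(pid, []):
                seen.setdefault(name)
        drugs = list(seen)
    records = []
    for drug in drugs:
        table = build_contingency(case_ids, exposures, drug)
        if table.a < 1:
            continue
        r = ror(table, haldane=haldane)
        ic = bcpnn_ic(table, priors, method=ic_method, rng=rng)
        is_signal = (table.a >= criteria.min_cases
                     and r.defined and r.ci_low > criteria.ror_low_gt
                     and ic.ic025 > criteria.ic025_gt)
        group, code = ("Unclassified", None)
        if atcmap is not None:
            group, code = atcmap.lookup(drug)
        warn = None
        if label_warnings is not None:
            warn = label_warnings.get(drug)
        records.append(SignalRecord(drug=drug, table=table, ror=r, ic=ic,
                                    is_signal=is_signal, atc_group=group,
                                    atc_code=code, label_warning=warn))
    records.sort(key=lambda s: (not s.is_signal,
                                -(s.ror.ror if s.ror.defined else -math.inf),
                                s.drug))
    return records


def signals_frame(records: list[SignalRecord]):
    """Flat delimited-export view of a screen's output."""
    import pandas as pd

    rows = []
    for s in records:
        rows.append({
            "drug": s.drug, "a": s.table.a, "b": s.table.b,
            "c": s.table.c, "d": s.table.d,
            "ror": s.ror.ror, "ror_low": s.ror.ci_low, "ror_high": s.ror.ci_high,
            "ic025": s.ic.ic025, "is_signal": s.is_signal,
            "atc_group": s.atc_group,
            "label_warning": "" if s.label_warning is None else s.label_warning,
        })
    return pd.DataFrame(rows, columns=["drug", "a", "b", "c", "d", "ror",
                                       "ror_low", "ror_high", "ic025",
                                       "is_signal", "atc_group", "label_warning"])
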