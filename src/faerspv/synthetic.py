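"""Synthetic FAERS-format data with known ground truth.

The generator emits spontaneous-report quarters in the same table layout
:mod:`faerspv.faers_io` reads, with a fully specified generative model so
every downstream stage — parsing, deduplication, case selection,
disproportionality — can be tested against analytic truth:

* each case draws exactly one Primary Suspect (PS) drug from a vocabulary
  with stated marginal probabilities (the unassigned remainder is an
  implicit background drug);
* each event in the event vocabulary is included independently with its
  background probability, multiplied by the planted rate ratio ``lam`` when
  the case's PS drug carries a planted association with that event (capped
  at 1);
* a configurable fraction of cases emit a second report version sharing the
  caseid with a later FDA receipt date and a higher primaryid, so that
  deduplication has observable work;
* drug mentions are written under brand-name/spelling variants with a stated
  probability, so that name normalization has observable work;
* ages are emitted in mixed units (YR/MON/DEC) to exercise unit conversion.

``truth_table`` computes the expected reporting odds ratio for every
(drug, event) pair in closed form from the model's 2x2 cell probabilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .faers_io import QuarterBundle, _empty_table

_FILLER_PT = ("Drug ineffective", 10017955)


@dataclass(frozen=True)
class DrugSpec:
    """One vocabulary drug: canonical generic name, its marginal probability
    of being the PS drug on a report, and verbatim spelling variants."""

    name: str
    marginal: float
    variants: tuple[str, ...] = ()


@dataclass(frozen=True)
class EventSpec:
    """One MedDRA preferred term with its background reporting probability."""

    pt_name: str
    pt_code: int
    background: float


@dataclass(frozen=True)
class PlantedAssociation:
    """Multiplicative enrichment ``lam`` of an event among reports whose PS
    drug is ``drug``; lam == 1 is the null."""

    drug: str
    event: str
    lam: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("rate ratio lam must be > 0")


def _default_drugs() -> tuple[DrugSpec, ...]:
    # 30 background drugs at ~2% each; remainder mass is the implicit
    # "OTHER" comparator pool
    specs = [DrugSpec(f"drug{i:02d}", 0.02, (f"BRAND{i:02d}",)) for i in range(30)]
    return tuple(specs)


def _default_events() -> tuple[EventSpec, ...]:
    return (
        EventSpec("Vitiligo", 10047642, 0.01),
        EventSpec("Rash", 10037844, 0.05),
        EventSpec("Nausea", 10028813, 0.06),
        EventSpec("Headache", 10019211, 0.06),
        EventSpec("Pruritus", 10037087, 0.03),
    )


@dataclass
class SyntheticConfig:
    """Full generative specification for a synthetic FAERS cohort.

    Defaults emulate a plausible spontaneous-report stream: a 1% background
    rate for the target event, an 8% duplicate-version rate, 30% brand-name
    spelling variants, a female-predominant sex mix with a substantial
    unknown fraction, and ages drawn in mixed units.
    """

    n_reports: int = 10000
    quarters: tuple[str, ...] = ("24Q1",)
    drugs: tuple[DrugSpec, ...] = field(default_factory=_default_drugs)
    events: tuple[EventSpec, ...] = field(default_factory=_default_events)
    planted: tuple[PlantedAssociation, ...] = ()
    duplicate_rate: float = 0.08
    synonym_prob: float = 0.3
    mean_extra_drugs: float = 1.0
    role_distribution: dict[str, float] = field(
        default_factory=lambda: {"SS": 0.5, "C": 0.4, "I": 0.1})
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"F": 0.46, "M": 0.36, "": 0.18})
    age_missing_prob: float = 0.4
    age_mean: float = 51.0
    age_sd: float = 19.0
    age_unit_probs: dict[str, float] = field(
        default_factory=lambda: {"YR": 0.9, "MON": 0.05, "DEC": 0.05})
    occp_probs: dict[str, float] = field(
        default_factory=lambda: {"MD": 0.35, "CN": 0.30, "OT": 0.28,
                                 "PH": 0.03, "LW": 0.01, "": 0.03})
    country_probs: dict[str, float] = field(
        default_factory=lambda: {"US": 0.52, "FR": 0.07, "DE": 0.04,
                                 "GB": 0.04, "CA": 0.03, "JP": 0.03, "": 0.27})
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {"": 0.40, "OT": 0.40, "HO": 0.13,
                                 "DS": 0.03, "DE": 0.02, "LT": 0.015,
                                 "CA": 0.003, "RI": 0.002})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        total = sum(d.marginal for d in self.drugs)
        if total > 1 + 1e-9:
            raise ValueError(f"drug marginals sum to {total:.4f} > 1")
        for d in self.drugs:
            if not 0 <= d.marginal <= 1:
                raise ValueError(f"marginal out of [0,1] for {d.name}")
        for e in self.events:
            if not 0 <= e.background <= 1:
                raise ValueError(f"background out of [0,1] for {e.pt_name}")
        if not 0 <= self.duplicate_rate <= 1:
            raise ValueError("duplicate_rate out of [0,1]")
        names = {d.name for d in self.drugs}
        events = {e.pt_name for e in self.events}
        for p in self.planted:
            if p.drug not in names:
                raise ValueError(f"planted drug {p.drug!r} not in vocabulary")
            if p.event not in events:
                raise ValueError(f"planted event {p.event!r} not in vocabulary")

    # -- serialization (CLI config files) ---------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        obj = json.loads(text)
        obj["drugs"] = tuple(DrugSpec(d["name"], d["marginal"], tuple(d.get("variants", ())))
                             for d in obj.get("drugs", []))
        obj["events"] = tuple(EventSpec(e["pt_name"], e["pt_code"], e["background"])
                              for e in obj.get("events", []))
        obj["planted"] = tuple(PlantedAssociation(p["drug"], p["event"], p["lam"])
                               for p in obj.get("planted", []))
        obj["quarters"] = tuple(obj.get("quarters", ("24Q1",)))
        return cls(**obj)


def _lam(config: SyntheticConfig, drug: str, event: str) -> float:
    for p in config.planted:
        if p.drug == drug and p.event == event:
            return p.lam
    return 1.0


def effective_rate(config: SyntheticConfig, drug: str, event: str) -> float:
    """P(event on a report | PS drug), i.e. background*lam capped at 1."""
    ev = next(e for e in config.events if e.pt_name == event)
    return min(1.0, ev.background * _lam(config, drug, event))


def truth_table(config: SyntheticConfig) -> pd.DataFrame:
    """Analytic (drug, event, effective lam, expected ROR) for every pair.

    The expected ROR is the odds ratio of the implied 2x2 probability table
    where the comparator is all other reports (other vocabulary drugs plus
    the implicit background pool, all at their own effective rates).
    """
    rows = []
    m_other = 1.0 - sum(d.marginal for d in config.drugs)
    for ev in config.events:
        # event probability within each exposure stratum
        rates = {d.name: effective_rate(config, d.name, ev.pt_name) for d in config.drugs}
        for d in config.drugs:
            q = rates[d.name]
            a = d.marginal * q
            b = d.marginal * (1 - q)
            c = sum(dd.marginal * rates[dd.name] for dd in config.drugs if dd.name != d.name)
            c += m_other * ev.background
            dd_ = 1.0 - a - b - c
            raw = _lam(config, d.name, ev.pt_name)
            eff = q / ev.background if ev.background > 0 else math.nan
            ror = (a * dd_) / (b * c) if b > 0 and c > 0 else math.inf
            rows.append({"drug": d.name, "event": ev.pt_name, "lam": raw,
                         "effective_lam": eff, "expected_ror": ror})
    return pd.DataFrame(rows)


def _choice(rng: np.random.Generator, probs: dict[str, float], n: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return np.asarray(keys, dtype=object)[rng.choice(len(keys), size=n, p=p)]


def generate(config: SyntheticConfig) -> QuarterBundle:
    """Draw a full synthetic cohort; deterministic given ``config.seed``.

    Duplicate report versions share a caseid, differ in primaryid (strictly
    increasing with version) and have non-decreasing fda_dt; reactions and
    drug rows are repeated identically across versions so the final case set
    is invariant to whether deduplication runs before or after selection.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    if n == 0:
        return _assemble(config, *[[] for _ in range(5)])

    # capped-rate warning bookkeeping
    for p in config.planted:
        ev = next(e for e in config.events if e.pt_name == p.event)
        if ev.background * p.lam > 1:
            import logging
            logging.getLogger(__name__).warning(
                "planted rate %s*%s > 1 for (%s, %s); capped at 1",
                ev.background, p.lam, p.drug, p.event)

    drug_names = [d.name for d in config.drugs]
    marginals = np.asarray([d.marginal for d in config.drugs])
    m_other = 1.0 - marginals.sum()
    ps_idx = rng.choice(len(drug_names) + 1, size=n,
                        p=np.append(marginals, m_other))
    # event inclusion: rate matrix [drug (incl other), event]
    rates = np.empty((len(drug_names) + 1, len(config.events)))
    for j, ev in enumerate(config.events):
        for i, name in enumerate(drug_names):
            rates[i, j] = effective_rate(config, name, ev.pt_name)
        rates[-1, j] = ev.background
    event_hits = rng.random((n, len(config.events))) < rates[ps_idx]

    caseids = 1_000_000 + np.arange(n)
    quarters = list(config.quarters)
    q_idx = rng.integers(0, len(quarters), size=n)
    q_year = np.array([2000 + int(q.upper().split("Q")[0]) for q in quarters])
    q_month0 = np.array([(int(q.upper().split("Q")[1]) - 1) * 3 + 1 for q in quarters])
    month = q_month0[q_idx] + rng.integers(0, 3, size=n)
    day = 1 + rng.integers(0, 28, size=n)
    fda_dt = q_year[q_idx] * 10000 + month * 100 + day

    sexes = _choice(rng, config.sex_probs, n)
    occp = _choice(rng, config.occp_probs, n)
    country = _choice(rng, config.country_probs, n)
    age_known = rng.random(n) >= config.age_missing_prob
    age_years = np.clip(rng.normal(config.age_mean, config.age_sd, n), 0.5, 100.0)
    age_unit = _choice(rng, config.age_unit_probs, n)

    n_extra = rng.poisson(config.mean_extra_drugs, n)
    dup = rng.random(n) < config.duplicate_rate

    # pre-draw everything per-report so the assembly loop does no RNG work
    outc_all = _choice(rng, config.outcome_probs, n)
    other_pool = [f"conmed{i:02d}" for i in range(20)]
    total_extra = int(n_extra.sum())
    extra_pool_idx = rng.integers(0, len(other_pool), size=total_extra)
    extra_roles = _choice(rng, config.role_distribution, total_extra)
    use_variant = rng.random(n) < config.synonym_prob
    variant_pick = rng.integers(0, 1 << 30, size=n)
    dup_bump = rng.integers(0, 20, size=n)

    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows = [], [], [], [], []
    unit_factor = {"YR": 1.0, "MON": 12.0, "DEC": 0.1}
    extra_cursor = 0

    for i in range(n):
        caseid = int(caseids[i])
        versions = 2 if dup[i] else 1
        base_dt = int(fda_dt[i])

        if ps_idx[i] < len(drug_names):
            spec = config.drugs[ps_idx[i]]
            ps_name = spec.name
            if spec.variants and use_variant[i]:
                ps_verbatim = spec.variants[variant_pick[i] % len(spec.variants)]
            else:
                ps_verbatim = ps_name.upper()
        else:
            ps_name = "othermed"
            ps_verbatim = "OTHERMED"
        k = int(n_extra[i])
        extras = [(other_pool[extra_pool_idx[j]], str(extra_roles[j]))
                  for j in range(extra_cursor, extra_cursor + k)]
        extra_cursor += k
        pts = [(config.events[j].pt_name, config.events[j].pt_code)
               for j in range(len(config.events)) if event_hits[i, j]]
        if not pts:
            pts = [_FILLER_PT]
        outc = str(outc_all[i])

        if age_known[i]:
            unit = str(age_unit[i])
            age_val = round(float(age_years[i]) * unit_factor[unit], 1)
        else:
            unit, age_val = "", ""

        for v in range(versions):
            pid = caseid * 100 + v + 1
            dt = base_dt if v == 0 else _bump_date(base_dt, int(dup_bump[i]))
            demo_rows.append((pid, caseid, dt, "", age_val, unit, str(sexes[i]),
                              str(occp[i]), str(country[i]), str(country[i])))
            seq = 1
            drug_rows.append((pid, seq, "PS", ps_verbatim, ps_name))
            for name, role in extras:
                seq += 1
                drug_rows.append((pid, seq, role, name.upper(), name))
            for pt_name, pt_code in pts:
                reac_rows.append((pid, pt_name, pt_code))
            if outc:
                outc_rows.append((pid, outc))
            ther_rows.append((pid, 1, dt, ""))

    return _assemble(config, demo_rows, drug_rows, reac_rows, outc_rows, ther_rows)


def _bump_date(dt: int, bump: int) -> int:
    """A receipt date >= dt (same-month bump, capped at day 28)."""
    day = dt % 100
    return dt - day + min(28, day + bump)


def _assemble(config, demo_rows, drug_rows, reac_rows, outc_rows, ther_rows) -> QuarterBundle:
    demo = pd.DataFrame(demo_rows, columns=[
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "occp_cod", "occr_country", "reporter_country"])
    drug = pd.DataFrame(drug_rows, columns=[
        "primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"])
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "pt_name", "pt_code"])
    outc = pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"])
    ther = pd.DataFrame(ther_rows, columns=["primaryid", "dsg_drug_seq", "start_dt", "end_dt"])
    for df, cols in ((demo, ("primaryid", "caseid", "fda_dt")),
                     (drug, ("primaryid", "drug_seq")),
                     (reac, ("primaryid", "pt_code")),
                     (outc, ("primaryid",)), (ther, ("primaryid",))):
        for c in cols:
            df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
    demo["age"] = pd.to_numeric(demo["age"], errors="coerce")
    for df in (demo, drug, reac, outc, ther):
        for c in df.columns:
            if df[c].dtype == object:
                df[c] = df[c].astype("string").replace("", pd.NA)
    bundle = QuarterBundle(demo=demo, drug=drug, reac=reac, outc=outc,
                           ther=ther, indi=_empty_table("indi"),
                           rpsr=_empty_table("rpsr"),
                           provenance=[(q, "<synthetic>") for q in config.quarters])
    return bundle


def synonym_table(config: SyntheticConfig) -> pd.DataFrame:
    """The ground-truth verbatim -> generic map for the config's vocabulary."""
    rows = []
    for d in config.drugs:
        rows.append({"verbatim": d.name.upper(), "generic": d.name, "provenance": "synthetic"})
        for v in d.variants:
            rows.append({"verbatim": v.upper(), "generic": d.name, "provenance": "synthetic"})
    rows.append({"verbatim": "OTHERMED", "generic": "othermed", "provenance": "synthetic"})
    return pd.DataFrame(rows)


def write_quarter_files(bundle: QuarterBundle, out_dir: str | Path,
                        quarter_label: str = "24Q1") -> dict[str, Path]:
    """Write the bundle in the FAERS ASCII dialect (DEMO24Q1.txt etc.)."""
    from .faers_io import TABLE_COLUMNS
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in QuarterBundle.TABLES:
        path = out_dir / f"{name.upper()}{quarter_label}.txt"
        bundle.table(name)[TABLE_COLUMNS[name]].to_csv(
            path, sep="$", index=False, lineterminator="\n")
        written[name] = path
    return written
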