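"""Case definition for a target adverse event: deduplication, Preferred-Term
selection, Primary-Suspect exposure, drug-name standardization, ATC lookup.

The flow mirrors standard FAERS practice:

1. deduplicate report versions: for identical caseids keep the version with
   the most recent FDA receipt date, ties broken by the higher primaryid;
2. select reports carrying the target MedDRA Preferred Term (code match
   preferred, case-insensitive name match as fallback);
3. define exposure by the Primary Suspect (PS) role only — Secondary
   Suspect, Concomitant and Interacting mentions are excluded;
4. standardize verbatim drug names through a user-supplied synonym table
   (DrugBank/MeSH-style) and classify generics by ATC anatomical main group.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .faers_io import QuarterBundle

logger = logging.getLogger(__name__)

#: trailing tokens stripped during name normalization (dose forms/units)
DOSAGE_TOKENS = frozenset({
    "TABLET", "TABLETS", "TAB", "CAPSULE", "CAPSULES", "CAP", "INJECTION",
    "SOLUTION", "SUSPENSION", "CREAM", "GEL", "OINTMENT", "PATCH", "SPRAY",
    "MG", "MCG", "G", "ML", "ORAL", "TOPICAL", "IV", "HCL", "SODIUM",
})
_NUMERIC_TOKEN = re.compile(r"^\d+(\.\d+)?(MG|MCG|G|ML|%)?$")
_PAREN = re.compile(r"\([^)]*\)\s*$")

UNKNOWN_ATC = "Unclassified"


class SynonymMap:
    """Uppercased verbatim drug name -> canonical generic name.

    Generic names are fixed points: ``map[UPPER(generic)] == generic`` for
    every generic appearing as a value.
    """

    def __init__(self, mapping: dict[str, str], provenance: dict[str, str] | None = None):
        self._map = {k.upper(): v for k, v in mapping.items()}
        self.provenance = provenance or {}
        for generic in set(self._map.values()):
            self._map.setdefault(generic.upper(), generic)

    def __contains__(self, key: str) -> bool:
        return key.upper() in self._map

    def __len__(self) -> int:
        return len(self._map)

    def get(self, key: str) -> str | None:
        return self._map.get(key.upper())

    @classmethod
    def from_file(cls, path: str | Path, sep: str = "\t") -> "SynonymMap":
        df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        prov = {}
        if "provenance" in cols:
            prov = dict(zip(df.iloc[:, 0].str.upper(), df["provenance"]))
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])), prov)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SynonymMap":
        prov = {}
        if "provenance" in df.columns:
            prov = dict(zip(df.iloc[:, 0].str.upper(), df["provenance"]))
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])), prov)


class AtcMap:
    """Generic drug name -> (ATC code prefix, anatomical main-group label)."""

    GROUPS = {
        "A": "Alimentary tract and metabolism",
        "B": "Blood and blood forming organs",
        "C": "Cardiovascular system",
        "D": "Dermatologicals",
        "G": "Genito urinary system and sex hormones",
        "H": "Systemic hormonal preparations, excl. sex hormones and insulins",
        "J": "Antiinfectives for systemic use",
        "L": "Antineoplastic and immunomodulating agents",
        "M": "Musculo-skeletal system",
        "N": "Nervous system",
        "P": "Antiparasitic products, insecticides and repellents",
        "R": "Respiratory system",
        "S": "Sensory organs",
        "V": "Various",
    }

    def __init__(self, mapping: dict[str, str]):
        # mapping: generic -> ATC code (first letter selects the main group)
        self._map = {k.lower(): v.upper() for k, v in mapping.items()}

    def lookup(self, generic: str) -> tuple[str, str | None]:
        """(group label, code) — (:data:`UNKNOWN_ATC`, None) if absent."""
        code = self._map.get(generic.lower())
        if code is None or code[0] not in self.GROUPS:
            return UNKNOWN_ATC, None
        return self.GROUPS[code[0]], code

    @classmethod
    def from_file(cls, path: str | Path, sep: str = "\t") -> "AtcMap":
        df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


@dataclass
class CaseSet:
    """Deduplicated target-event reports with per-case annotations.

    ``cases`` has one row per retained primaryid matching the target PT, with
    normalized PS drug list, demographics in analysis units, outcome codes
    and report year.  ``universe_size`` is the number of deduplicated reports
    the cases were drawn from (the N of every 2x2 table downstream).
    """

    cases: pd.DataFrame  # primaryid, sex, age_years, year, country, occp_cod
    ps_drugs: dict[int, list[str]]  # primaryid -> normalized PS generics
    outcomes: dict[int, list[str]]  # primaryid -> outcome codes
    universe_size: int

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def case_ids(self) -> set[int]:
        return set(self.cases["primaryid"].tolist())


def deduplicate(demo: pd.DataFrame) -> set[int]:
    """Retain one primaryid per caseid: max fda_dt, then max primaryid.

    A missing fda_dt sorts as the oldest possible date, so any dated version
    beats an undated one.  Records with a missing caseid are retained as
    their own singleton groups (logged).  Idempotent.
    """
    if demo.empty:
        return set()
    df = demo[["primaryid", "caseid", "fda_dt"]].copy()
    df = df[df["primaryid"].notna()]
    n_nocase = int(df["caseid"].isna().sum())
    if n_nocase:
        logger.warning("%d record(s) with missing caseid retained as singletons", n_nocase)
    dt = pd.to_numeric(df["fda_dt"], errors="coerce").fillna(-1)
    order = np.lexsort((df["primaryid"].to_numpy(dtype="int64"),
                        dt.to_numpy(dtype="int64")))
    df = df.iloc[order]
    grouped = df[df["caseid"].notna()].groupby("caseid", sort=False).tail(1)
    singletons = df[df["caseid"].isna()]
    return set(grouped["primaryid"].tolist()) | set(singletons["primaryid"].tolist())


def select_cases(reac: pd.DataFrame, retained: set[int],
                 target_code: int | None = None,
                 target_name: str | None = None) -> set[int]:
    """Retained reports with >=1 reaction matching the target PT.

    Matches by code where both sides have one, otherwise by case-insensitive
    exact name.  A PT listed twice on one report counts once (set semantics).
    """
    if target_code is None and not target_name:
        raise ValueError("target PT requires a code and/or a name")
    if reac.empty:
        return set()
    hit = pd.Series(False, index=reac.index)
    if target_code is not None and "pt_code" in reac.columns:
        hit |= pd.to_numeric(reac["pt_code"], errors="coerce") == target_code
    if target_name:
        hit |= reac["pt_name"].astype("string").str.strip().str.upper() == target_name.strip().upper()
    pids = set(reac.loc[hit, "primaryid"].dropna().astype(int).tolist())
    return pids & retained


def primary_suspect_exposures(drug: pd.DataFrame, retained: set[int]
                              ) -> dict[int, list[str]]:
    """primaryid -> verbatim PS drug names, for every retained report.

    Reports without any PS row map to an empty list, so the mapping's domain
    is exactly ``retained`` (the deduplicated universe downstream).
    Duplicate identical PS names within one report collapse to one.
    """
    exposures: dict[int, list[str]] = {int(pid): [] for pid in retained}
    if drug.empty:
        return exposures
    ps = drug[(drug["role_cod"] == "PS") & drug["primaryid"].isin(retained)]
    for pid, name in zip(ps["primaryid"].astype(int), ps["drugname"].astype(str)):
        bucket = exposures[pid]
        if name not in bucket:
            bucket.append(name)
    return exposures


def normalize_name(name: str, synmap: SynonymMap | None = None) -> tuple[str, bool]:
    """Canonicalize one verbatim drug name.

    Uppercase, trim, collapse internal whitespace, strip trailing
    parentheticals and dose-form/dose tokens, then exact synonym lookup.
    Unmapped names are returned in normalized casing with ``mapped=False``.
    """
    s = re.sub(r"\s+", " ", str(name).strip().upper())
    prev = None
    while prev != s:
        prev = s
        s = _PAREN.sub("", s).strip()
        parts = s.split(" ")
        while len(parts) > 1 and (parts[-1] in DOSAGE_TOKENS
                                  or _NUMERIC_TOKEN.match(parts[-1])):
            parts.pop()
        s = " ".join(parts)
    if synmap is not None:
        generic = synmap.get(s)
        if generic is not None:
            return generic, True
    return s, False


def normalize_names(names: list[str], synmap: SynonymMap) -> list[tuple[str, bool]]:
    """Vector form of :func:`normalize_name` (order preserved)."""
    return [normalize_name(n, synmap) for n in names]


def assign_atc(generic: str, atcmap: AtcMap) -> tuple[str, str | None]:
    """ATC main-group label and code for a generic; exact lookup only."""
    return atcmap.lookup(generic)


_AGE_FACTOR = {"DEC": 10.0, "YR": 1.0, "MON": 1 / 12.0,
               "WK": 1 / 52.1775, "DY": 1 / 365.25, "HR": 1 / 8766.0}


def normalize_age(age: float | None, unit: str | None) -> float | None:
    """Age in years, or None if missing/implausible (outside [0, 120]).

    A present age with a missing unit is assumed to be years (logged by the
    caller if needed) — FAERS leaves AGE_COD blank for most year-valued ages.
    """
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return None
    unit = (unit or "YR").strip().upper() or "YR"
    factor = _AGE_FACTOR.get(unit)
    if factor is None:
        return None
    years = float(age) * factor
    if not (0.0 <= years <= 120.0):
        return None
    return years


def build_caseset(bundle: QuarterBundle,
                  synmap: SynonymMap,
                  target_code: int | None = 10047642,
                  target_name: str | None = "Vitiligo",
                  country_field: str = "occr_country"
                  ) -> tuple[CaseSet, dict[int, list[str]], dict[str, int]]:
    """Run dedup -> PT selection -> PS exposure -> normalization end to end.

    Returns the CaseSet, the normalized PS-exposure mapping over the whole
    deduplicated universe (for contingency tables), and a flow-accounting
    dict of record counts at each stage.
    """
    retained = deduplicate(bundle.demo)
    case_ids = select_cases(bundle.reac, retained, target_code, target_name)
    raw_exposures = primary_suspect_exposures(bundle.drug, retained)

    norm_cache: dict[str, str] = {}

    def norm(name: str) -> str:
        if name not in norm_cache:
            norm_cache[name] = normalize_name(name, synmap)[0]
        return norm_cache[name]

    exposures = {pid: sorted({norm(n) for n in names})
                 for pid, names in raw_exposures.items()}

    demo = bundle.demo.set_index("primaryid")
    outc_by_pid: dict[int, list[str]] = {}
    for pid, code in zip(bundle.outc["primaryid"], bundle.outc["outc_cod"]):
        if pd.notna(pid):
            outc_by_pid.setdefault(int(pid), []).append(str(code))

    rows = []
    for pid in sorted(case_ids):
        rec = demo.loc[pid]
        if isinstance(rec, pd.DataFrame):  # duplicate primaryid rows: take last
            rec = rec.iloc[-1]
        age = rec.get("age")
        unit = rec.get("age_cod")
        age_years = normalize_age(
            None if pd.isna(age) else float(age),
            None if pd.isna(unit) else str(unit))
        fda_dt = rec.get("fda_dt")
        event_dt = rec.get("event_dt")
        year = None
        for dt in (fda_dt, event_dt):
            if pd.notna(dt):
                year = int(dt) // 10000
                break
        country = rec.get(country_field)
        if pd.isna(country) or str(country).strip() == "":
            country = rec.get("reporter_country")
        rows.append({
            "primaryid": pid,
            "sex": None if pd.isna(rec.get("sex")) else str(rec.get("sex")),
            "age_years": age_years,
            "year": year,
            "country": None if pd.isna(country) or str(country).strip() == ""
                       else str(country),
            "occp_cod": None if pd.isna(rec.get("occp_cod")) else str(rec.get("occp_cod")),
        })
    cases = pd.DataFrame(rows, columns=["primaryid", "sex", "age_years",
                                        "year", "country", "occp_cod"])
    caseset = CaseSet(
        cases=cases,
        ps_drugs={pid: exposures[pid] for pid in case_ids},
        outcomes={pid: outc_by_pid.get(pid, []) for pid in case_ids},
        universe_size=len(retained),
    )
    flow = {
        "reports_parsed": len(bundle.demo),
        "reports_deduplicated": len(retained),
        "cases_selected": len(case_ids),
    }
    return caseset, exposures, flow
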