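"""Reading and writing FAERS quarterly ASCII tables.

FAERS (the FDA Adverse Event Reporting System) is distributed as quarterly
sets of "$"-delimited ASCII files, one per table: DEMO (demographic and
administrative data, one row per report version), DRUG (drug mentions with a
role code), REAC (MedDRA-coded reactions), OUTC (outcome codes), plus THER,
INDI and RPSR which this package carries through untyped.

Parsing is *total*: every data line becomes either a typed record or a
quarantined row with a reason.  Child rows (DRUG/REAC/OUTC/...) whose report
identifier does not appear in DEMO are dropped with a logged count so the
referential invariant of :class:`QuarterBundle` always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
AGE_UNIT_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})
SEX_CODES = frozenset({"F", "M"})
OCCP_CODES = frozenset({"MD", "PH", "OT", "CN", "LW"})

#: table name -> canonical column order of the typed model
TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": [
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "occp_cod", "occr_country", "reporter_country",
    ],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "pt_name", "pt_code"],
    "outc": ["primaryid", "outc_cod"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
    "rpsr": ["primaryid", "rpsr_cod"],
}

#: columns that must be present (after alias resolution) for a table to parse
MANDATORY_COLUMNS: dict[str, list[str]] = {
    "demo": ["primaryid", "caseid"],
    "drug": ["primaryid", "role_cod", "drugname"],
    "reac": ["primaryid", "pt_name"],
    "outc": ["primaryid", "outc_cod"],
    "ther": ["primaryid"],
    "indi": ["primaryid"],
    "rpsr": ["primaryid"],
}

#: default alias map: raw header name (upper) -> canonical column name.
#: Extend for pre-2014 LAERS headers (e.g. ISR -> primaryid) via Dialect.
DEFAULT_ALIASES: dict[str, str] = {
    "PRIMARYID": "primaryid",
    "CASEID": "caseid",
    "CASEVERSION": "caseversion",
    "FDA_DT": "fda_dt",
    "EVENT_DT": "event_dt",
    "AGE": "age",
    "AGE_COD": "age_cod",
    "SEX": "sex",
    "GNDR_COD": "sex",  # pre-2014 header
    "OCCP_COD": "occp_cod",
    "OCCR_COUNTRY": "occr_country",
    "REPORTER_COUNTRY": "reporter_country",
    "DRUG_SEQ": "drug_seq",
    "ROLE_COD": "role_cod",
    "DRUGNAME": "drugname",
    "PROD_AI": "prod_ai",
    "PT": "pt_name",
    "PT_NAME": "pt_name",
    "PT_CODE": "pt_code",
    "OUTC_COD": "outc_cod",
    "OUTC_CODE": "outc_cod",
    "DSG_DRUG_SEQ": "dsg_drug_seq",
    "START_DT": "start_dt",
    "END_DT": "end_dt",
    "INDI_DRUG_SEQ": "indi_drug_seq",
    "INDI_PT": "indi_pt",
    "RPSR_COD": "rpsr_cod",
}


class FormatError(ValueError):
    """A FAERS file does not conform to the declared dialect."""


@dataclass(frozen=True)
class Dialect:
    """Parser configuration for one FAERS era.

    The modern (2014+) quarterly files are "$"-delimited with a single header
    line; older LAERS files differ mainly in column names, which the
    ``aliases`` map absorbs.
    """

    delimiter: str = "$"
    has_header: bool = True
    aliases: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ALIASES))

    def resolve(self, raw_columns: list[str]) -> list[str]:
        return [self.aliases.get(c.strip().upper(), c.strip().lower()) for c in raw_columns]


@dataclass
class QuarterBundle:
    """The seven linked FAERS tables for one or more quarters.

    Tables are pandas DataFrames in the canonical column order of
    ``TABLE_COLUMNS``.  Invariant: every primaryid appearing in a child table
    appears in ``demo``.  ``quarantine`` holds rows that failed type coercion,
    with a ``reason`` column; ``orphans_dropped`` counts child rows removed to
    restore referential integrity.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    rpsr: pd.DataFrame
    provenance: list[tuple[str, str]] = field(default_factory=list)
    quarantine: dict[str, pd.DataFrame] = field(default_factory=dict)
    orphans_dropped: dict[str, int] = field(default_factory=dict)

    TABLES = ("demo", "drug", "reac", "outc", "ther", "indi", "rpsr")

    def table(self, name: str) -> pd.DataFrame:
        if name not in self.TABLES:
            raise KeyError(name)
        return getattr(self, name)

    def counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in self.TABLES}


@dataclass(frozen=True)
class ValidationReport:
    """Exact per-table bookkeeping for a loaded bundle (reporting only)."""

    table_counts: dict[str, int]
    orphan_counts: dict[str, int]
    quarantine_counts: dict[str, int]

    @property
    def total_orphans(self) -> int:
        return sum(self.orphan_counts.values())


def empty_bundle() -> QuarterBundle:
    """A bundle with all seven tables present but empty (headers only)."""
    tables = {name: _empty_table(name) for name in QuarterBundle.TABLES}
    return QuarterBundle(**tables)


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})


def _to_int(series: pd.Series) -> pd.Series:
    """Coerce strings to nullable integers; non-numeric -> <NA>."""
    return pd.to_numeric(series, errors="coerce").astype("Int64")


def _pad_partial_date(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    """YYYYMMDD integers from possibly partial dates.

    YYYYMM and YYYY values are padded with 01 components and flagged so
    ordering semantics survive for deduplication.  Returns (dates, flagged).
    """
    num = pd.to_numeric(series, errors="coerce").astype("Int64")
    flagged = pd.Series(False, index=series.index)
    yyyy = num.notna() & (num < 10000)
    yyyymm = num.notna() & (num >= 10000) & (num < 1000000)
    flagged[yyyy | yyyymm] = True
    out = num.copy()
    out[yyyy] = num[yyyy] * 10000 + 101
    out[yyyymm] = num[yyyymm] * 100 + 1
    return out, flagged


def _enum_clean(series: pd.Series, allowed: frozenset[str]) -> pd.Series:
    s = series.astype("string").str.strip().str.upper()
    return s.where(s.isin(allowed))


def _coerce_table(name: str, raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Typed records + quarantined rows (with reasons) for one table."""
    df = raw.copy()
    for col in TABLE_COLUMNS[name]:
        if col not in df.columns:
            df[col] = pd.NA

    bad = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        mask = mask.fillna(False).astype(bool)
        bad[mask] = bad[mask].where(bad[mask] == "", bad[mask] + "; ") + reason

    pid = _to_int(df["primaryid"])
    flag(pid.isna(), "primaryid not an integer")
    df["primaryid"] = pid

    if name == "demo":
        cid = _to_int(df["caseid"])
        # missing caseid is tolerated downstream (singleton group) but a
        # non-numeric non-empty one is a parse failure
        nonempty = df["caseid"].astype("string").str.strip().fillna("") != ""
        flag(cid.isna() & nonempty, "caseid not an integer")
        df["caseid"] = cid
        for col in ("fda_dt", "event_dt"):
            dates, _flagged = _pad_partial_date(df[col])
            df[col] = dates
        age = pd.to_numeric(df["age"], errors="coerce")
        flag(age.notna() & ((age < 0) | ~np.isfinite(age.fillna(0.0))), "age negative or non-finite")
        df["age"] = age
        df["age_cod"] = _enum_clean(df["age_cod"], AGE_UNIT_CODES)
        df["sex"] = _enum_clean(df["sex"], SEX_CODES)
        df["occp_cod"] = _enum_clean(df["occp_cod"], OCCP_CODES)
        for col in ("occr_country", "reporter_country"):
            df[col] = df[col].astype("string").str.strip()
    elif name == "drug":
        df["drug_seq"] = _to_int(df["drug_seq"])
        role = df["role_cod"].astype("string").str.strip().str.upper()
        flag(~role.isin(ROLE_CODES), "role_cod not in {PS,SS,C,I}")
        df["role_cod"] = role
        dn = df["drugname"].astype("string").str.strip()
        flag(dn.isna() | (dn == ""), "drugname empty")
        df["drugname"] = dn
        df["prod_ai"] = df["prod_ai"].astype("string").str.strip()
    elif name == "reac":
        pt = df["pt_name"].astype("string").str.strip()
        flag(pt.isna() | (pt == ""), "pt_name empty")
        df["pt_name"] = pt
        df["pt_code"] = _to_int(df["pt_code"])
    elif name == "outc":
        oc = df["outc_cod"].astype("string").str.strip().str.upper()
        flag(~oc.isin(OUTCOME_CODES), "outc_cod not in the seven-code set")
        df["outc_cod"] = oc
    else:  # ther / indi / rpsr: pass-through, only primaryid typed
        for col in TABLE_COLUMNS[name]:
            if col != "primaryid":
                df[col] = df[col].astype("string")

    bad_mask = bad != ""
    quarantined = raw.loc[bad_mask].copy()
    quarantined["reason"] = bad[bad_mask]
    good = df.loc[~bad_mask, TABLE_COLUMNS[name]].reset_index(drop=True)
    return good, quarantined.reset_index(drop=True)


def read_table(path: str | Path, name: str, dialect: Dialect | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse one FAERS table file into (typed records, quarantine)."""
    dialect = dialect or Dialect()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{name}: file not found: {path}")
    try:
        raw = pd.read_csv(
            path,
            sep=dialect.delimiter,
            header=0 if dialect.has_header else None,
            dtype=str,
            keep_default_na=False,
            engine="python",
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{name}: empty file: {path}") from exc
    if raw.empty and raw.columns.empty:
        raise FormatError(f"{name}: empty file: {path}")
    if dialect.has_header:
        raw.columns = dialect.resolve(list(raw.columns))
    else:
        raw.columns = TABLE_COLUMNS[name][: raw.shape[1]]
    raw = raw.replace("", pd.NA)
    missing = [c for c in MANDATORY_COLUMNS[name] if c not in raw.columns]
    if missing:
        raise FormatError(f"{name}: missing mandatory column(s) {missing} in {path}")
    return _coerce_table(name, raw)


def read_quarter(paths: dict[str, str | Path] | list[str | Path],
                 dialect: Dialect | None = None,
                 quarter_label: str = "") -> QuarterBundle:
    """Read one quarter's table files into a :class:`QuarterBundle`.

    ``paths`` maps table name -> file path, or is a list of paths whose file
    names start with the table name (DEMO24Q1.txt etc.).  Tables without a
    file are loaded empty.  Child rows whose primaryid is absent from DEMO
    are dropped with a logged count.
    """
    dialect = dialect or Dialect()
    if not isinstance(paths, dict):
        resolved: dict[str, str | Path] = {}
        for p in paths:
            stem = Path(p).name.lower()
            for name in QuarterBundle.TABLES:
                if stem.startswith(name):
                    resolved[name] = p
                    break
            else:
                raise FormatError(f"cannot infer table name from file name: {p}")
        paths = resolved

    tables: dict[str, pd.DataFrame] = {}
    quarantine: dict[str, pd.DataFrame] = {}
    provenance: list[tuple[str, str]] = []
    for name in QuarterBundle.TABLES:
        if name in paths:
            good, quar = read_table(paths[name], name, dialect)
            tables[name] = good
            if len(quar):
                quarantine[name] = quar
            provenance.append((quarter_label, str(paths[name])))
        else:
            tables[name] = _empty_table(name)

    known = set(tables["demo"]["primaryid"].dropna().tolist())
    orphans: dict[str, int] = {}
    for name in QuarterBundle.TABLES:
        if name == "demo":
            continue
        df = tables[name]
        if df.empty:
            continue
        keep = df["primaryid"].isin(known)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("%s: dropped %d orphan row(s) without a DEMO parent", name, n_drop)
            orphans[name] = n_drop
            tables[name] = df.loc[keep].reset_index(drop=True)
    return QuarterBundle(**tables, provenance=provenance,
                         quarantine=quarantine, orphans_dropped=orphans)


def validate_bundle(bundle: QuarterBundle) -> ValidationReport:
    """Exact counts per table, orphan rows, and quarantined rows.

    Never mutates the bundle; orphan counts are recomputed from the current
    table contents (0 for a bundle produced by :func:`read_quarter`).
    """
    known = set(bundle.demo["primaryid"].dropna().tolist())
    orphan_counts: dict[str, int] = {}
    for name in QuarterBundle.TABLES:
        if name == "demo":
            continue
        df = bundle.table(name)
        if df.empty:
            orphan_counts[name] = 0
        else:
            orphan_counts[name] = int((~df["primaryid"].isin(known)).sum())
    return ValidationReport(
        table_counts=bundle.counts(),
        orphan_counts=orphan_counts,
        quarantine_counts={k: len(v) for k, v in bundle.quarantine.items()},
    )


def write_tables(bundle: QuarterBundle, out_dir: str | Path,
                 delimiter: str = "$") -> dict[str, Path]:
    """Write one normalized delimited file per table; round-trips with
    :func:`read_quarter` under the same delimiter."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in QuarterBundle.TABLES:
        path = out_dir / f"{name}.txt"
        df = bundle.table(name)[TABLE_COLUMNS[name]]
        try:
            df.to_csv(path, sep=delimiter, index=False, lineterminator="\n")
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        written[name] = path
    return written
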