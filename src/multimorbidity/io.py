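"""Readers that normalise primary-care extract dialects into coded-record tables.

The pipeline's atomic input is a *coded record*: one dated, coded event for
one patient, with an optional numeric value for test results.  UK Biobank
ships clinical events (``gp_clinical``: patient id, data provider, event
date, Read v2 / CTV3 code, value fields) and prescriptions
(``gp_scripts``: issue date, BNF / DM+D code) in separate layouts; the
readers here flatten both into a single tidy frame with columns

    patient_id, date, code, framework, domain, value

Dates are parsed at day precision; rows whose date fails to parse are
excluded with a logged count before any phenotyping.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .codemap import Domain, Framework

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["patient_id", "date", "code", "framework", "domain", "value"]


def _parse_dates(series: pd.Series, dayfirst: bool) -> pd.Series:
    return pd.to_datetime(series, errors="coerce", dayfirst=dayfirst, format="mixed")


def _finish(records: pd.DataFrame, source: str) -> pd.DataFrame:
    n_bad = int(records["date"].isna().sum())
    if n_bad:
        logger.warning("%s: excluded %d records with missing/invalid dates", source, n_bad)
    records = records.dropna(subset=["date", "code"]).reset_index(drop=True)
    records["code"] = records["code"].astype(str).str.strip()
    records = records[records["code"] != ""]
    return records[RECORD_COLUMNS].reset_index(drop=True)


def read_gp_clinical(path: str | Path, sep: str = ",", dayfirst: bool = False) -> pd.DataFrame:
    """Read a gp_clinical-style file into coded records.

    Expected columns: ``eid, data_provider, event_dt, read_2, read_3,
    value1`` (extra columns ignored).  Each row yields one record coded in
    Read v2 (``read_2``) or CTV3 (``read_3``); a parseable ``value1``
    marks the record as a test result, otherwise it is a diagnosis/symptom
    event.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    for col in ("eid", "event_dt"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    date = _parse_dates(frame["event_dt"], dayfirst)
    read2 = frame.get("read_2", pd.Series(index=frame.index, dtype=str))
    read3 = frame.get("read_3", pd.Series(index=frame.index, dtype=str))
    code = read2.where(read2.notna() & (read2.astype(str).str.strip() != ""), read3)
    framework = np.where(
        read2.notna() & (read2.astype(str).str.strip() != ""),
        Framework.READ2.value,
        Framework.CTV3.value,
    )
    value = pd.to_numeric(frame.get("value1", np.nan), errors="coerce")
    domain = np.where(value.notna(), Domain.TEST.value, Domain.DIAGNOSIS.value)
    records = pd.DataFrame(
        {
            "patient_id": frame["eid"],
            "date": date,
            "code": code,
            "framework": framework,
            "domain": domain,
            "value": value,
        }
    )
    return _finish(records, str(path))


def read_gp_scripts(path: str | Path, sep: str = ",", dayfirst: bool = False) -> pd.DataFrame:
    """Read a gp_scripts-style prescription file into coded records.

    Expected columns: ``eid, data_provider, issue_date, bnf_code,
    dmd_code``; each row yields one prescription record coded in BNF when
    available, else DM+D.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    for col in ("eid", "issue_date"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    date = _parse_dates(frame["issue_date"], dayfirst)
    bnf = frame.get("bnf_code", pd.Series(index=frame.index, dtype=str))
    dmd = frame.get("dmd_code", pd.Series(index=frame.index, dtype=str))
    has_bnf = bnf.notna() & (bnf.astype(str).str.strip() != "")
    code = bnf.where(has_bnf, dmd)
    framework = np.where(has_bnf, Framework.BNF.value, Framework.DMD.value)
    records = pd.DataFrame(
        {
            "patient_id": frame["eid"],
            "date": date,
            "code": code,
            "framework": framework,
            "domain": Domain.PRESCRIPTION.value,
            "value": np.nan,
        }
    )
    return _finish(records, str(path))


def read_records(path: str | Path) -> pd.DataFrame:
    """Read an already-normalised coded-record CSV (the package's own dialect)."""
    frame = pd.read_csv(path, dtype={"patient_id": str, "code": str}, comment="#")
    frame["date"] = pd.to_datetime(frame["date"], errors="coerce")
    if "value" not in frame.columns:
        frame["value"] = np.nan
    return _finish(frame, str(path))


def _read_dated(path: str | Path, date_cols: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"patient_id": str}, comment="#")
    for col in date_cols:
        if col in frame.columns:
            frame[col] = pd.to_datetime(frame[col], errors="coerce")
    return frame


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Cohort file: patient_id, index_date (baseline assessment date)."""
    return _read_dated(path, ["index_date"])


def read_registration(path: str | Path) -> pd.DataFrame:
    """Registration spells: patient_id, start, end, provider."""
    return _read_dated(path, ["start", "end"])


def read_deaths(path: str | Path) -> pd.DataFrame:
    """Death-registry table: patient_id, date_of_death."""
    return _read_dated(path, ["date_of_death"])


def read_cancers(path: str | Path) -> pd.DataFrame:
    """Cancer-registry table: patient_id, diagnosis_date, site_code."""
    return _read_dated(path, ["diagnosis_date"])


def read_demographics(path: str | Path) -> pd.DataFrame:
    """Demographics: patient_id, age (years at baseline), sex (0=female, 1=male)."""
    frame = pd.read_csv(path, dtype={"patient_id": str}, comment="#")
    return frame
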