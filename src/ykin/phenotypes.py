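"""Cardiovascular phenotype construction.

Implements the phenotype definitions used for Y-lineage association testing:
iterative modified-Tukey outlier removal, medication adjustment of blood
pressure (+15/+10 mm Hg) and lipids (LDL/0.7, total cholesterol/0.8),
hypertension classification, the coronary artery disease (CAD) case/control/
excluded algorithm from ICD-9/ICD-10/OPCS code lists and exclusion
medications, self-reported parental proxy phenotypes, and survival records
on the age timescale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SOURCES = (
    "self_report",
    "hospital_icd9",
    "hospital_icd10",
    "operation_opcs",
    "death_icd10_primary_or_secondary",
)

__all__ = [
    "HealthRecord",
    "tukey_filter",
    "adjust_blood_pressure",
    "mean_arterial_pressure",
    "classify_hypertension",
    "adjust_lipids",
    "load_codelists",
    "expand_code_range",
    "classify_cad",
    "classify_cad_cohort",
    "build_parent_phenotypes",
    "build_survival_records",
]


@dataclass(frozen=True)
class HealthRecord:
    """One coded health event for one individual."""

    source: str  # one of SOURCES
    code: str
    date: str | None = None


# ---------------------------------------------------------------------------
# Outlier removal


def tukey_filter(values, k: float = 3.0) -> pd.Series:
    """Iterative modified-Tukey outlier mask.

    Values strictly below Q1 - k*IQR or strictly above Q3 + k*IQR are
    removed; quartiles (linear-interpolation convention) are recomputed on
    the survivors and the test repeats until a pass removes nothing.

    Returns a nullable-boolean Series: True = retained, False = removed,
    NA where the input was missing. With fewer than 4 non-missing values no
    removal is attempted (a warning is emitted).
    """
    s = pd.Series(values, dtype=float)
    mask = pd.array(np.where(s.isna(), pd.NA, True), dtype="boolean")
    mask = pd.Series(mask, index=s.index)
    if int(s.notna().sum()) < 4:
        warnings.warn("tukey_filter: fewer than 4 non-missing values; no removal")
        return mask
    alive = s.notna().to_numpy()
    x = s.to_numpy()
    while True:
        q1, q3 = np.percentile(x[alive], [25, 75])
        iqr = q3 - q1
        out = alive & ((x < q1 - k * iqr) | (x > q3 + k * iqr))
        if not out.any():
            break
        alive &= ~out
    mask[s.notna() & ~alive] = False
    return mask


# ---------------------------------------------------------------------------
# Blood pressure


def adjust_blood_pressure(sbp_measured, dbp_measured, on_med):
    """Medication adjustment: +15 mm Hg systolic, +10 diastolic when the
    individual reports antihypertensive medication; identity otherwise."""
    sbp = np.asarray(sbp_measured, dtype=float)
    dbp = np.asarray(dbp_measured, dtype=float)
    med = np.asarray(on_med, dtype=bool)
    return sbp + 15.0 * med, dbp + 10.0 * med


def mean_arterial_pressure(sbp, dbp, formula: str = "standard"):
    """Mean arterial pressure in mm Hg.

    ``standard`` is the conventional dbp + (sbp - dbp)/3. ``printed``
    evaluates dbp + (dbp + sbp)/3 verbatim; it exceeds systolic pressure for
    any plausible reading and is provided for comparison only.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if formula == "standard":
        return dbp + (sbp - dbp) / 3.0
    if formula == "printed":
        logger.warning("mean_arterial_pressure: 'printed' formula yields values above SBP")
        return dbp + (dbp + sbp) / 3.0
    raise ValueError(f"unknown MAP formula {formula!r}")


def classify_hypertension(sbp_measured, dbp_measured, on_med):
    """Hypertension case iff on antihypertensive medication, or measured
    SBP >= 140, or measured DBP >= 90 (thresholds on *measured* values).
    Missing input yields a missing outcome."""
    idx = sbp_measured.index if isinstance(sbp_measured, pd.Series) else None
    sbp = pd.Series(np.asarray(sbp_measured, dtype=float), index=idx)
    dbp = pd.Series(np.asarray(dbp_measured, dtype=float), index=idx)
    med = pd.Series(np.asarray(on_med), index=idx).astype("boolean")
    case = med | (sbp >= 140) | (dbp >= 90)
    case[sbp.isna() | dbp.isna() | med.isna()] = pd.NA
    # medication alone decides even if BP is missing
    case[med.fillna(False).to_numpy() & case.isna().to_numpy()] = True
    return case


# ---------------------------------------------------------------------------
# Lipids


def adjust_lipids(total_chol, ldl, hdl, trig, on_med, apply_tukey: bool = True):
    """Lipid-lowering-medication adjustment and triglyceride transform.

    LDL is divided by 0.7 and total cholesterol by 0.8 for medicated
    individuals. Triglycerides are log-transformed (non-positive values
    become missing) before outlier filtering. Each trait then passes through
    the iterative Tukey filter; filtered values are set to missing.

    Returns a DataFrame with columns total_chol, ldl, hdl, log_trig.
    """
    med = np.asarray(on_med, dtype=bool)
    total = np.asarray(total_chol, dtype=float) / np.where(med, 0.8, 1.0)
    ldl_a = np.asarray(ldl, dtype=float) / np.where(med, 0.7, 1.0)
    hdl_a = np.asarray(hdl, dtype=float)
    trig_a = np.asarray(trig, dtype=float).copy()
    trig_a[trig_a <= 0] = np.nan
    with np.errstate(invalid="ignore"):
        log_trig = np.log(trig_a)
    out = pd.DataFrame(
        {"total_chol": total, "ldl": ldl_a, "hdl": hdl_a, "log_trig": log_trig}
    )
    if apply_tukey:
        for col in out.columns:
            keep = tukey_filter(out[col])
            out.loc[keep == False, col] = np.nan  # noqa: E712 (pd.NA-aware)
    return out


# ---------------------------------------------------------------------------
# Code lists and CAD classification


def expand_code_range(entry: str) -> list[str]:
    """Expand an ICD/OPCS range like "I21-I23" or "K40-K46" to prefixes.

    Single codes pass through (dots stripped). Ranges must share an alpha
    prefix and vary only in the trailing integer.
    """
    entry = entry.strip()
    if "-" not in entry:
        return [entry.replace(".", "")]
    lo, hi = entry.split("-", 1)
    lo, hi = lo.strip(), hi.strip()
    alpha = "".join(c for c in lo if c.isalpha())
    if not hi[0].isalpha():
        hi = alpha + hi
    lo_n, hi_n = int(lo[len(alpha):]), int(hi[len(alpha):])
    width = len(lo) - len(alpha)
    return [f"{alpha}{n:0{width}d}" for n in range(lo_n, hi_n + 1)]


def load_codelists(path: str | Path | None = None) -> dict:
    """Load the CAD code-list config, expanding ranges into prefix lists."""
    if path is None:
        path = Path(str(resources.files("ykin").joinpath("data", "codelists.yaml")))
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cad = raw["cad"]
    out = {"case": {}, "exclude": {}, "exclusion_med_codes": set()}
    for section in ("case", "exclude"):
        for key, entries in cad[section].items():
            if key == "medication_classes":
                continue
            expanded: list[str] = []
            for e in entries:
                expanded.extend(expand_code_range(str(e)))
            out[section][key] = expanded
    meds = raw.get("medications", {})
    for cls in cad["exclude"].get("medication_classes", []):
        out["exclusion_med_codes"].update(meds.get(cls, []))
    return out


def _norm(code: str) -> str:
    return str(code).replace(".", "").strip()


def _matches(code: str, prefixes: Iterable[str]) -> bool:
    c = _norm(code)
    return any(c.startswith(_norm(p)) for p in prefixes)


_CASE_SOURCE_KEYS = {
    "self_report": "self_report",
    "hospital_icd9": "hospital_icd9",
    "hospital_icd10": "hospital_icd10",
    "operation_opcs": "operation_opcs",
    "death_icd10_primary_or_secondary": "death_icd10_primary_or_secondary",
}


def classify_cad(
    records: Sequence[HealthRecord],
    meds: Iterable[str] = (),
    codelists: dict | None = None,
) -> str:
    """CAD status for one individual: ``case``, ``control`` or ``excluded``.

    Cases have any myocardial-infarction, PCI, CABG or CAD-death code.
    Non-cases are excluded when they carry an angina code (self-reported or
    hospital) or take an exclusion medication; the remainder are controls.
    Records with an unrecognised source are logged and ignored.
    """
    cl = codelists or load_codelists()
    is_case = is_excluded = False
    for rec in records:
        if rec.source not in SOURCES:
            logger.info("classify_cad: unrecognised record source %r ignored", rec.source)
            continue
        key = _CASE_SOURCE_KEYS[rec.source]
        if key in cl["case"] and _matches(rec.code, cl["case"][key]):
            is_case = True
        if key in cl["exclude"] and _matches(rec.code, cl["exclude"][key]):
            is_excluded = True
    if is_case:
        return "case"
    if is_excluded or any(str(m) in cl["exclusion_med_codes"] for m in meds):
        return "excluded"
    return "control"


def classify_cad_cohort(
    records: pd.DataFrame,
    meds: pd.DataFrame | None,
    individuals: Sequence[str],
    codelists: dict | None = None,
) -> pd.Series:
    """Vectorised CAD classification for a cohort.

    ``records`` has columns individual, source, code; ``meds`` has columns
    individual, med_code (may be None/empty). Individuals without any record
    or medication are controls.
    """
    cl = codelists or load_codelists()
    status = pd.Series("control", index=pd.Index(individuals, name="individual"))
    if records is not None and len(records):
        known = records["source"].isin(SOURCES)
        if (~known).any():
            logger.info("classify_cad_cohort: %d records with unknown source ignored",
                        int((~known).sum()))
        recs = records[known]
        norm_codes = recs["code"].astype(str).str.replace(".", "", regex=False)

        def hit(section: str) -> pd.Series:
            m = pd.Series(False, index=recs.index)
            for src, prefixes in cl[section].items():
                in_src = recs["source"] == src
                if not in_src.any() or not prefixes:
                    continue
                pat = "|".join(sorted({_norm(p) for p in prefixes}))
                m |= in_src & norm_codes.str.match(f"(?:{pat})")
            return m

        case_ids = set(recs.loc[hit("case"), "individual"])
        excl_ids = set(recs.loc[hit("exclude"), "individual"])
    else:
        case_ids, excl_ids = set(), set()
    if meds is not None and len(meds):
        med_excl = set(meds.loc[meds["med_code"].astype(str).isin(cl["exclusion_med_codes"]),
                                "individual"])
        excl_ids |= med_excl
    status[status.index.isin(excl_ids)] = "excluded"
    status[status.index.isin(case_ids)] = "case"
    return status


# ---------------------------------------------------------------------------
# Parental proxy phenotypes and survival


def build_parent_phenotypes(reports: pd.DataFrame, min_death_age: float = 40.0) -> pd.DataFrame:
    """Parental case/control vectors and parent survival fields.

    ``reports`` columns (per subject): father_conditions / mother_conditions
    (iterable of selected illness tokens, or None for "prefer not to
    answer"), father_age, mother_age (reported age, or age at death if
    dead), father_dead, mother_dead.

    "heart disease" selections give the parent CAD proxy; "high blood
    pressure" gives parent hypertension; any other answered selection is a
    control; no answer is missing. Parents dead before ``min_death_age`` are
    excluded from survival (their entry/event ages are set missing) to limit
    deaths from accident or injury.
    """
    out = pd.DataFrame(index=reports.index)
    for parent in ("father", "mother"):
        conds = reports[f"{parent}_conditions"]

        def status(tokens, disease):
            if tokens is None:
                return pd.NA
            return disease in set(tokens)

        out[f"{parent}_cad"] = conds.map(lambda t: status(t, "heart_disease")).astype("boolean")
        out[f"{parent}_hypertension"] = conds.map(
            lambda t: status(t, "high_blood_pressure")
        ).astype("boolean")
        age = pd.to_numeric(reports[f"{parent}_age"], errors="coerce")
        dead = reports[f"{parent}_dead"].astype("boolean")
        event_age = age.copy()
        ok = ~(dead.fillna(False) & (age < min_death_age))
        out[f"{parent}_event_age"] = event_age.where(ok)
        out[f"{parent}_dead"] = dead.where(ok)
        out[f"{parent}_age"] = age
    return out


def build_survival_records(
    entry_age, assess_date, death_date=None, censor_date: str = "2021-11-01"
) -> pd.DataFrame:
    """Subject survival on the age timescale with a fixed censoring date.

    ``assess_date`` and ``death_date`` are decimal years (or parseable
    dates); event age = entry age + (death or censor date - assessment
    date). The censoring date is cohort-wide.
    """
    def to_year(x):
        if x is None:
            return np.nan
        if isinstance(x, (int, float, np.floating)):
            return float(x)
        ts = pd.Timestamp(x)
        return ts.year + (ts.dayofyear - 1) / 365.25

    entry = pd.Series(np.asarray(entry_age, dtype=float))
    assess = pd.Series(np.asarray([to_year(a) for a in np.atleast_1d(assess_date)], dtype=float))
    if len(assess) == 1:
        assess = pd.Series(np.repeat(assess.iloc[0], len(entry)))
    censor = to_year(censor_date)
    if death_date is None:
        death = pd.Series(np.nan, index=entry.index)
    else:
        death = pd.Series(np.asarray([to_year(d) for d in np.atleast_1d(death_date)], dtype=float))
    dead = death.notna() & (death <= censor)
    event_year = np.where(dead, death, censor)
    event_age = entry + (event_year - assess)
    if (event_age < entry).any():
        raise ValueError("event age before entry age; check dates")
    return pd.DataFrame({"entry_age": entry, "event_age": event_age, "dead": dead})
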