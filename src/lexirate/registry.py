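"""Common data model for registry-style prescription/cancer cohort data.

Five national cohorts (Denmark, Finland, Norway, Sweden, UK primary care)
are represented by one unified CSV schema — ``country`` is a column and
per-country files may simply be concatenated.  Three tables make up a
:class:`RegistryBundle`:

* ``persons``        — one row per individual with the valid observation window,
* ``prescriptions``  — dispensing records with amounts in WHO defined daily
  doses (DDDs),
* ``events``         — cancer diagnoses, deaths and emigrations.

A :class:`CodingDictionary` maps ATC codes onto insulin classes and
co-medication groups and ICD-10 codes onto the studied cancer sites.
Dates are ISO-8601 strings on disk and integer day offsets internally.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COUNTRIES",
    "INSULIN_CLASSES",
    "CANCER_SITES",
    "COMED_GROUPS",
    "STUDY_PERIODS",
    "CodingDictionary",
    "RegistryBundle",
    "SchemaError",
    "ReferentialError",
    "RegistryParseError",
    "classify_insulin",
    "classify_cancer_site",
    "read_bundle",
    "write_bundle",
]

COUNTRIES = ("DK", "FI", "NO", "SE", "UK")
SEXES = ("male", "female")
EVENT_TYPES = ("cancer", "death", "emigration")

INSULIN_CLASSES = ("human", "glargine", "detemir", "other_insulin")
COMED_GROUPS = ("niad", "statin", "nsaid", "hrt")

#: The ten site-specific cancers plus non-melanoma skin cancer and the
#: residual "other" group.  NMSC is special-cased throughout: it neither
#: counts as cancer history nor ends follow-up.
CANCER_SITES = (
    "liver",
    "pancreas",
    "lung",
    "melanoma",
    "bladder",
    "colorectal",
    "nhl",
    "breast",
    "endometrial",
    "prostate",
    "nmsc",
    "other_cancer",
)

#: Per-country period of valid data collection (registry coverage window).
STUDY_PERIODS: dict[str, tuple[str, str]] = {
    "DK": ("1996-01-01", "2010-12-31"),
    "FI": ("1996-01-01", "2011-12-31"),
    "NO": ("2005-01-01", "2010-12-31"),
    "SE": ("2007-01-01", "2012-12-31"),
    "UK": ("1987-01-01", "2013-12-31"),
}

_HUMAN_INSULIN_ATC = ("A10AC01", "A10AB01", "A10AD01", "A10AE01", "A10AF01")

_DEFAULT_SITE_MAP: dict[str, str] = {
    "C33": "lung",
    "C34": "lung",
    "C43": "melanoma",
    "C67": "bladder",
    "C18": "colorectal",
    "C19": "colorectal",
    "C20": "colorectal",
    "C21": "colorectal",
    "C82": "nhl",
    "C83": "nhl",
    "C84": "nhl",
    "C85": "nhl",
    "C86": "nhl",
    "C884": "nhl",
    "C50": "breast",
    "C54": "endometrial",
    "C61": "prostate",
    "C22": "liver",
    "C25": "pancreas",
    "C44": "nmsc",
}

_DEFAULT_COMED_MAP: dict[str, str] = {
    "A10B": "niad",
    "C10A": "statin",
    "M01A": "nsaid",
    "G03": "hrt",
}


class SchemaError(ValueError):
    """A table is missing declared columns or violates a type contract."""


class ReferentialError(ValueError):
    """A foreign key (person_id) does not resolve against the persons table."""


class RegistryParseError(ValueError):
    """A cell could not be parsed; the message names the offending rows."""


@dataclass(frozen=True)
class CodingDictionary:
    """ATC → insulin class / co-medication group and ICD-10 → cancer site maps.

    ``insulin_map`` holds exact ATC codes; any other ``A10A``-prefixed code is
    an "other" insulin and anything outside ``A10A`` is not an insulin.
    ``site_map`` keys are ICD-10 prefixes with dots removed; matching is
    longest-prefix so ``C88.4`` (→ ``C884``) wins over a hypothetical ``C88``.
    """

    insulin_map: dict[str, str] = field(
        default_factory=lambda: {
            **{c: "human" for c in _HUMAN_INSULIN_ATC},
            "A10AE04": "glargine",
            "A10AE05": "detemir",
        }
    )
    site_map: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_SITE_MAP))
    comed_map: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_COMED_MAP))

    @classmethod
    def default(cls) -> "CodingDictionary":
        return cls()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "insulin_map": self.insulin_map,
                    "site_map": self.site_map,
                    "comed_map": self.comed_map,
                },
                indent=2,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CodingDictionary":
        raw = json.loads(Path(path).read_text())
        for key in ("insulin_map", "site_map", "comed_map"):
            if key not in raw:
                raise SchemaError(f"dictionary file missing key {key!r}")
        return cls(
            insulin_map=dict(raw["insulin_map"]),
            site_map={k.replace(".", "").upper(): v for k, v in raw["site_map"].items()},
            comed_map=dict(raw["comed_map"]),
        )


_ICD_SHAPE = re.compile(r"^[A-Za-z][0-9]{2}(\.?[0-9]{1,2})?$")


def classify_insulin(atc_code: str, dictionary: CodingDictionary | None = None) -> str:
    """Map an ATC code to ``human``/``glargine``/``detemir``/``other_insulin``
    or ``non_insulin``.  Total function: unknown codes are never an error."""
    if dictionary is None:
        dictionary = CodingDictionary.default()
    code = atc_code.strip().upper()
    hit = dictionary.insulin_map.get(code)
    if hit is not None:
        return hit
    if code.startswith("A10A"):
        return "other_insulin"
    return "non_insulin"


def classify_cancer_site(icd10_code: str, dictionary: CodingDictionary | None = None) -> str:
    """Map an ICD-10 code to a cancer-site label by longest-prefix match.

    Dots are ignored (``C88.4`` ≡ ``C884``).  Valid codes not covered by the
    site map fall into ``other_cancer``; strings that are not ICD-shaped raise
    :class:`RegistryParseError`.
    """
    if dictionary is None:
        dictionary = CodingDictionary.default()
    raw = icd10_code.strip()
    if not _ICD_SHAPE.match(raw):
        raise RegistryParseError(f"not an ICD-10-shaped code: {icd10_code!r}")
    code = raw.replace(".", "").upper()
    best: str | None = None
    best_len = 0
    for prefix, site in dictionary.site_map.items():
        if code.startswith(prefix) and len(prefix) > best_len:
            best, best_len = site, len(prefix)
    if best is not None:
        return best
    return "other_cancer"


@dataclass
class RegistryBundle:
    """The three raw tables plus coding dictionary and study periods.

    Date columns are pandas ``datetime64[ns]``; ``study_periods`` maps country
    to the (start, end) of its valid-data-collection window.
    """

    persons: pd.DataFrame
    prescriptions: pd.DataFrame
    events: pd.DataFrame
    dictionary: CodingDictionary = field(default_factory=CodingDictionary.default)
    study_periods: dict[str, tuple[pd.Timestamp, pd.Timestamp]] = field(
        default_factory=lambda: {
            c: (pd.Timestamp(a), pd.Timestamp(b)) for c, (a, b) in STUDY_PERIODS.items()
        }
    )

    def __eq__(self, other: object) -> bool:  # round-trip testing support
        if not isinstance(other, RegistryBundle):
            return NotImplemented
        return (
            self.persons.reset_index(drop=True).equals(other.persons.reset_index(drop=True))
            and self.prescriptions.reset_index(drop=True).equals(
                other.prescriptions.reset_index(drop=True)
            )
            and self.events.reset_index(drop=True).equals(other.events.reset_index(drop=True))
            and self.dictionary == other.dictionary
            and self.study_periods == other.study_periods
        )


PERSON_COLUMNS = ["person_id", "sex", "birth_date", "country", "data_start", "data_end"]
PRESCRIPTION_COLUMNS = ["person_id", "dispense_date", "atc_code", "ddd_amount"]
EVENT_COLUMNS = ["person_id", "event_date", "event_type", "diagnosis_code"]

_DATE_COLUMNS = {
    "persons": ["birth_date", "data_start", "data_end"],
    "prescriptions": ["dispense_date"],
    "events": ["event_date"],
}


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing columns: {missing}")


def _parse_dates(df: pd.DataFrame, cols: list[str], name: str) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        parsed = pd.to_datetime(out[col], format="ISO8601", errors="coerce")
        bad = out.index[parsed.isna() & out[col].notna()]
        if len(bad):
            vals = out.loc[bad[:5], col].tolist()
            raise RegistryParseError(
                f"{name}.{col}: unparsable dates at rows {bad[:5].tolist()} (values {vals})"
            )
        if parsed.isna().any():
            bad = out.index[parsed.isna()]
            raise RegistryParseError(f"{name}.{col}: missing dates at rows {bad[:5].tolist()}")
        out[col] = parsed
    return out


def validate_bundle(bundle: RegistryBundle) -> None:
    """Check schema, enum, referential and temporal invariants; raise on breach."""
    persons, rx, events = bundle.persons, bundle.prescriptions, bundle.events
    _require_columns(persons, PERSON_COLUMNS, "persons")
    _require_columns(rx, PRESCRIPTION_COLUMNS, "prescriptions")
    _require_columns(events, EVENT_COLUMNS, "events")

    if persons["person_id"].duplicated().any():
        dupes = persons.loc[persons["person_id"].duplicated(), "person_id"].tolist()[:5]
        raise ReferentialError(f"duplicate person_id values: {dupes}")
    bad_sex = ~persons["sex"].isin(SEXES)
    if bad_sex.any():
        raise SchemaError(f"persons.sex outside {SEXES}: rows {persons.index[bad_sex][:5].tolist()}")
    bad_country = ~persons["country"].isin(COUNTRIES)
    if bad_country.any():
        raise SchemaError(
            f"persons.country outside {COUNTRIES}: rows {persons.index[bad_country][:5].tolist()}"
        )
    bad_window = ~(
        (persons["birth_date"] < persons["data_start"])
        & (persons["data_start"] <= persons["data_end"])
    )
    if bad_window.any():
        raise SchemaError(
            "persons: require birth_date < data_start <= data_end; "
            f"violated at rows {persons.index[bad_window][:5].tolist()}"
        )

    known = set(persons["person_id"])
    for name, table in (("prescriptions", rx), ("events", events)):
        unknown = set(table["person_id"]) - known
        if unknown:
            raise ReferentialError(
                f"{name} reference unknown person_id(s): {sorted(unknown)[:5]}"
            )

    if (rx["ddd_amount"] <= 0).any():
        bad = rx.index[rx["ddd_amount"] <= 0][:5].tolist()
        raise SchemaError(f"prescriptions.ddd_amount must be > 0; rows {bad}")
    win = rx.merge(persons[["person_id", "data_start", "data_end"]], on="person_id")
    outside = ~(
        (win["dispense_date"] >= win["data_start"]) & (win["dispense_date"] <= win["data_end"])
    )
    if outside.any():
        raise SchemaError(
            "prescriptions: dispense_date outside person's observation window; "
            f"rows {win.index[outside][:5].tolist()}"
        )

    bad_type = ~events["event_type"].isin(EVENT_TYPES)
    if bad_type.any():
        raise SchemaError(
            f"events.event_type outside {EVENT_TYPES}: rows {events.index[bad_type][:5].tolist()}"
        )
    cancers = events["event_type"] == "cancer"
    codes = events["diagnosis_code"].fillna("").astype(str)
    if (cancers & (codes.str.strip() == "")).any():
        bad = events.index[cancers & (codes.str.strip() == "")][:5].tolist()
        raise SchemaError(f"cancer events require a diagnosis_code; rows {bad}")


def read_bundle(
    persons_path: str | Path,
    prescriptions_path: str | Path,
    events_path: str | Path,
    dictionary_path: str | Path | None = None,
    study_periods: dict[str, tuple[str, str]] | None = None,
) -> RegistryBundle:
    """Read and validate the three CSV tables (plus optional dictionary JSON)."""
    for p in (persons_path, prescriptions_path, events_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    persons = pd.read_csv(persons_path, dtype={"person_id": str})
    rx = pd.read_csv(prescriptions_path, dtype={"person_id": str, "atc_code": str})
    events = pd.read_csv(
        events_path, dtype={"person_id": str, "diagnosis_code": str}, keep_default_na=False
    )
    events["diagnosis_code"] = events["diagnosis_code"].replace({"": ""})
    _require_columns(persons, PERSON_COLUMNS, "persons")
    _require_columns(rx, PRESCRIPTION_COLUMNS, "prescriptions")
    _require_columns(events, EVENT_COLUMNS, "events")
    persons = _parse_dates(persons, _DATE_COLUMNS["persons"], "persons")
    rx = _parse_dates(rx, _DATE_COLUMNS["prescriptions"], "prescriptions")
    events = _parse_dates(events, _DATE_COLUMNS["events"], "events")
    rx["ddd_amount"] = pd.to_numeric(rx["ddd_amount"], errors="raise")

    dictionary = (
        CodingDictionary.from_json(dictionary_path)
        if dictionary_path is not None
        else CodingDictionary.default()
    )
    periods = {
        c: (pd.Timestamp(a), pd.Timestamp(b))
        for c, (a, b) in (study_periods or STUDY_PERIODS).items()
    }
    bundle = RegistryBundle(
        persons=persons[PERSON_COLUMNS],
        prescriptions=rx[PRESCRIPTION_COLUMNS],
        events=events[EVENT_COLUMNS],
        dictionary=dictionary,
        study_periods=periods,
    )
    validate_bundle(bundle)
    return bundle


def write_bundle(bundle: RegistryBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write persons/prescriptions/events CSVs and dictionary.json to ``out_dir``.

    Dates serialise as ISO-8601 dates; output is deterministic (stable row and
    column order) so identical bundles yield byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "persons": out / "persons.csv",
        "prescriptions": out / "prescriptions.csv",
        "events": out / "events.csv",
        "dictionary": out / "dictionary.json",
    }
    persons = bundle.persons.copy()
    for col in _DATE_COLUMNS["persons"]:
        persons[col] = persons[col].dt.strftime("%Y-%m-%d")
    persons[PERSON_COLUMNS].to_csv(paths["persons"], index=False)

    rx = bundle.prescriptions.copy()
    rx["dispense_date"] = rx["dispense_date"].dt.strftime("%Y-%m-%d")
    rx[PRESCRIPTION_COLUMNS].to_csv(paths["prescriptions"], index=False)

    events = bundle.events.copy()
    events["event_date"] = events["event_date"].dt.strftime("%Y-%m-%d")
    events[EVENT_COLUMNS].to_csv(paths["events"], index=False)

    bundle.dictionary.to_json(paths["dictionary"])
    return paths


def day_number(dates: pd.Series | pd.Timestamp) -> np.ndarray | int:
    """Integer day offset from 1970-01-01 (internal date arithmetic unit)."""
    if isinstance(dates, pd.Timestamp):
        return int(dates.value // 86_400_000_000_000)
    return (dates.values.astype("datetime64[D]")).astype("int64")
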