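"""Readers, writers and validators for the registry file schemas.

Six plain-text delimited schemas are supported, all with a mandatory
header row:

* **individual records** — one diagnosed patient per row: id, sex,
  disease group, age at diagnosis, month/year of diagnosis, month/year at
  end of follow-up, vital status (1 = dead, 0 = alive/censored), and
  follow-up in decimal years;
* **aggregated counts** — cases and person-years per
  sex x age-group x year x disease cell;
* **age-group scheme** — the age intervals used for stratification;
* **standard population** — one weight per age group, for direct
  standardization;
* **population distribution** — person-years per sex x age-group x year;
* **life table** — general-population annual survival probability per
  sex x single-year age x calendar year.

Comma and semicolon delimiters are auto-detected from the header line
(comma wins a tie).  Age-group indices in files are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    CoverageError,
    DuplicateKeyError,
    RowValidationError,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AgeGroupScheme",
    "read_individual_records",
    "read_aggregated",
    "write_aggregated",
    "read_age_groups",
    "read_standard_population",
    "read_population_distribution",
    "read_life_table",
    "aggregate_individuals",
    "validate_aggregated",
    "INDIVIDUAL_COLUMNS",
    "AGGREGATED_COLUMNS",
]

# Canonical (internal) name -> default file header, matching the
# individual-records layout: Patient_ID Sex d_group d_age i_month i_year
# f_month f_year Status Follow_up.
DEFAULT_INDIVIDUAL_SCHEMA: Mapping[str, str] = {
    "patient_id": "Patient_ID",
    "sex": "Sex",
    "group": "d_group",
    "age": "d_age",
    "diag_month": "i_month",
    "diag_year": "i_year",
    "end_month": "f_month",
    "end_year": "f_year",
    "status": "Status",
    "follow_up": "Follow_up",
}

INDIVIDUAL_COLUMNS = tuple(DEFAULT_INDIVIDUAL_SCHEMA)

AGGREGATED_FILE_COLUMNS: Mapping[str, str] = {
    "sex": "Sex",
    "age_group": "Age.group",
    "year": "Year",
    "group": "Group",
    "cases": "Cases",
    "person_years": "Population",
}

AGGREGATED_COLUMNS = tuple(AGGREGATED_FILE_COLUMNS)

AGGREGATED_KEY = ["sex", "age_group", "year", "group"]


# ---------------------------------------------------------------------------
# Age-group scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered, contiguous half-open age intervals ``[lower, upper)``.

    The first interval starts at age 0; only the last interval may be
    open-ended (``upper is None``).  Group indices are 1-based to match
    the file formats.
    """

    intervals: tuple[tuple[int, int | None], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise SchemaError("age-group scheme is empty")
        if self.intervals[0][0] != 0:
            raise SchemaError("first age group must start at age 0")
        prev_upper = 0
        for k, (lo, up) in enumerate(self.intervals, start=1):
            if lo != prev_upper:
                raise SchemaError(
                    f"age groups must be contiguous: group {k} starts at {lo}, "
                    f"expected {prev_upper}"
                )
            if up is None:
                if k != len(self.intervals):
                    raise SchemaError("only the last age group may be open-ended")
                break
            if up <= lo:
                raise SchemaError(f"age group {k} has non-positive width")
            prev_upper = up

    @classmethod
    def default(cls) -> "AgeGroupScheme":
        """Eighteen 5-year groups: 0-4, 5-9, ..., 80-84, 85+."""
        ivals = [(5 * i, 5 * (i + 1)) for i in range(17)]
        ivals.append((85, None))
        return cls(tuple(ivals))

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def indices(self) -> range:
        """1-based group indices."""
        return range(1, len(self.intervals) + 1)

    def index_of(self, age: float) -> int:
        """1-based index of the group containing ``age``.

        Ages above the last closed bound map to the open-ended final
        group when one exists.
        """
        if age < 0:
            raise RowValidationError(f"negative age {age}")
        for k, (lo, up) in enumerate(self.intervals, start=1):
            if up is None or lo <= age < up:
                return k
        raise RowValidationError(
            f"age {age} outside the age-group scheme (max {self.intervals[-1][1]})"
        )

    def lower(self, index: int) -> int:
        return self.intervals[index - 1][0]

    def upper(self, index: int) -> int | None:
        return self.intervals[index - 1][1]

    def width(self, index: int) -> int:
        lo, up = self.intervals[index - 1]
        if up is None:
            raise RowValidationError(f"age group {index} is open-ended; no width")
        return up - lo

    def label(self, index: int) -> str:
        lo, up = self.intervals[index - 1]
        return f"{lo}+" if up is None else f"{lo}-{up - 1}"

    def groups_within(self, lower: int, upper_exclusive: int) -> list[int]:
        """Indices of groups fully inside ``[lower, upper_exclusive)``.

        Raises :class:`AlignmentError` if the bounds do not coincide with
        group boundaries (so no group is split).
        """
        from .exceptions import AlignmentError

        lowers = [lo for lo, _ in self.intervals]
        uppers = [up for _, up in self.intervals]
        if lower not in lowers:
            raise AlignmentError(
                f"lower bound {lower} does not align with an age-group boundary"
            )
        if upper_exclusive not in [u for u in uppers if u is not None]:
            raise AlignmentError(
                f"upper bound {upper_exclusive} does not align with a closed "
                "age-group boundary"
            )
        out = []
        for k, (lo, up) in enumerate(self.intervals, start=1):
            if up is not None and lo >= lower and up <= upper_exclusive:
                out.append(k)
        return out


# ---------------------------------------------------------------------------
# Delimiter detection and generic reading
# ---------------------------------------------------------------------------


def detect_delimiter(path: str | Path) -> str:
    """Pick the delimiter from the header line: comma or semicolon.

    If both appear, comma wins.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if "," in header:
        return ","
    if ";" in header:
        return ";"
    return ","


def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    sep = delimiter or detect_delimiter(path)
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def _match_columns(
    df: pd.DataFrame, wanted: Mapping[str, str], what: str
) -> dict[str, str]:
    """Map canonical names to actual column names, case-insensitively."""
    lower = {c.lower(): c for c in df.columns}
    out: dict[str, str] = {}
    missing = []
    for canonical, header in wanted.items():
        if header.lower() in lower:
            out[canonical] = lower[header.lower()]
        elif canonical.lower() in lower:
            out[canonical] = lower[canonical.lower()]
        else:
            missing.append(header)
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")
    return out


def _to_num(value: str, row: int, column: str, kind=float):
    try:
        return kind(value)
    except (TypeError, ValueError):
        raise RowValidationError(
            f"row {row}: cannot parse {column}={value!r}"
        ) from None


# ---------------------------------------------------------------------------
# Individual records
# ---------------------------------------------------------------------------


def read_individual_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
    errors: str = "raise",
) -> pd.DataFrame | tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Read an individual-records file into a validated DataFrame.

    Parameters
    ----------
    schema
        Optional override mapping canonical column names
        (``patient_id, sex, group, age, diag_month, diag_year, end_month,
        end_year, status, follow_up``) to the file's headers.
    errors
        ``"raise"`` (default) raises :class:`RowValidationError` on the
        first bad row; ``"collect"`` returns ``(records, rejects)`` where
        *rejects* is a list of ``(row_number, reason)`` so that
        input rows = accepted + rejects.

    Validation: status in {0, 1}; follow_up >= 0; end date >= diagnosis
    date.  When follow-up disagrees with the date pair by more than one
    month, follow_up is taken as authoritative and a warning is logged.
    """
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")
    raw = _read_table(path, delimiter)
    cols = _match_columns(raw, dict(schema or DEFAULT_INDIVIDUAL_SCHEMA),
                          "individual records")
    rejects: list[tuple[int, str]] = []
    rows = []
    for pos, rec in enumerate(raw.itertuples(index=False), start=1):
        rec = dict(zip(raw.columns, rec))
        try:
            row = _parse_individual_row(rec, cols, pos)
        except RowValidationError as exc:
            if errors == "raise":
                raise
            rejects.append((pos, str(exc)))
            continue
        rows.append(row)
    out = pd.DataFrame(rows, columns=list(INDIVIDUAL_COLUMNS))
    if errors == "collect":
        return out, rejects
    return out


def _parse_individual_row(rec: Mapping[str, str], cols: Mapping[str, str],
                          pos: int) -> dict:
    row = {
        "patient_id": rec[cols["patient_id"]],
        "group": rec[cols["group"]],
        "sex": _to_num(rec[cols["sex"]], pos, "sex", int),
        "age": _to_num(rec[cols["age"]], pos, "age", int),
        "diag_month": _to_num(rec[cols["diag_month"]], pos, "diag_month", int),
        "diag_year": _to_num(rec[cols["diag_year"]], pos, "diag_year", int),
        "end_month": _to_num(rec[cols["end_month"]], pos, "end_month", int),
        "end_year": _to_num(rec[cols["end_year"]], pos, "end_year", int),
        "status": _to_num(rec[cols["status"]], pos, "status", int),
        "follow_up": _to_num(rec[cols["follow_up"]], pos, "follow_up", float),
    }
    if row["sex"] not in (1, 2):
        raise RowValidationError(f"row {pos}: sex must be 1 or 2, got {row['sex']}")
    if row["status"] not in (0, 1):
        raise RowValidationError(
            f"row {pos}: status must be 0 (alive) or 1 (dead), got {row['status']}"
        )
    if row["follow_up"] < 0:
        raise RowValidationError(
            f"row {pos}: follow_up must be >= 0, got {row['follow_up']}"
        )
    if row["age"] < 0:
        raise RowValidationError(f"row {pos}: negative age {row['age']}")
    if not (1 <= row["diag_month"] <= 12 and 1 <= row["end_month"] <= 12):
        raise RowValidationError(f"row {pos}: month outside 1-12")
    d_end = row["end_year"] + (row["end_month"] - 1) / 12.0
    d_diag = row["diag_year"] + (row["diag_month"] - 1) / 12.0
    if d_end < d_diag:
        raise RowValidationError(
            f"row {pos}: end of follow-up precedes diagnosis "
            f"({row['end_month']}/{row['end_year']} < "
            f"{row['diag_month']}/{row['diag_year']})"
        )
    # follow_up is authoritative; the redundant date pair only gets a warning.
    if abs((d_end - d_diag) - row["follow_up"]) > 1.0 / 12.0 + 1e-9:
        logger.warning(
            "row %d: follow_up %.2f differs from the diagnosis/end date span "
            "%.2f by more than one month; using follow_up",
            pos, row["follow_up"], d_end - d_diag,
        )
    return row


# ---------------------------------------------------------------------------
# Aggregated counts
# ---------------------------------------------------------------------------


def validate_aggregated(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an aggregated-counts DataFrame in canonical form.

    Canonical columns: sex, age_group, year, group, cases, person_years.
    """
    missing = [c for c in AGGREGATED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"aggregated data: missing column(s) {missing}")
    dup = df.duplicated(subset=AGGREGATED_KEY)
    if dup.any():
        key = df.loc[dup.idxmax(), AGGREGATED_KEY].tolist()
        raise DuplicateKeyError(
            f"duplicate (sex, age-group, year, group) key: {tuple(key)}"
        )
    if (df["cases"] < 0).any():
        i = int(df.index[df["cases"] < 0][0])
        raise RowValidationError(f"row {i + 1}: negative case count")
    if (df["person_years"] <= 0).any():
        i = int(df.index[df["person_years"] <= 0][0])
        raise RowValidationError(f"row {i + 1}: person-years must be > 0")
    return df


def read_aggregated(path: str | Path, *, delimiter: str | None = None
                    ) -> pd.DataFrame:
    """Read an aggregated-counts file (Sex, Age.group, Year, Group, Cases,
    Population) into the canonical DataFrame."""
    raw = _read_table(path, delimiter)
    cols = _match_columns(raw, dict(AGGREGATED_FILE_COLUMNS), "aggregated data")
    df = pd.DataFrame(
        {
            "sex": raw[cols["sex"]].map(lambda v: _to_num(v, 0, "sex", int)),
            "age_group": raw[cols["age_group"]].map(
                lambda v: _to_num(v, 0, "age_group", int)),
            "year": raw[cols["year"]].map(lambda v: _to_num(v, 0, "year", int)),
            "group": raw[cols["group"]],
            "cases": raw[cols["cases"]].map(lambda v: _to_num(v, 0, "cases", int)),
            "person_years": raw[cols["person_years"]].map(
                lambda v: _to_num(v, 0, "person_years", float)),
        }
    )
    return validate_aggregated(df)


def write_aggregated(df: pd.DataFrame, path: str | Path,
                     *, delimiter: str = ",") -> None:
    """Write canonical aggregated counts with the standard file headers."""
    validate_aggregated(df)
    out = df[list(AGGREGATED_COLUMNS)].rename(columns=AGGREGATED_FILE_COLUMNS)
    # person-years are whole numbers in registry practice; keep integers as
    # integers so round trips are byte-stable
    py = out["Population"]
    if (py == py.round()).all():
        out = out.assign(Population=py.astype(np.int64))
    out.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Auxiliary files
# ---------------------------------------------------------------------------


def read_age_groups(path: str | Path, *, delimiter: str | None = None
                    ) -> AgeGroupScheme:
    """Read an age-group file with columns Age.group, Lower, Upper.

    An empty/blank Upper marks the open-ended last group.
    """
    raw = _read_table(path, delimiter)
    cols = _match_columns(
        raw, {"age_group": "Age.group", "lower": "Lower", "upper": "Upper"},
        "age groups")
    raw = raw.sort_values(cols["age_group"],
                          key=lambda s: s.astype(int)).reset_index(drop=True)
    ivals = []
    for pos, rec in enumerate(raw.itertuples(index=False), start=1):
        rec = dict(zip(raw.columns, rec))
        lo = _to_num(rec[cols["lower"]], pos, "lower", int)
        up_raw = rec[cols["upper"]]
        if up_raw is None or (isinstance(up_raw, float) and np.isnan(up_raw)) \
                or str(up_raw).strip() == "":
            ivals.append((lo, None))
        else:
            # the file stores the inclusive upper age (e.g. 4 for 0-4)
            ivals.append((lo, _to_num(up_raw, pos, "upper", int) + 1))
    return AgeGroupScheme(tuple(ivals))


def write_age_groups(scheme: AgeGroupScheme, path: str | Path,
                     *, delimiter: str = ",") -> None:
    rows = []
    for k in scheme.indices:
        up = scheme.upper(k)
        rows.append({"Age.group": k, "Lower": scheme.lower(k),
                     "Upper": "" if up is None else up - 1})
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def read_standard_population(path: str | Path, *, delimiter: str | None = None
                             ) -> pd.Series:
    """Read a standard-population file (Age.group, Weight) into a Series
    indexed by 1-based age-group."""
    raw = _read_table(path, delimiter)
    cols = _match_columns(raw, {"age_group": "Age.group", "weight": "Weight"},
                          "standard population")
    idx = raw[cols["age_group"]].astype(int)
    w = raw[cols["weight"]].astype(float)
    if (w <= 0).any():
        raise RowValidationError("standard-population weights must be > 0")
    s = pd.Series(w.values, index=idx.values, name="weight").sort_index()
    if s.index.duplicated().any():
        raise DuplicateKeyError("duplicate age-group in standard population")
    return s


def write_standard_population(weights: pd.Series, path: str | Path,
                              *, delimiter: str = ",") -> None:
    pd.DataFrame({"Age.group": weights.index, "Weight": weights.values}
                 ).to_csv(path, sep=delimiter, index=False)


def read_population_distribution(path: str | Path,
                                 *, delimiter: str | None = None
                                 ) -> pd.DataFrame:
    """Read a population file (Sex, Age.group, Year, Population) of
    person-years at risk."""
    raw = _read_table(path, delimiter)
    cols = _match_columns(
        raw,
        {"sex": "Sex", "age_group": "Age.group", "year": "Year",
         "person_years": "Population"},
        "population distribution")
    df = pd.DataFrame({
        "sex": raw[cols["sex"]].astype(int),
        "age_group": raw[cols["age_group"]].astype(int),
        "year": raw[cols["year"]].astype(int),
        "person_years": raw[cols["person_years"]].astype(float),
    })
    if (df["person_years"] <= 0).any():
        raise RowValidationError("population person-years must be > 0")
    if df.duplicated(subset=["sex", "age_group", "year"]).any():
        raise DuplicateKeyError("duplicate (sex, age-group, year) in population")
    return df


def write_population_distribution(df: pd.DataFrame, path: str | Path,
                                  *, delimiter: str = ",") -> None:
    out = df.rename(columns={"sex": "Sex", "age_group": "Age.group",
                             "year": "Year", "person_years": "Population"})
    py = out["Population"]
    if (py == py.round()).all():
        out = out.assign(Population=py.astype(np.int64))
    out.to_csv(path, sep=delimiter, index=False)


def read_life_table(path: str | Path, *, delimiter: str | None = None
                    ) -> pd.Series:
    """Read a life-table file (Sex, Age, Year, Prob) into a Series indexed
    by (sex, age, year) holding the annual survival probability."""
    raw = _read_table(path, delimiter)
    cols = _match_columns(
        raw, {"sex": "Sex", "age": "Age", "year": "Year", "prob": "Prob"},
        "life table")
    p = raw[cols["prob"]].astype(float)
    if ((p <= 0) | (p > 1)).any():
        raise RowValidationError(
            "life-table survival probabilities must lie in (0, 1]")
    idx = pd.MultiIndex.from_arrays(
        [raw[cols["sex"]].astype(int), raw[cols["age"]].astype(int),
         raw[cols["year"]].astype(int)],
        names=["sex", "age", "year"])
    s = pd.Series(p.values, index=idx, name="prob")
    if s.index.duplicated().any():
        raise DuplicateKeyError("duplicate (sex, age, year) in life table")
    return s.sort_index()


def write_life_table(table: pd.Series, path: str | Path,
                     *, delimiter: str = ",") -> None:
    df = table.rename("Prob").reset_index()
    df.columns = ["Sex", "Age", "Year", "Prob"]
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Aggregation of individual records
# ---------------------------------------------------------------------------


def aggregate_individuals(
    records: pd.DataFrame,
    pop: pd.DataFrame,
    scheme: AgeGroupScheme | None = None,
) -> pd.DataFrame:
    """Tabulate individual records into aggregated counts.

    Each record is assigned to its (sex, age-group, diagnosis-year) cell;
    person-years are copied from the population distribution ``pop``.
    Every population cell is emitted for every disease group present, so
    cells with no cases appear with ``cases = 0``.  A record whose
    (sex, age-group, year) cell is absent from ``pop`` raises
    :class:`CoverageError`.
    """
    scheme = scheme or AgeGroupScheme.default()
    groups = sorted(records["group"].unique()) if len(records) else []
    rec = records.copy()
    if len(rec):
        rec["age_group"] = rec["age"].map(scheme.index_of)
        pop_keys = set(map(tuple, pop[["sex", "age_group", "year"]].values))
        cell_keys = rec[["sex", "age_group", "diag_year"]].drop_duplicates()
        for sex, ag, year in cell_keys.values:
            if (sex, ag, year) not in pop_keys:
                raise CoverageError(
                    f"population distribution lacks cell "
                    f"(sex={sex}, age_group={ag}, year={year})"
                )
    frames = []
    base = pop[["sex", "age_group", "year", "person_years"]]
    if not groups:
        out = base.copy()
        out["group"] = "all"
        out["cases"] = 0
        frames.append(out)
    for g in groups:
        counts = (
            rec[rec["group"] == g]
            .groupby(["sex", "age_group", "diag_year"])
            .size()
            .rename("cases")
            .reset_index()
            .rename(columns={"diag_year": "year"})
        )
        merged = base.merge(counts, on=["sex", "age_group", "year"], how="left")
        merged["cases"] = merged["cases"].fillna(0).astype(int)
        merged["group"] = g
        frames.append(merged)
    out = pd.concat(frames, ignore_index=True)
    out = out[list(AGGREGATED_COLUMNS)].sort_values(AGGREGATED_KEY
                                                    ).reset_index(drop=True)
    return validate_aggregated(out)
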