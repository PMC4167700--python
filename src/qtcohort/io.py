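"""Canonical data model for ECG interval tables.

The pipeline's currency is a table of per-ECG measurements: QT interval,
RR interval, sex, age and the manufacturer of the recording machine.
Internally everything is held in *seconds* — the correction formulas
(e.g. ``QT + (1 - RR)/7``) are only dimensionally correct in seconds —
while file I/O defaults to milliseconds, the unit clinical tables use.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("qt", "rr", "sex", "age", "manufacturer")
SEXES = ("female", "male")

_UNIT_FACTORS = {"ms": 1e-3, "s": 1.0}


@dataclass(frozen=True)
class IntervalRecord:
    """One ECG's automatic measurements.

    qt, rr are durations in seconds (strictly positive); sex is
    ``"female"`` or ``"male"``; age in years; manufacturer a free label.
    """

    qt: float
    rr: float
    sex: str
    age: float
    manufacturer: str

    def __post_init__(self) -> None:
        if not self.qt > 0:
            raise ValueError(f"qt must be positive, got {self.qt}")
        if not self.rr > 0:
            raise ValueError(f"rr must be positive, got {self.rr}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class RowRejection:
    """A data row dropped during parsing, with the rule that dropped it."""

    row: int
    reason: str


@dataclass
class IntervalTable:
    """Ordered collection of interval records backed by a DataFrame.

    ``data`` has columns qt, rr (seconds, float), sex (str), age (float),
    manufacturer (str). Row order is stable under write/read round-trips.
    """

    data: pd.DataFrame
    provenance: str = ""
    source_units: str = "s"
    rejections: list[RowRejection] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        self.data = self.data.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @classmethod
    def from_records(
        cls, records: Iterable[IntervalRecord], provenance: str = ""
    ) -> "IntervalTable":
        rows = [
            (r.qt, r.rr, r.sex, r.age, r.manufacturer) for r in records
        ]
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
        return cls(df, provenance=provenance)

    def records(self) -> Iterator[IntervalRecord]:
        for row in self.data.itertuples(index=False):
            yield IntervalRecord(row.qt, row.rr, row.sex, row.age, row.manufacturer)

    def manufacturers(self) -> list[str]:
        """Manufacturer labels in order of first appearance."""
        return list(pd.unique(self.data["manufacturer"]))

    def stratum_counts(self) -> pd.Series:
        """Record counts per (manufacturer, sex) stratum."""
        return self.data.groupby(["manufacturer", "sex"], sort=False).size()

    def subset(self, mask: np.ndarray | pd.Series) -> "IntervalTable":
        return IntervalTable(
            self.data.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            provenance=self.provenance,
            source_units=self.source_units,
        )


def _resolve_columns(
    columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map required names to actual header names, case-insensitively."""
    lower = {c.lower().strip(): c for c in columns}
    out: dict[str, str] = {}
    for name in REQUIRED_COLUMNS:
        wanted = (column_map or {}).get(name, name).lower()
        if wanted not in lower:
            raise ValueError(f"missing required column: {name!r}")
        out[name] = lower[wanted]
    return out


def read_interval_csv(
    source,
    units: str = "ms",
    column_map: Mapping[str, str] | None = None,
    provenance: str = "",
) -> IntervalTable:
    """Read an interval table from CSV, converting qt/rr to seconds.

    Rows with non-numeric qt/rr/age, non-positive qt/rr, or unknown sex
    are rejected individually (recorded in ``table.rejections``); a
    missing column or an empty file is a hard error.
    """
    if units not in _UNIT_FACTORS:
        raise ValueError(f"units must be one of {sorted(_UNIT_FACTORS)}, got {units!r}")
    try:
        raw = pd.read_csv(source, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ValueError("empty input: no header found") from None
    cols = _resolve_columns(raw.columns, column_map)

    factor = _UNIT_FACTORS[units]
    qt = pd.to_numeric(raw[cols["qt"]], errors="coerce")
    rr = pd.to_numeric(raw[cols["rr"]], errors="coerce")
    age = pd.to_numeric(raw[cols["age"]], errors="coerce")
    sex = raw[cols["sex"]].astype(str).str.strip().str.lower()
    manufacturer = raw[cols["manufacturer"]].astype(str).str.strip()

    rejections: list[RowRejection] = []
    keep = np.ones(len(raw), dtype=bool)

    def _reject(mask: pd.Series, reason: str) -> None:
        for i in raw.index[mask & keep]:
            rejections.append(RowRejection(int(i), reason))
        keep[np.asarray(mask)] = False

    _reject(qt.isna(), "non-numeric qt")
    _reject(rr.isna(), "non-numeric rr")
    _reject(age.isna(), "non-numeric age")
    _reject(qt.notna() & (qt <= 0), "non-positive qt")
    _reject(rr.notna() & (rr <= 0), "non-positive rr")
    _reject(~sex.isin(SEXES), "unrecognized sex")

    df = pd.DataFrame(
        {
            "qt": qt[keep] * factor,
            "rr": rr[keep] * factor,
            "sex": sex[keep],
            "age": age[keep],
            "manufacturer": manufacturer[keep],
        }
    )
    rejections.sort(key=lambda r: r.row)
    return IntervalTable(
        df, provenance=provenance or str(getattr(source, "name", source)),
        source_units=units, rejections=rejections,
    )


def write_interval_csv(table: IntervalTable, dest=None, units: str = "ms") -> str:
    """Write the table as CSV in the requested unit; returns the content.

    Values are written with enough digits (%.10g) that a read-back
    reproduces them to well below 1 ns.
    """
    if units not in _UNIT_FACTORS:
        raise ValueError(f"units must be one of {sorted(_UNIT_FACTORS)}, got {units!r}")
    factor = _UNIT_FACTORS[units]
    out = table.data.copy()
    out["qt"] = out["qt"] / factor
    out["rr"] = out["rr"] / factor
    buf = _io.StringIO()
    out.to_csv(buf, index=False, float_format="%.10g")
    content = buf.getvalue()
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(content)
        else:
            with open(dest, "w", encoding="utf-8") as fh:
                fh.write(content)
    return content


@dataclass
class ValidationReport:
    """Outcome of study-inclusion filtering."""

    kept: IntervalTable
    n_input: int
    n_kept: int
    rejected_by_rule: dict[str, int]

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_kept


def validate_table(table: IntervalTable, min_age: float = 20.0) -> ValidationReport:
    """Apply study-inclusion rules (adult age cut, inclusive) to a table.

    Positivity of qt/rr is re-checked defensively; the age filter keeps
    records with ``age >= min_age``.
    """
    df = table.data
    rules = {
        "non-positive qt": ~(df["qt"] > 0),
        "non-positive rr": ~(df["rr"] > 0),
        f"age < {min_age:g}": df["age"] < min_age,
    }
    keep = np.ones(len(df), dtype=bool)
    counts: dict[str, int] = {}
    for rule, bad in rules.items():
        newly = np.asarray(bad) & keep
        counts[rule] = int(newly.sum())
        keep &= ~np.asarray(bad)
    return ValidationReport(
        kept=table.subset(keep),
        n_input=len(df),
        n_kept=int(keep.sum()),
        rejected_by_rule=counts,
    )
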