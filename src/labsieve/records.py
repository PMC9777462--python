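"""Ingest long-format laboratory records into a case × analyte matrix.

Hospital lab exports are long-format tables: one row per measurement with a
case identifier, an analyte identifier/name, a value (numeric, or a token
such as ``arterial``/``venous`` for the type of blood collection), a unit and
optionally a collection timestamp.  This module pivots such records into a
:class:`LabMatrix` — a dense numeric matrix with an explicit observed-cell
mask — and derives a binary cohort label per case from ICD-10 diagnosis
codes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: logical column roles parse_records needs to find in the input table
REQUIRED_COLUMNS = ("case_id", "analyte_id", "analyte_name", "value", "unit")

_ICD_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}")


def _sniff_delimiter(path: Path) -> str:
    """Tab if the header line contains one, else comma."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


class SchemaError(ValueError):
    """A required column is missing from the input file / schema map."""


class UnitConflictError(ValueError):
    """One analyte appears with more than one distinct unit."""


@dataclass
class LabRecord:
    """One laboratory measurement (one row of the long-format export)."""

    case_id: str
    analyte_id: str
    analyte_name: str
    value: float | str
    unit: str
    timestamp: float | None = None

    def __post_init__(self) -> None:
        if not self.case_id or not self.analyte_id:
            raise ValueError("case_id and analyte_id must be non-empty")
        if isinstance(self.value, float) and not np.isfinite(self.value):
            raise ValueError(f"non-finite value for {self.analyte_id!r}")


@dataclass
class LabMatrix:
    """Case × analyte numeric matrix with an explicit missingness mask.

    ``values[i, j]`` is NaN wherever ``observed_mask[i, j]`` is False.
    Categorical analytes (two-level tokens) are stored 0/1 with the
    token → code map kept in ``encoding_map``.
    """

    values: np.ndarray
    observed_mask: np.ndarray
    cases: list[str]
    analytes: list[str]
    analyte_names: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    encoding_map: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask shapes differ")
        if self.values.shape != (len(self.cases), len(self.analytes)):
            raise ValueError("matrix shape inconsistent with case/analyte lists")
        if len(set(self.analytes)) != len(self.analytes):
            raise ValueError("analyte ids must be unique")
        if not np.all(np.isfinite(self.values[self.observed_mask])):
            raise ValueError("observed cells must be finite")

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_analytes(self) -> int:
        return len(self.analytes)

    def column(self, analyte_id: str) -> np.ndarray:
        return self.values[:, self.analytes.index(analyte_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cases, columns=self.analytes)

    def select_analytes(self, analyte_ids: list[str]) -> "LabMatrix":
        idx = [self.analytes.index(a) for a in analyte_ids]
        return LabMatrix(
            values=self.values[:, idx],
            observed_mask=self.observed_mask[:, idx],
            cases=list(self.cases),
            analytes=list(analyte_ids),
            analyte_names={a: self.analyte_names.get(a, a) for a in analyte_ids},
            units={a: self.units.get(a, "") for a in analyte_ids},
            encoding_map={a: m for a, m in self.encoding_map.items() if a in analyte_ids},
        )

    def select_cases(self, row_idx: np.ndarray) -> "LabMatrix":
        return LabMatrix(
            values=self.values[row_idx],
            observed_mask=self.observed_mask[row_idx],
            cases=[self.cases[i] for i in np.atleast_1d(row_idx)],
            analytes=list(self.analytes),
            analyte_names=dict(self.analyte_names),
            units=dict(self.units),
            encoding_map=dict(self.encoding_map),
        )


@dataclass
class CohortLabels:
    """Binary diagnosis indicator per case (1 = code in the target range)."""

    labels: dict[str, int]
    target_range: tuple[str, str] = ("I20", "I25")

    def vector(self, cases: list[str]) -> np.ndarray:
        missing = [c for c in cases if c not in self.labels]
        if missing:
            raise KeyError(f"cases without labels: {missing[:5]}")
        return np.array([self.labels[c] for c in cases], dtype=int)

    def subset(self, cases: list[str]) -> "CohortLabels":
        return CohortLabels({c: self.labels[c] for c in cases}, self.target_range)


def parse_records(path: str | Path, schema: dict[str, str] | None = None) -> list[LabRecord]:
    """Read a delimited long-format lab file into :class:`LabRecord` rows.

    ``schema`` maps the logical roles in :data:`REQUIRED_COLUMNS` (plus the
    optional ``timestamp``) to actual column names; by default the logical
    names themselves are used.  The delimiter (comma or tab) is sniffed.

    Per analyte, the value column is treated as numeric if at least one of
    its entries parses as a float; rows of a numeric analyte whose value does
    not parse are logged and skipped.  Analytes with no parseable value at
    all are kept as categorical tokens.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = schema or {c: c for c in REQUIRED_COLUMNS}
    try:
        df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    for role in REQUIRED_COLUMNS:
        col = schema.get(role)
        if col is None or col not in df.columns:
            raise SchemaError(f"schema column for {role!r} ({col!r}) not in file")
    ts_col = schema.get("timestamp", "timestamp")
    if ts_col not in df.columns:
        ts_col = None

    raw_values = df[schema["value"]]
    numeric = pd.to_numeric(raw_values, errors="coerce")
    analyte_col = df[schema["analyte_id"]]
    # an analyte is numeric if any of its values parse as a number
    analyte_is_numeric = numeric.notna().groupby(analyte_col).any()

    records: list[LabRecord] = []
    for i in range(len(df)):
        aid = analyte_col.iloc[i]
        if analyte_is_numeric.get(aid, False):
            if pd.isna(numeric.iloc[i]):
                logger.warning(
                    "row %d: unparseable numeric value %r for analyte %r; skipped",
                    i, raw_values.iloc[i], aid,
                )
                continue
            value: float | str = float(raw_values.iloc[i])  # exact strtod round-trip
        else:
            value = str(raw_values.iloc[i]).strip()
        ts = None
        if ts_col is not None and not pd.isna(df[ts_col].iloc[i]):
            ts = float(pd.to_numeric(df[ts_col].iloc[i]))
        records.append(
            LabRecord(
                case_id=str(df[schema["case_id"]].iloc[i]),
                analyte_id=str(aid),
                analyte_name=str(df[schema["analyte_name"]].iloc[i]),
                value=value,
                unit="" if pd.isna(df[schema["unit"]].iloc[i]) else str(df[schema["unit"]].iloc[i]),
                timestamp=ts,
            )
        )
    return records


def _dedup(group: list[tuple[int, LabRecord]], policy: str) -> LabRecord:
    if policy == "first_by_timestamp":
        return min(group, key=lambda t: (np.inf if t[1].timestamp is None else t[1].timestamp, t[0]))[1]
    if policy == "last":
        return group[-1][1]
    if policy == "mean":
        vals = [r.value for _, r in group]
        if not all(isinstance(v, float) for v in vals):
            raise ValueError("dedup='mean' not applicable to categorical analytes")
        rep = group[0][1]
        return LabRecord(rep.case_id, rep.analyte_id, rep.analyte_name,
                         float(np.mean(vals)), rep.unit, rep.timestamp)
    raise ValueError(f"unknown dedup policy {policy!r}")


def build_matrix(records: list[LabRecord], dedup: str = "first_by_timestamp") -> LabMatrix:
    """Pivot records to a case × analyte :class:`LabMatrix`.

    Duplicate (case, analyte) measurements are reduced per ``dedup``
    (default: earliest timestamp, the presentation value).  Two-level
    categorical analytes are encoded to {1, 0} over their sorted tokens with
    the mapping recorded; more than two levels is an error.  Mixed units for
    one analyte raise :class:`UnitConflictError`.
    """
    cases: list[str] = []
    analytes: list[str] = []
    seen_case: dict[str, int] = {}
    seen_analyte: dict[str, int] = {}
    groups: dict[tuple[str, str], list[tuple[int, LabRecord]]] = {}
    names: dict[str, str] = {}
    units: dict[str, set[str]] = {}
    for i, r in enumerate(records):
        if r.case_id not in seen_case:
            seen_case[r.case_id] = len(cases)
            cases.append(r.case_id)
        if r.analyte_id not in seen_analyte:
            seen_analyte[r.analyte_id] = len(analytes)
            analytes.append(r.analyte_id)
            names[r.analyte_id] = r.analyte_name
        groups.setdefault((r.case_id, r.analyte_id), []).append((i, r))
        units.setdefault(r.analyte_id, set()).add(r.unit)

    conflicts = {a: sorted(u) for a, u in units.items() if len(u) > 1}
    if conflicts:
        raise UnitConflictError(f"conflicting units per analyte: {conflicts}")

    # collect categorical token sets
    tokens: dict[str, set[str]] = {}
    for (_, aid), group in groups.items():
        for _, r in group:
            if isinstance(r.value, str):
                tokens.setdefault(aid, set()).add(r.value)
    encoding_map: dict[str, dict[str, int]] = {}
    for aid, toks in tokens.items():
        ordered = sorted(toks)
        if len(ordered) > 2:
            raise ValueError(f"analyte {aid!r} has >2 categorical levels: {ordered}")
        # two-level convention: first sorted token -> 1, second -> 0
        encoding_map[aid] = {ordered[0]: 1} if len(ordered) == 1 else {ordered[0]: 1, ordered[1]: 0}

    values = np.full((len(cases), len(analytes)), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    for (cid, aid), group in groups.items():
        rec = _dedup(group, dedup)
        v = encoding_map[aid][rec.value] if isinstance(rec.value, str) else rec.value
        values[seen_case[cid], seen_analyte[aid]] = v
        mask[seen_case[cid], seen_analyte[aid]] = True

    return LabMatrix(
        values=values,
        observed_mask=mask,
        cases=cases,
        analytes=analytes,
        analyte_names=names,
        units={a: next(iter(u)) for a, u in units.items()},
        encoding_map=encoding_map,
    )


def icd_category(code: str) -> str | None:
    """Normalized three-character ICD-10 category of ``code``, or None."""
    norm = code.strip().upper()
    m = _ICD_CATEGORY_RE.match(norm)
    if m is None:
        return None
    return m.group(0)


def label_cases(
    diagnoses: dict[str, list[str]],
    range_lo: str = "I20",
    range_hi: str = "I25",
) -> CohortLabels:
    """Binarize per-case ICD-10 code lists against a category interval.

    A case is labelled 1 iff at least one of its codes falls, by
    three-character category, lexicographically inside
    ``[range_lo, range_hi]`` (both endpoints inclusive, so I25.90 matches
    with the default I20–I25 range).  Primary and secondary diagnoses are
    not distinguished.  Malformed codes (no letter+digits prefix) are warned
    about and treated as non-matching.
    """
    labels: dict[str, int] = {}
    for case_id, codes in diagnoses.items():
        hit = 0
        for code in codes:
            cat = icd_category(code)
            if cat is None:
                logger.warning("case %r: malformed ICD-10 code %r ignored", case_id, code)
                continue
            if range_lo <= cat <= range_hi:
                hit = 1
        labels[case_id] = hit
    return CohortLabels(labels, (range_lo, range_hi))


def read_diagnoses(path: str | Path, case_col: str = "case_id", codes_col: str = "icd10_codes") -> dict[str, list[str]]:
    """Read a delimited diagnoses file with semicolon-separated ICD-10 codes."""
    df = pd.read_csv(path, sep=_sniff_delimiter(Path(path)), dtype=str)
    if case_col not in df.columns or codes_col not in df.columns:
        raise SchemaError(f"diagnoses file needs columns {case_col!r}, {codes_col!r}")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        raw = row[codes_col]
        codes = [] if pd.isna(raw) or not str(raw).strip() else str(raw).split(";")
        out[str(row[case_col])] = [c for c in (s.strip() for s in codes) if c]
    return out


def filter_troponin_cohort(
    matrix: LabMatrix, labels: CohortLabels, troponin_id: str
) -> tuple[LabMatrix, CohortLabels]:
    """Keep exactly the cases with an observed troponin measurement.

    This is the cohort preselection: troponin is on the lab request of every
    patient worked up for myocardial ischemia, so requiring a measured value
    defines the differential-diagnosis cohort and makes the troponin column
    100% observed in the output.
    """
    if troponin_id not in matrix.analytes:
        raise KeyError(f"troponin analyte {troponin_id!r} not in matrix")
    j = matrix.analytes.index(troponin_id)
    keep = np.flatnonzero(matrix.observed_mask[:, j])
    if keep.size == 0:
        logger.warning("no case has an observed %r value; empty cohort", troponin_id)
    sub = matrix.select_cases(keep)
    return sub, labels.subset(sub.cases)


def write_matrix(matrix: LabMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write the wide table (empty field = missing) plus a YAML sidecar."""
    path = Path(path)
    df = matrix.to_frame()
    df.index.name = "case_id"
    df.to_csv(path, sep="\t", na_rep="")
    meta = {
        "analyte_names": matrix.analyte_names,
        "units": matrix.units,
        "encoding_map": matrix.encoding_map,
    }
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.yaml")
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_matrix(path: str | Path, meta_path: str | Path | None = None) -> LabMatrix:
    """Inverse of :func:`write_matrix`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="case_id", dtype={"case_id": str})
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    values = df.to_numpy(dtype=float)
    return LabMatrix(
        values=values,
        observed_mask=np.isfinite(values),
        cases=[str(c) for c in df.index],
        analytes=[str(a) for a in df.columns],
        analyte_names=meta.get("analyte_names", {}),
        units=meta.get("units", {}),
        encoding_map=meta.get("encoding_map", {}),
    )
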