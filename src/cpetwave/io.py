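"""Reading and writing breath-by-breath CPET tables.

Two source dialects are built in: the MS/HF repository files (headers like
``HR(beats/min)``, gas volumes already in L/min) and the treadmill
healthy-subject files (bare headers, gas volumes in mL/min).  Both are
harmonized into :class:`~cpetwave.records.CPETRecord` via a
:class:`ColumnMap`; the canonical dialect round-trips records to disk.

Canonical CSV: comma separated, ``.`` decimal, one row per breath, header
row of canonical variable names, preceded by ``#``-prefixed comment lines
carrying subject id, condition and metadata.
"""

from __future__ import annotations

import enum
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cpetwave.errors import DataError, FormatError
from cpetwave.records import CANONICAL_VARIABLES, Condition, CPETRecord

#: Pseudo-variable name for the sample-time column.
TIME = "Time"


class Dialect(enum.Enum):
    GITHUB_MSHF = "GITHUB_MSHF"
    PHYSIONET_H = "PHYSIONET_H"
    CANONICAL = "CANONICAL"


@dataclass(frozen=True)
class ColumnMap:
    """Maps source CSV headers to canonical variable names.

    ``scale`` holds per-canonical-variable multiplicative unit conversions
    (applied after parsing).  When ``allow_missing`` is true, mapped columns
    absent from a file are silently skipped — used by the canonical dialect,
    whose files may legitimately carry any subset of variables.
    """

    dialect: Dialect
    mapping: dict[str, str]
    scale: dict[str, float] = field(default_factory=dict)
    allow_missing: bool = False

    def __post_init__(self) -> None:
        valid = set(CANONICAL_VARIABLES) | {TIME}
        for src, dst in self.mapping.items():
            if dst not in valid:
                raise FormatError(f"column map target {dst!r} (from {src!r}) is not canonical")
        for var, factor in self.scale.items():
            if not factor > 0:
                raise FormatError(f"scale factor for {var!r} must be positive, got {factor}")


GITHUB_MSHF_MAP = ColumnMap(
    dialect=Dialect.GITHUB_MSHF,
    mapping={
        "Time(min)": TIME,
        "METS": "METS",
        "HR(beats/min)": "HR",
        "VO2(L/min)": "VO2",
        "VCO2(L/min)": "VCO2",
        "RER": "RER",
        "VE(L/min)": "VE",
        "RR(breaths/min)": "RR",
        "Vtex(L)": "Vtex",
        "Vtin(L)": "Vtin",
    },
)

# Healthy-subject treadmill files: bare headers, VO2/VCO2 recorded in mL/min.
PHYSIONET_H_MAP = ColumnMap(
    dialect=Dialect.PHYSIONET_H,
    mapping={
        "time": TIME,
        "HR": "HR",
        "VO2": "VO2",
        "VCO2": "VCO2",
        "VE": "VE",
        "RR": "RR",
    },
    scale={"VO2": 1e-3, "VCO2": 1e-3},
)

CANONICAL_MAP = ColumnMap(
    dialect=Dialect.CANONICAL,
    mapping={name: name for name in (TIME, *CANONICAL_VARIABLES)},
    allow_missing=True,
)

BUILTIN_MAPS = {
    Dialect.GITHUB_MSHF: GITHUB_MSHF_MAP,
    Dialect.PHYSIONET_H: PHYSIONET_H_MAP,
    Dialect.CANONICAL: CANONICAL_MAP,
}


def _parse_comments(text: str) -> tuple[dict[str, str], dict[str, str]]:
    """Extract ``# key=value`` and ``# meta:key=value`` header comments."""
    head: dict[str, str] = {}
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, value = body.partition("=")
        key = key.strip()
        if key.startswith("meta:"):
            meta[key[5:]] = value.strip()
        else:
            head[key] = value.strip()
    return head, meta


def read_cpet_csv(
    path: str | Path,
    colmap: ColumnMap,
    condition: Condition | None = None,
    subject_id: str | None = None,
) -> CPETRecord:
    """Read one subject's CSV and harmonize it into a :class:`CPETRecord`.

    Non-numeric and missing cells are dropped per variable (sample order is
    otherwise preserved), and unit scale factors are applied.  ``condition``
    and ``subject_id`` default to values found in ``#`` header comments,
    else UNKNOWN / the file stem.

    Raises
    ------
    FormatError
        A mapped source column is absent (unless the map allows it).
    DataError
        A mapped variable ends up with zero finite samples.
    """
    path = Path(path)
    text = path.read_text()
    head, meta = _parse_comments(text)
    frame = pd.read_csv(
        _stdio.StringIO(text), comment="#", skip_blank_lines=True, float_precision="round_trip"
    )

    missing = [src for src in colmap.mapping if src not in frame.columns]
    if missing and not colmap.allow_missing:
        raise FormatError(f"{path.name}: missing mapped column(s): {', '.join(sorted(missing))}")

    signals: dict[str, np.ndarray] = {}
    time: np.ndarray | None = None
    for src, canonical in colmap.mapping.items():
        if src not in frame.columns:
            continue
        values = pd.to_numeric(frame[src], errors="coerce").to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        values = values * colmap.scale.get(canonical, 1.0)
        if canonical == TIME:
            time = values if values.size else None
            continue
        if values.size == 0:
            raise DataError(f"{path.name}: variable {canonical!r} has zero finite samples")
        signals[canonical] = values

    if condition is None:
        condition = Condition(head.get("condition", "UNKNOWN"))
    if subject_id is None:
        subject_id = head.get("subject_id", path.stem)
    record = CPETRecord(subject_id=subject_id, condition=condition, signals=signals, time=time, meta=meta)
    record.validate()
    return record


def write_canonical(record: CPETRecord, path: str | Path) -> None:
    """Write a record as canonical CSV, round-trippable via ``read_cpet_csv``
    with the CANONICAL column map."""
    record.validate()
    path = Path(path)

    columns: dict[str, np.ndarray] = {}
    if record.time is not None:
        columns[TIME] = np.asarray(record.time, dtype=float)
    for name in CANONICAL_VARIABLES:  # canonical column order
        if name in record.signals:
            columns[name] = record.signals[name]
    width = max(arr.size for arr in columns.values())
    padded = {
        name: np.concatenate([arr, np.full(width - arr.size, np.nan)]) for name, arr in columns.items()
    }

    lines = [f"# subject_id={record.subject_id}", f"# condition={record.condition.value}"]
    lines += [f"# meta:{key}={value}" for key, value in sorted(record.meta.items())]
    frame = pd.DataFrame(padded)
    with path.open("w") as handle:
        handle.write("\n".join(lines) + "\n")
        frame.to_csv(handle, index=False, lineterminator="\n")


def read_manifest(path: str | Path) -> list[tuple[str, Condition, str]]:
    """Read a cohort manifest CSV with columns subject_id, condition, filename."""
    frame = pd.read_csv(path, comment="#")
    required = {"subject_id", "condition", "filename"}
    if not required.issubset(frame.columns):
        raise FormatError(f"manifest {path}: needs columns {sorted(required)}")
    return [
        (str(row.subject_id), Condition(str(row.condition)), str(row.filename))
        for row in frame.itertuples()
    ]


def load_cohort(
    directory: str | Path,
    colmap: ColumnMap,
    ordering: list[tuple[str, Condition]] | list[tuple[str, Condition, str]],
    allow_duplicates: bool = False,
) -> list[CPETRecord]:
    """Load the listed subjects, preserving the given row order exactly.

    ``ordering`` entries are ``(subject_id, condition)`` pairs — the file is
    then ``<subject_id>.csv`` — or ``(subject_id, condition, filename)``
    triples.  The caller's ordering defines downstream feature-matrix rows
    (HF block first, then MS, then H), so it is never reordered here.
    """
    directory = Path(directory)
    entries = []
    for item in ordering:
        if len(item) == 2:
            subject_id, condition = item
            filename = f"{subject_id}.csv"
        else:
            subject_id, condition, filename = item
        entries.append((str(subject_id), condition, filename))

    ids = [subject_id for subject_id, _, _ in entries]
    duplicates = sorted({x for x in ids if ids.count(x) > 1})
    if duplicates and not allow_duplicates:
        raise DataError(f"duplicate subject id(s) in ordering: {', '.join(duplicates)}")

    absent = [subject_id for subject_id, _, filename in entries if not (directory / filename).exists()]
    if absent:
        raise DataError(f"missing subject file(s) for: {', '.join(absent)}")

    return [
        read_cpet_csv(directory / filename, colmap, condition=condition, subject_id=subject_id)
        for subject_id, condition, filename in entries
    ]
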