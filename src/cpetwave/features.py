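"""Feature-matrix layouts built from per-signal coefficient statistics.

Five layouts are supported.  ``X`` summarises each raw variable by its mean
and variance (2V columns).  The wavelet layouts summarise every band of a
3- or 5-level db2 decomposition — details d1..dL plus the approximation —
by mean and variance, giving 2V(L+1) columns: BW3/BW5 for the two-class
task (default 8 variables -> 64/96 columns), MW3/MW5 for the three-class
task (default 5 variables -> 40/60 columns).

Feature-name grammar: ``<VAR>__<component>__<mean|var>`` with component in
{raw, d1..d5, ap}.  Canonical column order is variable-major, then
component (d1..dL, ap), then statistic.
"""

from __future__ import annotations

import enum
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cpetwave.errors import ConfigError, DataError, DecompositionError, FormatError
from cpetwave.records import Condition, CPETRecord
from cpetwave.wavelets import BoundaryMode, WaveletDecomposition, decompose, max_levels


class Layout(enum.Enum):
    X = "X"
    BW3 = "BW3"
    BW5 = "BW5"
    MW3 = "MW3"
    MW5 = "MW5"


#: Wavelet depth per layout (None = raw statistics only).
LAYOUT_LEVELS: dict[Layout, int | None] = {
    Layout.X: None,
    Layout.BW3: 3,
    Layout.BW5: 5,
    Layout.MW3: 3,
    Layout.MW5: 5,
}

# Eight of the nine two-class variables; Vtex is dropped as redundant with
# Vtin so that X has 16 columns and BW3/BW5 have 64/96.
BINARY_VARIABLES = ("METS", "HR", "VO2", "VCO2", "RER", "VE", "RR", "Vtin")

# Three-class task uses only variables available for all cohorts.
MULTI_VARIABLES = ("HR", "VO2", "VCO2", "VE", "RR")


def default_variables(layout: Layout) -> tuple[str, ...]:
    return MULTI_VARIABLES if layout in (Layout.MW3, Layout.MW5) else BINARY_VARIABLES


@dataclass
class FeatureConfig:
    """Configuration for :func:`build_feature_matrix`.

    ``variance_ddof=1`` selects the unbiased (n-1 denominator) convention.
    """

    layout: Layout
    variables: tuple[str, ...] | None = None
    wavelet: str = "db2"
    boundary_mode: BoundaryMode = BoundaryMode.SYMMETRIC
    variance_ddof: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.layout, str):
            self.layout = Layout(self.layout)
        if self.variables is None:
            self.variables = default_variables(self.layout)
        self.variables = tuple(self.variables)
        if not self.variables:
            raise ConfigError("at least one variable is required")
        if self.variance_ddof not in (0, 1):
            raise ConfigError("variance_ddof must be 0 (biased) or 1 (unbiased)")

    @property
    def levels(self) -> int | None:
        return LAYOUT_LEVELS[self.layout]

    def components(self) -> tuple[str, ...]:
        if self.levels is None:
            return ("raw",)
        return tuple(f"d{k + 1}" for k in range(self.levels)) + ("ap",)

    def feature_names(self) -> list[str]:
        return [
            f"{var}__{comp}__{stat}"
            for var in self.variables
            for comp in self.components()
            for stat in ("mean", "var")
        ]


@dataclass
class FeatureMatrix:
    """Subjects x features table with labels, in cohort row order."""

    layout: Layout
    values: np.ndarray
    feature_names: list[str]
    labels: list[Condition]
    row_ids: list[str]
    variables: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("feature values must be 2-D")
        n_rows, n_cols = self.values.shape
        if n_cols != len(self.feature_names):
            raise DataError("feature_names length does not match column count")
        if n_rows != len(self.labels) or n_rows != len(self.row_ids):
            raise DataError("labels/row_ids length does not match row count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def classes(self) -> list[Condition]:
        """Distinct labels in first-appearance (cohort block) order."""
        seen: list[Condition] = []
        for label in self.labels:
            if label not in seen:
                seen.append(label)
        return seen

    def restrict(self, keep: list[Condition]) -> "FeatureMatrix":
        mask = np.array([label in keep for label in self.labels])
        return FeatureMatrix(
            layout=self.layout,
            values=self.values[mask],
            feature_names=list(self.feature_names),
            labels=[l for l in self.labels if l in keep],
            row_ids=[r for r, m in zip(self.row_ids, mask) if m],
            variables=self.variables,
        )


def summarize(
    dec: WaveletDecomposition, variance_ddof: int = 1
) -> list[tuple[str, float, float]]:
    """(component, mean, variance) per band in canonical order d1..dL, ap."""
    out = []
    for name, band in dec.components():
        ddof = variance_ddof if band.size > variance_ddof else 0
        out.append((name, float(np.mean(band)), float(np.var(band, ddof=ddof))))
    return out


def _signal_stats(record: CPETRecord, var: str, config: FeatureConfig) -> list[float]:
    signal = record.signals[var]
    ddof = config.variance_ddof
    if config.levels is None:
        use_ddof = ddof if signal.size > ddof else 0
        return [float(np.mean(signal)), float(np.var(signal, ddof=use_ddof))]
    try:
        dec = decompose(signal, config.levels, config.boundary_mode, config.wavelet)
    except DecompositionError as exc:
        raise DecompositionError(f"subject {record.subject_id!r}, variable {var!r}: {exc}") from exc
    row: list[float] = []
    for _, mean, var_ in summarize(dec, ddof):
        row += [mean, var_]
    return row


def build_feature_matrix(cohort: list[CPETRecord], config: FeatureConfig) -> FeatureMatrix:
    """Assemble the configured layout for a cohort, one row per subject.

    Deterministic: identical cohort and config give a bitwise-identical
    matrix.  Rows follow the cohort order (HF block, MS block, H block).
    """
    if not cohort:
        raise DataError("empty cohort")
    rows = []
    for record in cohort:
        missing = [v for v in config.variables if v not in record.signals]
        if missing:
            raise DataError(
                f"subject {record.subject_id!r} is missing variable(s): {', '.join(missing)}"
            )
        if config.levels is not None:
            for var in config.variables:
                n = record.signals[var].size
                if config.levels > max_levels(n, config.wavelet, config.boundary_mode):
                    raise DecompositionError(
                        f"subject {record.subject_id!r}, variable {var!r}: signal of "
                        f"length {n} too short for {config.levels} levels"
                    )
        row: list[float] = []
        for var in config.variables:
            row += _signal_stats(record, var, config)
        rows.append(row)

    values = np.array(rows, dtype=float)
    if not np.isfinite(values).all():
        raise DataError("non-finite feature values produced")
    return FeatureMatrix(
        layout=config.layout,
        values=values,
        feature_names=config.feature_names(),
        labels=[record.condition for record in cohort],
        row_ids=[record.subject_id for record in cohort],
        variables=config.variables,
    )


_NAME_STATS = ("mean", "var")
_NAME_COMPONENTS = ("raw", "d1", "d2", "d3", "d4", "d5", "ap")


def _parse_feature_name(name: str) -> tuple[str, str, str]:
    parts = name.split("__")
    if len(parts) != 3 or parts[1] not in _NAME_COMPONENTS or parts[2] not in _NAME_STATS:
        raise FormatError(f"unknown feature name {name!r}")
    return parts[0], parts[1], parts[2]


def save_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Write ``subject_id,label,<features...>`` CSV with layout metadata in
    ``#`` comments."""
    path = Path(path)
    frame = pd.DataFrame(fm.values, columns=fm.feature_names)
    frame.insert(0, "label", [label.value for label in fm.labels])
    frame.insert(0, "subject_id", fm.row_ids)
    header = [f"# layout={fm.layout.value}", f"# variables={','.join(fm.variables)}"]
    with path.open("w") as handle:
        handle.write("\n".join(header) + "\n")
        frame.to_csv(handle, index=False, lineterminator="\n")


def load_features(path: str | Path) -> FeatureMatrix:
    """Load a feature CSV, restoring canonical column order by name."""
    path = Path(path)
    text = path.read_text()
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    if "layout" not in meta or "variables" not in meta:
        raise FormatError(f"{path.name}: missing '# layout=' / '# variables=' header comments")
    layout = Layout(meta["layout"])
    variables = tuple(v for v in meta["variables"].split(",") if v)

    frame = pd.read_csv(_stdio.StringIO(text), comment="#", float_precision="round_trip")
    if "subject_id" not in frame.columns or "label" not in frame.columns:
        raise FormatError(f"{path.name}: missing subject_id/label columns")
    present = [c for c in frame.columns if c not in ("subject_id", "label")]
    for name in present:
        _parse_feature_name(name)

    config = FeatureConfig(layout=layout, variables=variables)
    canonical = config.feature_names()
    missing = sorted(set(canonical) - set(present))
    extra = sorted(set(present) - set(canonical))
    if missing or extra:
        detail = []
        if missing:
            detail.append(f"missing: {', '.join(missing[:4])}")
        if extra:
            detail.append(f"unexpected: {', '.join(extra[:4])}")
        raise FormatError(f"{path.name}: feature columns do not match layout ({'; '.join(detail)})")

    return FeatureMatrix(
        layout=layout,
        values=frame[canonical].to_numpy(dtype=float),
        feature_names=canonical,
        labels=[Condition(v) for v in frame["label"]],
        row_ids=[str(v) for v in frame["subject_id"]],
        variables=variables,
    )
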