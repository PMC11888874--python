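"""Canonical in-memory representation of one subject's CPET recording."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from cpetwave.errors import DataError

#: Canonical breath-by-breath variable names understood by the pipeline.
CANONICAL_VARIABLES = ("HR", "VO2", "VCO2", "VE", "RR", "METS", "RER", "Vtex", "Vtin")


class Condition(enum.Enum):
    """Subject condition label. Class indices follow the cohort layout:
    heart failure first, metabolic syndrome second, healthy third."""

    HF = "HF"
    MS = "MS"
    H = "H"
    UNKNOWN = "UNKNOWN"


#: Block order used everywhere a cohort is laid out row by row.
CONDITION_ORDER = (Condition.HF, Condition.MS, Condition.H)


@dataclass
class CPETRecord:
    """One subject's harmonized multichannel breath-by-breath recording.

    ``signals`` maps canonical variable names to 1-D float arrays ordered by
    time.  Vectors of different variables may have different lengths (cells
    dropped during cleaning are dropped per variable, not per breath).
    """

    subject_id: str
    condition: Condition
    signals: dict[str, np.ndarray]
    time: np.ndarray | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, values in self.signals.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1:
                raise DataError(f"signal {name!r} of subject {self.subject_id!r} is not 1-D")
            clean[name] = arr
        self.signals = clean

    def validate(self) -> None:
        """Raise :class:`DataError` unless every signal has >= 1 finite sample."""
        if not self.signals:
            raise DataError(f"record {self.subject_id!r} has no signals")
        for name, arr in self.signals.items():
            if arr.size == 0 or not np.isfinite(arr).all():
                raise DataError(
                    f"signal {name!r} of subject {self.subject_id!r} must hold "
                    f"at least one finite sample and no non-finite values"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CPETRecord):
            return NotImplemented
        if (self.subject_id, self.condition, self.meta) != (
            other.subject_id,
            other.condition,
            other.meta,
        ):
            return False
        if set(self.signals) != set(other.signals):
            return False
        for name in self.signals:
            if not np.array_equal(self.signals[name], other.signals[name]):
                return False
        if (self.time is None) != (other.time is None):
            return False
        if self.time is not None and not np.array_equal(self.time, other.time):
            return False
        return True
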