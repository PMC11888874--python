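"""Seeded synthetic CPET cohorts with rest / ramp / recovery structure.

Each subject's variables follow a piecewise trajectory: constant baseline
during rest, a linear ramp to a class-dependent peak during exercise, and
an exponential relaxation back toward baseline, with AR(1) breath-to-breath
noise on top.  Class effects scale with a single separation knob ``delta``:
at ``delta = 0`` all classes are drawn from the same distribution; for
``delta > 0`` heart failure has the most blunted exercise response,
metabolic syndrome an intermediate one (plus a raised baseline heart
rate), and healthy subjects the full response — so peak VO2 orders
HF < MS < H by construction.

The generator exists to make every pipeline stage testable without real
recordings; it aims for plausible structure, not physiological fidelity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cpetwave.errors import ConfigError
from cpetwave.records import CANONICAL_VARIABLES, Condition, CONDITION_ORDER, CPETRecord

#: Healthy-subject trajectory defaults per variable:
#: (baseline level, peak level, recovery time constant as a fraction of the
#: recovery-phase length).
DEFAULT_VARIABLE_PARAMS: dict[str, tuple[float, float, float]] = {
    "HR": (70.0, 165.0, 0.25),
    "VO2": (0.30, 2.80, 0.25),
    "VCO2": (0.25, 3.10, 0.25),
    "VE": (10.0, 95.0, 0.25),
    "RR": (14.0, 42.0, 0.30),
    "METS": (1.0, 11.0, 0.25),
    "RER": (0.82, 1.15, 0.30),
    "Vtex": (0.60, 2.40, 0.30),
    "Vtin": (0.60, 2.40, 0.30),
}

#: Severity of the blunted exercise response per class (scales with delta).
DEFAULT_CLASS_SEVERITY: dict[Condition, float] = {
    Condition.HF: 1.0,
    Condition.MS: 0.5,
    Condition.H: 0.0,
}

#: Relative baseline-HR elevation per class (scales with delta).
DEFAULT_BASELINE_HR_SHIFT: dict[Condition, float] = {
    Condition.HF: 0.0,
    Condition.MS: 0.03,
    Condition.H: 0.0,
}

# Per unit of delta*severity the ramp amplitude shrinks by this fraction.
_AMPLITUDE_EFFECT = 0.12
_MAX_AMPLITUDE_REDUCTION = 0.95


@dataclass
class SyntheticConfig:
    n_per_class: int = 15
    classes: tuple[Condition, ...] = (Condition.HF, Condition.MS, Condition.H)
    n_breaths: tuple[int, int] = (120, 480)
    phase_fractions: tuple[float, float, float] = (0.2, 0.5, 0.3)  # rest, exercise, recovery
    variables: tuple[str, ...] = CANONICAL_VARIABLES
    variable_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLE_PARAMS)
    )
    class_severity: dict[Condition, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SEVERITY)
    )
    baseline_hr_shift: dict[Condition, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_HR_SHIFT)
    )
    delta: float = 1.0
    noise_fraction: float = 0.05  # noise sd as a fraction of (peak - baseline)
    noise_rho: float = 0.3  # AR(1) breath-to-breath correlation
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigError(f"n_per_class must be >= 1, got {self.n_per_class}")
        self.classes = tuple(
            Condition(c) if isinstance(c, str) else c for c in self.classes
        )
        if not self.classes or any(c not in CONDITION_ORDER for c in self.classes):
            raise ConfigError("classes must be a non-empty subset of {HF, MS, H}")
        lo, hi = self.n_breaths
        if not 3 <= lo <= hi:
            raise ConfigError(f"invalid n_breaths range {self.n_breaths} (need 3 <= min <= max)")
        fractions = np.asarray(self.phase_fractions, dtype=float)
        if fractions.shape != (3,) or (fractions <= 0).any() or abs(fractions.sum() - 1) > 1e-9:
            raise ConfigError("phase_fractions must be three positive numbers summing to 1")
        if self.delta < 0:
            raise ConfigError("delta must be nonnegative")
        if not 0 <= self.noise_rho < 1:
            raise ConfigError("noise_rho must lie in [0, 1)")
        for var in self.variables:
            if var not in self.variable_params:
                raise ConfigError(f"no trajectory parameters for variable {var!r}")
            baseline, peak, tau = self.variable_params[var]
            if peak < baseline or tau <= 0:
                raise ConfigError(f"variable {var!r}: need peak >= baseline and tau > 0")


def _class_params(cfg: SyntheticConfig, cls: Condition, var: str) -> tuple[float, float]:
    """(baseline, peak) for one class and variable at the configured delta."""
    baseline, peak, _ = cfg.variable_params[var]
    severity = cfg.class_severity.get(cls, 0.0)
    reduction = min(cfg.delta * _AMPLITUDE_EFFECT * severity, _MAX_AMPLITUDE_REDUCTION)
    amplitude = (peak - baseline) * (1.0 - reduction)
    if var == "HR":
        baseline = baseline * (1.0 + cfg.delta * cfg.baseline_hr_shift.get(cls, 0.0))
    return baseline, baseline + amplitude


def _trajectory(cfg: SyntheticConfig, cls: Condition, var: str, n: int) -> np.ndarray:
    baseline, peak, tau_frac = (*_class_params(cfg, cls, var), cfg.variable_params[var][2])
    n_rest = max(1, round(cfg.phase_fractions[0] * n))
    n_exercise = max(1, round(cfg.phase_fractions[1] * n))
    n_recovery = max(1, n - n_rest - n_exercise)
    n_rest = n - n_exercise - n_recovery  # absorb rounding into the rest phase

    rest = np.full(n_rest, baseline)
    ramp = baseline + (peak - baseline) * np.linspace(0.0, 1.0, n_exercise)
    tau = max(tau_frac * n_recovery, 1e-9)
    t = np.arange(1, n_recovery + 1)
    recovery = baseline + (peak - baseline) * np.exp(-t / tau)
    return np.concatenate([rest, ramp, recovery])


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    # stationary AR(1): marginal standard deviation equals sd
    shocks = rng.normal(0.0, 1.0, size=n)
    noise = np.empty(n)
    noise[0] = shocks[0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        noise[t] = rho * noise[t - 1] + scale * shocks[t]
    return sd * noise


def generate_subject(
    cls: Condition, cfg: SyntheticConfig, rng: np.random.Generator, subject_id: str | None = None
) -> CPETRecord:
    """Draw one subject: trajectory per variable plus AR(1) noise, with a
    per-subject breath count drawn uniformly from ``cfg.n_breaths``."""
    lo, hi = cfg.n_breaths
    n = int(rng.integers(lo, hi + 1))
    signals = {}
    for var in cfg.variables:
        baseline, peak, _ = cfg.variable_params[var]
        sd = cfg.noise_fraction * (peak - baseline)
        clean = _trajectory(cfg, cls, var, n)
        noise = _ar1_noise(rng, n, sd, cfg.noise_rho) if sd > 0 else np.zeros(n)
        signals[var] = clean + noise
    if subject_id is None:
        subject_id = f"SYN-{cls.value}"
    record = CPETRecord(subject_id=subject_id, condition=cls, signals=signals)
    record.validate()
    return record


def generate_cohort(cfg: SyntheticConfig) -> list[CPETRecord]:
    """Full cohort in class-block order HF, MS, H (restricted to the
    requested classes), ``cfg.n_per_class`` subjects per block."""
    rng = np.random.default_rng(cfg.seed)
    cohort = []
    for cls in CONDITION_ORDER:
        if cls not in cfg.classes:
            continue
        for i in range(cfg.n_per_class):
            cohort.append(
                generate_subject(cls, cfg, rng, subject_id=f"SYN-{cls.value}-{i + 1:03d}")
            )
    return cohort


def write_fixture_cohort(cfg: SyntheticConfig, directory: str | Path) -> Path:
    """Write the cohort as canonical CSVs plus a manifest; returns the
    manifest path.  Regenerating with the same config is byte-identical."""
    from cpetwave.io import write_canonical  # deferred: io imports records only

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg)

    lines = ["subject_id,condition,filename"]
    for record in cohort:
        filename = f"{record.subject_id}.csv"
        write_canonical(record, directory / filename)
        lines.append(f"{record.subject_id},{record.condition.value},{filename}")
    manifest = directory / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")

    echo = {
        "n_per_class": cfg.n_per_class,
        "classes": [c.value for c in cfg.classes],
        "n_breaths": list(cfg.n_breaths),
        "phase_fractions": list(cfg.phase_fractions),
        "variables": list(cfg.variables),
        "delta": cfg.delta,
        "noise_fraction": cfg.noise_fraction,
        "noise_rho": cfg.noise_rho,
        "seed": cfg.seed,
    }
    (directory / "manifest_config.json").write_text(json.dumps(echo, indent=1) + "\n")
    return manifest
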