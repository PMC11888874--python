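"""Multilevel discrete wavelet transform for irregular breath-by-breath series.

Implements the orthogonal Daubechies DWT directly (the runtime ships no
wavelet library): analysis by convolution of the boundary-extended signal
with the decomposition filters followed by dyadic downsampling, synthesis
by zero-upsampling and convolution with the reconstruction filters.

Two boundary modes:

* ``symmetric`` — half-point symmetric extension; the default.  Constant
  signals produce exactly-zero detail bands and reconstruction is exact.
* ``periodization`` — circular transform (odd lengths padded by repeating
  the last sample).  Orthonormal, so coefficient energy equals signal
  energy exactly for even-length inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from cpetwave.errors import DataError, DecompositionError

_SQRT2 = np.sqrt(2.0)
_SQRT3 = np.sqrt(3.0)

#: Orthonormal scaling (reconstruction low-pass) filters.
_SCALING_FILTERS: dict[str, np.ndarray] = {
    "db1": np.array([1.0, 1.0]) / _SQRT2,
    "db2": np.array([1.0 + _SQRT3, 3.0 + _SQRT3, 3.0 - _SQRT3, 1.0 - _SQRT3]) / (4.0 * _SQRT2),
}


class BoundaryMode(enum.Enum):
    SYMMETRIC = "symmetric"
    PERIODIZATION = "periodization"


def filter_bank(wavelet: str = "db2") -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (dec_lo, dec_hi, rec_lo, rec_hi) for an orthogonal wavelet."""
    if wavelet not in _SCALING_FILTERS:
        raise DataError(f"unknown wavelet {wavelet!r}; available: {sorted(_SCALING_FILTERS)}")
    rec_lo = _SCALING_FILTERS[wavelet]
    dec_lo = rec_lo[::-1].copy()
    signs = (-1.0) ** np.arange(rec_lo.size)
    dec_hi = signs * rec_lo  # quadrature mirror of the scaling filter
    rec_hi = dec_hi[::-1].copy()
    return dec_lo, dec_hi, rec_lo, rec_hi


@dataclass
class WaveletDecomposition:
    """Detail bands ``d1..dL`` (fine to coarse) plus the level-L approximation."""

    details: list[np.ndarray]
    approximation: np.ndarray
    boundary_mode: BoundaryMode
    wavelet: str
    level_lengths: list[int]  # input length at each analysis level, for inversion

    @property
    def levels(self) -> int:
        return len(self.details)

    def components(self) -> list[tuple[str, np.ndarray]]:
        """Coefficient vectors in canonical order d1, d2, ..., dL, ap."""
        out = [(f"d{k + 1}", band) for k, band in enumerate(self.details)]
        out.append(("ap", self.approximation))
        return out


def _dwt_symmetric(x: np.ndarray, dec_lo: np.ndarray, dec_hi: np.ndarray):
    width = dec_lo.size - 1
    ext = np.pad(x, (width, width), mode="symmetric")
    ca = np.convolve(ext, dec_lo, mode="valid")[1::2]
    cd = np.convolve(ext, dec_hi, mode="valid")[1::2]
    return ca, cd


def _idwt_symmetric(ca, cd, rec_lo, rec_hi, out_len: int) -> np.ndarray:
    up_a = np.zeros(2 * ca.size)
    up_d = np.zeros(2 * cd.size)
    up_a[::2] = ca
    up_d[::2] = cd
    y = np.convolve(up_a, rec_lo) + np.convolve(up_d, rec_hi)
    start = rec_lo.size - 2
    return y[start : start + out_len]


def _dwt_periodized(x: np.ndarray, rec_lo: np.ndarray, rec_hi: np.ndarray):
    if x.size % 2:
        x = np.append(x, x[-1])
    n = x.size
    k = np.arange(n // 2)
    ca = np.zeros(n // 2)
    cd = np.zeros(n // 2)
    for m in range(rec_lo.size):
        idx = (2 * k + m) % n
        ca += rec_lo[m] * x[idx]
        cd += rec_hi[m] * x[idx]
    return ca, cd


def _idwt_periodized(ca, cd, rec_lo, rec_hi, out_len: int) -> np.ndarray:
    n = 2 * ca.size
    y = np.zeros(n)
    k = np.arange(ca.size)
    for m in range(rec_lo.size):
        idx = (2 * k + m) % n
        np.add.at(y, idx, rec_lo[m] * ca + rec_hi[m] * cd)
    return y[:out_len]


def max_levels(
    n: int, wavelet: str = "db2", boundary_mode: BoundaryMode = BoundaryMode.SYMMETRIC
) -> int:
    """Deepest decomposition for which every analysis step sees a signal at
    least as long as the filter."""
    filt_len = _SCALING_FILTERS[wavelet].size if wavelet in _SCALING_FILTERS else None
    if filt_len is None:
        raise DataError(f"unknown wavelet {wavelet!r}")
    levels = 0
    while n >= filt_len:
        if boundary_mode is BoundaryMode.SYMMETRIC:
            n = (n + filt_len - 1) // 2
        else:
            n = (n + 1) // 2
        levels += 1
    return levels


def decompose(
    signal: np.ndarray,
    levels: int,
    boundary_mode: BoundaryMode = BoundaryMode.SYMMETRIC,
    wavelet: str = "db2",
) -> WaveletDecomposition:
    """Run a ``levels``-deep DWT, recursively splitting the approximation band.

    Raises :class:`DecompositionError` if the signal is too short for the
    requested depth (the message states the maximum feasible depth) and
    :class:`DataError` on non-finite samples.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise DataError("decompose expects a 1-D signal")
    if not np.isfinite(x).all():
        raise DataError("signal contains non-finite samples")
    if levels < 1:
        raise DecompositionError(f"levels must be >= 1, got {levels}")
    dec_lo, dec_hi, rec_lo, rec_hi = filter_bank(wavelet)

    feasible = max_levels(x.size, wavelet, boundary_mode)
    if levels > feasible:
        raise DecompositionError(
            f"signal of length {x.size} supports at most {feasible} {wavelet} "
            f"level(s); {levels} requested"
        )

    details: list[np.ndarray] = []
    level_lengths: list[int] = []
    approx = x
    for _ in range(levels):
        level_lengths.append(approx.size)
        if boundary_mode is BoundaryMode.SYMMETRIC:
            approx, detail = _dwt_symmetric(approx, dec_lo, dec_hi)
        else:
            approx, detail = _dwt_periodized(approx, rec_lo, rec_hi)
        details.append(detail)
    return WaveletDecomposition(
        details=details,
        approximation=approx,
        boundary_mode=boundary_mode,
        wavelet=wavelet,
        level_lengths=level_lengths,
    )


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Invert :func:`decompose` exactly (within floating-point roundoff)."""
    _, _, rec_lo, rec_hi = filter_bank(dec.wavelet)
    approx = dec.approximation
    for detail, out_len in zip(reversed(dec.details), reversed(dec.level_lengths)):
        if dec.boundary_mode is BoundaryMode.SYMMETRIC:
            approx = _idwt_symmetric(approx, detail, rec_lo, rec_hi, out_len)
        else:
            approx = _idwt_periodized(approx, detail, rec_lo, rec_hi, out_len)
    return approx
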