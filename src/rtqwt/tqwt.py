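"""Tunable-Q wavelet transform (TQWT).

The TQWT is an overcomplete, perfect-reconstruction discrete wavelet
transform parameterized by a quality factor ``Q`` (relative bandwidth of
the wavelet) and a redundancy rate ``r`` (oversampling of the filter
bank).  It is realized as an iterated two-channel filter bank applied in
the DFT domain: at every level the current low-pass signal is split into
a low-pass branch, frequency-scaled by ``alpha``, and a high-pass
branch, frequency-scaled by ``beta``, where

    beta  = 2 / (Q + 1)
    alpha = 1 - beta / r

An ``L``-level decomposition yields ``L`` high-pass subbands (SB1 is the
highest-frequency band) plus one final low-pass subband.  The two
channel responses overlap on a transition band where they satisfy
``|H0|^2 + |H1|^2 = 1`` pointwise, so the bank is a Parseval frame: the
inverse transform reconstructs the input exactly (to floating-point
round-off) and subband energies sum to the signal energy.

This module implements the transform on arbitrary even signal lengths
(full-length DFT realization, no radix-2 restriction), the parameter
relations, the maximum-depth formula and the reconstruction
mean-squared-error used as the tuning fitness elsewhere in the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    LevelOverflowError,
    StructureError,
)

__all__ = [
    "TQWTParams",
    "SubbandSet",
    "beta_from_q",
    "alpha_from",
    "lmax",
    "tqwt_forward",
    "tqwt_inverse",
    "decomposition_mse",
    "save_subbands",
    "load_subbands",
]


def beta_from_q(q: float) -> float:
    """High-pass scaling factor ``beta = 2/(Q+1)``.

    Inverts the definition of the quality factor ``Q = (2 - beta)/beta``.
    ``Q = 1`` gives ``beta = 1`` (octave-band limit); larger ``Q`` gives
    narrower relative bandwidth.
    """
    if not np.isfinite(q) or q < 1:
        raise InvalidParameterError(f"quality factor must satisfy Q >= 1, got {q!r}")
    return 2.0 / (q + 1.0)


def alpha_from(beta: float, r: float) -> float:
    """Low-pass scaling factor ``alpha = 1 - beta/r``.

    Rearranges the redundancy definition ``r = beta/(1 - alpha)``.
    ``r > 1`` is required so that ``alpha + beta > 1``, i.e. the two
    channel responses share a non-degenerate transition band.
    """
    if not (0.0 < beta <= 1.0):
        raise InvalidParameterError(f"beta must lie in (0, 1], got {beta!r}")
    if not np.isfinite(r) or r <= 1:
        raise InvalidParameterError(
            f"redundancy must satisfy r > 1 (degenerate transition band), got {r!r}"
        )
    return 1.0 - beta / r


def lmax(m: int, q: float, r: float) -> int:
    """Maximum number of decomposition levels for a length-``m`` signal.

    ``Lmax = floor( log(m / (4(Q+1))) / log(1/alpha) )`` — the depth at
    which the shrinking low-pass subband would drop below ``4(Q+1)``
    samples.  Monotonically non-decreasing in ``m``.
    """
    beta = beta_from_q(q)
    alpha = alpha_from(beta, r)
    if m < 4.0 * (q + 1.0):
        raise InvalidInputError(
            f"signal length {m} is too short for one level at Q={q} (needs >= {4 * (q + 1):.0f})"
        )
    return int(math.floor(math.log(m / (4.0 * (q + 1.0))) / math.log(1.0 / alpha)))


@dataclass(frozen=True)
class TQWTParams:
    """Transform parameters: quality factor, redundancy and depth.

    ``alpha`` and ``beta`` are derived from ``(q, r)`` and stored for
    inspection; they are not free fields.
    """

    q: float
    r: float
    levels: int
    beta: float = field(init=False)
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        beta = beta_from_q(self.q)
        alpha = alpha_from(beta, self.r)
        if int(self.levels) != self.levels or self.levels < 1:
            raise InvalidParameterError(f"levels must be a positive integer, got {self.levels!r}")
        object.__setattr__(self, "levels", int(self.levels))
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "alpha", alpha)

    def validate_for_length(self, m: int) -> None:
        limit = lmax(m, self.q, self.r)
        if self.levels > limit:
            raise LevelOverflowError(
                f"levels={self.levels} exceeds Lmax={limit} for length {m} at Q={self.q}, r={self.r}"
            )


@dataclass
class SubbandSet:
    """Result of an L-level decomposition.

    ``highpass[0]`` (SB1) is the highest-frequency band; ``lowpass`` is
    the final approximation (SB ``L+1``).
    """

    highpass: list[np.ndarray]
    lowpass: np.ndarray
    params: TQWTParams
    original_length: int

    def __len__(self) -> int:  # number of subbands
        return len(self.highpass) + 1

    @property
    def subbands(self) -> list[np.ndarray]:
        """All subbands in SB1..SB(L+1) order (low-pass last)."""
        return [*self.highpass, self.lowpass]

    def energies(self) -> np.ndarray:
        """Per-subband energy, SB1..SB(L+1) order."""
        return np.array([float(np.sum(np.square(s))) for s in self.subbands])


# ---------------------------------------------------------------------------
# one-level analysis / synthesis in the DFT domain
# ---------------------------------------------------------------------------


def _level_geometry(n: int, alpha: float, beta: float) -> tuple[int, int, int, int]:
    """Output lengths and transition-band bin indices for a length-n parent.

    Lengths are forced even (2*round(scale*n/2)); k1/k0 are the input
    DFT bins bounding the transition band ((1-beta)pi, alpha*pi).  At
    short parent lengths the rounding can close the transition band or
    stall the low-pass cascade; the rule then clamps deterministically —
    low-pass at most n-2 (guaranteed progress) and high-pass widened to
    keep at least one transition bin.  The identical rule is replayed by
    the inverse, so reconstruction stays exact.
    """
    n0 = min(2 * int(round(alpha * n / 2.0)), n - 2)
    n1 = max(2 * int(round(beta * n / 2.0)), 2)
    if n0 + n1 < n + 2:
        n1 = n - n0 + 2  # minimal non-degenerate transition band
    k1 = (n - n1) // 2
    k0 = n0 // 2
    if k0 <= k1 or n0 < 4 or n1 > n:
        raise LevelOverflowError(
            f"filter-bank geometry degenerate at parent length {n} (alpha={alpha}, beta={beta})"
        )
    return n0, n1, k1, k0

def _transition_gains(k1: int, k0: int) -> tuple[np.ndarray, np.ndarray]:
    # theta(w) = 0.5*(1+cos w)*sqrt(2-cos w) on (0, pi); power complementary:
    # theta(w)^2 + theta(pi-w)^2 = 1, so |H0|^2+|H1|^2 = 1 on the transition band.
    s = (np.arange(k1 + 1, k0) - k1) * (np.pi / (k0 - k1))
    g0 = 0.5 * (1.0 + np.cos(s)) * np.sqrt(2.0 - np.cos(s))
    g1 = 0.5 * (1.0 + np.cos(np.pi - s)) * np.sqrt(2.0 - np.cos(np.pi - s))
    return g0, g1


def _analyze_level(x: np.ndarray, alpha: float, beta: float) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    n0, n1, k1, k0 = _level_geometry(n, alpha, beta)
    g0, g1 = _transition_gains(k1, k0)
    spec = np.fft.rfft(x) / math.sqrt(n)  # unitary normalization

    low = np.zeros(n0 // 2 + 1, dtype=complex)
    low[: k1 + 1] = spec[: k1 + 1]
    low[k1 + 1 : k0] = spec[k1 + 1 : k0] * g0
    # bin k0 == n0/2 (output Nyquist) stays 0: H0(alpha*pi) = 0

    high = np.zeros(n1 // 2 + 1, dtype=complex)
    high[1 : k0 - k1] = spec[k1 + 1 : k0] * g1
    high[k0 - k1 :] = spec[k0 : n // 2 + 1]

    v0 = np.fft.irfft(low, n0) * math.sqrt(n0)
    v1 = np.fft.irfft(high, n1) * math.sqrt(n1)
    return v0, v1


def _synthesize_level(v0: np.ndarray, v1: np.ndarray, n: int, alpha: float, beta: float) -> np.ndarray:
    n0, n1, k1, k0 = _level_geometry(n, alpha, beta)
    if v0.size != n0 or v1.size != n1:
        raise StructureError(
            f"subband lengths ({v0.size}, {v1.size}) inconsistent with parent length {n} "
            f"(expected ({n0}, {n1}))"
        )
    g0, g1 = _transition_gains(k1, k0)
    low = np.fft.rfft(v0) / math.sqrt(n0)
    high = np.fft.rfft(v1) / math.sqrt(n1)

    spec = np.zeros(n // 2 + 1, dtype=complex)
    spec[: k1 + 1] = low[: k1 + 1]
    spec[k1 + 1 : k0] = low[k1 + 1 : k0] * g0 + high[1 : k0 - k1] * g1
    spec[k0 : n // 2 + 1] = high[k0 - k1 :]
    return np.fft.irfft(spec, n) * math.sqrt(n)


# ---------------------------------------------------------------------------
# public transform API
# ---------------------------------------------------------------------------


def tqwt_forward(signal: Sequence[float], params: TQWTParams) -> SubbandSet:
    """L-level forward transform of an even-length real signal."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError(f"expected a 1-D signal, got shape {x.shape}")
    if x.size % 2 != 0 or x.size == 0:
        raise InvalidInputError(f"signal length must be even and positive, got {x.size}")
    params.validate_for_length(x.size)

    highpass: list[np.ndarray] = []
    low = x
    for _ in range(params.levels):
        low, high = _analyze_level(low, params.alpha, params.beta)
        highpass.append(high)
    return SubbandSet(highpass=highpass, lowpass=low, params=params, original_length=x.size)


def tqwt_inverse(subbands: SubbandSet) -> np.ndarray:
    """Exact inverse of :func:`tqwt_forward` (up to floating-point error)."""
    params = subbands.params
    if len(subbands.highpass) != params.levels:
        raise StructureError(
            f"expected {params.levels} high-pass subbands, got {len(subbands.highpass)}"
        )
    # replay the cascade of parent lengths from the original length
    lengths = [subbands.original_length]
    for _ in range(params.levels):
        n0, _, _, _ = _level_geometry(lengths[-1], params.alpha, params.beta)
        lengths.append(n0)

    y = np.asarray(subbands.lowpass, dtype=float)
    for j in range(params.levels - 1, -1, -1):
        y = _synthesize_level(y, np.asarray(subbands.highpass[j], dtype=float),
                              lengths[j], params.alpha, params.beta)
    return y


def decomposition_mse(signal: Sequence[float], params: TQWTParams) -> float:
    """Mean squared reconstruction error of the analysis/synthesis round trip.

    This is the fitness minimized when tuning (Q, r).  Because the filter
    bank is a Parseval frame the value is at floating-point round-off for
    any valid parameters; it is nonzero only through accumulated
    arithmetic error.
    """
    x = np.asarray(signal, dtype=float)
    xhat = tqwt_inverse(tqwt_forward(x, params))
    return float(np.mean(np.square(x - xhat)))


# ---------------------------------------------------------------------------
# serialization: one delimited file per subband + JSON sidecar
# ---------------------------------------------------------------------------


def save_subbands(subbands: SubbandSet, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, band in enumerate(subbands.subbands, start=1):
        np.savetxt(directory / f"sb{i:02d}.txt", band)
    meta = {
        "q": subbands.params.q,
        "r": subbands.params.r,
        "levels": subbands.params.levels,
        "alpha": subbands.params.alpha,
        "beta": subbands.params.beta,
        "original_length": subbands.original_length,
    }
    (directory / "tqwt.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_subbands(directory: str | Path) -> SubbandSet:
    directory = Path(directory)
    meta = json.loads((directory / "tqwt.json").read_text())
    params = TQWTParams(q=meta["q"], r=meta["r"], levels=meta["levels"])
    bands = [
        np.atleast_1d(np.loadtxt(directory / f"sb{i:02d}.txt"))
        for i in range(1, params.levels + 2)
    ]
    return SubbandSet(
        highpass=bands[:-1],
        lowpass=bands[-1],
        params=params,
        original_length=int(meta["original_length"]),
    )
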