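"""Subband statistics for motor-imagery discrimination.

Five time-domain statistics are computed on every subband of every
epoch and channel:

* ``HE``   — Hurst exponent, a rescaled-range (R/S) estimate of
  long-term memory: the slope of log(R/S) against log(window size)
  over dyadic windows.
* ``MAV1`` — weighted mean absolute value: central half of the samples
  (0.25 J <= j <= 0.75 J, 1-based, inclusive) weighted 1, the rest 0.5.
* ``DASDV`` — difference absolute standard deviation value,
  sqrt( sum (y[j+1]-y[j])^2 / (J-1) ): the RMS first difference.
* ``LEE``  — log-energy entropy, -sum (log2 p_j)^2 over the normalized
  energy distribution p_j = y_j^2 / sum y^2 (zero-energy samples are
  excluded; the sum of squared log-probabilities measures how spread
  the energy is).
* ``VAR``  — population variance (divisor J).

:func:`build_feature_table` decomposes each (epoch, channel) signal
with the tuned TQWT parameters at the uniform depth and tabulates all
five statistics per subband.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidInputError
from .preprocessing import EpochedDataset
from .tqwt import TQWTParams, lmax, tqwt_forward

__all__ = [
    "FEATURE_NAMES",
    "FeatureTable",
    "hurst_exponent",
    "mav1",
    "dasdv",
    "log_energy_entropy",
    "variance",
    "compute_features",
    "build_feature_table",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("HE", "MAV1", "DASDV", "LEE", "VAR")


def hurst_exponent(x: np.ndarray) -> float:
    """Rescaled-range (R/S) Hurst exponent.

    For each dyadic window size n (16 up to J/2) the series is cut into
    blocks; within each block the range of cumulative mean-adjusted sums
    is divided by the block standard deviation, and R/S is averaged over
    blocks.  HE is the least-squares slope of log(R/S) vs log(n).
    White noise gives HE near 0.5, a random walk near 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise InvalidInputError(f"Hurst estimate needs >= 64 samples, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no rescaled range")

    sizes = []
    n = 16
    while n <= x.size // 2:
        sizes.append(n)
        n *= 2
    log_n, log_rs = [], []
    for n in sizes:
        n_blocks = x.size // n
        blocks = x[: n_blocks * n].reshape(n_blocks, n)
        centered = blocks - blocks.mean(axis=1, keepdims=True)
        walk = np.cumsum(centered, axis=1)
        rng = walk.max(axis=1) - walk.min(axis=1)
        std = blocks.std(axis=1)
        ok = std > 0
        if not ok.any():
            continue
        log_n.append(np.log(n))
        log_rs.append(np.log(np.mean(rng[ok] / std[ok])))
    if len(log_n) < 2:
        raise DegenerateInputError("too few usable scales for the R/S regression")
    slope, _ = np.polyfit(log_n, log_rs, 1)
    return float(slope)


def mav1(x: np.ndarray) -> float:
    """Weighted mean absolute value (window-weighted MAV variant)."""
    x = np.asarray(x, dtype=float)
    j_total = x.size
    if j_total < 4:
        raise InvalidInputError(f"MAV1 needs >= 4 samples, got {j_total}")
    j = np.arange(1, j_total + 1)  # 1-based sample index
    w = np.where((j >= 0.25 * j_total) & (j <= 0.75 * j_total), 1.0, 0.5)
    return float(np.sum(w * np.abs(x)) / j_total)


def dasdv(x: np.ndarray) -> float:
    """RMS of the first difference, normalized by J - 1."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidInputError(f"DASDV needs >= 2 samples, got {x.size}")
    return float(np.sqrt(np.sum(np.diff(x) ** 2) / (x.size - 1)))


def log_energy_entropy(x: np.ndarray) -> float:
    """Negative sum of squared log2 energy probabilities.

    ``p_j = y_j^2 / sum(y^2)``; samples with zero energy contribute
    nothing.  All energy in one sample gives 0; spreading energy makes
    the value more negative.
    """
    x = np.asarray(x, dtype=float)
    energy = np.square(x)
    total = energy.sum()
    if total == 0:
        raise DegenerateInputError("all-zero series has no energy distribution")
    p = energy / total
    p = p[p > 0]
    return float(-np.sum(np.square(np.log2(p))))


def variance(x: np.ndarray) -> float:
    """Population variance (divisor J)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidInputError("variance of an empty sequence is undefined")
    return float(np.mean(np.square(x - x.mean())))


_FEATURE_FUNCS: Mapping[str, Callable[[np.ndarray], float]] = {
    "HE": hurst_exponent,
    "MAV1": mav1,
    "DASDV": dasdv,
    "LEE": log_energy_entropy,
    "VAR": variance,
}


def compute_features(x: np.ndarray) -> dict[str, float]:
    """All five statistics of one subband.

    Degenerate cases (constant/all-zero subbands, or subbands too short
    for the R/S regression) are imputed as 0 with a warning so the
    feature table stays rectangular.
    """
    out: dict[str, float] = {}
    for name, fn in _FEATURE_FUNCS.items():
        try:
            out[name] = fn(x)
        except (DegenerateInputError, InvalidInputError) as exc:
            logger.warning("imputing %s = 0 (%s)", name, exc)
            out[name] = 0.0
    return out


@dataclass
class FeatureTable:
    """4-way table (epoch, channel, subband, feature) with epoch labels."""

    values: np.ndarray  # (n_epochs, n_channels, n_subbands, n_features)
    labels: np.ndarray
    channel_names: list[str]
    feature_names: tuple[str, ...] = FEATURE_NAMES
    n_imputed: int = 0

    @property
    def n_subbands(self) -> int:
        return self.values.shape[2]

    def channel_matrix(self, channel: int, subband: int | None = None) -> np.ndarray:
        """(epochs x features) matrix for one channel.

        With ``subband=None`` the features are averaged across subbands
        (one 5-vector per epoch); otherwise the given subband is used.
        """
        if subband is None:
            return self.values[:, channel].mean(axis=1)
        return self.values[:, channel, subband]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: epoch, channel, subband, feature, value, label."""
        n_e, n_c, n_s, n_f = self.values.shape
        idx = pd.MultiIndex.from_product(
            [range(n_e), self.channel_names, range(1, n_s + 1), self.feature_names],
            names=["epoch", "channel", "subband", "feature"],
        )
        df = pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()
        df["label"] = df["epoch"].map(dict(enumerate(self.labels)))
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        channels = list(dict.fromkeys(df["channel"]))
        features = tuple(dict.fromkeys(df["feature"]))
        n_e = df["epoch"].nunique()
        n_s = df["subband"].nunique()
        pivot = df.pivot_table(
            index="epoch", columns=["channel", "subband", "feature"], values="value", sort=False
        )
        values = pivot.to_numpy().reshape(n_e, len(channels), n_s, len(features))
        labels = df.drop_duplicates("epoch").sort_values("epoch")["label"].to_numpy()
        return cls(values=values, labels=labels, channel_names=channels, feature_names=features)


def build_feature_table(
    dataset: EpochedDataset,
    params: TQWTParams | Mapping[tuple[int, int], TQWTParams],
    levels: int,
) -> FeatureTable:
    """Decompose every (epoch, channel) signal and tabulate the statistics.

    ``params`` is either one parameter set used everywhere or a mapping
    from (epoch, channel) to the per-signal tuned parameters.  The
    uniform depth ``levels`` is clipped to each signal's own maximum
    depth (clips are logged); the table then holds ``levels + 1``
    subbands per signal, with missing deep subbands only possible when a
    clip occurred (they are filled by decomposing at the clipped depth
    and imputing 0 for the absent bands).
    """
    n_e, n_c, m = dataset.epochs.shape
    n_s = levels + 1
    values = np.zeros((n_e, n_c, n_s, len(FEATURE_NAMES)))
    n_imputed = 0
    for e in range(n_e):
        for c in range(n_c):
            p = params[(e, c)] if isinstance(params, Mapping) else params
            limit = lmax(m, p.q, p.r)
            depth = min(levels, limit)
            if depth < levels:
                logger.warning(
                    "epoch %d channel %d: depth clipped from %d to Lmax=%d", e, c, levels, limit
                )
            bands = tqwt_forward(
                dataset.epochs[e, c], TQWTParams(q=p.q, r=p.r, levels=depth)
            ).subbands
            for s in range(n_s):
                if s < len(bands):
                    feats = compute_features(bands[s])
                else:  # clipped: deep band absent
                    feats = {name: 0.0 for name in FEATURE_NAMES}
                    n_imputed += len(FEATURE_NAMES)
                for fi, name in enumerate(FEATURE_NAMES):
                    values[e, c, s, fi] = feats[name]
    return FeatureTable(
        values=values,
        labels=dataset.labels.copy(),
        channel_names=list(dataset.channel_names),
        n_imputed=n_imputed,
    )
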