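"""Laplacian-score channel ranking and Kruskal-Wallis feature screening.

The Laplacian score judges a feature by how well it respects the local
geometry of the data.  Per channel, a dense heat-kernel similarity
graph is built over the epochs' feature vectors,

    S_ij = exp(-||y_i - y_j||^2 / t),

with degree matrix ``D = diag(S 1)`` and graph Laplacian ``L = D - S``
(the standard positive-semidefinite sign; with it every score is
non-negative).  For feature column ``F_k``, after degree-weighted
centering, the score is the Rayleigh-like ratio

    L_k = (F~' L F~) / (F~' D F~).

A feature that varies little between similar epochs scores low; one
that varies independently of the graph scores near 1.  Channel choice
takes, for each feature, the extremal channel, then a majority vote
across features (ties go to the lowest channel index).  The voting
direction is configurable: ``"highest"`` follows the convention used
with the negated Laplacian (L = S - D), ``"lowest"`` is the classical
locality-preserving direction and is what isolates a channel whose
features carry class structure.

Kruskal-Wallis screening then flags, on the chosen channel, features
whose two-class rank distributions differ (chi-square approximation,
p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .exceptions import InvalidInputError

__all__ = [
    "LaplacianScoreTable",
    "laplacian_score",
    "laplacian_scores",
    "select_channel",
    "kruskal_wallis",
    "kw_screen",
]

logger = logging.getLogger(__name__)


@dataclass
class LaplacianScoreTable:
    scores: np.ndarray  # (n_channels, n_features)
    channel_names: list[str]
    feature_names: tuple[str, ...]
    graph_bandwidth: np.ndarray  # per-channel heat-kernel constant t

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.channel_names, columns=self.feature_names)


def laplacian_score(points: np.ndarray, bandwidth: float | None = None) -> np.ndarray:
    """Laplacian score of every column of an (epochs x features) matrix.

    ``bandwidth`` is the heat-kernel constant ``t``; by default the mean
    squared pairwise distance of the points (scale-adaptive).  A feature
    constant across epochs has a zero centered vector and scores 0.
    """
    y = np.asarray(points, dtype=float)
    if y.ndim != 2 or y.shape[0] < 3:
        raise InvalidInputError("need an (epochs x features) matrix with >= 3 epochs")
    sq = squareform(pdist(y, "sqeuclidean"))
    if bandwidth is None:
        off = sq[np.triu_indices_from(sq, k=1)]
        bandwidth = float(off.mean()) if off.size and off.mean() > 0 else 1.0
    s = np.exp(-sq / bandwidth)
    d = s.sum(axis=1)
    d_total = d.sum()

    scores = np.zeros(y.shape[1])
    for k in range(y.shape[1]):
        f = y[:, k]
        f_centered = f - (f @ d) / d_total
        denom = float(d @ np.square(f_centered))
        if denom <= 0 or np.ptp(f) == 0:
            logger.warning("feature %d constant across epochs: score set to 0", k)
            continue
        num = float(f_centered @ (d * f_centered) - f_centered @ (s @ f_centered))
        scores[k] = num / denom
    return scores


def laplacian_scores(
    features_by_channel: Sequence[np.ndarray],
    feature_names: Sequence[str] | None = None,
    channel_names: Sequence[str] | None = None,
    bandwidth: float | None = None,
    standardize: bool = True,
) -> LaplacianScoreTable:
    """Score every feature of every channel on its own epoch graph.

    With ``standardize`` (default) feature columns are z-scored per
    channel before the similarity graph is built, so no single feature's
    physical scale dominates the pairwise distances (the log-energy
    entropy is orders of magnitude larger than the other statistics).
    The score itself is scale-invariant per feature, so standardization
    affects only the graph geometry.
    """
    scores, bandwidths = [], []
    for y in features_by_channel:
        y = np.asarray(y, dtype=float)
        if standardize:
            sd = y.std(axis=0)
            y = (y - y.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        sq = squareform(pdist(y, "sqeuclidean"))
        off = sq[np.triu_indices_from(sq, k=1)]
        t = bandwidth if bandwidth is not None else (float(off.mean()) if off.mean() > 0 else 1.0)
        scores.append(laplacian_score(y, bandwidth=t))
        bandwidths.append(t)
    scores = np.vstack(scores)
    n_c, n_f = scores.shape
    return LaplacianScoreTable(
        scores=scores,
        channel_names=list(channel_names or (f"CH{i + 1}" for i in range(n_c))),
        feature_names=tuple(feature_names or (f"F{k + 1}" for k in range(n_f))),
        graph_bandwidth=np.asarray(bandwidths),
    )


def select_channel(
    table: LaplacianScoreTable, direction: Literal["highest", "lowest"] = "highest"
) -> int:
    """Majority vote of per-feature extremal channels; ties -> lowest index."""
    if table.scores.size == 0:
        raise InvalidInputError("empty score table")
    pick = np.argmax if direction == "highest" else np.argmin
    winners = pick(table.scores, axis=0)  # per-feature winning channel
    votes = np.bincount(winners, minlength=table.scores.shape[0])
    return int(np.argmax(votes))  # argmax takes the lowest index on ties


def kruskal_wallis(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Two-class Kruskal-Wallis H and its chi-square p-value (1 df)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise InvalidInputError(f"expected exactly 2 classes, got {classes.size}")
    groups = [values[labels == c] for c in classes]
    if any(g.size < 2 for g in groups):
        raise InvalidInputError("each class needs >= 2 observations")
    if np.ptp(values) == 0:
        # every observation tied: no rank information, H degenerates to 0
        logger.warning("all observations identical: H = 0, p = 1")
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kw_screen(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis p-value per feature column; flags p < alpha."""
    feature_matrix = np.asarray(feature_matrix, dtype=float)
    names = list(feature_names or (f"F{k + 1}" for k in range(feature_matrix.shape[1])))
    rows = []
    for k, name in enumerate(names):
        h, p = kruskal_wallis(feature_matrix[:, k], labels)
        rows.append({"feature": name, "H": h, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)
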