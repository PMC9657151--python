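"""Band-pass filtering and epoching of multichannel EEG.

Motor-imagery information rides on the sensorimotor mu (~7-13 Hz) and
beta (~14-30 Hz) rhythms, so recordings are band-passed to 7-30 Hz with
a sixth-order Butterworth filter before segmentation.  The filter is
applied zero-phase (forward-backward, :func:`scipy.signal.sosfiltfilt`)
by default to avoid phase-distorting the rhythms; a causal single-pass
option is available.

Epoching cuts each continuous recording into consecutive,
non-overlapping windows of fixed even length (2000 samples at 100 Hz by
default); a trailing partial window is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = ["EpochedDataset", "bandpass", "epoch_signals", "load_edf", "load_csv_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class EpochedDataset:
    """Labeled epochs: an (n_epochs, n_channels, n_samples) array."""

    epochs: np.ndarray
    labels: np.ndarray  # one class tag per epoch
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise InvalidInputError(f"epochs must be 3-D, got shape {self.epochs.shape}")
        if self.labels.shape[0] != self.epochs.shape[0]:
            raise InvalidInputError("one label per epoch is required")
        if not self.channel_names:
            self.channel_names = [f"CH{i + 1}" for i in range(self.n_channels)]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_length(self) -> int:
        return self.epochs.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_counts(self) -> dict[str, int]:
        classes, counts = np.unique(self.labels, return_counts=True)
        return {str(c): int(n) for c, n in zip(classes, counts)}

    # -- container I/O ----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Write the dataset to an ``.npz`` container (arrays + metadata)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path,
            epochs=self.epochs,
            labels=self.labels.astype(str),
            fs=self.fs,
            channel_names=np.array(self.channel_names),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EpochedDataset":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                epochs=data["epochs"],
                labels=data["labels"],
                fs=float(data["fs"]),
                channel_names=[str(c) for c in data["channel_names"]],
            )


def bandpass(
    x: Sequence[float] | np.ndarray,
    fs: float,
    low: float = 7.0,
    high: float = 30.0,
    order: int = 6,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth band-pass along the last axis; output length preserved.

    ``order`` is the order of the underlying analog prototype (a 6th
    order band-pass has 3 pole pairs per edge).  With ``zero_phase`` the
    filter runs forward and backward, squaring its magnitude response
    and cancelling phase.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < low < high:
        raise InvalidParameterError(f"cutoffs must satisfy 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise InvalidParameterError(f"high cutoff {high} Hz reaches Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order // 2, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def epoch_signals(
    continuous: np.ndarray,
    fs: float,
    epoch_length: int = 2000,
    labels: Sequence | None = None,
    label: str | None = None,
    channel_names: list[str] | None = None,
) -> EpochedDataset:
    """Cut a (channels x samples) recording into consecutive epochs.

    Windows never overlap and never cross the end of the recording; a
    trailing remainder shorter than ``epoch_length`` is dropped (and
    logged).  Provide either one ``label`` for the whole recording or a
    per-epoch ``labels`` sequence.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    if epoch_length <= 0 or epoch_length % 2 != 0:
        raise InvalidParameterError(f"epoch_length must be positive and even, got {epoch_length}")
    n_samples = continuous.shape[1]
    n_epochs = n_samples // epoch_length
    if n_epochs == 0:
        raise InvalidInputError(
            f"recording of {n_samples} samples is shorter than one epoch ({epoch_length})"
        )
    dropped = n_samples - n_epochs * epoch_length
    if dropped:
        logger.info("dropping trailing %d samples (< one epoch)", dropped)

    trimmed = continuous[:, : n_epochs * epoch_length]
    epochs = trimmed.reshape(continuous.shape[0], n_epochs, epoch_length).transpose(1, 0, 2)

    if labels is None:
        if label is None:
            raise InvalidInputError("provide either a per-epoch `labels` sequence or one `label`")
        labels = [label] * n_epochs
    labels = np.asarray(labels)
    if labels.shape[0] != n_epochs:
        raise InvalidInputError(f"expected {n_epochs} labels, got {labels.shape[0]}")
    return EpochedDataset(
        epochs=epochs, labels=labels, fs=fs, channel_names=channel_names or []
    )


def load_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF recording: (channels x samples) array, rate and names."""
    import mne  # heavy import kept local

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)


def load_csv_matrix(path: str | Path, delimiter: str = ",") -> np.ndarray:
    """Read a delimited (channels x samples) numeric matrix."""
    mat = np.loadtxt(path, delimiter=delimiter)
    return np.atleast_2d(mat)
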