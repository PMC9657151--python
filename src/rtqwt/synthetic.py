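"""Seeded generator of two-class, multichannel EEG-like epochs.

Every pipeline stage in this package is testable without real
recordings: the generator emulates the relevant structure of a
two-class motor-imagery experiment — band-limited mu (~10 Hz) and beta
(~20 Hz) rhythms over a 1/f background, 2000-sample epochs at 100 Hz —
with exactly one informative channel whose rhythm power differs
between the classes by a known multiplicative contrast.

Each epoch is

    x(t) = noise_1/f(t) + A * env(t) * [sin(2 pi f_mu t + p1)
                                        + sin(2 pi f_beta t + p2)]

where ``env`` is a Hann-smoothed random-walk envelope (slow amplitude
modulation, as real sensorimotor rhythms wax and wane) and the phases
are uniform.  On the informative channel only, class-2 epochs scale the
rhythm amplitude by sqrt(class_power_ratio) so the rhythm band power
scales by the ratio exactly in expectation.  ``snr_db`` sets the
rhythm-to-background power ratio on class-1 epochs.

What this does *not* emulate: volume conduction between channels,
artifacts, inter-subject variability — conclusions from these fixtures
are about the pipeline's mechanics, not about real-EEG performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidParameterError
from .preprocessing import EpochedDataset

__all__ = ["SynthSpec", "generate"]

TASK1, TASK2 = "task1", "task2"


@dataclass(frozen=True)
class SynthSpec:
    """Study-condition parameters of the synthetic two-class dataset."""

    n_channels: int = 4
    n_epochs_per_class: int = 30
    fs: float = 100.0
    epoch_length: int = 2000
    informative_channel: int = 0
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    class_power_ratio: float = 2.5
    noise_exponent: float = 1.0
    snr_db: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or not 0 <= self.informative_channel < self.n_channels:
            raise InvalidParameterError("informative_channel must index an existing channel")
        if self.n_epochs_per_class < 1:
            raise InvalidParameterError("need at least one epoch per class")
        if self.epoch_length % 2 != 0 or self.epoch_length <= 0:
            raise InvalidParameterError("epoch_length must be positive and even")
        if self.class_power_ratio <= 1:
            raise InvalidParameterError("class_power_ratio must exceed 1")
        if self.fs <= 2 * max(self.mu_freq, self.beta_freq):
            raise InvalidParameterError("sampling rate must exceed twice the beta frequency")


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent noise with unit variance, via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0  # zero-mean
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std()


def _envelope(rng: np.random.Generator, n: int) -> np.ndarray:
    """Positive slow amplitude modulation: Hann-smoothed random walk."""
    walk = np.cumsum(rng.standard_normal(n))
    win = sps.windows.hann(n // 8 + 1)
    smooth = sps.convolve(walk, win / win.sum(), mode="same")
    smooth = (smooth - smooth.mean()) / (smooth.std() + 1e-12)
    return 1.0 + 0.3 * smooth  # ~±30% waxing/waning, mean 1


def generate(spec: SynthSpec) -> EpochedDataset:
    """Generate the labeled dataset; bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.epoch_length
    t = np.arange(n) / spec.fs
    # class-1 rhythm amplitude from the target SNR (rhythm power vs unit noise)
    rhythm_power_target = 10.0 ** (spec.snr_db / 10.0)
    base_amp = np.sqrt(rhythm_power_target)  # two unit-power sinusoids at amp 1 give power 1

    n_total = 2 * spec.n_epochs_per_class
    epochs = np.empty((n_total, spec.n_channels, n))
    labels = np.array([TASK1] * spec.n_epochs_per_class + [TASK2] * spec.n_epochs_per_class)
    for e in range(n_total):
        is_task2 = labels[e] == TASK2
        for c in range(spec.n_channels):
            amp = base_amp
            if c == spec.informative_channel and is_task2:
                amp *= np.sqrt(spec.class_power_ratio)
            env = _envelope(rng, n)
            p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
            rhythm = np.sin(2 * np.pi * spec.mu_freq * t + p1) + np.sin(
                2 * np.pi * spec.beta_freq * t + p2
            )
            epochs[e, c] = _pink_noise(rng, n, spec.noise_exponent) + amp * env * rhythm
    return EpochedDataset(epochs=epochs, labels=labels, fs=spec.fs)
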