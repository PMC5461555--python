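"""Core in-memory containers shared by the simulation and analysis modules.

All time axes are expressed in milliseconds; sampling rates in Hz.  Signals
live in ``trials x channels x samples`` arrays; single-channel data may be
passed as ``trials x samples`` and is promoted to a singleton channel axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError, InvalidInputError


@dataclass
class TrialTensor:
    """Real-valued multitrial signal with a common time axis.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)``; a 2-D array is
        interpreted as single-channel ``(n_trials, n_samples)``.
    fs
        Sampling rate in Hz.
    t0_ms
        Time of the first sample, in milliseconds relative to the event of
        interest (e.g. target onset at 0 ms).
    """

    data: np.ndarray
    fs: float
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[:, None, :]
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"expected 2-D or 3-D signal array, got ndim={self.data.ndim}"
            )
        if not self.fs > 0:
            raise InvalidConfigError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def index_of(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``; must lie inside the axis."""
        idx = int(round((t_ms - self.t0_ms) * self.fs / 1000.0))
        if not 0 <= idx < self.n_samples:
            raise InvalidInputError(
                f"time {t_ms} ms falls outside the sampled axis "
                f"[{self.t0_ms}, {self.times_ms[-1]}] ms"
            )
        return idx

    def copy(self) -> "TrialTensor":
        return TrialTensor(self.data.copy(), self.fs, self.t0_ms)


@dataclass
class Irf:
    """Per-channel linear impulse-response kernel over a non-negative lag axis.

    ``kernel[c, l]`` maps stimulus luminance (regression-coefficient units per
    luminance unit) at lag ``l`` samples into signal units on channel ``c``.
    """

    kernel: np.ndarray  # (n_channels, n_lags)
    fs: float
    lag0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.kernel = np.atleast_2d(np.asarray(self.kernel, dtype=np.float64))
        if not np.all(np.isfinite(self.kernel)):
            raise InvalidInputError("IRF kernel contains non-finite values")
        if self.lag0_ms < 0:
            raise InvalidConfigError("IRF lag axis must start at a lag >= 0")
        if not self.fs > 0:
            raise InvalidConfigError("IRF sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.kernel.shape[0]

    @property
    def n_lags(self) -> int:
        return self.kernel.shape[1]

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lag0_ms + np.arange(self.n_lags) * 1000.0 / self.fs
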