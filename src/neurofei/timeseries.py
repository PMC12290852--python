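"""Uniformly sampled time series, the universal input of the package."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Minimum recording duration (seconds) recommended for reliable DFA / fE/I.
MIN_ANALYSIS_SECONDS = 120.0


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array-like
        Signal values (arbitrary units, e.g. microvolts or population spike
        counts). Must be finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_id : str, optional
        Label of the originating channel.
    """

    samples: np.ndarray
    fs: float
    channel_id: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs

    def check_analysis_length(self, min_seconds: float = MIN_ANALYSIS_SECONDS) -> None:
        """Warn when the recording is shorter than the recommended minimum.

        DFA and fE/I estimates on short recordings are unreliable: the upper
        fitting bound of 30 s requires several independent windows of the
        longest scale.
        """
        if self.duration < min_seconds:
            warnings.warn(
                f"recording of {self.duration:.1f} s is shorter than the "
                f"recommended {min_seconds:.0f} s minimum for DFA/fE/I",
                UserWarning,
                stacklevel=2,
            )

    def scaled(self, factor: float) -> "TimeSeries":
        return TimeSeries(self.samples * factor, self.fs, self.channel_id)
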