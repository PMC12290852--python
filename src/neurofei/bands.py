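"""Narrow frequency bins over 1-150 Hz and band-limited amplitude envelopes.

The binning scheme uses one wide delta bin (1-4 Hz) followed by
geometrically spaced bins up to 150 Hz.  Band-limited activity is obtained
with a linear-phase FIR bandpass applied forward-backward (zero net phase),
and the amplitude envelope is the magnitude of the analytic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from neurofei.timeseries import TimeSeries

#: Canonical 17 edges of the default 16-bin scheme over 1-150 Hz.
#: One delta bin (1-4 Hz) plus 15 geometrically spaced bins within
#: 4-150 Hz; edges are pinned to 0.5-Hz resolution, calibrated against the
#: spectral overlap of adjacent bins rather than rounded mechanically.
DEFAULT_EDGES: tuple[float, ...] = (
    1.0, 4.0, 5.0, 6.5, 8.0, 10.5, 13.0, 17.0, 22.0, 28.0,
    35.5, 45.0, 57.5, 73.0, 93.0, 118.0, 150.0,
)

#: The two alpha bins of the default scheme (Hz).
ALPHA_BINS: tuple[tuple[float, float], ...] = ((8.0, 10.5), (10.5, 13.0))


@dataclass(frozen=True)
class FrequencyBin:
    """A contiguous frequency interval [f_low, f_high] in Hz."""

    f_low: float
    f_high: float
    index: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"invalid frequency bin [{self.f_low}, {self.f_high}]"
            )

    @property
    def bandwidth(self) -> float:
        return self.f_high - self.f_low

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.f_low:g}-{self.f_high:g} Hz"


def make_frequency_bins(
    f_min: float,
    f_max: float,
    n_log_bins: int,
    delta_edge: float,
    round_to: float = 0.5,
) -> list[FrequencyBin]:
    """Construct ``1 + n_log_bins`` contiguous bins over ``[f_min, f_max]``.

    Bin 0 spans ``[f_min, delta_edge]``; the remaining edges are spaced
    geometrically between ``delta_edge`` and ``f_max`` with ratio
    ``(f_max/delta_edge)**(1/n_log_bins)`` and rounded to the nearest
    ``round_to`` Hz.

    Parameters
    ----------
    f_min, f_max : float
        Overall frequency span in Hz.
    n_log_bins : int
        Number of geometrically spaced bins above ``delta_edge``.
    delta_edge : float
        Upper edge of the first (wide, low-frequency) bin.
    round_to : float
        Edge rounding granularity in Hz; 0 disables rounding.
    """
    if not (0 < f_min < delta_edge < f_max):
        raise ValueError(
            f"need 0 < f_min < delta_edge < f_max, got "
            f"({f_min}, {delta_edge}, {f_max})"
        )
    if n_log_bins < 1:
        raise ValueError("n_log_bins must be >= 1")
    ratio = (f_max / delta_edge) ** (1.0 / n_log_bins)
    edges = [f_min, delta_edge]
    for k in range(1, n_log_bins + 1):
        edges.append(delta_edge * ratio**k)
    if round_to > 0:
        edges = [round(e / round_to) * round_to for e in edges]
    edges[-1] = float(f_max)
    if any(hi <= lo for lo, hi in zip(edges, edges[1:])):
        raise ValueError(
            f"rounding to {round_to} Hz collapsed adjacent edges: {edges}"
        )
    return [
        FrequencyBin(lo, hi, index=i)
        for i, (lo, hi) in enumerate(zip(edges, edges[1:]))
    ]


def default_bins() -> list[FrequencyBin]:
    """The canonical 16-bin scheme (1-4 Hz delta bin + 15 log bins to 150 Hz)."""
    return [
        FrequencyBin(lo, hi, index=i)
        for i, (lo, hi) in enumerate(zip(DEFAULT_EDGES, DEFAULT_EDGES[1:]))
    ]


def alpha_bin_indices(bins: list[FrequencyBin]) -> list[int]:
    """Indices of bins matching the canonical alpha bins (8-10.5, 10.5-13 Hz)."""
    return [
        i for i, b in enumerate(bins) if (b.f_low, b.f_high) in ALPHA_BINS
    ]


@dataclass(frozen=True)
class FIRFilter:
    """A linear-phase FIR bandpass and its transient bookkeeping.

    ``coefficients`` hold the one-pass (linear-phase) design; the filter is
    applied forward-backward, so the effective impulse response is the
    autocorrelation of ``coefficients`` and has zero phase.
    ``transient_samples`` is half the effective impulse-response length,
    i.e. ``numtaps - 1`` one-pass samples.
    """

    coefficients: np.ndarray
    fs: float
    bin: FrequencyBin

    @property
    def numtaps(self) -> int:
        return int(self.coefficients.size)

    @property
    def transient_samples(self) -> int:
        return self.numtaps - 1

    @property
    def transient_seconds(self) -> float:
        return self.transient_samples / self.fs

    def frequency_response(self, n_freqs: int = 4096) -> tuple[np.ndarray, np.ndarray]:
        """Frequencies (Hz) and magnitude of the effective zero-phase response."""
        w, h = sps.freqz(self.coefficients, worN=n_freqs, fs=self.fs)
        return w, np.abs(h) ** 2  # forward-backward squares the magnitude

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Zero-phase (forward-backward) filtering via FFT convolution.

        Equivalent to convolving with the symmetric autocorrelation of the
        one-pass kernel; edges are zero-padded, which is why a transient is
        trimmed downstream.
        """
        kernel = sps.fftconvolve(self.coefficients, self.coefficients[::-1])
        return sps.fftconvolve(x, kernel, mode="same")


def design_bandpass(
    bin: FrequencyBin,
    fs: float,
    n_cycles: float = 2.0,
    transition_factor: float = 1.0,
    window: str = "hamming",
) -> FIRFilter:
    """Design a windowed-sinc FIR bandpass for one frequency bin.

    The impulse response spans the larger of ``n_cycles`` cycles of
    ``f_low`` and ``transition_factor`` periods of the bin bandwidth.  Both
    constraints shrink with bin frequency in a geometric bin scheme, so the
    filter transient -- and with it the smallest trustworthy DFA window
    size -- shortens as frequency grows.  Keeping the filter this short is
    deliberate: its autocorrelation must decay well below the 5-s fE/I
    window, at the price of a transition band comparable to the bin width.
    The cutoffs are widened by half a transition band on each side so the
    passband stays flat (< 1 dB ripple) across the whole nominal bin; the
    leakage into neighbouring bins is the spectral overlap the bin-width
    calibration is based on.
    """
    nyq = fs / 2.0
    if bin.f_high >= nyq:
        raise ValueError(
            f"bin upper edge {bin.f_high} Hz >= Nyquist {nyq} Hz at fs={fs}"
        )
    taps_cycles = n_cycles * fs / bin.f_low
    taps_transition = transition_factor * fs / bin.bandwidth
    numtaps = int(np.ceil(max(taps_cycles, taps_transition)))
    tw = 3.3 * fs / numtaps  # Hamming main-lobe width
    cutoff_lo = max(bin.f_low - tw / 2.0, bin.f_low / 4.0)
    cutoff_hi = min(bin.f_high + tw / 2.0, nyq * 0.99)
    if numtaps % 2 == 0:
        numtaps += 1  # odd length -> integer group delay, type-I linear phase
    coeffs = sps.firwin(
        numtaps,
        [cutoff_lo, cutoff_hi],
        pass_zero=False,
        window=window,
        fs=fs,
    )
    return FIRFilter(coefficients=coeffs, fs=fs, bin=bin)


@dataclass(frozen=True)
class BandEnvelope:
    """Amplitude envelope of band-limited activity.

    The envelope is the magnitude of the analytic (Hilbert-transformed)
    band-filtered signal, with one filter transient trimmed from each edge.
    """

    envelope: np.ndarray
    bin: FrequencyBin
    fs: float
    transient_trim: float  # seconds removed at each edge

    def __post_init__(self) -> None:
        env = np.asarray(self.envelope, dtype=np.float64)
        if env.size == 0:
            raise ValueError("empty envelope")
        if np.any(env < 0):
            raise ValueError("envelope must be non-negative")
        object.__setattr__(self, "envelope", env)

    @property
    def n_samples(self) -> int:
        return int(self.envelope.size)

    @property
    def duration(self) -> float:
        return self.envelope.size / self.fs


def band_envelope(
    ts: TimeSeries,
    bin: FrequencyBin,
    n_cycles: float = 2.0,
    transition_factor: float = 0.5,
    window: str = "hamming",
    fir: FIRFilter | None = None,
) -> BandEnvelope:
    """Band-filter a signal and extract its amplitude envelope.

    Pipeline: zero-phase FIR bandpass -> analytic signal magnitude -> trim
    one filter transient at each edge (filter and Hilbert edge effects bias
    fluctuation estimates).

    Parameters
    ----------
    ts : TimeSeries
        Input signal.
    bin : FrequencyBin
        Passband.
    fir : FIRFilter, optional
        Pre-designed filter (must match ``bin`` and ``ts.fs``); designed on
        the fly otherwise.
    """
    if fir is None:
        fir = design_bandpass(
            bin, ts.fs, n_cycles=n_cycles,
            transition_factor=transition_factor, window=window,
        )
    trim = fir.transient_samples
    if ts.n_samples <= 2 * trim:
        raise ValueError(
            f"signal of {ts.n_samples} samples is shorter than twice the "
            f"filter transient ({trim} samples); need a longer recording or "
            f"a shorter filter"
        )
    filtered = fir.apply(ts.samples)
    n = filtered.size
    nfft = next_fast_len(n)
    analytic = sps.hilbert(filtered, N=nfft)[:n]
    env = np.abs(analytic)
    env = env[trim: n - trim]
    return BandEnvelope(
        envelope=env, bin=bin, fs=ts.fs, transient_trim=trim / ts.fs
    )
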