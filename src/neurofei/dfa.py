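"""Detrended fluctuation analysis (DFA) of band-limited amplitude envelopes.

DFA estimates the power-law decay of long-range temporal correlations
(LRTC): the signal profile (cumulative sum of the demeaned envelope) is
split into windows of growing size, linearly detrended per window, and the
mean RMS residual F(t) is fitted against window size t in log-log
coordinates.  The slope is the DFA exponent: 0.5 for uncorrelated noise,
>0.5 in the presence of LRTC.

Narrow-band filtering introduces short-range correlations that inflate the
local slope of F(t) at small t.  ``calibrate_lower_bound`` reproduces, on
demand, the calibration of the smallest trustworthy window size per
frequency bin: it measures, on band-limited white noise, where the local
slope of F(t) settles at the 0.5 null value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from neurofei.bands import BandEnvelope, FrequencyBin, band_envelope, design_bandpass
from neurofei.timeseries import TimeSeries

#: Upper bound of the default DFA fitting interval (seconds).
DEFAULT_T_MAX = 30.0

#: Practical LRTC gate: exponents below this are treated as random
#: fluctuations for the purposes of fE/I.
DFA_GATE = 0.6


class EstimationError(RuntimeError):
    """Raised when a quantity cannot be estimated from the given input."""


class CalibrationError(RuntimeError):
    """Raised when no window size satisfies the calibration tolerance."""

    def __init__(self, message: str, curve: "FluctuationCurve | None" = None):
        super().__init__(message)
        self.curve = curve


@dataclass(frozen=True)
class FittingRange:
    """Interval of window sizes (seconds) used for the log-log fit."""

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not (0 < self.t_min < self.t_max):
            raise ValueError(f"invalid fitting range [{self.t_min}, {self.t_max}]")


@dataclass(frozen=True)
class FluctuationCurve:
    """Mean detrended fluctuation F(t) per window size t."""

    window_sizes: np.ndarray  # seconds, strictly increasing
    fluctuations: np.ndarray  # same units as the signal
    n_windows: np.ndarray  # windows averaged per size

    def __post_init__(self) -> None:
        ws = np.asarray(self.window_sizes, dtype=np.float64)
        fl = np.asarray(self.fluctuations, dtype=np.float64)
        nw = np.asarray(self.n_windows, dtype=np.int64)
        if not (ws.size == fl.size == nw.size):
            raise ValueError("window_sizes, fluctuations, n_windows lengths differ")
        if np.any(np.diff(ws) <= 0):
            raise ValueError("window_sizes must be strictly increasing")
        object.__setattr__(self, "window_sizes", ws)
        object.__setattr__(self, "fluctuations", fl)
        object.__setattr__(self, "n_windows", nw)

    def local_slopes(self) -> np.ndarray:
        """Finite-difference slope of log10 F vs log10 t between adjacent sizes."""
        logt = np.log10(self.window_sizes)
        logf = np.log10(self.fluctuations)
        return np.diff(logf) / np.diff(logt)


@dataclass(frozen=True)
class DFAResult:
    """Fitted DFA exponent with fit diagnostics."""

    exponent: float
    r_squared: float
    fitting_range: FittingRange
    n_windows_per_size: dict[float, int] = field(default_factory=dict)


def default_window_sizes(
    t_max: float = DEFAULT_T_MAX,
    t_min: float = 0.1,
    sizes_per_decade: int = 10,
) -> np.ndarray:
    """Log-spaced grid of window sizes in seconds (10 per decade by default)."""
    n = int(np.floor(np.log10(t_max / t_min) * sizes_per_decade)) + 1
    sizes = t_min * 10 ** (np.arange(n) / sizes_per_decade)
    # include t_max itself unless it (nearly) duplicates the last grid size,
    # which would make the log-log spacing degenerate
    if sizes[-1] < t_max * 0.98:
        sizes = np.append(sizes, t_max)
    else:
        sizes[-1] = t_max
    return sizes


def signal_profile(env: BandEnvelope | np.ndarray) -> np.ndarray:
    """Cumulative sum of the demeaned envelope (the DFA signal profile)."""
    x = env.envelope if isinstance(env, BandEnvelope) else np.asarray(env, float)
    if x.size == 0:
        raise ValueError("empty envelope")
    return np.cumsum(x - x.mean())


def _fluctuation_one_size(profile: np.ndarray, n: int, step: int) -> tuple[float, int]:
    """Mean RMS residual of linear detrending over sliding windows of n samples."""
    windows = np.lib.stride_tricks.sliding_window_view(profile, n)[::step]
    t = np.arange(n, dtype=np.float64) - (n - 1) / 2.0
    denom = float(t @ t)
    slopes = windows @ t / denom
    resid = windows - windows.mean(axis=1, keepdims=True) - slopes[:, None] * t
    rms = np.sqrt(np.mean(resid**2, axis=1))
    return float(rms.mean()), int(windows.shape[0])


def compute_fluctuations(
    profile: np.ndarray,
    fs: float,
    window_sizes: np.ndarray | None = None,
    overlap: float = 0.5,
) -> FluctuationCurve:
    """Compute the fluctuation function F(t) of a signal profile.

    For each window size, windows slide with the given overlap, a
    least-squares line is removed per window, the RMS residual is taken per
    window and averaged arithmetically across windows.

    Window sizes longer than the profile are skipped with a warning.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if not (0 <= overlap < 1):
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    if window_sizes is None:
        window_sizes = default_window_sizes()
    sizes_sec, flucts, counts = [], [], []
    seen_n: set[int] = set()
    for t_sec in np.asarray(window_sizes, dtype=np.float64):
        n = int(round(t_sec * fs))
        if n < 4 or n in seen_n:
            continue
        if n > profile.size:
            warnings.warn(
                f"window of {t_sec:g} s ({n} samples) exceeds profile length "
                f"({profile.size} samples); skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        seen_n.add(n)
        step = max(1, int(round(n * (1 - overlap))))
        f, k = _fluctuation_one_size(profile, n, step)
        sizes_sec.append(n / fs)
        flucts.append(f)
        counts.append(k)
    if not sizes_sec:
        raise EstimationError("no usable window sizes for this profile")
    return FluctuationCurve(
        window_sizes=np.array(sizes_sec),
        fluctuations=np.array(flucts),
        n_windows=np.array(counts),
    )


def fit_exponent(curve: FluctuationCurve, fitting_range: FittingRange) -> DFAResult:
    """OLS slope of log10 F(t) vs log10 t restricted to the fitting range."""
    tol = 1e-9
    mask = (curve.window_sizes >= fitting_range.t_min * (1 - tol)) & (
        curve.window_sizes <= fitting_range.t_max * (1 + tol)
    )
    if mask.sum() < 3:
        raise EstimationError(
            f"only {int(mask.sum())} window sizes inside "
            f"[{fitting_range.t_min}, {fitting_range.t_max}] s; need >= 3 "
            f"(available sizes: {np.round(curve.window_sizes, 3).tolist()})"
        )
    logt = np.log10(curve.window_sizes[mask])
    logf = np.log10(curve.fluctuations[mask])
    slope, intercept = np.polyfit(logt, logf, 1)
    pred = slope * logt + intercept
    ss_res = float(np.sum((logf - pred) ** 2))
    ss_tot = float(np.sum((logf - logf.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return DFAResult(
        exponent=float(slope),
        r_squared=float(min(r2, 1.0)),
        fitting_range=fitting_range,
        n_windows_per_size={
            float(t): int(k)
            for t, k in zip(curve.window_sizes[mask], curve.n_windows[mask])
        },
    )


def dfa(
    env: BandEnvelope,
    fitting_range: FittingRange,
    overlap: float = 0.5,
    window_sizes: np.ndarray | None = None,
) -> DFAResult:
    """Convenience wrapper: profile -> F(t) -> exponent for one envelope."""
    if window_sizes is None:
        window_sizes = default_window_sizes(t_max=fitting_range.t_max)
    profile = signal_profile(env)
    curve = compute_fluctuations(profile, env.fs, window_sizes, overlap=overlap)
    return fit_exponent(curve, fitting_range)


# One calibration per (bin edges, fs, filter settings, tolerance, seed).
_CALIBRATION_CACHE: dict[tuple, float] = {}


def calibrate_lower_bound(
    bin: FrequencyBin,
    fs: float,
    n_sims: int = 20,
    tolerance: float = 0.02,
    seed: int = 0,
    sim_duration: float = 600.0,
    t_max_calibration: float = 25.0,
    n_cycles: float = 2.0,
    transition_factor: float = 1.0,
    use_cache: bool = True,
) -> float:
    """Smallest trustworthy DFA window size (seconds) for a frequency bin.

    Simulates ``n_sims`` Gaussian white-noise signals, extracts the bin's
    amplitude envelope, and averages their fluctuation curves in log space.
    Filter-induced short-range correlations add a constant to the squared
    fluctuation function of an otherwise uncorrelated envelope,
    F^2(t) = a^2 t - c, which makes the local log-log slope approach the
    white-noise value 0.5 from above like 0.5 + 0.5 c / (a^2 t).  The two
    constants are fitted to the averaged curve beyond the filter transient,
    and the smallest window size whose analytic local slope deviates from
    0.5 by at most ``tolerance`` -- t* = c (0.5 + tolerance) / (a^2
    tolerance) -- is returned, discretized to the nearest grid size.
    Fitting the crossover parametrically instead of thresholding noisy
    finite-difference slopes keeps the calibration stable across seeds.
    The bound shrinks as the bin frequency grows because the filter
    transient does.

    A ``tolerance`` of ``inf`` degenerates to the smallest available window
    size.  Raises :class:`CalibrationError` (with the averaged curve
    attached) when the required window size exceeds ``t_max_calibration``.
    """
    if n_sims < 10:
        raise ValueError("n_sims must be >= 10 for a stable calibration")
    key = (
        bin.f_low, bin.f_high, fs, n_sims, tolerance, seed,
        sim_duration, t_max_calibration, n_cycles, transition_factor,
    )
    if use_cache and key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    fir = design_bandpass(
        bin, fs, n_cycles=n_cycles, transition_factor=transition_factor
    )
    # the simulated signal must survive trimming and hold several windows
    # of the largest calibration scale
    duration = max(sim_duration, 6 * t_max_calibration + 2 * fir.transient_seconds)
    n = int(round(duration * fs))
    grid = default_window_sizes(t_max=t_max_calibration)
    rng = np.random.default_rng(seed)
    log_curves = []
    sizes_ref = None
    for _ in range(n_sims):
        ts = TimeSeries(rng.standard_normal(n), fs)
        env = band_envelope(ts, bin, fir=fir)
        curve = compute_fluctuations(signal_profile(env), fs, grid)
        if sizes_ref is None:
            sizes_ref = curve.window_sizes
        log_curves.append(np.log10(curve.fluctuations))
    mean_log_f = np.mean(log_curves, axis=0)
    mean_curve = FluctuationCurve(
        window_sizes=sizes_ref,
        fluctuations=10.0**mean_log_f,
        n_windows=np.zeros(sizes_ref.size, dtype=int),
    )
    if not np.isfinite(tolerance):
        t_min = float(sizes_ref[0])
        if use_cache:
            _CALIBRATION_CACHE[key] = t_min
        return t_min

    t_star = _crossover_time(
        sizes_ref, mean_log_f,
        fit_from=max(2 * fir.transient_seconds, 0.5),
        tolerance=tolerance,
    )
    if t_star > sizes_ref[-1]:
        raise CalibrationError(
            f"local slope settles within {tolerance} of 0.5 only beyond "
            f"{t_star:.1f} s (> {t_max_calibration} s) for bin {bin} at "
            f"fs={fs}; use a shorter filter or a larger tolerance",
            curve=mean_curve,
        )
    # nearest grid size in log distance
    i = int(np.argmin(np.abs(np.log(sizes_ref) - np.log(t_star))))
    t_min = float(sizes_ref[i])
    if use_cache:
        _CALIBRATION_CACHE[key] = t_min
    return t_min


def _crossover_time(
    sizes: np.ndarray, mean_log_f: np.ndarray, fit_from: float, tolerance: float
) -> float:
    """Tolerance crossing of the F^2(t) = a^2 t - c short-range model."""
    from scipy.optimize import least_squares

    sel = sizes >= fit_from
    if sel.sum() < 4:
        raise CalibrationError(
            "too few window sizes beyond the filter transient to fit the "
            "fluctuation crossover"
        )
    t_fit, log_f = sizes[sel], mean_log_f[sel]
    a2_0 = (10.0 ** log_f[-1]) ** 2 / t_fit[-1]

    def residuals(p):
        a2, c = np.exp(p)
        model = np.maximum(a2 * t_fit - c, 1e-300)
        return 0.5 * np.log10(model) - log_f

    p0 = np.log([a2_0, max(0.1 * a2_0 * t_fit[0], 1e-12)])
    fit = least_squares(residuals, p0)
    a2, c = np.exp(fit.x)
    return c * (0.5 + tolerance) / (a2 * tolerance)
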