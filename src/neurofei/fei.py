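"""Functional excitation/inhibition ratio (fE/I).

fE/I infers the E/I balance of the network generating a narrow-band
oscillation from the windowed co-variation of the oscillation amplitude and
the amplitude-normalized fluctuation function nF(t), a short-timescale
proxy of the DFA exponent.  In slightly sub-critical networks amplitude and
temporal structure co-fluctuate positively (fE/I < 1), in super-critical
networks negatively (fE/I > 1), and at criticality they decouple
(fE/I = 1).  The measure is only defined in the presence of genuine LRTC,
gated by a DFA exponent > 0.6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from neurofei.bands import BandEnvelope, FrequencyBin, band_envelope, design_bandpass
from neurofei.dfa import (
    DEFAULT_T_MAX,
    DFA_GATE,
    DFAResult,
    EstimationError,
    FittingRange,
    calibrate_lower_bound,
    compute_fluctuations,
    default_window_sizes,
    fit_exponent,
    signal_profile,
)
from neurofei.timeseries import TimeSeries

#: Default fE/I window length in seconds.
FEI_WINDOW_SECONDS = 5.0
#: Default fE/I window overlap fraction.
FEI_OVERLAP = 0.8


@dataclass(frozen=True)
class WindowStats:
    """Per-window mean amplitude and normalized fluctuation (log10 scale)."""

    window_amplitudes: np.ndarray
    window_nf: np.ndarray  # log10 of the amplitude-normalized fluctuation
    window_size: float  # seconds
    overlap: float
    n_excluded: int = 0  # windows dropped for zero mean amplitude
    degenerate: bool = False  # constant envelope: zero fluctuation everywhere

    def __post_init__(self) -> None:
        a = np.asarray(self.window_amplitudes, dtype=np.float64)
        f = np.asarray(self.window_nf, dtype=np.float64)
        if a.size != f.size:
            raise ValueError("window_amplitudes and window_nf lengths differ")
        object.__setattr__(self, "window_amplitudes", a)
        object.__setattr__(self, "window_nf", f)

    @property
    def n_windows(self) -> int:
        return int(self.window_amplitudes.size)


@dataclass(frozen=True)
class FEIResult:
    """fE/I value (or the reason it is missing) plus its ingredients."""

    fei: float | None
    dfa_exponent: float
    n_windows: int
    correlation: float | None
    missing_reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.fei is None


def windowed_statistics(
    env: BandEnvelope,
    window_size: float = FEI_WINDOW_SECONDS,
    overlap: float = FEI_OVERLAP,
) -> WindowStats:
    """Mean amplitude and normalized fluctuation per sliding window.

    The signal profile (cumulative sum of the demeaned envelope) is computed
    once over the whole envelope.  Per window: the mean envelope amplitude,
    and the RMS residual of the linearly detrended profile segment divided
    by that mean amplitude.  Dividing by amplitude removes its influence on
    F(t) -- doubling the envelope doubles the window amplitudes but leaves
    nF(t) unchanged -- and the result is stored on a log10 scale.

    Windows whose mean amplitude is zero are excluded (nF undefined).
    """
    if env.duration < 2 * window_size:
        raise ValueError(
            f"envelope of {env.duration:.1f} s is shorter than two fE/I "
            f"windows of {window_size:g} s"
        )
    if not (0 <= overlap < 1):
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    n = int(round(window_size * env.fs))
    step = max(1, int(round(n * (1 - overlap))))
    x = env.envelope
    profile = signal_profile(env)
    amp_windows = np.lib.stride_tricks.sliding_window_view(x, n)[::step]
    prof_windows = np.lib.stride_tricks.sliding_window_view(profile, n)[::step]
    amps = amp_windows.mean(axis=1)

    t = np.arange(n, dtype=np.float64) - (n - 1) / 2.0
    denom = float(t @ t)
    slopes = prof_windows @ t / denom
    resid = (
        prof_windows
        - prof_windows.mean(axis=1, keepdims=True)
        - slopes[:, None] * t
    )
    fluct = np.sqrt(np.mean(resid**2, axis=1))

    keep = amps > 0
    n_excluded = int((~keep).sum())
    amps, fluct = amps[keep], fluct[keep]
    nf = fluct / amps
    degenerate = bool(np.all(nf == 0))
    if degenerate:
        warnings.warn(
            "constant envelope: zero fluctuation in every window",
            UserWarning,
            stacklevel=2,
        )
        log_nf = np.full(nf.shape, -np.inf)
    else:
        with np.errstate(divide="ignore"):
            log_nf = np.log10(nf)
    return WindowStats(
        window_amplitudes=amps,
        window_nf=log_nf,
        window_size=window_size,
        overlap=overlap,
        n_excluded=n_excluded,
        degenerate=degenerate,
    )


def compute_fei(
    stats: WindowStats,
    dfa: DFAResult,
    gate: float = DFA_GATE,
    method: str = "pearson",
) -> FEIResult:
    """fE/I = 1 - corr(window amplitude, window nF), gated by the DFA exponent.

    When the gate exponent is <= ``gate`` (default 0.6) amplitude and
    temporal structure do not co-vary and the ratio is reported as missing
    rather than as a number.
    """
    if stats.n_windows < 10:
        raise EstimationError(
            f"need >= 10 windows to correlate, got {stats.n_windows}"
        )
    base = dict(dfa_exponent=dfa.exponent, n_windows=stats.n_windows)
    if stats.degenerate or not np.all(np.isfinite(stats.window_nf)):
        return FEIResult(
            fei=None, correlation=None,
            missing_reason="degenerate_input", **base,
        )
    a, f = stats.window_amplitudes, stats.window_nf
    if np.ptp(a) == 0 or np.ptp(f) == 0:
        return FEIResult(
            fei=None, correlation=None,
            missing_reason="zero_variance", **base,
        )
    if method == "pearson":
        r = float(np.corrcoef(a, f)[0, 1])
    elif method == "spearman":
        from scipy.stats import spearmanr

        r = float(spearmanr(a, f).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    if dfa.exponent <= gate:
        return FEIResult(
            fei=None, correlation=r, missing_reason="dfa_gate", **base
        )
    return FEIResult(fei=1.0 - r, correlation=r, missing_reason=None, **base)


def spectral_fei(
    ts: TimeSeries,
    bins: list[FrequencyBin],
    window_size: float = FEI_WINDOW_SECONDS,
    overlap: float = FEI_OVERLAP,
    t_max: float = DEFAULT_T_MAX,
    t_min: float | None = None,
    gate: float = DFA_GATE,
    dfa_overlap: float = 0.5,
    calibration_tolerance: float = 0.02,
    n_cycles: float = 2.0,
    transition_factor: float = 1.0,
    method: str = "pearson",
    warn_short: bool = True,
) -> pd.DataFrame:
    """DFA and fE/I per frequency bin for one recording.

    Per bin: band envelope -> DFA over the frequency-adaptive fitting range
    (lower bound calibrated on band-limited white noise unless ``t_min`` is
    given; upper bound ``t_max``, shrunk to 1/6 of the signal length when
    needed) -> windowed fE/I.  Per-bin failures are recorded, not raised, so
    one bad bin does not abort the others.

    Returns a tidy table with one row per bin: ``bin_low, bin_high, dfa,
    r_squared, t_min, t_max, fei, correlation, n_windows, missing_reason``.
    """
    if warn_short:
        ts.check_analysis_length()
    rows = []
    for fbin in bins:
        row: dict = {"bin_low": fbin.f_low, "bin_high": fbin.f_high}
        try:
            fir = design_bandpass(
                fbin, ts.fs, n_cycles=n_cycles,
                transition_factor=transition_factor,
            )
            env = band_envelope(ts, fbin, fir=fir)
            if t_min is None:
                lo = calibrate_lower_bound(
                    fbin, ts.fs, tolerance=calibration_tolerance,
                    n_cycles=n_cycles, transition_factor=transition_factor,
                )
            else:
                lo = t_min
            hi = min(t_max, env.duration / 6.0)
            fit_range = FittingRange(t_min=lo, t_max=hi)
            curve = compute_fluctuations(
                signal_profile(env), env.fs,
                default_window_sizes(t_max=hi), overlap=dfa_overlap,
            )
            dfa_res = fit_exponent(curve, fit_range)
            stats = windowed_statistics(env, window_size, overlap)
            fei_res = compute_fei(stats, dfa_res, gate=gate, method=method)
            row.update(
                dfa=dfa_res.exponent,
                r_squared=dfa_res.r_squared,
                t_min=lo,
                t_max=hi,
                fei=np.nan if fei_res.fei is None else fei_res.fei,
                correlation=(
                    np.nan if fei_res.correlation is None else fei_res.correlation
                ),
                n_windows=fei_res.n_windows,
                missing_reason=fei_res.missing_reason,
            )
        except (ValueError, EstimationError) as exc:
            row.update(
                dfa=np.nan, r_squared=np.nan, t_min=np.nan, t_max=np.nan,
                fei=np.nan, correlation=np.nan, n_windows=0,
                missing_reason=f"error: {exc}",
            )
        rows.append(row)
    return pd.DataFrame(rows)
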