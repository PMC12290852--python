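"""Neuronal avalanches and the k-index criticality metric.

An avalanche is a contiguous period in which the population spike count
stays above half the median activity; its size is the total number of
spikes in the period.  The k-index compares the empirical cumulative size
(or duration) distribution A with the CDF P of a reference power law
(exponent -1.5 for sizes, -2.0 for durations) at 10 log-spaced evaluation
points: k = mean(P - A) + 1.  Sub-critical (quickly dissipating) activity
gives k < 1, heavy-tailed super-critical activity k > 1, and k = 1 marks
criticality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from neurofei.dfa import EstimationError

#: Reference power-law exponents for avalanche sizes and durations.
SIZE_EXPONENT = -1.5
DURATION_EXPONENT = -2.0

#: Near-critical k range determined from the simulator's phase space.
NEAR_CRITICAL_K = (0.87, 1.14)


@dataclass(frozen=True)
class AvalancheSet:
    """Sizes and durations of supra-threshold activity periods."""

    sizes: np.ndarray  # total spikes per avalanche
    durations: np.ndarray  # timesteps per avalanche
    threshold: float  # half the median per-step activity

    def __post_init__(self) -> None:
        s = np.asarray(self.sizes, dtype=np.float64)
        d = np.asarray(self.durations, dtype=np.int64)
        if s.size != d.size:
            raise ValueError("sizes and durations lengths differ")
        object.__setattr__(self, "sizes", s)
        object.__setattr__(self, "durations", d)

    @property
    def n_avalanches(self) -> int:
        return int(self.sizes.size)


@dataclass(frozen=True)
class KIndex:
    """k-index against a reference power law."""

    k: float
    reference_exponent: float
    evaluation_points: np.ndarray  # the 10 log-spaced beta values

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "evaluation_points",
            np.asarray(self.evaluation_points, dtype=np.float64),
        )


def detect_avalanches(activity: np.ndarray) -> AvalancheSet:
    """Segment population activity into avalanches.

    The threshold is half the median per-step activity; maximal contiguous
    runs of strictly supra-threshold steps become avalanches with
    size = total spikes in the run and duration = run length.
    """
    activity = np.asarray(activity, dtype=np.float64)
    if activity.size == 0:
        raise ValueError("empty activity")
    threshold = 0.5 * float(np.median(activity))
    above = activity > threshold
    if not above.any():
        warnings.warn(
            "no supra-threshold activity: empty avalanche set",
            UserWarning,
            stacklevel=2,
        )
        return AvalancheSet(np.array([]), np.array([], dtype=int), threshold)
    if above.all():
        warnings.warn(
            "activity never drops below threshold: a single avalanche spans "
            "the whole record (degenerate segmentation)",
            UserWarning,
            stacklevel=2,
        )
    # run boundaries of the boolean mask
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [above.size]))
    csum = np.concatenate(([0.0], np.cumsum(activity)))
    sizes = csum[ends] - csum[starts]
    durations = ends - starts
    return AvalancheSet(sizes=sizes, durations=durations, threshold=threshold)


def powerlaw_cdf(beta: np.ndarray, exponent: float, support: tuple[float, float]) -> np.ndarray:
    """CDF of a continuous power law with the given density exponent on ``support``."""
    lo, hi = support
    if not (0 < lo < hi):
        raise ValueError(f"invalid support {support}")
    beta = np.asarray(beta, dtype=np.float64)
    a1 = exponent + 1.0
    if a1 == 0:
        return (np.log(beta) - np.log(lo)) / (np.log(hi) - np.log(lo))
    return (beta**a1 - lo**a1) / (hi**a1 - lo**a1)


def k_index(
    sizes: np.ndarray,
    reference_exponent: float = SIZE_EXPONENT,
    n_points: int = 10,
    empirical: str = "step",
) -> KIndex:
    """k-index of an avalanche size (or duration) sample.

    k = (1/n) sum_i [P(beta_i) - A(beta_i)] + 1, with P the reference
    power-law CDF (normalized over the empirical support [min, max]) and A
    the empirical CDF, evaluated at ``n_points`` logarithmically equally
    spaced beta between the smallest and largest observed value, inclusive.

    ``empirical`` chooses the evaluation of A at beta_i: ``"step"`` (the
    default, fraction of observations <= beta_i) or ``"interp"`` (linear
    interpolation between the step CDF's jump points).
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    sizes = sizes[np.isfinite(sizes)]
    if sizes.size < 2 or np.unique(sizes).size < 2:
        raise EstimationError(
            "k-index needs at least 2 distinct observed sizes"
        )
    if np.any(sizes <= 0):
        raise EstimationError("avalanche sizes must be positive")
    lo, hi = float(sizes.min()), float(sizes.max())
    beta = np.logspace(np.log10(lo), np.log10(hi), n_points)
    p = powerlaw_cdf(beta, reference_exponent, (lo, hi))
    sorted_sizes = np.sort(sizes)
    if empirical == "step":
        a = np.searchsorted(sorted_sizes, beta, side="right") / sizes.size
    elif empirical == "interp":
        ecdf_y = np.arange(1, sizes.size + 1) / sizes.size
        a = np.interp(beta, sorted_sizes, ecdf_y)
    else:
        raise ValueError(f"unknown empirical CDF mode {empirical!r}")
    k = float(np.mean(p - a) + 1.0)
    return KIndex(k=k, reference_exponent=reference_exponent, evaluation_points=beta)


def classify_near_critical(
    k: KIndex | float,
    bounds: tuple[float, float] = NEAR_CRITICAL_K,
) -> str:
    """Label a k value as ``'sub'``, ``'near-critical'`` or ``'super'``."""
    value = k.k if isinstance(k, KIndex) else float(k)
    lo, hi = bounds
    if value < lo:
        return "sub"
    if value > hi:
        return "super"
    return "near-critical"


def sample_powerlaw(
    n: int,
    exponent: float = SIZE_EXPONENT,
    support: tuple[float, float] = (1.0, 1e4),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Inverse-CDF samples from a continuous power law on ``support``.

    Independent reference oracle for the k-index self-consistency check: a
    sample drawn exactly from the reference law has k -> 1.
    """
    rng = np.random.default_rng(rng)
    lo, hi = support
    a1 = exponent + 1.0
    u = rng.random(n)
    if a1 == 0:
        return lo * (hi / lo) ** u
    return (lo**a1 + u * (hi**a1 - lo**a1)) ** (1.0 / a1)
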