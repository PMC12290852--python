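"""CRitical OScillations (CROS) network simulator.

A population of probabilistic integrate-and-fire neurons on an open
(non-wrapping) square grid, 75% excitatory / 25% inhibitory.  The control
parameters are the synapse densities per source type: each excitatory
neuron connects to C_E% of the neurons within its local range, each
inhibitory neuron to C_I% of the neurons within its (smaller) local range.
Tuning (C_E, C_I) moves the network between
sub-critical, critical, and super-critical regimes: along the diagonal
C_E + C_I = 80% the avalanche k-index crosses 1 and narrow-band amplitude
envelopes develop long-range temporal correlations near the crossing.

Dynamics (1-ms timesteps, synchronous update): each neuron carries an
excitatory and an inhibitory input trace, each decaying exponentially with
its own time constant and incremented by the signed synaptic weights of the
previous step's presynaptic spikes.  The neuron fires with probability
p_spont + (1 - p_spont) * clip(vE - vI, 0, 1); firing consumes the
excitatory trace (hyperpolarization persists) and triggers an absolute
refractory period.  Optional multi-timescale short-term synaptic depression
scales each neuron's outgoing efficacy by slowly recovering resource pools.
The EEG-like network signal is the per-step population spike count plus
Gaussian white measurement noise (SD 3 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

#: Measurement-noise standard deviation added to the population signal.
DEFAULT_NOISE_SD = 3.0


@dataclass(frozen=True)
class NetworkConfig:
    """Topology and dynamics parameters of a CROS network.

    Connectivity percentages ``c_e``/``c_i`` are the model's control
    parameters; all dynamics constants are exposed so an alternative
    parameter table can be supplied without code changes.  Synaptic weights
    ``w_xy`` denote the signed weight from a type-X source onto a type-Y
    target (excitatory sources positive, inhibitory negative).
    """

    c_e: float = 36.0  # % of local neurons each excitatory neuron targets
    c_i: float = 44.0  # % of local neurons each inhibitory neuron targets
    grid_side: int = 50
    frac_excitatory: float = 0.75
    local_range_e: int = 4  # Chebyshev range of excitatory sources
    local_range_i: int = 2  # Chebyshev range of inhibitory sources
    w_ee: float = 0.008
    w_ei: float = 0.008
    w_ie: float = -0.05
    w_ii: float = -0.05
    tau_ms: float = 9.0  # decay time constant of the excitatory input trace
    tau_inh_ms: float = 9.0  # decay of the inhibitory input trace
    p_spont: float = 1e-5  # spontaneous firing probability per step
    refractory_ms: float = 10.0  # absolute refractory period after a spike
    depression_u: float = 0.0  # per-pool resource used per excitatory spike
    depression_u_inh: float = 0.0  # per-pool resource used per inhibitory spike
    #: recovery time constants of the short-term-depression pools; several
    #: log-spread timescales give the synaptic efficacy an approximately
    #: 1/f modulation over the seconds range
    tau_recovery_ms: tuple[float, ...] = (500.0, 2000.0, 8000.0, 32000.0)
    timestep_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.c_e <= 100 and 0 <= self.c_i <= 100):
            raise ValueError("connectivity percentages must be in [0, 100]")
        if not (0 < self.frac_excitatory < 1):
            raise ValueError("frac_excitatory must be in (0, 1)")
        if self.grid_side < 2:
            raise ValueError("grid_side must be >= 2")
        if self.local_range_e < 1 or self.local_range_i < 1:
            raise ValueError("local ranges must be >= 1")
        if self.tau_ms <= 0 or self.tau_inh_ms <= 0 or self.timestep_ms <= 0:
            raise ValueError("time constants and timestep must be positive")
        taus = self.tau_recovery_ms
        if np.isscalar(taus):
            taus = (float(taus),)
        object.__setattr__(self, "tau_recovery_ms", tuple(float(t) for t in taus))
        if any(t <= 0 for t in self.tau_recovery_ms):
            raise ValueError("recovery time constants must be positive")

    @property
    def n_neurons(self) -> int:
        return self.grid_side**2

    @property
    def fs(self) -> float:
        """Sampling rate of the emitted population signal in Hz."""
        return 1000.0 / self.timestep_ms

    def with_connectivity(self, c_e: float, c_i: float, seed: int | None = None) -> "NetworkConfig":
        return replace(
            self, c_e=c_e, c_i=c_i, seed=self.seed if seed is None else seed
        )


@dataclass(frozen=True)
class Network:
    """A realized topology: CSR adjacency with signed synaptic weights."""

    config: NetworkConfig
    indptr: np.ndarray  # CSR row pointers, one row per presynaptic neuron
    indices: np.ndarray  # postsynaptic neuron ids
    weights: np.ndarray  # signed synaptic weights
    excitatory: np.ndarray  # bool per neuron

    @property
    def n_neurons(self) -> int:
        return int(self.excitatory.size)

    def out_degree(self, to_excitatory: bool | None = None) -> np.ndarray:
        """Out-degree per neuron, optionally restricted by target type."""
        if to_excitatory is None:
            return np.diff(self.indptr)
        mask = self.excitatory[self.indices] == to_excitatory
        return np.add.reduceat(
            mask.astype(np.int64), self.indptr[:-1]
        ) * (np.diff(self.indptr) > 0)


@dataclass(frozen=True)
class SpikeRaster:
    """Per-timestep population spike counts from one simulation run."""

    counts: np.ndarray  # int, one entry per timestep
    fs: float
    config: NetworkConfig | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", np.asarray(self.counts, dtype=np.int64)
        )

    @property
    def duration(self) -> float:
        return self.counts.size / self.fs


def build_network(cfg: NetworkConfig) -> Network:
    """Assign E/I identities and sample the probabilistic local topology.

    Exactly ``round(frac_excitatory * n)`` neurons are excitatory, placed
    uniformly at random.  Each *excitatory* neuron connects, independently
    with probability ``c_e/100``, to each neuron within Chebyshev distance
    ``local_range_e`` (excluding itself); each *inhibitory* neuron connects
    with probability ``c_i/100`` to each neuron within ``local_range_i``.
    The mean out-degree of an excitatory neuron to excitatory targets is
    therefore C_E% of the local excitatory candidates, with binomial
    sampling error across seeds.
    """
    g = cfg.grid_side
    n = cfg.n_neurons
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC805]))
    n_exc = int(round(cfg.frac_excitatory * n))
    if n_exc == 0 or n_exc == n:
        raise ValueError("network must contain both excitatory and inhibitory neurons")
    excitatory = np.zeros(n, dtype=bool)
    excitatory[rng.choice(n, size=n_exc, replace=False)] = True
    exc_grid = excitatory.reshape(g, g)

    ids = np.arange(n).reshape(g, g)
    targets_per_source: list[np.ndarray] = []
    for row in range(g):
        for col in range(g):
            j = row * g + col
            if excitatory[j]:
                reach, p = cfg.local_range_e, cfg.c_e / 100.0
            else:
                reach, p = cfg.local_range_i, cfg.c_i / 100.0
            if p <= 0:
                targets_per_source.append(np.empty(0, dtype=np.int64))
                continue
            r0, r1 = max(0, row - reach), min(g, row + reach + 1)
            c0, c1 = max(0, col - reach), min(g, col + reach + 1)
            cand = ids[r0:r1, c0:c1].ravel()
            cand = cand[cand != j]
            if cand.size == 0:
                raise ValueError(
                    f"local range contains no candidate neurons for neuron {j}"
                )
            targets_per_source.append(cand[rng.random(cand.size) < p])

    indptr = np.zeros(n + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([t.size for t in targets_per_source])
    indices = (
        np.concatenate(targets_per_source)
        if indptr[-1] > 0
        else np.empty(0, dtype=np.int64)
    ).astype(np.int64)
    w_lut = np.array(
        [[cfg.w_ii, cfg.w_ie], [cfg.w_ei, cfg.w_ee]], dtype=np.float64
    )  # [source is E][target is E]
    src_exc = np.repeat(excitatory, np.diff(indptr))
    tgt_exc = excitatory[indices] if indices.size else np.empty(0, dtype=bool)
    weights = w_lut[src_exc.astype(int), tgt_exc.astype(int)]
    return Network(
        config=cfg,
        indptr=indptr,
        indices=indices,
        weights=weights,
        excitatory=excitatory,
    )


@njit(cache=True)
def _simulate_loop(
    indptr, indices, weights, excitatory, n_neurons, n_steps,
    decay_exc, decay_inh, p_spont, t_ref, depl_u, depl_u_inh, rec_rates, seed,
):
    np.random.seed(seed)
    n_pools = rec_rates.size
    v_exc = np.zeros(n_neurons, dtype=np.float64)
    v_inh = np.zeros(n_neurons, dtype=np.float64)
    resource = np.ones((n_neurons, n_pools), dtype=np.float64)
    spiked = np.zeros(n_neurons, dtype=np.bool_)
    refr = np.zeros(n_neurons, dtype=np.int64)
    counts = np.zeros(n_steps, dtype=np.int64)
    for t in range(n_steps):
        # synchronous update: integrate last step's spikes, then decay
        for j in range(n_neurons):
            if spiked[j]:
                # synaptic efficacy is scaled by the product of the
                # presynaptic short-term resource pools, then depleted
                r = 1.0
                for q in range(n_pools):
                    r *= resource[j, q]
                if excitatory[j]:
                    for p in range(indptr[j], indptr[j + 1]):
                        v_exc[indices[p]] += weights[p] * r
                    for q in range(n_pools):
                        resource[j, q] *= 1.0 - depl_u
                else:
                    for p in range(indptr[j], indptr[j + 1]):
                        v_inh[indices[p]] -= weights[p] * r
                    for q in range(n_pools):
                        resource[j, q] *= 1.0 - depl_u_inh
        c = 0
        for i in range(n_neurons):
            v_exc[i] *= decay_exc
            v_inh[i] *= decay_inh
            for q in range(n_pools):
                resource[i, q] += rec_rates[q] * (1.0 - resource[i, q])
            if refr[i] > 0:
                refr[i] -= 1
                spiked[i] = False
                continue
            drive = v_exc[i] - v_inh[i]
            if drive < 0.0:
                drive = 0.0
            elif drive > 1.0:
                drive = 1.0
            prob = p_spont + (1.0 - p_spont) * drive
            if np.random.random() < prob:
                spiked[i] = True
                # firing consumes the excitatory drive; inhibition persists
                v_exc[i] = 0.0
                refr[i] = t_ref
                c += 1
            else:
                spiked[i] = False
        counts[t] = c
    return counts


def run_simulation(
    network: Network,
    duration: float,
    fs: float | None = None,
    dynamics_seed: int | None = None,
) -> SpikeRaster:
    """Advance the probabilistic integrate-and-fire dynamics.

    ``fs`` defaults to (and must match) the config's timestep; the dynamics
    random stream is separate from the topology stream and derived from the
    config seed unless ``dynamics_seed`` is given.  Identical (network,
    seed) reproduce the raster bit for bit.
    """
    cfg = network.config
    if fs is None:
        fs = cfg.fs
    if abs(fs - cfg.fs) > 1e-9:
        raise ValueError(
            f"fs={fs} Hz does not match the config timestep of "
            f"{cfg.timestep_ms} ms ({cfg.fs} Hz)"
        )
    n_steps = int(round(duration * fs))
    if n_steps < 1:
        raise ValueError("duration x fs must be >= 1")
    if dynamics_seed is None:
        dynamics_seed = int(
            np.random.SeedSequence([cfg.seed, 0xD1]).generate_state(1)[0] % (2**31)
        )
    counts = _simulate_loop(
        network.indptr,
        network.indices,
        network.weights,
        network.excitatory,
        network.n_neurons,
        n_steps,
        math.exp(-cfg.timestep_ms / cfg.tau_ms),
        math.exp(-cfg.timestep_ms / cfg.tau_inh_ms),
        cfg.p_spont,
        int(round(cfg.refractory_ms / cfg.timestep_ms)),
        cfg.depression_u,
        cfg.depression_u_inh,
        cfg.timestep_ms / np.atleast_1d(np.asarray(cfg.tau_recovery_ms, dtype=np.float64)),
        dynamics_seed,
    )
    return SpikeRaster(counts=counts, fs=fs, config=cfg)


def network_signal(
    raster: SpikeRaster,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
) -> np.ndarray:
    """EEG-like signal: spike counts plus i.i.d. Gaussian white noise.

    The noise (mean 0, SD 3 by default) guarantees a time-varying phase in
    otherwise silent periods.  The noise stream is independent of the
    topology and dynamics streams.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    signal = raster.counts.astype(np.float64)
    if noise_sd > 0:
        if seed is None:
            base = raster.config.seed if raster.config is not None else 0
            seed = int(
                np.random.SeedSequence([base, 0x5E]).generate_state(1)[0] % (2**31)
            )
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, signal.size)
    return signal


def sample_diagonal(
    start_ce: float = 30.0,
    end_ce: float = 42.0,
    step: float = 0.5,
    total: float = 80.0,
) -> list[tuple[float, float]]:
    """(C_E, C_I) pairs along the diagonal C_E + C_I = ``total``.

    The defaults trace C_E from 30% to 42% (C_I from 50% down to 38%) at
    0.5% intervals: 25 combinations crossing the critical line.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(math.floor((end_ce - start_ce) / step + 1e-9)) + 1
    return [
        (round(start_ce + i * step, 10), round(total - start_ce - i * step, 10))
        for i in range(n)
    ]


def sample_phase_space(
    low: float = 20.0,
    high: float = 100.0,
    step: float = 2.0,
) -> list[tuple[float, float]]:
    """Full Cartesian grid of (C_E, C_I) combinations, endpoints inclusive."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(math.floor((high - low) / step + 1e-9)) + 1
    vals = [round(low + i * step, 10) for i in range(n)]
    return [(ce, ci) for ce in vals for ci in vals]
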