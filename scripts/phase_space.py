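"""Coarse phase-space sweep of the critical-oscillations network.

Long-running exploration script: simulates a (C_E, C_I) grid, computes the
avalanche k-index and the alpha-band DFA/fE/I for each combination, and
writes one tidy CSV.  The full 20-100% grid at 2% steps (1,681
combinations x 10 realizations x 1000 s) is a large batch; the default here
is a much coarser sub-grid that still shows the near-critical band
structure.

Usage:
    python scripts/phase_space.py --low 24 --high 60 --step 6 \
        --realizations 2 --duration 300 --seed 1 --out phase_space.csv
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from neurofei.avalanches import detect_avalanches, k_index
from neurofei.bands import FrequencyBin
from neurofei.cros import (
    NetworkConfig,
    build_network,
    network_signal,
    run_simulation,
    sample_phase_space,
)
from neurofei.dfa import EstimationError
from neurofei.fei import spectral_fei
from neurofei.timeseries import TimeSeries


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--low", type=float, default=24.0)
    parser.add_argument("--high", type=float, default=60.0)
    parser.add_argument("--step", type=float, default=6.0)
    parser.add_argument("--realizations", type=int, default=2)
    parser.add_argument("--duration", type=float, default=300.0)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    bins = [FrequencyBin(8.0, 10.5, 4), FrequencyBin(10.5, 13.0, 5)]
    combos = sample_phase_space(args.low, args.high, args.step)
    run_seeds = np.random.SeedSequence(args.seed).generate_state(
        len(combos) * args.realizations
    )
    rows = []
    idx = 0
    for c_e, c_i in combos:
        for real in range(args.realizations):
            seed = int(run_seeds[idx] % (2**31))
            idx += 1
            cfg = NetworkConfig(c_e=c_e, c_i=c_i, seed=seed)
            raster = run_simulation(build_network(cfg), args.duration)
            try:
                k = k_index(detect_avalanches(raster.counts).sizes).k
            except EstimationError:
                k = np.nan
            ts = TimeSeries(network_signal(raster), raster.fs)
            table = spectral_fei(ts, bins, warn_short=False)
            for _, row in table.iterrows():
                rows.append(
                    dict(
                        c_e=c_e, c_i=c_i, realization=real, k=k,
                        bin_low=row.bin_low, bin_high=row.bin_high,
                        dfa=row.dfa, fei=row.fei,
                    )
                )
            print(f"[{idx}] C_E={c_e} C_I={c_i} k={k:.3f}", flush=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {len(rows)} rows to {args.out}")


if __name__ == "__main__":
    main()
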