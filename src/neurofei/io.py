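"""Readers and writers for recordings, simulator runs, and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from neurofei.cros import NetworkConfig, SpikeRaster
from neurofei.timeseries import TimeSeries


def read_recording(path: str | Path, format: str | None = None) -> list[TimeSeries]:
    """Read a continuous recording into one TimeSeries per channel.

    Supported formats: EDF (``.edf``), BrainVision (``.vhdr``), and plain
    CSV/TSV matrices (channels x samples) accompanied by a JSON sidecar
    (same stem, ``.json``) that must carry the sampling rate under ``"fs"``
    and may carry ``"channels"`` labels.  ``format`` overrides extension
    detection with ``"edf"``, ``"brainvision"``, or ``"csv"``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".edf": "edf",
            ".vhdr": "brainvision",
            ".csv": "csv",
            ".tsv": "csv",
        }.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from extension {suffix!r}")

    if format in ("edf", "brainvision"):
        import mne

        reader = {
            "edf": mne.io.read_raw_edf,
            "brainvision": mne.io.read_raw_brainvision,
        }[format]
        raw = reader(path, preload=True, verbose="error")
        fs = float(raw.info["sfreq"])
        data = raw.get_data()
        return [
            TimeSeries(data[i], fs, channel_id=name)
            for i, name in enumerate(raw.ch_names)
        ]

    if format == "csv":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"CSV recordings need a JSON sidecar with the sampling rate; "
                f"{sidecar} not found"
            )
        meta = json.loads(sidecar.read_text())
        if "fs" not in meta:
            raise KeyError(
                f"sidecar {sidecar} is missing the required field 'fs'"
            )
        fs = float(meta["fs"])
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        data = pd.read_csv(path, header=None, sep=sep).to_numpy(dtype=float)
        labels = meta.get("channels") or [f"ch{i}" for i in range(data.shape[0])]
        if len(labels) != data.shape[0]:
            raise ValueError(
                f"{len(labels)} channel labels for {data.shape[0]} rows"
            )
        return [
            TimeSeries(data[i], fs, channel_id=labels[i])
            for i in range(data.shape[0])
        ]

    raise ValueError(f"unknown format {format!r}")


def write_matrix_recording(
    path: str | Path, series: list[TimeSeries], channels: list[str] | None = None
) -> None:
    """Write channels x samples CSV plus the JSON sidecar ``read_recording`` expects."""
    path = Path(path)
    data = np.vstack([ts.samples for ts in series])
    pd.DataFrame(data).to_csv(path, header=False, index=False)
    meta = {
        "fs": series[0].fs,
        "channels": channels
        or [ts.channel_id or f"ch{i}" for i, ts in enumerate(series)],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def save_raster(path: str | Path, raster: SpikeRaster) -> None:
    """Persist a simulation run (counts + embedded config) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=raster.counts, compression="gzip")
        f.attrs["fs"] = raster.fs
        if raster.config is not None:
            from dataclasses import asdict

            f.attrs["config"] = json.dumps(asdict(raster.config))


def load_raster(path: str | Path) -> SpikeRaster:
    import h5py

    with h5py.File(path, "r") as f:
        counts = f["counts"][:]
        fs = float(f.attrs["fs"])
        cfg = None
        if "config" in f.attrs:
            cfg = NetworkConfig(**json.loads(f.attrs["config"]))
    return SpikeRaster(counts=counts, fs=fs, config=cfg)


def write_avalanches(path: str | Path, avalanches, k: float | None = None) -> None:
    """Export an avalanche set to CSV (sizes, durations) plus a JSON summary.

    The sibling ``<path>.json`` carries the detection threshold, the count,
    and optionally the k-index of the run.
    """
    path = Path(path)
    pd.DataFrame(
        {"size": avalanches.sizes, "duration": avalanches.durations}
    ).to_csv(path, index=False)
    summary = {
        "threshold": avalanches.threshold,
        "n_avalanches": avalanches.n_avalanches,
    }
    if k is not None:
        summary["k"] = float(k)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )


def write_results(path: str | Path, table: pd.DataFrame, config_json: str | None = None) -> None:
    """Write a tidy results table; the resolved config rides along as a sibling file."""
    path = Path(path)
    table.to_csv(path, index=False)
    if config_json is not None:
        path.with_suffix(path.suffix + ".config.json").write_text(config_json)
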