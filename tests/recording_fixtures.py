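"""Minimal EDF and BrainVision writers for round-trip fixtures.

Only used by the tests: they emit small, spec-conformant files so the
readers can be exercised without shipping binary data.
"""

from pathlib import Path

import numpy as np


def write_edf(path: Path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    """Write a minimal EDF file (one data record per second, int16)."""
    n_ch, n_samp = data.shape
    record_len = int(fs)
    n_records = n_samp // record_len
    data = data[:, : n_records * record_len]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    dig_min, dig_max = -32768, 32767

    def pad(value, width):
        s = str(value)[:width]
        return s.ljust(width)

    header = b""
    header += pad("0", 8).encode()
    header += pad("test subject", 80).encode()
    header += pad("test recording", 80).encode()
    header += pad("01.01.20", 8).encode()
    header += pad("00.00.00", 8).encode()
    header += pad(str(256 * (1 + n_ch)), 8).encode()
    header += pad("", 44).encode()
    header += pad(str(n_records), 8).encode()
    header += pad("1", 8).encode()  # record duration, seconds
    header += pad(str(n_ch), 4).encode()
    for lab in labels:
        header += pad(lab, 16).encode()
    header += b"".join(pad("", 80).encode() for _ in range(n_ch))  # transducer
    header += b"".join(pad("uV", 8).encode() for _ in range(n_ch))
    header += b"".join(pad(f"{m:.4f}"[:8], 8).encode() for m in phys_min)
    header += b"".join(pad(f"{m:.4f}"[:8], 8).encode() for m in phys_max)
    header += b"".join(pad(str(dig_min), 8).encode() for _ in range(n_ch))
    header += b"".join(pad(str(dig_max), 8).encode() for _ in range(n_ch))
    header += b"".join(pad("", 80).encode() for _ in range(n_ch))  # prefilter
    header += b"".join(pad(str(record_len), 8).encode() for _ in range(n_ch))
    header += b"".join(pad("", 32).encode() for _ in range(n_ch))

    scaled = np.empty_like(data, dtype=np.int16)
    for i in range(n_ch):
        scaled[i] = np.round(
            (data[i] - phys_min[i]) / span[i] * (dig_max - dig_min) + dig_min
        ).astype(np.int16)

    with open(path, "wb") as f:
        f.write(header)
        for rec in range(n_records):
            sl = slice(rec * record_len, (rec + 1) * record_len)
            for i in range(n_ch):
                f.write(scaled[i, sl].astype("<i2").tobytes())


def write_brainvision(stem: Path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    """Write a minimal BrainVision triplet (.vhdr/.vmrk/.eeg, float32)."""
    n_ch, _ = data.shape
    vhdr = stem.with_suffix(".vhdr")
    vmrk = stem.with_suffix(".vmrk")
    eeg = stem.with_suffix(".eeg")
    channel_lines = "\n".join(
        f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(labels)
    )
    vhdr.write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={eeg.name}\n"
        f"MarkerFile={vmrk.name}\n"
        "DataFormat=BINARY\n"
        "DataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={n_ch}\n"
        f"SamplingInterval={1e6 / fs:.6f}\n"
        "[Binary Infos]\n"
        "BinaryFormat=IEEE_FLOAT_32\n"
        f"[Channel Infos]\n{channel_lines}\n",
        encoding="utf-8",
    )
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={eeg.name}\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n",
        encoding="utf-8",
    )
    data.T.astype("<f4").tofile(eeg)
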