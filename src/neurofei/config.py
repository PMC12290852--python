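"""Analysis configuration: one declarative record driving the full pipeline.

The resolved configuration of every run is embedded in its outputs so a
result file is self-describing; the record round-trips losslessly through
JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Parameters of the spectral DFA / fE/I pipeline."""

    # frequency binning
    f_min: float = 1.0
    f_max: float = 150.0
    n_log_bins: int = 15
    delta_edge: float = 4.0
    use_default_scheme: bool = True  # pinned canonical edges vs. generic geometric

    # FIR filter
    filter_n_cycles: float = 2.0
    filter_transition_factor: float = 1.0
    filter_window: str = "hamming"

    # DFA
    t_max: float = 30.0
    t_min: float | None = None  # None -> frequency-adaptive calibration
    calibration_tolerance: float = 0.02
    dfa_overlap: float = 0.5

    # fE/I
    fei_window: float = 5.0
    fei_overlap: float = 0.8
    gate: float = 0.6
    correlation: str = "pearson"

    # reproducibility
    seed: int = 0

    def bins(self):
        from neurofei.bands import default_bins, make_frequency_bins

        if self.use_default_scheme:
            return default_bins()
        return make_frequency_bins(
            self.f_min, self.f_max, self.n_log_bins, self.delta_edge
        )

    def spectral_kwargs(self) -> dict:
        """Keyword arguments for :func:`neurofei.fei.spectral_fei`."""
        return dict(
            window_size=self.fei_window,
            overlap=self.fei_overlap,
            t_max=self.t_max,
            t_min=self.t_min,
            gate=self.gate,
            dfa_overlap=self.dfa_overlap,
            calibration_tolerance=self.calibration_tolerance,
            n_cycles=self.filter_n_cycles,
            transition_factor=self.filter_transition_factor,
            method=self.correlation,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        return cls(**data)
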