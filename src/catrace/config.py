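"""Run-wide configuration for the trace-characterization pipeline.

A single :class:`PipelineConfig` instance is threaded through every stage so
that one seed and one set of tuning knobs govern a whole batch run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class PipelineConfig:
    # -- total-variation derivative estimation -------------------------------
    #: scale factor c in alpha = c * sigma_plus * N * mean(dt)
    tv_alpha_scale: float = 1.0
    tv_max_iter: int = 50
    #: spike-rejection thresholds in units of tau_rm * sigma_plus; the
    #: multiplier keeps rejection targeted at high-amplitude contamination
    #: rather than the upper tail of ordinary Gaussian residuals
    spike_threshold_scale: float = 3.0

    # -- drift fitting -------------------------------------------------------
    drift_multistart: int = 3
    #: seconds to discard from the start of each trace before analysis
    trim_before: float | None = None

    # -- transient-response fitting ------------------------------------------
    hill_n_max: float = 50.0
    #: minimum number of samples after the inflection point for tau_decay
    min_tail_points: int = 10
    #: detection threshold in units of sigma_minus, and its minimum run length
    detection_sigma: float = 4.0
    detection_min_points: int = 6

    # -- multi-peaked-response analysis --------------------------------------
    mpr_min_height_sigma: float = 6.0
    mpr_min_spacing_s: float = 5.0
    gmm_kmax: int = 5
    gap_B: int = 20

    # -- shared --------------------------------------------------------------
    #: multiplier applied to the time column on ingestion (1.0 = seconds)
    time_scale: float = 1.0
    seed: int = 0
    make_plots: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)
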