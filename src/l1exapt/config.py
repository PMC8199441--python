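"""Pipeline configuration: analysis thresholds and input locations.

The analysis parameters mirror the conventions of repeat/ChIP interval
work: full-length elements are strictly longer than 6000 bp, the 5' UTR
is the first 1000 bp, GTRD sites merge at gap 300 while ChIP-Atlas and
the combined catalogue merge at gap 0, a site counts as inside an
element when at least half of it overlaps, co-localisation uses a
500 bp window with a 0.0005 one-tailed significance cut, motif hits are
called at p < 1e-4 with a 10% prevalence cut, and positional histograms
use 5 bp bins over 0-6500 bp of consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "load_config"]

DEFAULT_SUBFAMILIES = (
    "L1HS", "L1PA2", "L1PA3", "L1PA4", "L1PA5", "L1PA6",
    "L1PA7", "L1PA8", "L1PA8A", "L1PA10", "L1PA11", "L1PA12",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds (see module docstring for the conventions)."""

    full_length_min_bp: int = 6000
    utr5_len_bp: int = 1000
    merge_gap_gtrd_bp: int = 300
    merge_gap_chipatlas_bp: int = 0
    merge_gap_combined_bp: int = 0
    overlap_fraction: float = 0.5
    coloc_window_bp: int = 500
    motif_p_threshold: float = 1e-4
    prevalence_threshold: float = 0.10
    prevalence_mode: str = "any"
    coloc_p_threshold: float = 0.0005
    hist_bin_bp: int = 5
    hist_max_bp: int = 6500
    subfamilies: tuple[str, ...] = DEFAULT_SUBFAMILIES
    main_chroms_only: bool = True

    def __post_init__(self) -> None:
        positive = {
            "full_length_min_bp": self.full_length_min_bp,
            "utr5_len_bp": self.utr5_len_bp,
            "motif_p_threshold": self.motif_p_threshold,
            "coloc_p_threshold": self.coloc_p_threshold,
            "hist_bin_bp": self.hist_bin_bp,
            "hist_max_bp": self.hist_max_bp,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        for name, value in (
            ("merge_gap_gtrd_bp", self.merge_gap_gtrd_bp),
            ("merge_gap_chipatlas_bp", self.merge_gap_chipatlas_bp),
            ("merge_gap_combined_bp", self.merge_gap_combined_bp),
            ("coloc_window_bp", self.coloc_window_bp),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not (0 < self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if not (0 < self.prevalence_threshold < 1):
            raise ValueError("prevalence_threshold must be in (0, 1)")
        if self.prevalence_mode not in ("any", "all"):
            raise ValueError("prevalence_mode must be 'any' or 'all'")
        if not self.subfamilies:
            raise ValueError("subfamilies must be non-empty")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["subfamilies"] = list(self.subfamilies)
        return d


def load_config(path: str | Path) -> tuple[PipelineConfig, dict[str, Any]]:
    """Load a YAML run configuration.

    The file carries a ``params`` mapping (PipelineConfig fields, all
    optional) plus free-form input/output entries (paths, cell lines,
    seed) returned as the second element.
    """
    with open(path) as fh:
        raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
    params = dict(raw.get("params") or {})
    if "subfamilies" in params:
        params["subfamilies"] = tuple(params["subfamilies"])
    try:
        config = PipelineConfig(**params)
    except TypeError as exc:
        raise ValueError(f"{path}: invalid params section: {exc}") from None
    rest = {k: v for k, v in raw.items() if k != "params"}
    return config, rest
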