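"""Run configuration: every threshold the pipeline uses, in one place.

Nothing is hardcoded downstream: the read-gate thresholds, the summary
statistic, the per-dataset-class depth-eligibility cutoffs (ultra-deep
amplicon 500,000X; hybridization capture 15,000X; merged WGS 20,000X;
WES sample-level 50X) and the dilution parameters are all fields here,
serializable to a plain ``key = value`` text file.  Every CLI run
writes its resolved configuration alongside its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

from .read_qc import FilterConfig

__all__ = ["RunConfig", "DEPTH_CUTOFFS"]

#: Depth-eligibility defaults by dataset class.
DEPTH_CUTOFFS = {
    "ultra_deep": 500_000,
    "capture": 15_000,
    "merged_wgs": 20_000,
    "wes_sample_level": 50,
}


def _parse_scalar(text: str):
    text = text.strip()
    if text in ("", "None", "none"):
        return None
    if text in ("True", "true"):
        return True
    if text in ("False", "false"):
        return False
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


@dataclass
class RunConfig:
    """Flat, text-serializable configuration of one pipeline run."""

    # read gates (mirrors FilterConfig)
    trim_bp: int = 5
    mapq_min: int = 55
    discard_missing_mapq: bool = True
    lowq_phred: int = 20
    lowq_frac_max: float = 0.05
    lowq_count_max: int | None = None
    base_qual_min: int = 30
    match_only_cigar: bool = True
    # counting / eligibility
    counting_mode: str = "cleandeepseq"
    depth_class: str = "ultra_deep"
    depth_min: int | None = None  # None: resolved from depth_class
    dominant_frac: float = 0.95
    # profile summary
    statistic: str = "median"
    min_sites_per_type: int | None = None
    # dilution design
    dilution_factor: int = 1000
    min_fold_frac: float = 0.1
    # randomness
    seed: int = 0

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            trim_bp=self.trim_bp,
            mapq_min=self.mapq_min,
            discard_missing_mapq=self.discard_missing_mapq,
            lowq_phred=self.lowq_phred,
            lowq_frac_max=self.lowq_frac_max,
            lowq_count_max=self.lowq_count_max,
            base_qual_min=self.base_qual_min,
            match_only_cigar=self.match_only_cigar,
        )

    def resolved_depth_min(self) -> int:
        if self.depth_min is not None:
            return self.depth_min
        if self.depth_class not in DEPTH_CUTOFFS:
            raise ValueError(f"unknown dataset class {self.depth_class!r}")
        return DEPTH_CUTOFFS[self.depth_class]

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {line!r}")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = _parse_scalar(value)
        return cls(**kwargs)

    def evolve(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
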