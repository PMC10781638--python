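"""Run configuration with the pipeline's default constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """All tunable pipeline constants, at their standard defaults.

    Defaults: 50-kb bins; QC at 750,000 minimum reads and CV <= 0.1 over
    chr1-19; outlier masking at the lower 5th / upper 1st percentile of
    stage-mean RPM; 95% mappability retention; width-15 median filter;
    replication-score filter keeping 10-90%; interval grid 35% / 4.33%
    (16 intervals); 15 RT clusters; 21-bin feature window; 16 sigmoid
    anchor points; 1,000 bootstrap iterations.
    """

    bin_size: int = 50_000
    min_reads: int = 750_000
    cv_threshold: float = 0.1
    autosomes: list[str] = field(default_factory=lambda: [f"chr{i}" for i in range(1, 20)])
    low_percentile: float = 5.0
    high_percentile: float = 1.0
    first_penalty: float = 1.0
    second_penalty: float = 4.0
    retain_fraction: float = 0.95
    filter_width: int = 15
    score_lo: float = 10.0
    score_hi: float = 90.0
    interval_window: float = 35.0
    interval_step: float = 4.33
    cluster_k: int = 15
    feature_window: int = 21
    sigmoid_anchors: int = 16
    bootstrap_b: int = 1000
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
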