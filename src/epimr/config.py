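"""Run configuration: a flat, validated key/value set echoed into every log.

The config file is YAML; unknown keys are rejected so typos surface
immediately, and every threshold is echoed verbatim into the run log and
into the pipeline manifest.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields

import yaml

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # simulation
    n_genes: int = 1000
    n_deg_per_direction: int = 100
    planted_lfc: float = 2.0
    n_denovo: int = 150
    master_tf: bool = True
    n_pwms: int = 50
    sites_per_promoter: int = 2
    planted_fraction: float = 0.7
    # thresholds
    alpha: float = 0.05
    fdr: float = 0.05
    lfc_min: float = 0.0
    high_fc: float = 2.0
    low_fc: float = 0.5
    log_ratio_cutoff: float = 1.0
    min_abs_r: float = 0.5
    n_perm: int = 1000
    n_shuffles: int = 200
    gsea_weight: float = 1.0
    # bookkeeping
    seed: int = 0
    outdir: str = "epimr_out"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def echo(self) -> None:
        for key, value in sorted(asdict(self).items()):
            logger.info("config %s = %r", key, value)
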