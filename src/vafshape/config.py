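"""Pipeline configuration: one dataclass, YAML-serialisable.

Defaults reproduce the canonical analysis settings: depth >= 20,
copy-neutral window +/-0.2 with >= 10 probes, >= 2 MF mutations per
sample, k = 5 clusters on two standardized PCs, survival gate at 10
samples per cluster, CART with CP = 0.1 and 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "derive_seed"]

# stage identifiers used for seed fan-out
STAGES = ("simulate", "cluster", "survival", "tree", "stats")


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the single config seed.

    ``SeedSequence(seed, spawn_key=(stage_index,))`` collapsed to a
    31-bit integer: stages stay statistically independent, and running a
    stage in isolation reproduces its in-pipeline randomness exactly.
    """
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, with analysis-grade defaults."""

    # inputs
    mutations_path: str = ""
    segments_path: str = ""
    clinical_path: str = ""
    dialect: str = "gdc"  # gdc | simple

    # filter chain
    min_depth: int = 20
    cnv_mean_lo: float = -0.2
    cnv_mean_hi: float = 0.2
    min_probes: int = 10
    min_mf_mutations: int = 2
    cap_vaf: bool = True
    missing_purity: str = "drop"

    # shape parameters
    kde_grid_points: int = 512
    kde_bandwidth: str = "silverman"
    math_scale_constant: float = 1.4826
    math_percent: bool = False

    # clustering
    k: int = 5
    standardize: bool = True
    n_components: int = 2

    # survival
    min_cluster_size: int = 10
    covariates: list = field(default_factory=lambda: ["age", "gender", "stage"])
    univariate_reference: int = 2
    stage_binary: bool = True

    # classifier
    tree_cp: float = 0.1
    tree_min_leaf: int = 5
    cv_folds: int = 10

    # cohort stats
    cnv_abundance_threshold: float = 0.2
    top_genes: int = 10

    # simulation (used by the simulate stage)
    n_samples: int = 500

    seed: int = 1
    output_dir: str = "vafshape_out"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
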