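"""Run configuration: one object holding every knob of the pipeline.

All thresholds and sizes that the screen depends on live here so a run is
fully described by (config, seed). ``RunConfig.to_dict`` round-trips through
YAML/JSON for the replayable run summary.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from suppressor_screen.simulate import CYTOTOX_GENES


@dataclass
class RunConfig:
    seed: int = 0
    alpha: float = 0.05
    receiver_subsets: tuple[str, ...] = ("NK", "CD8T", "gdT")
    cytotox_genes: tuple[str, ...] = CYTOTOX_GENES
    correlation_method: str = "pearson"

    # interaction inference
    n_perm: int = 100
    Kh: float = 0.5
    hill_n: float = 1.0
    trim: float = 0.10
    stratified_null: bool = False

    # scoring / aggregation
    n_bins: int = 25
    n_ctrl: int = 100
    min_cells: int = 5

    # survival validation
    min_group_frac: float = 0.10

    # secretome
    k_top: int = 100

    # synthetic benchmark (used when no input paths are supplied)
    n_tumors: int = 24
    n_null_ligands: int = 20
    effect_r: float = -0.8
    n_genes: int = 300
    bulk_n_samples: tuple[int, ...] = (498, 122)
    bulk_endpoints: tuple[str, ...] = ("EFS", "OS")
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.1
    secretome_n_proteins: int = 1000
    secretome_n_samples: int = 3

    # optional real-data inputs; when None the synthetic benchmark runs
    cohort_dir: str | None = None
    lr_db_path: str | None = None
    secreted_list_path: str | None = None
    bulk_expr_paths: tuple[str, ...] = ()
    bulk_surv_paths: tuple[str, ...] = ()
    proteomics_path: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in (
            "cohort_dir", "lr_db_path", "secreted_list_path", "proteomics_path"
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for p in list(self.bulk_expr_paths) + list(self.bulk_surv_paths):
            if not Path(p).exists():
                raise FileNotFoundError(f"bulk cohort file {p} does not exist")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update(overrides)
        return cls.from_dict(d)
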