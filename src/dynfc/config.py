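"""Run configuration: validated settings with main/validation presets.

``RunConfig`` gathers every tunable of the pipeline.  Defaults equal the
main-analysis settings (22-TR window, sigma = 3 TR taper, step 1, k-means
with 100 replicates, sparsity 0.2-0.3 step 0.01); the ``val20`` and
``val30`` presets change only the window length, for the standard
window-length robustness check.  Unknown keys in a config file are
rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .graphmetrics import SparsityGrid
from .windows import GlassoConfig, TaperedWindowSpec


@dataclass
class RunConfig:
    window_length_tr: int = 22
    taper_sigma_tr: float = 3.0
    step_tr: int = 1
    count_convention: str = "n_minus_w"
    penalty_grid: tuple[float, ...] = (0.0, 0.01, 0.03, 0.1)
    glasso_repeats: int = 50
    k: int | None = 4                  # None -> elbow selection over k_range
    k_range: tuple[int, int] = (2, 10)
    n_replicates: int = 100
    sparsity_min: float = 0.2
    sparsity_max: float = 0.3
    sparsity_step: float = 0.01
    n_null: int = 100
    seed: int = 0
    covariate_columns: tuple[str, ...] = ("age", "sex", "education", "mean_fd")
    stats_covariates: tuple[str, ...] = ("age", "sex", "education",
                                         "disease_duration", "mean_fd")
    disease_duration_mode: str = "impute_centered"
    compute_normalized: bool = True
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        self.window_spec()   # validates window fields
        self.glasso_config()
        self.sparsity_grid()
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.disease_duration_mode not in ("impute_centered", "drop"):
            raise ValueError("unknown disease_duration_mode")

    def window_spec(self) -> TaperedWindowSpec:
        return TaperedWindowSpec(self.window_length_tr, self.taper_sigma_tr,
                                 self.step_tr, self.count_convention)

    def glasso_config(self) -> GlassoConfig:
        return GlassoConfig(list(self.penalty_grid), n_repeats=self.glasso_repeats)

    def sparsity_grid(self) -> SparsityGrid:
        return SparsityGrid(self.sparsity_min, self.sparsity_max, self.sparsity_step)

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        presets = {"main22": 22, "val20": 20, "val30": 30}
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        return cls(window_length_tr=presets[name], **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("penalty_grid", "covariate_columns", "stats_covariates",
                    "k_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
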