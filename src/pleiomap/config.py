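"""Pipeline configuration: YAML round-trip and per-stage seeds."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .datatypes import PleiomapError


@dataclass
class PipelineConfig:
    """All stage parameters, seeds and paths for one pipeline run.

    Every stochastic stage has its own explicit seed so each stage is
    reproducible in isolation; :meth:`with_seed` derives per-stage seeds
    from a single master seed.
    """

    stages: list = field(default_factory=lambda: [
        "simulate", "scan", "bivariate", "fst", "impute", "stats"])
    out_dir: str = "pleiomap_out"

    # inputs; when None the simulate stage provides them
    genotype_csv: str | None = None
    phenotype_csv: str | None = None
    snp_panel: str | None = None
    accession_metadata: str | None = None
    climate_csv: str | None = None

    ril: dict = field(default_factory=dict)        # RILSimConfig overrides
    panel: dict = field(default_factory=dict)      # PanelSimConfig overrides

    grid_step_cM: float = 2.0
    map_scale: str = "ril"
    n_perm: int = 1000
    alpha: float = 0.05
    interval_rule: str = "peak_fraction"
    interval_param: float = 0.5
    fst_estimator: str = "nei"
    permutation_K: int = 1000
    regional_interval_bp: int = 50_000
    bootstrap_n_snps: int = 1000
    bootstrap_tolerance: float = 0.02
    window_half_span_bp: int = 100_000
    cv_folds: int = 4
    subset_ns: list = field(default_factory=lambda: [10, 20, 40])
    subset_repeats: int = 20

    seeds: dict = field(default_factory=lambda: {
        "simulate_ril": 1, "simulate_panel": 2, "scan": 3,
        "fst": 4, "impute": 5})

    def validate(self) -> None:
        known = {"simulate", "scan", "bivariate", "fst", "impute", "stats"}
        bad = set(self.stages) - known
        if bad:
            raise PleiomapError(f"unknown stages: {sorted(bad)}")
        if not 0 < self.alpha < 1:
            raise PleiomapError("alpha must be in (0, 1)")
        for name in ("simulate_ril", "simulate_panel", "scan", "fst", "impute"):
            if name not in self.seeds:
                raise PleiomapError(f"missing seed for stage {name!r}")

    def with_seed(self, master: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        cfg.seeds = {k: (master * 7919 + i) % (2 ** 31)
                     for i, k in enumerate(
                         ["simulate_ril", "simulate_panel", "scan",
                          "fst", "impute"])}
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise PleiomapError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]
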