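"""Run configuration for the command-line interface."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import CohortConfig, ErrorModel
from .variant import CallingParams


@dataclass
class RunConfig:
    """Parsed YAML run configuration shared by all subcommands."""

    out_dir: str = "ampliclone_out"
    seed: int = 0
    panel_config: str | None = None  # None -> bundled synthetic panel
    reference_fasta: str | None = None
    manifest: str | None = None
    covariates: str | None = None
    calling: CallingParams = field(default_factory=CallingParams)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    calibration_coverage: int = 4000
    max_discordant_fraction: float = 0.05
    hotspot_only: bool = False
    dynamics_rel_tolerance: float = 0.5
    max_indel_slack: int = 10
    config_hash: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path | None, seed: int | None = None,
                  out_dir: str | None = None) -> "RunConfig":
        raw: dict = {}
        digest = "none"
        if path is not None:
            text = Path(path).read_text()
            digest = hashlib.sha256(text.encode()).hexdigest()[:12]
            raw = yaml.safe_load(text) or {}
        try:
            cfg = cls(
                out_dir=raw.get("out_dir", "ampliclone_out"),
                seed=int(raw.get("seed", 0)),
                panel_config=raw.get("panel_config"),
                reference_fasta=raw.get("reference_fasta"),
                manifest=raw.get("manifest"),
                covariates=raw.get("covariates"),
                calling=CallingParams(**raw.get("calling", {})),
                error_model=ErrorModel(**raw.get("error_model", {})),
                cohort=CohortConfig(
                    **{**raw.get("cohort", {}), "error_model": ErrorModel(**raw.get("error_model", {}))}
                ),
                calibration_coverage=int(raw.get("calibration_coverage", 4000)),
                max_discordant_fraction=float(raw.get("max_discordant_fraction", 0.05)),
                hotspot_only=bool(raw.get("hotspot_only", False)),
                dynamics_rel_tolerance=float(raw.get("dynamics_rel_tolerance", 0.5)),
                max_indel_slack=int(raw.get("max_indel_slack", 10)),
                config_hash=digest,
            )
        except TypeError as exc:
            raise ConfigError(f"invalid configuration field: {exc}") from exc
        if seed is not None:
            cfg.seed = seed
            cfg.cohort.seed = seed
        else:
            cfg.cohort.seed = cfg.seed
        if out_dir is not None:
            cfg.out_dir = out_dir
        return cfg

    def load_panel(self):
        from .panel import default_panel, load_panel

        if self.panel_config is None:
            return default_panel()
        if self.reference_fasta is None:
            raise ConfigError("panel_config requires reference_fasta")
        return load_panel(self.panel_config, self.reference_fasta)
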