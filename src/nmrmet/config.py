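"""Run configuration: every stage parameter with its default, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .preprocess import QCConfig
from .simulate.cohort import CohortConfig
from .simulate.spectra import SpectraConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline stage parameters, centrally defaulted.

    The configuration (echoed into every run report) fully determines a
    run together with ``seed``, from which all per-stage random streams
    are derived.
    """

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    qc_enabled: bool = True
    # ppm grid
    grid_high: float = 9.0
    grid_low: float = 0.5
    grid_step: float = 0.001
    # preprocessing
    baseline_windows: list[tuple[float, float]] = field(
        default_factory=lambda: [(8.70, 9.00), (0.52, 0.68)]
    )
    calibration_target_ppm: float = 5.23
    calibration_halfwidth_ppm: float = 0.05
    cow_segment_length: int = 50
    cow_slack: int = 5
    cow_max_drift: int | None = 10
    # quantification
    fit_window_halfwidth_ppm: float = 0.02
    pls_components: int = 10
    assignment_correlation_threshold: float = 0.5
    # post-processing
    shapiro_alpha: float = 0.05
    kinship_method: str = "mixed_model"
    # modeling
    enet_alpha: float = 0.5
    enet_folds: int = 50
    lambda_rule: str = "lambda_min"
    n_lambdas: int = 25
    cv_mode: str = "kfold"
    # convenience for desk-scale runs: restrict to the first k metabolites
    max_metabolites: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_windows"] = [list(w) for w in self.baseline_windows]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("cohort", CohortConfig), ("spectra", SpectraConfig), ("qc", QCConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "baseline_windows" in d:
            d["baseline_windows"] = [tuple(w) for w in d["baseline_windows"]]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
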