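"""Run configuration: the pipeline constants, serializable to YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """All tunable pipeline constants for one experiment.

    Defaults follow clinical convention and the published pipeline
    configuration: a 130 HU extraction threshold, full 26-neighbourhood
    3D connectivity, an ensemble of 250 extremely randomized trees, a 0.5
    decision threshold on the ensemble's CAC probability, and tenfold
    patient-level cross-validation.
    """

    threshold_hu: float = 130.0
    connectivity: int = 26
    gaussian_scales_mm: tuple[float, ...] = (1.0, 2.0, 4.0)
    n_trees: int = 250
    decision_threshold: float = 0.5
    n_folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gaussian_scales_mm"] = list(self.gaussian_scales_mm)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gaussian_scales_mm" in payload:
            payload["gaussian_scales_mm"] = tuple(payload["gaussian_scales_mm"])
        return cls(**payload)
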