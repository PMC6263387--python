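"""Run configuration: the pipeline's fixed constants, overridable via YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable pipeline constants with their default values.

    Defaults mirror the lab protocol's constants: 10 s windows at 100 Hz,
    20 selected wavelet coefficients, a 10-component PCA feature space,
    the >50% merge rule, and a 2-D..10-D model-selection sweep.
    """

    window_s: float = 10.0
    sample_rate_hz: float = 100.0
    n_wavelet_coeffs: int = 20
    pca_dims: int = 10
    classifier: str = "hmm"
    n_components: int = 2
    merge_threshold: float = 0.5
    dims: list[int] = field(default_factory=lambda: list(range(2, 11)))
    k_min: int = 1
    k_max: int = 8
    freeliving_dims: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_s", "sample_rate_hz", "n_wavelet_coeffs",
                     "pca_dims", "n_components", "k_min", "k_max",
                     "freeliving_dims"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.merge_threshold < 1.0:
            raise ValueError("merge_threshold must lie in (0, 1)")
        if self.classifier not in ("gmm", "hmm"):
            raise ValueError("classifier must be 'gmm' or 'hmm'")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build a config from an optional YAML file plus keyword overrides."""
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
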