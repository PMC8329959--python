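"""Run configuration: one dataclass, YAML-loadable, hashable for provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .texture import validate_ssf

__all__ = ["RunConfig"]

DEFAULT_SCALES = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Paths are resolved at run time; ``scales`` are SSF values in mm (0 = no
    filtration).  ``alpha`` gates which features are dichotomized after the
    survivor / non-survivor comparison; ``holm`` optionally applies a Holm
    correction to that gate.
    """

    image_dir: str | None = None
    mask_dir: str | None = None
    clinical_csv: str | None = None
    out_dir: str = "texsurv_out"
    scales: tuple[float, ...] = DEFAULT_SCALES
    entropy_bin_width: float = 1.0
    cutoff_criterion: str = "youden"
    cox_ties: str = "efron"
    icc_form: str = "absolute"
    alpha: float = 0.05
    holm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", tuple(validate_ssf(s) for s in self.scales))
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.cox_ties != "efron":
            raise ValueError("only the Efron tie correction is supported")
        if self.icc_form not in ("absolute", "consistency"):
            raise ValueError("icc_form must be 'absolute' or 'consistency'")
        if not (self.entropy_bin_width > 0):
            raise ValueError("entropy_bin_width must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "scales" in raw:
            raw["scales"] = tuple(float(s) for s in raw["scales"])
        return cls(**raw)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})

    def hash(self) -> str:
        """Digest of the analysis-relevant parameters (paths excluded)."""
        payload = asdict(self)
        for key in ("image_dir", "mask_dir", "clinical_csv", "out_dir"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def provenance(self) -> str:
        return f"texsurv config={self.hash()} seed={self.seed}"
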