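"""Run configuration: one validated object tying file paths and model
options together, loadable from YAML or JSON with CLI-flag overrides
(precedence: flags > config file > defaults)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .features import LIKELIHOOD_BOUNDS


class RunConfig(BaseModel):
    subjects: Optional[Path] = None
    trials: Optional[Path] = None
    criteria: dict[str, Path] = Field(default_factory=dict)  # region -> JSON path
    curves: Optional[Path] = None
    rounding_mode: Optional[str] = None  # None: use each table's own mode
    horizons: tuple[int, ...] = (5, 10, 15)
    likelihood_bounds: tuple[float, float] = LIKELIHOOD_BOUNDS
    parametric_mode: str = "independent"
    seed: int = 0
    out_dir: Path = Path("msdrisk-out")
    log_level: str = "INFO"

    @field_validator("horizons")
    @classmethod
    def _positive_horizons(cls, v):
        if any(t <= 0 for t in v):
            raise ValueError(f"horizons must be positive, got {v}")
        return v

    def require_files(self) -> list[str]:
        """Names of referenced files that do not exist."""
        missing = []
        for label, p in [("subjects", self.subjects), ("trials", self.trials),
                         ("curves", self.curves),
                         *[(f"criteria[{r}]", p) for r, p in self.criteria.items()]]:
            if p is not None and not Path(p).exists():
                missing.append(f"{label}: {p}")
        return missing

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file and apply keyword overrides (flags win)."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
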