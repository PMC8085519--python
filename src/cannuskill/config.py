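"""Run configuration shared by the pipeline subcommands.

One JSON file governs all stages, so no analysis constant is buried in
code.  ``RunConfig.default()`` materialises every default; ``cannuskill
config --init`` writes it as a template.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .derivatives import DEFAULT_SPANS
from .stats import DEFAULT_GRS_SUBSCORES
from .synthetic import CohortSpec

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclasses.dataclass
class RunConfig:
    """All tunables for the simulate / compute / analyze pipeline."""

    spans: tuple = DEFAULT_SPANS
    sparc_padlevel: int = 4
    sparc_f_max: float = 10.0
    sparc_amp_threshold: float = 0.05
    peak_prominence: float = 0.0
    alpha: float = 0.05
    pks_offset: float = 1.0
    log_sparc: bool = True
    tukey_variance: str = "pooled"
    grs_subscores: tuple = DEFAULT_GRS_SUBSCORES
    seed: int = 0
    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec)

    def validate(self) -> None:
        for span in self.spans:
            if int(span) % 2 == 0 or int(span) < 5:
                raise ConfigError(f"window span {span} must be odd and >= 5")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.tukey_variance not in ("pooled", "per_pair"):
            raise ConfigError(f"unknown tukey_variance {self.tukey_variance!r}")
        try:
            self.cohort.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spans"] = list(self.spans)
        d["grs_subscores"] = list(self.grs_subscores)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        cfg = cls(
            **{k: tuple(v) if k in ("spans", "grs_subscores") else v
               for k, v in d.items()},
            cohort=CohortSpec.from_dict(cohort) if cohort else CohortSpec(),
        )
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
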