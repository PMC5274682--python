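"""Aggregated run configuration.

One structured YAML file with per-module sections configures a whole run;
command-line flags override file values.  Defaults follow the published
protocol constants where they exist (window 600, step 200, periods 2-50,
raw threshold 390.0, triplet skip 3.0).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .align import GapParams
from .ga import GAConfig
from .scan import ScanConfig
from .significance import SignificanceConfig


@dataclass(frozen=True)
class RunConfig:
    scan: ScanConfig = field(default_factory=ScanConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    gaps: GapParams = field(default_factory=GapParams)
    verbosity: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load sections from a YAML file; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ga = GAConfig(**raw.get("ga", {}))
        gaps = GapParams(**raw.get("gaps", {}))
        scan_kw = dict(raw.get("scan", {}))
        scan_kw.setdefault("ga", ga)
        scan_kw.setdefault("gaps", gaps)
        if not isinstance(scan_kw["ga"], GAConfig):
            scan_kw["ga"] = GAConfig(**scan_kw["ga"])
        if not isinstance(scan_kw["gaps"], GapParams):
            scan_kw["gaps"] = GapParams(**scan_kw["gaps"])
        kwargs = dict(
            scan=ScanConfig(**scan_kw),
            significance=SignificanceConfig(**raw.get("significance", {})),
            ga=ga,
            gaps=gaps,
            verbosity=int(raw.get("verbosity", 0)),
            seed=int(raw.get("seed", 0)),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "scan": {
                k: v for k, v in asdict(self.scan).items() if k not in ("ga", "gaps")
            },
            "significance": asdict(self.significance),
            "ga": asdict(self.ga),
            "gaps": asdict(self.gaps),
            "verbosity": self.verbosity,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
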