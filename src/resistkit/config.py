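"""Structured YAML configuration for the command-line pipeline.

Every option has a documented default; unknown keys are rejected so typos
fail loudly; the resolved configuration is echoed into the output directory
by every run for reproducibility.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .core import FormatError


def _take(section: dict, allowed: dict[str, Any], where: str) -> dict:
    unknown = set(section) - set(allowed)
    if unknown:
        raise FormatError(f"unknown key(s) {sorted(unknown)} in config section {where!r}")
    merged = dict(allowed)
    merged.update(section)
    return merged


@dataclass
class PathsConfig:
    susceptible_fasta: Optional[str] = None
    resistant_fasta: Optional[str] = None
    reference_fasta: Optional[str] = None
    transfer_gff: Optional[str] = None
    contig_lengths: Optional[str] = None
    bioassay_susceptible: Optional[str] = None
    bioassay_resistant: Optional[str] = None
    ortholog_map: Optional[str] = None


@dataclass
class ScoringConfig:
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1


@dataclass
class ScreenOptions:
    allow_two_way: bool = False
    indel_counting: str = "run"
    window_bp: int = 1000
    ortholog: str = "shared_id"
    min_ortholog_score: int = 0


@dataclass
class SimulateOptions:
    n_transcripts: int = 500
    length_range: tuple[int, int] = (40, 60)
    class_counts: dict = field(
        default_factory=lambda: {
            "resistant_specific_sub": 20,
            "resistant_specific_indel": 10,
            "susceptible_specific": 15,
            "reference_specific": 10,
            "triallelic": 5,
        }
    )
    truncation_fraction: float = 0.0
    max_cut: int = 5
    bioassay: Optional[dict] = None  # {ld50, slope, doses, n_per_dose, control_mortality}


@dataclass
class PipelineConfig:
    seed: Optional[int] = None
    output_dir: str = "resistkit_out"
    paths: PathsConfig = field(default_factory=PathsConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    screen: ScreenOptions = field(default_factory=ScreenOptions)
    simulate: SimulateOptions = field(default_factory=SimulateOptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, where=str(path))

    @classmethod
    def from_dict(cls, raw: dict, where: str = "<config>") -> "PipelineConfig":
        top = _take(
            raw,
            {
                "seed": None,
                "output_dir": "resistkit_out",
                "paths": {},
                "scoring": {},
                "screen": {},
                "simulate": {},
            },
            where,
        )
        paths = PathsConfig(**_take(top["paths"] or {}, asdict(PathsConfig()), "paths"))
        scoring = ScoringConfig(
            **_take(top["scoring"] or {}, asdict(ScoringConfig()), "scoring")
        )
        screen = ScreenOptions(
            **_take(top["screen"] or {}, asdict(ScreenOptions()), "screen")
        )
        sim_defaults = asdict(SimulateOptions())
        sim = _take(top["simulate"] or {}, sim_defaults, "simulate")
        sim["length_range"] = tuple(sim["length_range"])
        simulate = SimulateOptions(**sim)
        if scoring.matrix != "BLOSUM62":
            raise FormatError(f"unsupported scoring matrix {scoring.matrix!r}")
        return cls(
            seed=top["seed"],
            output_dir=top["output_dir"],
            paths=paths,
            scoring=scoring,
            screen=screen,
            simulate=simulate,
        )

    def echo(self, out_dir: str | Path) -> None:
        """Write the fully resolved configuration into the output directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
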