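"""YAML pipeline configuration: parsing, defaulting and cross-validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .decode import DecoderConfig
from .synthgen import CONTRASTS


class ConfigError(ValueError):
    """Human-readable list of configuration problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in self.problems))


@dataclass(frozen=True)
class PatchSection:
    n_x: int = 60
    n_y: int = 60
    spacing_mm: float = 0.3
    thickness_mm: float = 2.0
    curvature_amp: float = 0.0
    n_intermediate: int = 9


@dataclass(frozen=True)
class OdcSection:
    period_mm: float = 1.0
    anisotropy: float = 1.0
    sigmoid_gain: float = 3.0


@dataclass(frozen=True)
class DesignSection:
    run_duration_s: float = 270.0
    baseline_s: float = 15.0
    block_s: float = 30.0
    n_blocks: int = 8
    tr_s: float = 3.0


@dataclass(frozen=True)
class StudySection:
    n_participants: int = 2
    sessions_per_contrast: int = 2
    runs_per_session: int = 10
    contrasts: tuple[str, ...] = ("GE_BOLD",)
    amplitude_jitter_sd: float = 0.1


@dataclass(frozen=True)
class StatsSection:
    n_perm: int = 10000
    n_boot: int = 1000
    subsample_frac: float = 0.1
    chance: float = 0.5


@dataclass(frozen=True)
class StagesSection:
    decode: bool = True
    regions: bool = True
    distances: bool = True
    sweep: bool = False
    write_maps: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    patch: PatchSection = field(default_factory=PatchSection)
    odc: OdcSection = field(default_factory=OdcSection)
    design: DesignSection = field(default_factory=DesignSection)
    study: StudySection = field(default_factory=StudySection)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    stats: StatsSection = field(default_factory=StatsSection)
    stages: StagesSection = field(default_factory=StagesSection)
    sweep_grid: tuple[int, ...] = (1, 2, 5, 10, 20, 50)


_SECTIONS = {"patch": PatchSection, "odc": OdcSection, "design": DesignSection,
             "study": StudySection, "decoder": DecoderConfig, "stats": StatsSection,
             "stages": StagesSection}


def _build_section(cls, data: dict, name: str, problems: list[str]):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        problems.append(f"{name}: unknown field {key!r}")
    kwargs = {k: v for k, v in data.items() if k in known}
    for key in ("contrasts", "feature_count_grid"):
        if isinstance(kwargs.get(key), list):
            kwargs[key] = tuple(kwargs[key])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        problems.append(f"{name}: {err}")
        return cls()


def normalize_config(data: dict) -> PipelineConfig:
    """Validate a parsed config mapping; raise ConfigError listing problems."""
    problems: list[str] = []
    if not isinstance(data, dict):
        raise ConfigError(["top-level config must be a mapping"])
    top_known = {"seed", "out_dir", "sweep_grid"} | set(_SECTIONS)
    for key in sorted(set(data) - top_known):
        problems.append(f"unknown top-level field {key!r}")
    sections = {}
    for name, cls in _SECTIONS.items():
        raw = data.get(name, {})
        if not isinstance(raw, dict):
            problems.append(f"{name}: must be a mapping")
            raw = {}
        sections[name] = _build_section(cls, raw, name, problems)

    for c in sections["study"].contrasts:
        if c not in CONTRASTS:
            problems.append(f"study.contrasts: unknown contrast {c!r} "
                            f"(choose from {', '.join(CONTRASTS)})")
    d = sections["design"]
    if abs(2 * d.baseline_s + d.n_blocks * d.block_s - d.run_duration_s) > 1e-9:
        problems.append("design: 2*baseline_s + n_blocks*block_s must equal run_duration_s")
    if d.tr_s <= 0 or (d.run_duration_s / d.tr_s) % 1 > 1e-9:
        problems.append("design: run_duration_s must be divisible by tr_s")
    p = sections["patch"]
    if min(p.n_x, p.n_y) < 8 or p.spacing_mm <= 0 or p.thickness_mm <= 0:
        problems.append("patch: require n_x, n_y >= 8 and positive spacing/thickness")
    o = sections["odc"]
    if o.period_mm <= 2 * p.spacing_mm:
        problems.append("odc: period_mm must exceed twice the vertex spacing")
    s = sections["stats"]
    if s.n_perm < 1 or s.n_boot < 1 or not 0 < s.subsample_frac <= 1:
        problems.append("stats: n_perm/n_boot must be >= 1 and subsample_frac in (0, 1]")
    if problems:
        raise ConfigError(problems)
    grid = tuple(int(k) for k in data.get("sweep_grid", PipelineConfig.sweep_grid))
    return PipelineConfig(seed=int(data.get("seed", 0)),
                          out_dir=str(data.get("out_dir", "results")),
                          sweep_grid=grid, **sections)


def validate_config(path) -> PipelineConfig:
    """Load, default and cross-validate a YAML pipeline configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return normalize_config(data)
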