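"""Pipeline configuration: one flat, human-editable YAML document.

Every tunable of every stage appears here with its default; a run
serializes the frozen config into its output directory for provenance.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from . import __version__


@dataclass
class BinningConfig:
    genome: str | None = None        # FASTA path
    read_length: int = 76
    n_bins: int = 5000
    exclude: str | None = None       # BED path of exclusions


@dataclass
class ProfilingConfig:
    mapq_min: int = 30
    pseudocount: float = 1.0
    lowess_span: float = 0.3
    lowess_iters: int = 3
    alpha: float = 0.02
    min_width: int = 3
    seg_perm: int = 100
    ci_halfwidth: int = 2
    m_lo: float = 1.0
    m_hi: float = 8.0
    m_step: float = 0.01
    quantize_error_flag: float = 0.10


@dataclass
class ClonalConfig:
    combine: str = "fisher"
    linkage: str = "average"
    n_perm: int = 100
    fdr_threshold: float = 0.05
    nshare_min: int = 3
    share_pct: float = 0.8
    min_clone_size: int = 3
    halfwidth: int = 2
    subclone_recursion: int = 1


@dataclass
class SimulateConfig:
    n_cells: int = 200
    n_bins: int = 5000
    lam: float = 25.0
    ploidy: int = 2
    clone_fraction: float = 0.10
    n_events: int = 30
    gc_bias_linear: float = 1.5
    gc_bias_quadratic: float = -15.0
    n_chroms: int = 1
    private_event_rate: float = 0.0


@dataclass
class PipelineConfig:
    seed: int = 0
    workers: int = 1
    version: str = field(default_factory=lambda: __version__)
    binning: BinningConfig = field(default_factory=BinningConfig)
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)
    clonal: ClonalConfig = field(default_factory=ClonalConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {"binning": BinningConfig, "profiling": ProfilingConfig,
                    "clonal": ClonalConfig, "simulate": SimulateConfig}
        kwargs = {}
        for name, section_cls in sections.items():
            section = data.pop(name, {}) or {}
            _check_keys(section, section_cls, name)
            kwargs[name] = section_cls(**section)
        _check_keys(data, cls, "top level", skip=set(sections))
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _check_keys(data: dict, cls, where: str, skip=frozenset()):
    valid = {f.name for f in dataclasses.fields(cls)} - set(skip)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def default_config_yaml() -> str:
    """The full annotated default configuration."""
    return PipelineConfig().to_yaml()
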