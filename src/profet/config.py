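"""Declarative run configuration with deterministic per-stage seeding."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .force_matching import FMConfig
from .gpa import GPAConfig

__all__ = ["RunConfig", "PreprocessConfig", "EvalConfig", "DownstreamConfig", "derive_seed"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, decoupling the pipeline stages."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class PreprocessConfig:
    log1p: bool = True
    n_top_genes: int | None = None
    latent_dim: int = 2


@dataclass
class EvalConfig:
    held_out_times: list[float] = field(default_factory=list)
    epsilons: list[float] = field(default_factory=lambda: [0.01, 0.1, 1.0, 10.0, 100.0])
    mmd_gamma: float = 1.0
    baseline_epsilon: float = 0.1
    sinkhorn_tol: float = 1e-4
    sinkhorn_max_iter: int = 2000


@dataclass
class DownstreamConfig:
    n_perm: int = 1000
    perm_metrics: list[str] = field(default_factory=lambda: ["tv", "kl", "sinkhorn"])
    k_candidates: list[int] = field(default_factory=lambda: list(range(2, 9)))


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run from data paths + seed."""

    manifest: str = ""
    out_dir: str = "profet_run"
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    gpa: GPAConfig = field(default_factory=GPAConfig)
    fm: FMConfig = field(default_factory=FMConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    downstream: DownstreamConfig = field(default_factory=DownstreamConfig)
    integrate_steps_per_unit: int = 200
    align_mode: str = "relaxation"
    align_warp: float = 3.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gpa"]["hidden"] = list(d["gpa"]["hidden"])
        d["fm"]["hidden"] = list(d["fm"]["hidden"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "gpa" in d:
            g = dict(d["gpa"])
            if "hidden" in g:
                g["hidden"] = tuple(g["hidden"])
            d["gpa"] = GPAConfig(**g)
        if "fm" in d:
            f = dict(d["fm"])
            if "hidden" in f:
                f["hidden"] = tuple(f["hidden"])
            d["fm"] = FMConfig(**f)
        if "evaluation" in d:
            d["evaluation"] = EvalConfig(**d["evaluation"])
        if "downstream" in d:
            d["downstream"] = DownstreamConfig(**d["downstream"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)
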