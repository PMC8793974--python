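"""Run configuration: a YAML file is the single source of truth for a run.

Schema (all keys optional unless noted)::

    data: path/to/table.csv        # UCI-dialect CSV; or use `synthetic:`
    header: false                  # headered CSV variant
    schema: path/to/schema.yaml    # feature metadata; default = bundled Cleveland
    synthetic:                     # alternative to `data:`
      n: 297
      class_prob: 0.461
      cleveland_like: true         # use the bundled Cleveland-shaped effects
      continuous_effects: {A: 1.0} # or spell out effects explicitly
      categorical_effects:
        B: {codes: [0, 1], probs_pos: [0.3, 0.7], probs_neg: [0.6, 0.4]}
    weights_mode: per-split        # per-split | full-data
    standardize: true
    tune_mode: nested              # nested | once | fixed
    C: 1.0                         # used when tune_mode == fixed
    gamma: 0.5
    grid:                          # used when tuning
      C: [0.125, 0.5, 2.0, 8.0, 32.0, 128.0, 512.0]
      gamma: [0.001953125, 0.0078125, 0.03125, 0.125, 0.5, 2.0]
    ratios: [0.95, 0.90, 0.80, 0.75, 0.50]
    n_iter: 1000
    master_seed: 2021
    methods: [wsvm, svm, rf, nb]   # for `compare`
    out_dir: results

Command-line flags override the file.  Every output embeds the SHA-256
hash of the resolved configuration and the master seed, so a result file
is traceable to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .svm import DEFAULT_GRID
from .synthetic import CategoricalEffect, SyntheticSpec, cleveland_like_spec

__all__ = ["RunConfig", "load_config", "config_hash"]

#: the published protocol: five splitting ratios, 1,000 iterations each
DEFAULT_RATIOS = (0.95, 0.90, 0.80, 0.75, 0.50)


@dataclass
class RunConfig:
    data: str | None = None
    header: bool = False
    schema: str | None = None
    synthetic: dict | None = None
    weights_mode: str = "per-split"
    standardize: bool = True
    tune_mode: str = "nested"
    C: float = 1.0
    gamma: float = 0.5
    grid: tuple[tuple[float, float], ...] = DEFAULT_GRID
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    n_iter: int = 1000
    master_seed: int = 2021
    methods: tuple[str, ...] = ("wsvm", "svm", "rf", "nb")
    out_dir: str = "results"

    def synthetic_spec(self) -> SyntheticSpec | None:
        if self.synthetic is None:
            return None
        syn = dict(self.synthetic)
        seed = int(syn.get("seed", self.master_seed))
        if syn.get("cleveland_like"):
            return cleveland_like_spec(n=int(syn.get("n", 297)), seed=seed)
        cat = {
            name: CategoricalEffect(
                codes=tuple(d["codes"]),
                probs_pos=tuple(d["probs_pos"]),
                probs_neg=tuple(d["probs_neg"]),
            )
            for name, d in syn.get("categorical_effects", {}).items()
        }
        return SyntheticSpec(
            n=int(syn["n"]),
            class_prob=float(syn.get("class_prob", 0.5)),
            continuous_effects={
                k: float(v) for k, v in syn.get("continuous_effects", {}).items()
            },
            categorical_effects=cat,
            seed=seed,
        )


def _parse_grid(raw) -> tuple[tuple[float, float], ...]:
    if raw is None:
        return DEFAULT_GRID
    if isinstance(raw, dict):
        return tuple(
            (float(c), float(g)) for c in raw["C"] for g in raw["gamma"]
        )
    return tuple((float(c), float(g)) for c, g in raw)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus flag overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(
        data=raw.get("data"),
        header=bool(raw.get("header", False)),
        schema=raw.get("schema"),
        synthetic=raw.get("synthetic"),
        weights_mode=raw.get("weights_mode", "per-split"),
        standardize=bool(raw.get("standardize", True)),
        tune_mode=raw.get("tune_mode", "nested"),
        C=float(raw.get("C", 1.0)),
        gamma=float(raw.get("gamma", 0.5)),
        grid=_parse_grid(raw.get("grid")),
        ratios=tuple(float(r) for r in raw.get("ratios", DEFAULT_RATIOS)),
        n_iter=int(raw.get("n_iter", 1000)),
        master_seed=int(raw.get("master_seed", 2021)),
        methods=tuple(raw.get("methods", ("wsvm", "svm", "rf", "nb"))),
        out_dir=raw.get("out_dir", "results"),
    )
    if cfg.weights_mode not in ("per-split", "full-data"):
        raise ValueError(f"unknown weights_mode {cfg.weights_mode!r}")
    if cfg.tune_mode not in ("nested", "once", "fixed"):
        raise ValueError(f"unknown tune_mode {cfg.tune_mode!r}")
    if not all(0.0 < r < 1.0 for r in cfg.ratios):
        raise ValueError("ratios must lie strictly inside (0, 1)")
    if cfg.n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Short SHA-256 of the canonical JSON form of the configuration."""
    canon = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
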