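"""YAML/JSON run configuration mirroring the estimator parameters."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import yaml

from .estimator import DMLMM

__all__ = ["ModelConfig"]


@dataclass
class ModelConfig:
    """Flat run configuration; keys match :class:`~dmlmm.estimator.DMLMM`."""

    d: int = 10
    basis: str = "legendre"
    layer_dims: tuple = (4, 1)
    layer_components: tuple = (6, 3)
    domain: tuple = None
    period: float = None
    n_seasonal: int = None
    prior: dict = field(default_factory=dict)   # A, c_mu, c_delta, horseshoe_scale, alpha
    n_iter: int = 1000
    batch_size: int = 64
    full_batch: bool = False
    step_kappa: float = 0.75
    step_tau: float = 10.0
    n_inner: int = 20
    inner_tol: float = 1e-8
    random_state: int = 0

    def to_estimator(self) -> DMLMM:
        kw = asdict(self)
        prior = kw.pop("prior") or {}
        kw["layer_dims"] = tuple(kw["layer_dims"])
        kw["layer_components"] = tuple(kw["layer_components"])
        if kw["domain"] is not None:
            kw["domain"] = tuple(kw["domain"])
        return DMLMM(**kw, **prior)

    @classmethod
    def from_file(cls, path) -> "ModelConfig":
        text = open(path).read()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"configuration file {path} must hold a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)
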