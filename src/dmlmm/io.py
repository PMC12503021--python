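"""Versioned text serialization of fitted models.

A model file is self-describing JSON holding the pruned collapsed mixture,
the error-variance point estimate, the basis specification and the
architecture — everything conditional prediction needs.  The full
variational state is deliberately not stored.
"""

from __future__ import annotations

import json

import numpy as np

from .basis import BasisSpec
from .dmfa import DMFAArchitecture, GaussianMixture
from .estimator import DMLMM

SCHEMA_VERSION = 1

__all__ = ["save_model", "load_model", "SCHEMA_VERSION"]


def save_model(model: DMLMM, path) -> None:
    """Write a fitted estimator to a versioned JSON file."""
    if not hasattr(model, "gmm_"):
        raise ValueError("model must be fitted before saving")
    gmm = model.gmm_
    payload = {
        "schema_version": SCHEMA_VERSION,
        "params": model.get_params(),
        "basis": model.basis_spec_.to_dict(),
        "architecture": {"D": list(model.architecture_.D),
                         "K": list(model.architecture_.K)},
        "sigma2": float(model.sigma2_),
        "gmm": {
            "weights": gmm.weights.tolist(),
            "means": gmm.means.tolist(),
            "covariances": gmm.covariances.tolist(),
            "path_labels": [list(p) for p in gmm.path_labels],
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> DMLMM:
    """Read a model file; raises on unknown schema versions or truncation."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {version!r} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    model = DMLMM(**payload["params"])
    model.basis_spec_ = BasisSpec.from_dict(payload["basis"])
    arch = payload["architecture"]
    model.architecture_ = DMFAArchitecture(tuple(arch["D"]), tuple(arch["K"]))
    g = payload["gmm"]
    model.gmm_ = GaussianMixture(
        np.array(g["weights"]), np.array(g["means"]),
        np.array(g["covariances"]),
        path_labels=[tuple(p) for p in g["path_labels"]],
    )
    model.sigma2_ = float(payload["sigma2"])
    model.training_data_ = {}
    return model
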