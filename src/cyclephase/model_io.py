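"""Versioned JSON serialization of trained predictors, with validation."""

from __future__ import annotations

import json

import numpy as np

from cyclephase.predictor import PhaseGrid, TrainedPredictor
from cyclephase.trend import CyclicTrend

__all__ = ["serialize_model", "deserialize_model", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"


def serialize_model(model: TrainedPredictor, path: str) -> None:
    """Write a trained predictor as versioned JSON; round-trips losslessly."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "grid_K": model.grid.K,
        "provenance": model.provenance,
        "genes": [
            {
                "gene_id": t.gene_id,
                "train_thetas": t.train_thetas.tolist(),
                "fitted_values": t.fitted_values.tolist(),
                "sigma": t.sigma,
                "pve": t.pve,
                "lambda": t.lam,
            }
            for t in model.trends
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def deserialize_model(path: str) -> TrainedPredictor:
    """Load a predictor, validating schema version and model invariants."""
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema_version {version!r}; "
            f"this build reads {SCHEMA_VERSION!r}"
        )
    trends = []
    for rec in payload["genes"]:
        thetas = np.asarray(rec["train_thetas"], dtype=float)
        if np.any(np.diff(thetas) <= 0):
            raise ValueError(
                f"validation error in gene {rec['gene_id']}: train_thetas "
                "must be strictly increasing"
            )
        if rec["sigma"] <= 0:
            raise ValueError(
                f"validation error in gene {rec['gene_id']}: sigma must be > 0"
            )
        trends.append(
            CyclicTrend(
                gene_id=rec["gene_id"],
                train_thetas=thetas,
                fitted_values=np.asarray(rec["fitted_values"], dtype=float),
                sigma=float(rec["sigma"]),
                pve=float(rec["pve"]),
                lam=float(rec["lambda"]),
            )
        )
    grid = PhaseGrid(int(payload["grid_K"]))
    if not np.allclose(np.diff(grid.angles), 2 * np.pi / grid.K):
        raise ValueError("validation error: grid spacing is not 2*pi/K")
    return TrainedPredictor(
        trends=trends, grid=grid, provenance=payload.get("provenance", {})
    )
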