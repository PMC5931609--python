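"""Model persistence: a single JSON container for grids and fitted models.

Arrays are stored as nested lists (row-major for weights), so the files are
plain text, diffable, and loadable anywhere. The training configuration is
echoed verbatim for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .consensus import CsomModel, PriorTable, ProbabilityMap
from .som import SomConfig, SomGrid

_FORMAT = "csom-model-v1"


def save_model(model: CsomModel, path) -> None:
    """Write a fitted consensus SOM model to a JSON container."""
    payload = {
        "format": _FORMAT,
        "config": model.grid.config.to_dict(),
        "scaler_mean": model.grid.scaler_mean.tolist(),
        "scaler_scale": model.grid.scaler_scale.tolist(),
        "weights": model.grid.weights.tolist(),
        "class_names": model.class_names,
        "threshold": model.threshold,
        "n_runs": model.priors.n_runs,
        "priors": model.priors.priors.tolist(),
        "prob_map": model.prob_map.probs.tolist(),
        "occupied": model.prob_map.occupied.astype(int).tolist(),
        "wave": model.prob_map.wave.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> CsomModel:
    """Load a model written by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a {_FORMAT} container")
    config = SomConfig(**payload["config"])
    grid = SomGrid(
        config=config,
        weights=np.asarray(payload["weights"], dtype=float),
        scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
        scaler_scale=np.asarray(payload["scaler_scale"], dtype=float),
    )
    prob_map = ProbabilityMap(
        probs=np.asarray(payload["prob_map"], dtype=float),
        occupied=np.asarray(payload["occupied"], dtype=int).astype(bool),
        wave=np.asarray(payload["wave"], dtype=int),
    )
    priors = PriorTable(
        priors=np.asarray(payload["priors"], dtype=float),
        n_runs=int(payload["n_runs"]),
    )
    return CsomModel(
        grid=grid,
        prob_map=prob_map,
        priors=priors,
        threshold=float(payload["threshold"]),
        class_names=list(payload["class_names"]),
    )


def export_map_csv(model: CsomModel, path) -> None:
    """Write the probability map as CSV: row, col, origin, one column per class."""
    lines = ["row,col,origin," + ",".join(model.class_names)]
    pm = model.prob_map
    for r in range(pm.height):
        for c in range(pm.width):
            origin = "occupied" if pm.occupied[r, c] else "expanded"
            probs = ",".join(f"{v:.10g}" for v in pm.probs[r, c])
            lines.append(f"{r},{c},{origin},{probs}")
    Path(path).write_text("\n".join(lines) + "\n")
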