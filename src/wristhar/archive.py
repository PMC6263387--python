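"""Lossless JSON serialization of every fitted model type.

The archive format is a tagged JSON object: ``{"type": <name>, ...}`` with
numeric arrays stored as nested lists plus explicit shape metadata.  A
write-then-read round trip reproduces all parameters to full float
precision (Python's repr round-trips doubles exactly).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from .classifiers import (
    ClassifierBank,
    GaussianComponent,
    HMMClassifier,
    MixtureModel,
)
from .features import CoefficientSelector, FeatureExtractor, PCAProjection


def _arr(a: np.ndarray) -> dict:
    a = np.asarray(a)
    return {"shape": list(a.shape), "data": a.ravel().tolist()}


def _unarr(d: dict) -> np.ndarray:
    return np.asarray(d["data"], dtype=float).reshape(d["shape"])


def to_jsonable(obj: Any) -> dict:
    """Convert a fitted model object into a tagged, JSON-safe dict."""
    if isinstance(obj, CoefficientSelector):
        return {
            "type": "CoefficientSelector",
            "positions": obj.positions.tolist(),
            "ks_scores": _arr(obj.ks_scores),
        }
    if isinstance(obj, PCAProjection):
        return {
            "type": "PCAProjection",
            "mean": _arr(obj.mean),
            "components": _arr(obj.components),
            "explained_variance": _arr(obj.explained_variance),
        }
    if isinstance(obj, GaussianComponent):
        return {
            "type": "GaussianComponent",
            "weight": obj.weight,
            "mean": _arr(obj.mean),
            "cov": _arr(obj.cov),
        }
    if isinstance(obj, MixtureModel):
        return {
            "type": "MixtureModel",
            "class_id": obj.class_id,
            "dim": obj.dim,
            "components": [to_jsonable(c) for c in obj.components],
        }
    if isinstance(obj, ClassifierBank):
        return {
            "type": "ClassifierBank",
            "dim": obj.dim,
            "class_ids": obj.class_ids,
            "models": {str(c): to_jsonable(obj.models[c]) for c in obj.class_ids},
            "priors": {str(c): obj.priors[c] for c in obj.class_ids},
        }
    if isinstance(obj, HMMClassifier):
        return {
            "type": "HMMClassifier",
            "states": list(obj.states),
            "transition": _arr(obj.transition),
            "initial": _arr(obj.initial),
            "emissions": {str(s): to_jsonable(obj.emissions[s]) for s in obj.states},
        }
    if isinstance(obj, FeatureExtractor):
        return {
            "type": "FeatureExtractor",
            "n_wavelet_coeffs": obj.n_wavelet_coeffs,
            "selector": to_jsonable(obj.selector) if obj.selector else None,
            "signal_pcas": (
                {s: to_jsonable(p) for s, p in obj.signal_pcas.items()}
                if obj.signal_pcas else None
            ),
        }
    if isinstance(obj, dict):
        return {"type": "dict", "items": {k: to_jsonable(v) for k, v in obj.items()}}
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def from_jsonable(d: dict) -> Any:
    """Reconstruct a model object from its tagged dict."""
    t = d["type"]
    if t == "CoefficientSelector":
        return CoefficientSelector(
            positions=np.asarray(d["positions"], dtype=int),
            ks_scores=_unarr(d["ks_scores"]),
        )
    if t == "PCAProjection":
        return PCAProjection(
            mean=_unarr(d["mean"]),
            components=_unarr(d["components"]),
            explained_variance=_unarr(d["explained_variance"]),
        )
    if t == "GaussianComponent":
        return GaussianComponent(
            weight=d["weight"], mean=_unarr(d["mean"]), cov=_unarr(d["cov"])
        )
    if t == "MixtureModel":
        return MixtureModel(
            components=[from_jsonable(c) for c in d["components"]],
            class_id=d["class_id"],
        )
    if t == "ClassifierBank":
        return ClassifierBank(
            models={int(c): from_jsonable(m) for c, m in d["models"].items()},
            priors={int(c): p for c, p in d["priors"].items()},
        )
    if t == "HMMClassifier":
        return HMMClassifier(
            states=[int(s) for s in d["states"]],
            transition=_unarr(d["transition"]),
            initial=_unarr(d["initial"]),
            emissions={int(s): from_jsonable(m) for s, m in d["emissions"].items()},
        )
    if t == "FeatureExtractor":
        fe = FeatureExtractor(n_wavelet_coeffs=d["n_wavelet_coeffs"])
        fe.selector = from_jsonable(d["selector"]) if d["selector"] else None
        fe.signal_pcas = (
            {s: from_jsonable(p) for s, p in d["signal_pcas"].items()}
            if d["signal_pcas"] else None
        )
        return fe
    if t == "dict":
        return {k: from_jsonable(v) for k, v in d["items"].items()}
    raise TypeError(f"unknown archive type {t!r}")


def save_archive(path: str | Path, obj: Any) -> None:
    """Write a model (or dict of models) to a JSON archive."""
    with open(path, "w") as fh:
        json.dump(to_jsonable(obj), fh)


def load_archive(path: str | Path) -> Any:
    """Read a model (or dict of models) back from a JSON archive."""
    with open(path) as fh:
        return from_jsonable(json.load(fh))
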