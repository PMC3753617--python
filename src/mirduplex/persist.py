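"""Versioned single-file model container.

The container is a joblib pickle of a dict carrying a format tag, a format
version, the ensemble, hyperparameters, the feature-registry fingerprint and
the clade label.  Loading refuses containers with a different format version
or a registry fingerprint that does not match the running package — a stale
model must be retrained, not silently rescored.
"""

from __future__ import annotations

from pathlib import Path

import joblib

from .classifier import DuplexModel, ModelParams
from .errors import FingerprintMismatchError, ModelLoadError
from .features import registry_fingerprint

FORMAT_TAG = "mirduplex-model"
FORMAT_VERSION = 1


def save_model(model: DuplexModel, path) -> None:
    payload = {
        "format": FORMAT_TAG,
        "format_version": FORMAT_VERSION,
        "ensemble": model.ensemble,
        "params": model.params,
        "fingerprint": model.fingerprint,
        "clade": model.clade,
        "training_summary": model.training_summary,
        "model_version": model.version,
    }
    joblib.dump(payload, str(path))


def load_model(path, check_fingerprint: bool = True) -> DuplexModel:
    p = Path(path)
    if not p.exists():
        raise ModelLoadError(f"model file {path} does not exist")
    try:
        payload = joblib.load(str(p))
    except Exception as exc:  # truncated/corrupted pickles raise many types
        raise ModelLoadError(f"cannot read model container {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != FORMAT_TAG:
        raise ModelLoadError(f"{path} is not a {FORMAT_TAG} container")
    if payload.get("format_version") != FORMAT_VERSION:
        raise ModelLoadError(
            f"model format version {payload.get('format_version')} "
            f"is incompatible with {FORMAT_VERSION}"
        )
    if check_fingerprint and payload["fingerprint"] != registry_fingerprint():
        raise FingerprintMismatchError(
            "model was trained against a different feature registry; retrain"
        )
    return DuplexModel(
        ensemble=payload["ensemble"],
        params=payload["params"],
        fingerprint=payload["fingerprint"],
        clade=payload.get("clade", "all"),
        training_summary=payload.get("training_summary", {}),
        version=payload.get("model_version", 1),
    )
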