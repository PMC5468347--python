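"""Trained-model container and JSON (de)serialisation.

Linear families (ridge logistic regression, linear SVM) are stored as
explicit coefficients and scored through the logistic transform

    Probability(secretory) = 1 / (1 + exp(-z)),   z = sum_i c_i x_i + b,

on features standardised with the stored per-feature mean/sd.  Non-linear
families (kernel SVMs, random forests) carry an opaque fitted payload and
return their native probability output.
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

SCHEMA_VERSION = 1

LINEAR_FAMILIES = ("ridge-logistic", "linear-svm", "intercept")
ALL_FAMILIES = LINEAR_FAMILIES + ("polynomial-svm", "gaussian-svm", "random-forest")


@dataclass
class TrainedModel:
    view: str
    window_length: int
    groups: list
    selected_features: list
    means: list
    sds: list
    family: str
    params: dict
    threshold: float
    coefficients: Optional[list] = None
    intercept: Optional[float] = None
    payload_b64: Optional[str] = None
    cv_auc: Optional[float] = None
    corrected_auc: Optional[float] = None
    auc_ci: Optional[list] = None
    alternate_signatures: list = field(default_factory=list)
    cpseaac: dict = field(
        default_factory=lambda: {"scale": "K/D", "lam": 5, "w": 0.05}
    )
    provenance: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.family not in ALL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.is_linear and self.family != "intercept" and self.coefficients is None:
            raise ValueError("linear model without coefficients")
        n = len(self.selected_features)
        if len(self.means) != n or len(self.sds) != n:
            raise ValueError("standardization constants disagree with signature size")

    @property
    def is_linear(self) -> bool:
        return self.family in LINEAR_FAMILIES

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        mu = np.asarray(self.means, dtype=np.float64)
        sd = np.asarray(self.sds, dtype=np.float64)
        sd = np.where(sd > 0, sd, 1.0)
        return (X - mu) / sd

    def _estimator(self):
        if self.payload_b64 is None:
            raise ValueError("model carries no fitted payload")
        return pickle.loads(base64.b64decode(self.payload_b64))

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Probabilities for rows of X (columns = selected features, raw scale)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != len(self.selected_features):
            raise ValueError(
                f"expected {len(self.selected_features)} features, got {X.shape[1]}"
            )
        if self.family == "intercept":
            z = np.full(X.shape[0], self.intercept)
            return 1.0 / (1.0 + np.exp(-z))
        Z = self._standardize(X)
        if self.family == "ridge-logistic" or (self.is_linear and self.payload_b64 is None):
            z = Z @ np.asarray(self.coefficients, dtype=np.float64) + self.intercept
            return 1.0 / (1.0 + np.exp(-z))
        # linear SVMs keep their fitted payload: probabilities come from
        # Platt scaling, not from the raw hyperplane distance
        est = self._estimator()
        proba = est.predict_proba(Z)
        positive = list(est.classes_).index(1)
        return proba[:, positive]

    def score(self, x: np.ndarray) -> float:
        return float(self.score_matrix(np.atleast_2d(x))[0])

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "TrainedModel":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                data = json.loads(text)
            else:
                with open(text) as fh:
                    data = json.load(fh)
        if data.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {data.get('schema_version')!r}"
            )
        return cls(**data)


def encode_payload(estimator) -> str:
    return base64.b64encode(pickle.dumps(estimator)).decode("ascii")
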