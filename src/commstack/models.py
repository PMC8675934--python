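"""Uniform training/prediction interface over the three model families.

Linear regression, random forest and gradient-boosted trees all consume
the same stacked ``ModelFrame`` and return real-valued predictions.
Predictions are never rounded or clipped: linear and boosted models may
return negative abundances and those are preserved so that model
families can be compared on equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from xgboost import XGBRegressor

from .data import ModelFrame

FAMILIES = ("linear", "random-forest", "gradient-boosted-trees")

_ALIASES = {
    "linear": "linear", "lm": "linear", "lr": "linear",
    "random-forest": "random-forest", "rf": "random-forest",
    "gradient-boosted-trees": "gradient-boosted-trees",
    "xgb": "gradient-boosted-trees", "xgboost": "gradient-boosted-trees",
    "gbt": "gradient-boosted-trees",
}


@dataclass(frozen=True)
class ModelSpec:
    """Model family + hyperparameters + seed.

    Defaults: 500 trees, unlimited depth, one third of the features per
    split for the forest; 500 rounds, depth 6, learning rate 0.1 for the
    boosted trees. ``n_estimators=None`` means the family default.
    """
    family: str = "random-forest"
    n_estimators: int | None = None
    max_depth: int | None = None
    learning_rate: float = 0.1
    max_features: float = 1.0 / 3.0
    max_samples: float | None = None     # forest only: bootstrap fraction per tree
    seed: int = 0

    def __post_init__(self):
        fam = _ALIASES.get(self.family)
        if fam is None:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"choose from {FAMILIES}")
        object.__setattr__(self, "family", fam)

    def with_seed(self, seed: int) -> "ModelSpec":
        return replace(self, seed=int(seed))

    def build(self):
        if self.family == "linear":
            return LinearRegression()
        if self.family == "random-forest":
            return RandomForestRegressor(
                n_estimators=self.n_estimators or 500,
                max_depth=self.max_depth,
                max_features=self.max_features,
                max_samples=self.max_samples,
                random_state=self.seed, n_jobs=1)
        return XGBRegressor(
            n_estimators=self.n_estimators or 500,
            max_depth=self.max_depth or 6,
            learning_rate=self.learning_rate,
            random_state=self.seed, n_jobs=1,
            tree_method="hist", verbosity=0)


@dataclass
class TrainedModel:
    """Fitted estimator + the frozen, ordered feature list it was trained on."""
    estimator: object
    feature_names: tuple[str, ...]
    spec: ModelSpec
    target_range: tuple[float, float]

    def predict(self, X) -> np.ndarray:
        """Predict; refuses inputs whose feature set differs from training."""
        if isinstance(X, ModelFrame):
            X = X.X
        missing = [c for c in self.feature_names if c not in X.columns]
        extra = [c for c in X.columns if c not in self.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing={missing} extra={extra}")
        if len(X) == 0:
            return np.empty(0)
        return np.asarray(
            self.estimator.predict(X[list(self.feature_names)]), float)


def fit(spec: ModelSpec, frame: ModelFrame) -> TrainedModel:
    """Fit one global cross-species model on the stacked frame.

    A single model serves every focal species (species identity is a
    one-hot feature); deterministic under a fixed seed.
    """
    if len(frame) == 0:
        raise ValueError("cannot fit on an empty frame")
    if frame.X.shape[1] == 0:
        raise ValueError("frame has zero features")
    values = frame.X.to_numpy(float)
    if not np.all(np.isfinite(values)) or not np.all(np.isfinite(frame.y)):
        raise ValueError("non-finite values in features or target")
    est = spec.build()
    est.fit(frame.X, frame.y.to_numpy())
    return TrainedModel(estimator=est,
                        feature_names=tuple(frame.X.columns),
                        spec=spec,
                        target_range=(float(frame.y.min()), float(frame.y.max())))
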