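"""End-to-end prediction pipelines used by the evaluation protocols.

An ``AbundancePipeline`` bundles one of the three model configurations
compared throughout the package:

- ``all_features``: observed competitor abundances + abiotic features,
- ``abiotic``: abiotic features only,
- ``two_step``: the sequential stacked ensemble (stage-1 predicted
  competitors + abiotic features).

All three share the stacked cross-species frame, the focal zero-out rule
and one global model across species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .data import CommunityTable, build_model_frame
from .models import ModelSpec, fit
from .two_step import fit_two_step, predict_two_step

KINDS = ("all_features", "abiotic", "two_step")


@dataclass
class AbundancePipeline:
    """One fit/predict unit; ``pipeline_factory = lambda seed: pipeline.reseed(seed)``."""

    kind: str = "two_step"
    spec: ModelSpec = field(default_factory=ModelSpec)      # model (stage 2 for two_step)
    stage1_spec: ModelSpec | None = None                    # two_step only
    features: tuple[str, ...] | None = None                 # None = all abiotic
    stage1_features: tuple[str, ...] | None = None
    chaining: str = "in-sample"
    seed: int = 0
    _removed: tuple[str, ...] = ()
    _model: object = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")

    # -- configuration ----------------------------------------------------------
    def reseed(self, seed: int) -> "AbundancePipeline":
        return replace(self, seed=int(seed), _model=None)

    def without_feature(self, name: str) -> "AbundancePipeline":
        """Drop an abiotic feature from every stage (e.g. precipitation)."""
        return replace(self, _removed=self._removed + (name,), _model=None)

    def _resolve(self, table: CommunityTable, features):
        feats = list(features) if features is not None \
            else list(table.schema.abiotic_variables)
        return [f for f in feats if f not in self._removed]

    # -- fit / predict ----------------------------------------------------------
    def fit(self, table: CommunityTable) -> "AbundancePipeline":
        feats = self._resolve(table, self.features)
        if self.kind == "two_step":
            s1 = self.stage1_spec or self.spec
            self._model = fit_two_step(
                table, stage1_spec=s1, stage2_spec=self.spec,
                stage1_features=self._resolve(table, self.stage1_features
                                              if self.stage1_features is not None
                                              else self.features),
                stage2_features=feats,
                chaining=self.chaining, seed=self.seed)
        else:
            frame = build_model_frame(
                table, feats,
                include_competitors=(self.kind == "all_features"))
            self._model = fit(self.spec.with_seed(self.seed), frame)
            self._features_used = feats
        return self

    def predict_table(self, table: CommunityTable) -> pd.DataFrame:
        """Predict every (community, species) of ``table``.

        Returns tidy long format with both observed and predicted values.
        The two-step pipeline sees only the abiotic side of the table,
        honouring its abiotic-only prediction contract.
        """
        if self._model is None:
            raise RuntimeError("pipeline is not fitted")
        if self.kind == "two_step":
            pred = predict_two_step(self._model, table.abiotic_records())
        else:
            frame = build_model_frame(
                table, self._features_used,
                include_competitors=(self.kind == "all_features"))
            pred = frame.meta.copy()
            pred["prediction"] = self._model.predict(frame)
        observed = table.data.melt(
            id_vars=["plot", "subplot", "year"],
            value_vars=list(table.species),
            var_name="species", value_name="observed")
        out = pred.merge(observed, on=["plot", "subplot", "year", "species"],
                         validate="one_to_one")
        return out.rename(columns={"prediction": "predicted"})


def pipeline_factory(kind: str, spec: ModelSpec, features=None,
                     stage1_spec: ModelSpec | None = None,
                     stage1_features=None, chaining: str = "in-sample"):
    """Convenience factory builder for the evaluation loops."""
    proto = AbundancePipeline(kind=kind, spec=spec, stage1_spec=stage1_spec,
                              features=tuple(features) if features else None,
                              stage1_features=(tuple(stage1_features)
                                               if stage1_features else None),
                              chaining=chaining)
    return proto.reseed
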