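"""Two-step sequential stacked abundance predictor.

Stage 1 predicts every species' abundance from abiotic features alone
(plus species identity). Stage 2 predicts the focal species' abundance
from abiotic features *plus the stage-1 predicted competitor abundances*
bound in as competitor columns (focal column zeroed, as in the observed-
competitor model). The fitted ensemble therefore needs only abiotic
measurements at prediction time: the prediction interface rejects inputs
that carry observed abundance columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .data import (CommunityTable, add_competitor_columns, build_abiotic_frame,
                   build_model_frame)
from .models import ModelSpec, TrainedModel, fit

CHAINING_MODES = ("in-sample", "out-of-fold")


@dataclass
class TwoStepModel:
    """Stage-1 abiotic predictor + stage-2 predictor over predicted competitors."""
    stage1: TrainedModel
    stage2: TrainedModel
    stage1_features: tuple[str, ...]
    stage2_features: tuple[str, ...]
    species: tuple[str, ...]
    chaining: str
    seed: int


def _stage_seeds(seed: int) -> tuple[int, int]:
    # distinct deterministic sub-seeds so each stage reproduces independently
    state = np.random.SeedSequence(seed).generate_state(2)
    return int(state[0] % 2**31), int(state[1] % 2**31)


def _predictions_matrix(model: TrainedModel, frame) -> np.ndarray:
    """Stage-1 predictions reshaped to (n_records, n_species)."""
    n_sp = len(frame.species)
    pred = model.predict(frame)
    return pred.reshape(n_sp, -1).T


def fit_two_step(table: CommunityTable,
                 stage1_spec: ModelSpec | None = None,
                 stage2_spec: ModelSpec | None = None,
                 stage1_features=None, stage2_features=None,
                 chaining: str = "in-sample", n_folds: int = 5,
                 seed: int = 0) -> TwoStepModel:
    """Fit the sequential ensemble.

    ``chaining`` controls which stage-1 predictions feed the stage-2
    training frame: ``in-sample`` (default) uses stage 1's predictions on
    its own training data; ``out-of-fold`` replaces them with K-fold
    held-out predictions as an anti-leakage option.
    """
    stage1_spec = stage1_spec or ModelSpec("random-forest")
    stage2_spec = stage2_spec or ModelSpec("random-forest")
    if chaining not in CHAINING_MODES:
        raise ValueError(f"chaining must be one of {CHAINING_MODES}")
    s1, s2 = _stage_seeds(seed)

    frame1 = build_model_frame(table, stage1_features, include_competitors=False)
    stage1 = fit(stage1_spec.with_seed(s1), frame1)

    n = len(table.data)
    if chaining == "in-sample":
        xtilde = _predictions_matrix(stage1, frame1)
    else:
        if n_folds < 2:
            raise ValueError("out-of-fold chaining needs at least 2 folds")
        xtilde = np.empty((n, len(table.species)))
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=s1)
        for train_idx, test_idx in kf.split(np.arange(n)):
            mask = np.zeros(n, bool)
            mask[train_idx] = True
            sub_model = fit(stage1_spec.with_seed(s1),
                            build_model_frame(table.subset(mask),
                                              stage1_features,
                                              include_competitors=False))
            test_frame = build_model_frame(table.subset(~mask), stage1_features,
                                           include_competitors=False)
            xtilde[test_idx] = _predictions_matrix(sub_model, test_frame)

    frame2 = build_model_frame(table, stage2_features, include_competitors=False)
    frame2 = add_competitor_columns(frame2, xtilde)
    stage2 = fit(stage2_spec.with_seed(s2), frame2)

    return TwoStepModel(stage1=stage1, stage2=stage2,
                        stage1_features=frame1.abiotic_features,
                        stage2_features=frame2.abiotic_features,
                        species=table.species, chaining=chaining, seed=seed)


def _check_abiotic_only(model: TwoStepModel, records: pd.DataFrame) -> None:
    observed = [sp for sp in model.species if sp in records.columns]
    if observed:
        raise ValueError(
            "prediction input must be abiotic-only; found observed abundance "
            f"columns: {observed}")


def predict_stage1(model: TwoStepModel, records: pd.DataFrame) -> pd.DataFrame:
    """Abiotic-only predicted abundances for every species and record."""
    _check_abiotic_only(model, records)
    frame = build_abiotic_frame(records, list(model.stage1_features),
                                model.species)
    pred = model.stage1.predict(frame)
    out = frame.meta.copy()
    out["prediction"] = pred
    return out


def predict_two_step(model: TwoStepModel, records: pd.DataFrame) -> pd.DataFrame:
    """Final two-step predictions in tidy long format.

    Stage 1 fills the competitor columns from the abiotic data; stage 2
    returns one prediction per (record, species).
    """
    _check_abiotic_only(model, records)
    frame1 = build_abiotic_frame(records, list(model.stage1_features),
                                 model.species)
    xtilde = _predictions_matrix(model.stage1, frame1)
    frame2 = build_abiotic_frame(records, list(model.stage2_features),
                                 model.species)
    frame2 = add_competitor_columns(frame2, xtilde)
    pred = model.stage2.predict(frame2)
    out = frame2.meta.copy()
    out["prediction"] = pred
    return out
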