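"""Metrics and evaluation protocols.

Implements RMSE and the coefficient of determination (with RSE = 1 - R^2),
spatial block K-fold assignment, repeated random 80/20 holdout, leave-one-
year-out temporal evaluation, per-species error profiles, and Moran's I
for spatial autocorrelation checks.

Evaluation loops are generic over a *pipeline factory*: a callable
``factory(seed) -> pipeline`` returning a fresh object with
``fit(table)`` and ``predict_table(table) -> DataFrame`` (columns plot,
subplot, year, species, observed, predicted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(y, yhat) -> float:
    """Root mean squared error between observed and predicted vectors."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y, yhat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    SS_tot uses deviations of the observations from their mean; the value
    may be negative when the predictor is worse than the mean predictor.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero-variance target")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


@dataclass
class MetricsRecord:
    """One evaluation result; rse is defined as 1 - r2 exactly."""
    rmse: float
    r2: float | None
    n: int
    scope: str = "global"            # global | per-species | per-year
    species: str | None = None
    year: int | None = None
    run: int | None = None
    flagged: bool = False            # zero-variance observations, not scored

    @property
    def rse(self) -> float | None:
        return None if self.r2 is None else 1.0 - self.r2


@dataclass
class RunDistribution:
    """Collection of MetricsRecords over runs/folds with median summaries."""
    records: list = field(default_factory=list)          # global scope
    per_species: list = field(default_factory=list)

    @property
    def median_r2(self) -> float:
        return float(np.median([r.r2 for r in self.records if r.r2 is not None]))

    @property
    def median_rmse(self) -> float:
        return float(np.median([r.rmse for r in self.records]))

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(r) | {"rse": r.rse} for r in self.records + self.per_species]
        return pd.DataFrame(rows)


def per_species_metrics(observed, predicted, labels, run=None) -> list[MetricsRecord]:
    """RMSE/R2/RSE per species; zero-variance species are flagged, not scored."""
    df = pd.DataFrame({"y": np.asarray(observed, float),
                       "yhat": np.asarray(predicted, float),
                       "species": list(labels)})
    out = []
    for sp, grp in df.groupby("species", sort=True):
        y, yhat = grp["y"].to_numpy(), grp["yhat"].to_numpy()
        if len(y) < 2 or np.all(y == y[0]):
            out.append(MetricsRecord(rmse=rmse(y, yhat), r2=None, n=len(y),
                                     scope="per-species", species=sp, run=run,
                                     flagged=True))
        else:
            out.append(MetricsRecord(rmse=rmse(y, yhat), r2=r_squared(y, yhat),
                                     n=len(y), scope="per-species", species=sp,
                                     run=run))
    return out


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Mapping (plot, subplot) -> fold index; folds partition the subplots."""
    mapping: dict
    k: int
    scheme: str

    def fold_of(self, df: pd.DataFrame) -> np.ndarray:
        keys = list(zip(df["plot"], df["subplot"]))
        return np.array([self.mapping[key] for key in keys])


def spatial_block_kfold(sites: pd.DataFrame, k: int = 4,
                        block: tuple[float, float] = (3.0, 3.0),
                        seed: int = 0) -> FoldAssignment:
    """Group subplots into contiguous spatial blocks and deal blocks to folds.

    Blocks are axis-aligned windows of ``block`` metres over the subplot
    coordinates within each plot (default 3x3, i.e. four blocks of nine
    subplots in a 6x6 plot). Whole blocks are assigned to folds so that
    nearby subplots never straddle the train/test boundary; every year of
    a subplot inherits its fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sub = sites[["plot", "subplot", "x", "y"]].drop_duplicates(["plot", "subplot"])
    bw, bh = block
    blocks: dict[tuple, list] = {}
    for plot, grp in sub.groupby("plot", sort=True):
        lx = grp["x"] - grp["x"].min()
        ly = grp["y"] - grp["y"].min()
        for key, bx, by in zip(zip(grp["plot"], grp["subplot"]),
                               (lx // bw).astype(int), (ly // bh).astype(int)):
            blocks.setdefault((plot, bx, by), []).append(key)
    if len(blocks) < k:
        raise ValueError(f"only {len(blocks)} spatial blocks for k={k} folds")
    rng = np.random.default_rng(seed)
    order = list(blocks)
    rng.shuffle(order)
    sizes = np.zeros(k, int)
    mapping = {}
    for b in order:
        fold = int(np.argmin(sizes))        # balance subplot counts
        for key in blocks[b]:
            mapping[key] = fold
        sizes[fold] += len(blocks[b])
    return FoldAssignment(mapping=mapping, k=k, scheme="spatial-block")


def random_kfold(sites: pd.DataFrame, k: int, seed: int = 0) -> FoldAssignment:
    """Plain random partition of subplots into k folds (non-spatial control)."""
    sub = sites[["plot", "subplot"]].drop_duplicates()
    keys = list(zip(sub["plot"], sub["subplot"]))
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    mapping = {key: i % k for i, key in enumerate(keys)}
    return FoldAssignment(mapping=mapping, k=k, scheme="random")


# ---------------------------------------------------------------------------
# evaluation loops
# ---------------------------------------------------------------------------

def _score(pred: pd.DataFrame, run=None, year=None) -> tuple[MetricsRecord, list]:
    y, yhat = pred["observed"].to_numpy(), pred["predicted"].to_numpy()
    rec = MetricsRecord(rmse=rmse(y, yhat), r2=r_squared(y, yhat), n=len(y),
                        scope="global", run=run, year=year)
    return rec, per_species_metrics(y, yhat, pred["species"], run=run)


def repeated_random_split_eval(table, pipeline_factory, n_runs: int = 100,
                               test_fraction: float = 0.2,
                               seed: int = 0) -> RunDistribution:
    """Repeated random 80/20 community-level holdout evaluation.

    Each run redraws the train/test split of communities, refits the full
    pipeline on the training set and scores the held-out communities,
    pooled across species and per species.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(table.data)
    n_test = int(round(n * test_fraction))
    if n_test == 0 or n_test == n:
        raise ValueError("test split empty or train split empty")
    ss = np.random.SeedSequence(seed)
    dist = RunDistribution()
    for run, child in enumerate(ss.spawn(n_runs)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        test_idx = np.zeros(n, bool)
        test_idx[perm[:n_test]] = True
        pipe = pipeline_factory(int(child.generate_state(1)[0] % 2**31))
        pipe.fit(table.subset(~test_idx))
        pred = pipe.predict_table(table.subset(test_idx))
        rec, per_sp = _score(pred, run=run)
        dist.records.append(rec)
        dist.per_species.extend(per_sp)
    return dist


def spatial_cv_eval(table, pipeline_factory, k: int = 4,
                    block: tuple[float, float] = (3.0, 3.0),
                    seed: int = 0) -> RunDistribution:
    """Spatial block K-fold cross-validation (one record per fold)."""
    assignment = spatial_block_kfold(table.data, k=k, block=block, seed=seed)
    folds = assignment.fold_of(table.data)
    dist = RunDistribution()
    for fold in range(k):
        mask = folds == fold
        pipe = pipeline_factory(seed * 1000 + fold)
        pipe.fit(table.subset(~mask))
        pred = pipe.predict_table(table.subset(mask))
        rec, per_sp = _score(pred, run=fold)
        dist.records.append(rec)
        dist.per_species.extend(per_sp)
    return dist


def leave_one_year_out_eval(table, pipeline_factory,
                            drop_precipitation: bool = False,
                            seed: int = 0) -> RunDistribution:
    """Hold out each year in turn; train on all other years.

    The training set deliberately includes years *after* the held-out one:
    this evaluates the procedure's temporal transferability, not a
    forecast. With ``drop_precipitation`` the year-level precipitation
    feature is removed from every stage of the pipeline.
    """
    years = table.years
    if len(years) < 2:
        raise ValueError("need at least 2 distinct years")
    dist = RunDistribution()
    for i, year in enumerate(years):
        mask = table.data["year"] == year
        pipe = pipeline_factory(seed * 1000 + i)
        if drop_precipitation:
            pipe = pipe.without_feature("precipitation")
        pipe.fit(table.subset(~mask))
        pred = pipe.predict_table(table.subset(mask))
        rec, per_sp = _score(pred, year=year)
        dist.records.append(rec)
        dist.per_species.extend(per_sp)
    return dist


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def morans_i(values, coords, scheme: str = "inverse_distance") -> float:
    """Global Moran's I with row-standardised weights.

    ``scheme`` is ``inverse_distance`` (1/d between all pairs) or ``rook``
    (unit weight for orthogonally adjacent grid cells at spacing 1).
    Under spatial randomness E[I] = -1/(n-1).
    """
    z = np.asarray(values, float)
    xy = np.asarray(coords, float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 sites")
    if np.all(z == z[0]):
        raise ValueError("zero-variance values")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    if scheme == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
    elif scheme == "rook":
        w = (np.abs(d - 1.0) < 1e-9).astype(float)
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    w = w / rs
    z = z - z.mean()
    return float(n / w.sum() * (z @ w @ z) / (z @ z))


def per_species_morans_i(table) -> dict[str, float]:
    """Mean Moran's I per species over (plot, year) abundance fields.

    Fields where the species is absent or constant carry no spatial signal
    and are skipped; species with no scoreable field are omitted.
    """
    out = {}
    df = table.data
    for sp in table.species:
        vals = []
        for (_, _), grp in df.groupby(["plot", "year"], sort=False):
            z = grp[sp].to_numpy(float)
            if len(z) >= 3 and not np.all(z == z[0]):
                vals.append(morans_i(z, grp[["x", "y"]].to_numpy()))
        if vals:
            out[sp] = float(np.mean(vals))
    return out
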