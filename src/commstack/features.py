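"""Two-stage feature selection.

Stage one removes redundancy: abiotic features are grouped into clusters
by transitive |Spearman rho| above a threshold and one representative is
kept per cluster. Stage two benchmarks each surviving feature's
permutation importance against an injected pure-noise column: features
that matter less than noise are candidates for removal. Both stages
support manual overrides, and the selection rules used for the saline-
grassland case study ship with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import (PRECIPITATION, SOIL_VARIABLES, SPECIES_PREFIX,
                   CommunityTable, ModelFrame)
from .evaluation import r_squared
from .models import ModelSpec, fit

NOISE_FEATURE = "random_noise"
SPECIES_FACTOR = "species"


@dataclass
class SelectionReport:
    """Everything the two selection stages decided, with provenance."""
    candidates: tuple[str, ...]
    spearman: pd.DataFrame | None = None
    clusters: list = field(default_factory=list)       # list[set[str]]
    kept: list = field(default_factory=list)
    dropped: dict = field(default_factory=dict)        # feature -> reason
    constant: list = field(default_factory=list)
    importance: pd.DataFrame | None = None             # feature, importance, se

    def validate(self) -> None:
        assert set(self.kept) | set(self.dropped) == set(self.candidates)
        assert not set(self.kept) & set(self.dropped)


@dataclass(frozen=True)
class KeepPolicy:
    """How to choose the representative of a correlated cluster.

    A cluster member listed in ``prefer`` always wins; otherwise the
    member with the highest marginal importance (|Spearman rho| against
    total community abundance in a preliminary pass) is kept.
    """
    prefer: tuple[str, ...] = ()


def spearman_cluster_filter(table: CommunityTable, threshold: float = 0.7,
                            keep_policy: KeepPolicy | None = None,
                            candidates=None) -> SelectionReport:
    """Group features by transitive |rho| >= threshold; keep one per cluster.

    Constant features have undefined rank correlation: they are flagged,
    excluded from clustering, and kept. Singleton clusters are kept.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    keep_policy = keep_policy or KeepPolicy()
    candidates = tuple(candidates or table.schema.abiotic_variables)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate features")
    df = table.data[list(candidates)]
    constant = [c for c in candidates if df[c].nunique() <= 1]
    active = [c for c in candidates if c not in constant]

    rho = pd.DataFrame(np.eye(len(active)), index=active, columns=active)
    if len(active) >= 2:
        mat, _ = stats.spearmanr(df[active].to_numpy())
        mat = np.atleast_2d(mat)
        rho = pd.DataFrame(mat, index=active, columns=active)

    # union-find over |rho| >= threshold
    parent = {c: c for c in active}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(active):
        for b in active[i + 1:]:
            if abs(rho.loc[a, b]) >= threshold:
                parent[find(a)] = find(b)

    groups: dict[str, list] = {}
    for c in active:
        groups.setdefault(find(c), []).append(c)
    clusters = [set(g) for g in groups.values() if len(g) > 1]

    # marginal importance for the fallback policy: |rho| with total abundance
    total = table.abundance_matrix().sum(axis=1)
    marginal = {}
    for c in active:
        r = stats.spearmanr(df[c], total).statistic if len(df) > 2 else 0.0
        marginal[c] = abs(float(r)) if np.isfinite(r) else 0.0

    kept, dropped = list(constant), {}
    for g in groups.values():
        if len(g) == 1:
            kept.append(g[0])
            continue
        preferred = [c for c in g if c in keep_policy.prefer]
        rep = preferred[0] if preferred else max(g, key=lambda c: marginal[c])
        kept.append(rep)
        for c in g:
            if c != rep:
                dropped[c] = "correlation-cluster"

    kept = [c for c in candidates if c in kept]         # original order
    report = SelectionReport(candidates=candidates, spearman=rho,
                             clusters=clusters, kept=kept, dropped=dropped,
                             constant=constant)
    report.validate()
    return report


def noise_benchmark_importance(frame: ModelFrame, spec: ModelSpec,
                               seed: int = 0, n_repeats: int = 10,
                               test_fraction: float = 0.2) -> pd.DataFrame:
    """Permutation importance of every feature, benchmarked against noise.

    A uniform random column is appended to the frame, the model is fitted
    on an 80% split, and each feature's importance is the mean drop in
    held-out R^2 over ``n_repeats`` shuffles of that feature. The one-hot
    species identity columns are shuffled jointly as a single *species*
    factor. Returns a table (feature, importance, se) sorted descending;
    exactly one row is the noise benchmark.
    """
    if len(frame) < 2:
        raise ValueError("insufficient data for permutation importance")
    rng = np.random.default_rng(seed)
    X = frame.X.copy()
    X[NOISE_FEATURE] = rng.uniform(size=len(X))
    y = frame.y.to_numpy()

    n = len(X)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    if len(train_idx) == 0:
        raise ValueError("insufficient data for permutation importance")

    est = spec.build()
    est.fit(X.iloc[train_idx], y[train_idx])
    X_test, y_test = X.iloc[test_idx].reset_index(drop=True), y[test_idx]
    base = r_squared(y_test, est.predict(X_test))

    dummy_cols = [c for c in X.columns if c.startswith(SPECIES_PREFIX)]
    groups: dict[str, list[str]] = {
        c: [c] for c in X.columns if c not in dummy_cols}
    if dummy_cols:
        groups[SPECIES_FACTOR] = dummy_cols

    rows = []
    for name, cols in groups.items():
        drops = []
        for _ in range(n_repeats):
            shuffled = X_test.copy()
            p = rng.permutation(len(X_test))
            shuffled[cols] = X_test[cols].to_numpy()[p]
            drops.append(base - r_squared(y_test, est.predict(shuffled)))
        drops = np.asarray(drops)
        rows.append({"feature": name, "importance": float(drops.mean()),
                     "se": float(drops.std(ddof=1) / np.sqrt(n_repeats))})
    out = pd.DataFrame(rows).sort_values("importance", ascending=False)
    return out.reset_index(drop=True)


def select_features(report: SelectionReport, drop_below_noise: bool = False,
                    manual_drop=(), manual_keep=()) -> list[str]:
    """Apply the below-noise rule and manual overrides to a report.

    Features already dropped by the correlation filter stay dropped. With
    ``drop_below_noise`` every feature whose importance falls below the
    noise benchmark is removed unless listed in ``manual_keep``; features
    in ``manual_drop`` are always removed. The noise column itself never
    survives. Decisions are recorded in ``report.dropped``.
    """
    for name in list(manual_drop) + list(manual_keep):
        if name not in report.candidates:
            raise ValueError(f"override names unknown feature {name!r}")
    retained = [c for c in report.kept if c != NOISE_FEATURE]
    if NOISE_FEATURE in report.candidates:
        report.dropped.setdefault(NOISE_FEATURE, "noise-benchmark")

    if drop_below_noise:
        if report.importance is None:
            raise ValueError("report carries no importance table")
        imp = dict(zip(report.importance["feature"], report.importance["importance"]))
        if NOISE_FEATURE not in imp:
            raise ValueError("importance table lacks the noise benchmark")
        cut = imp[NOISE_FEATURE]
        for c in list(retained):
            if c in manual_keep:
                continue
            if c in imp and imp[c] < cut:
                retained.remove(c)
                report.dropped[c] = "below-noise"
    for c in manual_drop:
        if c in retained:
            retained.remove(c)
            report.dropped[c] = "manual-override"
    report.kept = retained
    report.validate()
    return retained


# ---------------------------------------------------------------------------
# shipped case-study selection rules
# ---------------------------------------------------------------------------

#: Correlated clusters resolved for the saline-grassland survey: the carbon
#: cluster keeps C, the salinity cluster keeps salinity.
GRASSLAND_CLUSTER_DROPS = ("organic_matter", "N", "cn_ratio", "Na", "Cl", "K")
#: Features ranking below the noise benchmark in the abiotic random forest.
GRASSLAND_BELOW_NOISE = ("Ca", "pH", "Mg")
#: Ca is retained by explicit override despite ranking below noise.
GRASSLAND_MANUAL_KEEP = ("Ca",)


def grassland_feature_sets() -> dict[str, list[str]]:
    """The retained abiotic feature sets of the grassland case study.

    ``abiotic``: the 6-feature set used by the abiotic-only model.
    ``full``: the 8-feature set used by the all-features and two-step
    models (keeps Mg and pH, which rank slightly higher under boosting).
    """
    candidates = tuple(SOIL_VARIABLES) + (PRECIPITATION,)
    after_cluster = [c for c in candidates if c not in GRASSLAND_CLUSTER_DROPS]
    report_full = SelectionReport(
        candidates=candidates, kept=list(after_cluster),
        dropped={c: "correlation-cluster" for c in GRASSLAND_CLUSTER_DROPS})
    full = select_features(report_full)

    report_abiotic = SelectionReport(
        candidates=candidates, kept=list(after_cluster),
        dropped={c: "correlation-cluster" for c in GRASSLAND_CLUSTER_DROPS})
    drops = tuple(c for c in GRASSLAND_BELOW_NOISE
                  if c not in GRASSLAND_MANUAL_KEEP)
    abiotic = select_features(report_abiotic, manual_drop=drops,
                              manual_keep=GRASSLAND_MANUAL_KEEP)
    return {"abiotic": abiotic, "full": full}
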