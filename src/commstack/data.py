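"""Community data model: tidy tables of abundances + abiotic variables.

The basic observational unit is a *community*: one 1 m^2 subplot in one
year, carrying integer counts of adult individuals for every species in
the survey plus the subplot's soil profile and the year's precipitation.
Tables are stored wide (one column per species, one per abiotic
variable) and exchanged as plain CSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

#: Soil chemistry / physics measured once per subplot.
SOIL_VARIABLES = [
    "pH", "salinity", "carbonates", "organic_matter", "cn_ratio",
    "Cl", "C", "N", "P", "Ca", "Mg", "K", "Na",
]

#: Year-level climate variable (identical for every subplot in a year).
PRECIPITATION = "precipitation"

#: Columns identifying a community record.
KEY_COLUMNS = ["plot", "subplot", "year", "x", "y"]

COMPETITOR_PREFIX = "comp_"
SPECIES_PREFIX = "sp_"


class SchemaError(ValueError):
    """A required column is missing or the schema itself is malformed."""


class ValidationError(ValueError):
    """Record-level violation: negative/non-integer counts, inconsistent soils."""


@dataclass(frozen=True)
class CommunitySchema:
    """Column layout of a community table: species codes + abiotic variables."""

    species: tuple[str, ...]
    soil_variables: tuple[str, ...] = tuple(SOIL_VARIABLES)

    def __post_init__(self):
        clash = (set(self.species) & set(self.soil_variables)
                 | set(self.species) & {PRECIPITATION}
                 | set(self.species) & set(KEY_COLUMNS))
        if clash:
            raise SchemaError(f"species codes collide with other columns: {sorted(clash)}")
        if len(set(self.species)) != len(self.species):
            raise SchemaError("duplicate species codes")

    @property
    def abiotic_variables(self) -> tuple[str, ...]:
        return self.soil_variables + (PRECIPITATION,)

    @property
    def columns(self) -> list[str]:
        return KEY_COLUMNS + list(self.abiotic_variables) + list(self.species)

    @classmethod
    def from_yaml(cls, path) -> "CommunitySchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            species=tuple(raw["species"]),
            soil_variables=tuple(raw.get("soil_variables", SOIL_VARIABLES)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"species": list(self.species),
                 "soil_variables": list(self.soil_variables)},
                fh, sort_keys=False)


def default_schema() -> CommunitySchema:
    """Schema shipped with the package: 23 annual-plant species codes."""
    ref = importlib.resources.files("commstack") / "schemas" / "grassland.yaml"
    with importlib.resources.as_file(ref) as path:
        return CommunitySchema.from_yaml(path)


@dataclass
class CommunityTable:
    """Validated wide table: one row per (plot, subplot, year) community."""

    data: pd.DataFrame
    schema: CommunitySchema

    def __post_init__(self) -> None:
        self.validate()

    # -- container conveniences -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> tuple[str, ...]:
        return self.schema.species

    @property
    def n_communities(self) -> int:
        return len(self.data)

    @property
    def years(self) -> list:
        return sorted(self.data["year"].unique())

    def abundance_matrix(self) -> np.ndarray:
        """(n_communities, n_species) integer counts, column order = schema order."""
        return self.data[list(self.schema.species)].to_numpy()

    def abiotic_records(self) -> pd.DataFrame:
        """Key columns + abiotic variables only (no abundances)."""
        cols = KEY_COLUMNS + list(self.schema.abiotic_variables)
        return self.data[cols].copy()

    def subset(self, mask) -> "CommunityTable":
        return CommunityTable(self.data.loc[mask].reset_index(drop=True),
                              self.schema)

    def equals(self, other: "CommunityTable") -> bool:
        if self.schema != other.schema:
            return False
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        if len(a) == 0:
            return True
        text = ["plot", "subplot"]
        if not a[text].equals(b[text]):
            return False
        num = [c for c in a.columns if c not in text]
        return bool(np.all(np.isclose(a[num].to_numpy(float),
                                      b[num].to_numpy(float))))

    # -- validation -------------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing = [c for c in self.schema.columns if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        df = df[self.schema.columns].copy()

        for sp in self.schema.species:
            col = pd.to_numeric(df[sp], errors="coerce")
            bad = col.isna() | (col < 0) | (col != np.round(col))
            if bad.any():
                loc = df.loc[bad, ["plot", "subplot", "year"]].iloc[0]
                raise ValidationError(
                    f"abundance of {sp} at plot={loc['plot']} "
                    f"subplot={loc['subplot']} year={loc['year']} is not a "
                    "non-negative integer")
            df[sp] = col.astype(np.int64)

        for col in self.schema.abiotic_variables:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"missing or non-numeric values in {col!r}")
            df[col] = vals.astype(float)

        if len(df):
            dup = df.duplicated(subset=["plot", "subplot", "year"])
            if dup.any():
                raise ValidationError("duplicate (plot, subplot, year) records")
            # soils and coordinates were measured once per subplot
            per_subplot = df.groupby(["plot", "subplot"], sort=False)
            static = list(self.schema.soil_variables) + ["x", "y"]
            n_unique = per_subplot[static].nunique()
            if (n_unique > 1).any().any():
                var = n_unique.columns[(n_unique > 1).any()][0]
                raise ValidationError(
                    f"{var!r} varies across years for at least one subplot")
            # precipitation is a year-level variable
            if (df.groupby("year")[PRECIPITATION].nunique() > 1).any():
                raise ValidationError(
                    "precipitation differs between subplots within a year")

        self.data = df.reset_index(drop=True)


def infer_schema(columns) -> CommunitySchema:
    """Derive a schema from a wide CSV header.

    Soil variables are recognised by their canonical names; every other
    non-key, non-precipitation column is taken to be a species code.
    """
    known = set(KEY_COLUMNS) | {PRECIPITATION} | set(SOIL_VARIABLES)
    soil = tuple(c for c in SOIL_VARIABLES if c in columns)
    species = tuple(c for c in columns if c not in known)
    if not species:
        raise SchemaError("no species abundance columns found in header")
    return CommunitySchema(species=species, soil_variables=soil)


def read_community_table(path, schema: CommunitySchema | None = None) -> CommunityTable:
    """Read a wide community CSV and validate it against ``schema``.

    With ``schema=None`` the schema is inferred from the header (canonical
    soil variable names; remaining columns are species codes).
    """
    df = pd.read_csv(path)
    schema = schema or infer_schema(df.columns)
    return CommunityTable(df, schema)


def write_community_table(table: CommunityTable, path) -> None:
    """Write the table as CSV; ``read_community_table`` round-trips it."""
    table.data.to_csv(path, index=False)


def long_to_wide(long_df: pd.DataFrame, schema: CommunitySchema) -> CommunityTable:
    """Convert a long-format table (one row per species observation) to wide.

    Expects columns: the key columns, the abiotic variables, ``species`` and
    ``abundance``. Species absent from a community are filled with zeros.
    """
    abiotic = list(schema.abiotic_variables)
    wide = (long_df.pivot_table(index=KEY_COLUMNS + abiotic, columns="species",
                                values="abundance", fill_value=0)
            .reset_index())
    wide.columns.name = None
    for sp in schema.species:
        if sp not in wide.columns:
            wide[sp] = 0
    return CommunityTable(wide, schema)


@dataclass
class ModelFrame:
    """Stacked cross-species design matrix.

    One row per (focal species, community); predictors are the retained
    abiotic features, optionally one competitor-abundance column per
    species (the focal's own column forced to 0), and a one-hot species
    identity factor. The target is the focal species' abundance.
    """

    X: pd.DataFrame
    y: pd.Series
    meta: pd.DataFrame          # plot, subplot, year, species (focal)
    abiotic_features: tuple[str, ...]
    species: tuple[str, ...]
    has_competitors: bool

    def __len__(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def competitor_columns(self) -> list[str]:
        return [c for c in self.X.columns if c.startswith(COMPETITOR_PREFIX)]


def _species_dummies(focal: pd.Series, species: tuple[str, ...]) -> pd.DataFrame:
    out = {}
    for sp in species:
        out[SPECIES_PREFIX + sp] = (focal == sp).astype(float).to_numpy()
    return pd.DataFrame(out, index=focal.index)


def build_model_frame(
    table: CommunityTable,
    features: list[str] | None = None,
    include_competitors: bool = True,
    competitor_values: pd.DataFrame | None = None,
) -> ModelFrame:
    """Stack the community table into the per-focal-species design matrix.

    Parameters
    ----------
    features
        Retained abiotic features; default = every abiotic variable.
    include_competitors
        If False, build the abiotic-only frame (no competitor columns).
    competitor_values
        Optional (n_communities, n_species) frame of abundances to bind as
        competitor columns instead of the observed counts — used by the
        two-step model to bind stage-1 predictions. Column order must match
        the schema's species order.

    Whatever the source of the competitor values, the column matching the
    focal species of a row is set to 0: the focal's own abundance is the
    target and may never leak into its features.
    """
    schema = table.schema
    features = list(features) if features is not None else list(schema.abiotic_variables)
    unknown = [f for f in features if f not in schema.abiotic_variables]
    if unknown:
        raise SchemaError(f"requested features not in table: {unknown}")
    if not schema.species:
        raise SchemaError("schema has no species")

    n_comm = len(table.data)
    n_sp = len(schema.species)
    if competitor_values is not None:
        comp_source = competitor_values[list(schema.species)].to_numpy(float)
        if comp_source.shape != (n_comm, n_sp):
            raise ValueError("competitor_values shape does not match table")
    else:
        comp_source = table.data[list(schema.species)].to_numpy(float)

    blocks_X, blocks_meta, targets = [], [], []
    base = table.data[features].reset_index(drop=True)
    keys = table.data[["plot", "subplot", "year"]].reset_index(drop=True)
    for i, focal in enumerate(schema.species):
        block = base.copy()
        if include_competitors:
            comp = comp_source.copy()
            comp[:, i] = 0.0          # zero-out rule
            for j, sp in enumerate(schema.species):
                block[COMPETITOR_PREFIX + sp] = comp[:, j]
        meta = keys.copy()
        meta["species"] = focal
        blocks_X.append(block)
        blocks_meta.append(meta)
        targets.append(table.data[focal].to_numpy(float))

    X = pd.concat(blocks_X, ignore_index=True)
    meta = pd.concat(blocks_meta, ignore_index=True)
    X = pd.concat([X, _species_dummies(meta["species"], schema.species)], axis=1)
    y = pd.Series(np.concatenate(targets) if targets else [], name="abundance",
                  dtype=float)
    return ModelFrame(X=X, y=y, meta=meta,
                      abiotic_features=tuple(features),
                      species=schema.species,
                      has_competitors=include_competitors)


def add_competitor_columns(frame: ModelFrame,
                           competitor_values: np.ndarray) -> ModelFrame:
    """Bind competitor-abundance columns into an abiotic-only stacked frame.

    ``competitor_values`` is (n_records, n_species) in the frame's species
    order — typically stage-1 predictions. The focal species' own column
    is zeroed block-wise, preserving the zero-out rule.
    """
    if frame.has_competitors:
        raise ValueError("frame already carries competitor columns")
    comp = np.asarray(competitor_values, float)
    n_sp = len(frame.species)
    n_rec = len(frame) // n_sp
    if comp.shape != (n_rec, n_sp):
        raise ValueError(f"competitor_values shape {comp.shape} != ({n_rec}, {n_sp})")
    blocks = []
    for i in range(n_sp):
        blk = comp.copy()
        blk[:, i] = 0.0
        blocks.append(blk)
    stacked = np.vstack(blocks)
    comp_df = pd.DataFrame(
        {COMPETITOR_PREFIX + sp: stacked[:, j]
         for j, sp in enumerate(frame.species)},
        index=frame.X.index)
    dummy_cols = [SPECIES_PREFIX + sp for sp in frame.species]
    abiotic_cols = [c for c in frame.X.columns if c not in dummy_cols]
    X = pd.concat([frame.X[abiotic_cols], comp_df, frame.X[dummy_cols]], axis=1)
    return ModelFrame(X=X, y=frame.y, meta=frame.meta,
                      abiotic_features=frame.abiotic_features,
                      species=frame.species, has_competitors=True)


def build_abiotic_frame(records: pd.DataFrame, features: list[str],
                        species: tuple[str, ...]) -> ModelFrame:
    """Stacked abiotic-only frame from key+abiotic records (no abundances).

    Used at prediction time, when only abiotic measurements exist. The
    returned frame has an all-NaN target.
    """
    missing = [f for f in features if f not in records.columns]
    if missing:
        raise SchemaError(f"records lack abiotic features: {missing}")
    blocks_X, blocks_meta = [], []
    base = records[list(features)].reset_index(drop=True)
    keys = records[["plot", "subplot", "year"]].reset_index(drop=True)
    for focal in species:
        meta = keys.copy()
        meta["species"] = focal
        blocks_X.append(base.copy())
        blocks_meta.append(meta)
    X = pd.concat(blocks_X, ignore_index=True)
    meta = pd.concat(blocks_meta, ignore_index=True)
    X = pd.concat([X, _species_dummies(meta["species"], species)], axis=1)
    y = pd.Series(np.nan, index=X.index, name="abundance", dtype=float)
    return ModelFrame(X=X, y=y, meta=meta, abiotic_features=tuple(features),
                      species=tuple(species), has_competitors=False)
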