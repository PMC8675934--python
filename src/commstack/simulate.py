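"""Synthetic community generator with stored ground truth.

Emulates a five-year survey of an annual-plant community on a soil
salinity gradient: 9 plots of 6x6 1 m^2 subplots, 23 species, soil
chemistry measured once per subplot, and year-level precipitation.
The generator is calibrated so that its default output reproduces the
aggregate statistics of such surveys: ~75% zero abundances, Taylor's-law
variance-mean scaling with exponent ~2.15, weak within-plot spatial
autocorrelation, and soil variables organised in correlated clusters.

Data-generating model, per species ``i`` and community ``s`` (subplot x
year):

1. *Niche*: a log-linear suitability in the standardised measured soil
   variables plus a Gaussian (quadratic) niche on salinity, saturated so
   stands plateau at a carrying density, and a species-specific
   log-linear precipitation (year) response give the interaction-free
   latent abundance ``K_is``.
2. *Competition*: a Beverton-Holt-style denominator suppresses the
   latent mean, ``N_is = K_is / (1 + sum_j alpha_ij K_js)`` with
   ``alpha_ij >= 0`` (diagonal included; dominant species are the
   stronger competitors).
3. *Hurdle + counts*: establishment succeeds only in a species'
   better-than-typical sites — occupancy is Bernoulli with a logit in
   the suitability relative to the species' own median — and occupied
   communities draw a negative-binomial count around ``N_is`` (with
   optional lognormal micro-site clumping). Structural zeros can be
   forced via ``hurdle.structural_zero_prob``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from .data import (PRECIPITATION, SOIL_VARIABLES, CommunitySchema,
                   CommunityTable, default_schema)
from .evaluation import per_species_morans_i


class ConfigError(ValueError):
    """Generator configuration is inconsistent."""


@dataclass(frozen=True)
class SoilCluster:
    """Soil variables sharing a latent factor with a target rank correlation."""
    members: tuple[str, ...]
    correlation: float = 0.9


@dataclass(frozen=True)
class HurdleParams:
    """Occupancy model: p = (1 - szp) * sigmoid(a_i + b * rel_suitability).

    ``rel_suitability`` is log latent abundance minus its per-species
    median. ``intercept`` may be a (rare, abundant) pair interpolated
    along the species' abundance rank: a declining intercept confines
    dominant species to their best sites, concentrating their populations
    and pushing Taylor's exponent above 2 while staying predictable from
    the measured soil variables.
    """
    intercept: tuple[float, float] | float = (0.6, -5.2)
    intercept_jitter: float = 0.8      # per-species uniform offset on a_i
    slope: float = 3.0
    structural_zero_prob: float = 0.0


#: Nominal measurement scales (mean, sd) for the emitted soil columns.
DEFAULT_SOIL_SCALES: dict[str, tuple[float, float]] = {
    "pH": (7.6, 0.45), "salinity": (2.2, 0.9), "carbonates": (11.0, 4.0),
    "organic_matter": (2.1, 0.7), "cn_ratio": (10.5, 2.0), "Cl": (310.0, 130.0),
    "C": (1.25, 0.45), "N": (0.13, 0.05), "P": (12.5, 4.5), "Ca": (950.0, 280.0),
    "Mg": (155.0, 48.0), "K": (82.0, 28.0), "Na": (260.0, 110.0),
}

DEFAULT_CLUSTERS = (
    SoilCluster(("salinity", "Na", "Cl", "K"), 0.9),
    SoilCluster(("C", "organic_matter", "N", "cn_ratio"), 0.9),
)

#: Soil variables the species actually respond to (standardised observed
#: values; the salinity niche is quadratic and handled separately). pH, Ca
#: and Mg are measured but have exactly zero effect on abundance — they
#: exist to exercise the below-noise feature-selection rule.
RESPONSE_VARIABLES = ("C", "carbonates", "P")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic survey."""

    n_plots: int = 9
    grid: tuple[int, int] = (6, 6)                  # subplots per plot (rows, cols)
    plot_spacing: float = 120.0                     # metres along the gradient
    years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019)
    precipitation: tuple[float, ...] = (530.0, 625.0, 445.0, 570.0, 384.0)
    n_species: int = 23

    # soil model
    soil_scales: dict = field(default_factory=lambda: dict(DEFAULT_SOIL_SCALES))
    clusters: tuple[SoilCluster, ...] = DEFAULT_CLUSTERS
    salinity_gradient: float = 1.15                 # plot-level trend on the salinity axis
    carbonates_gradient: float = 0.55
    subplot_noise: float = 0.85                     # iid within-plot latent noise (keeps Moran's I low)

    # species niche model; (rare, abundant) pairs are interpolated along each
    # species' abundance rank — dominant annual plants are the more
    # environmentally responsive, aggregated and weather-sensitive
    base_log_abundance: tuple[float, float] = (0.0, 6.0)   # U(range) of log K at neutral conditions
    response_scale: tuple[float, float] = (0.4, 1.3)       # sd of axis coefficients
    niche_width: tuple[float, float] = (0.3, 2.5)           # quadratic salinity penalty
    niche_optimum: tuple[float, float] = (-2.0, 2.0)        # optimum on the salinity axis
    niche_saturation: float = 2.2                           # cap on |log suitability| (density plateau)
    precipitation_effect: tuple[float, float] = (0.4, 2.0)  # |log-linear year effect|
    patchiness: tuple[float, float] = (0.0, 0.25)            # lognormal micro-site aggregation sd
    patchiness_jitter: float = 0.1                         # species-level scatter around the trend
    generalist_fraction: float = 0.25                       # evenly-spread, weakly-aggregated species

    # competition
    competition_density: float = 0.35               # fraction of non-zero alpha_ij
    competition_strength: float = 0.4               # mean of exp-distributed alpha (scaled)
    self_regulation: float = 0.1                    # guaranteed diagonal alpha (density capping)

    # noise model: NB size parameter k (var = mu + mu^2/k), interpolated per
    # species from rare (first) to abundant (second) — abundant annual plants
    # are the more spatially aggregated, which keeps Taylor's exponent above 2
    nb_dispersion: tuple[float, float] = (4.0, 1.5)
    hurdle: HurdleParams = field(default_factory=HurdleParams)

    seed: int = 0

    def __post_init__(self):
        if min(self.n_plots, self.n_species, *self.grid) <= 0:
            raise ConfigError("dimensions must be positive")
        if len(self.precipitation) != len(self.years):
            raise ConfigError("precipitation list length must equal number of years")
        known = set(self.soil_scales)
        for cl in self.clusters:
            unknown = set(cl.members) - known
            if unknown:
                raise ConfigError(f"cluster references unknown variable(s): {sorted(unknown)}")

    # -- YAML round trip --------------------------------------------------------
    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["clusters"] = [
            {"members": list(c.members), "correlation": c.correlation}
            for c in self.clusters]
        raw["hurdle"] = dataclasses.asdict(self.hurdle)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "soil_scales" in raw:
            raw["soil_scales"] = {k: tuple(v) for k, v in raw["soil_scales"].items()}
        if "clusters" in raw:
            raw["clusters"] = tuple(
                SoilCluster(tuple(c["members"]), c["correlation"])
                for c in raw["clusters"])
        if "hurdle" in raw:
            hp = dict(raw["hurdle"])
            if isinstance(hp.get("intercept"), list):
                hp["intercept"] = tuple(hp["intercept"])
            raw["hurdle"] = HurdleParams(**hp)
        for key in ("grid", "years", "precipitation", "base_log_abundance",
                    "response_scale", "niche_width", "niche_optimum",
                    "precipitation_effect", "patchiness", "nb_dispersion"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class Landscape:
    """Subplot positions, soil measurements and the latent axes behind them."""
    sites: pd.DataFrame     # plot, subplot, x, y + soil variable columns
    factors: pd.DataFrame   # latent axes per subplot: salinity_axis, fertility, ...


@dataclass
class GroundTruth:
    """Everything the generator actually used, for recovery tests."""
    latent_mean: np.ndarray          # (n_communities, n_species) E[X] incl. hurdle
    interaction_free: np.ndarray     # K before competitive suppression
    occupancy: np.ndarray            # per-entry occupancy probability
    base_log_abundance: np.ndarray   # per-species intercepts
    axis_coefficients: np.ndarray    # (n_species, len(RESPONSE_VARIABLES))
    niche_width: np.ndarray
    niche_optimum: np.ndarray
    precipitation_effect: np.ndarray
    competition: np.ndarray          # (n_species, n_species) alpha_ij >= 0
    species: tuple[str, ...]


@dataclass
class CalibrationReport:
    """Summary statistics checked against the survey the generator emulates."""
    zero_fraction: float
    taylor_slope: float
    taylor_adj_r2: float
    morans_i: dict[str, float]       # per species
    species_summary: pd.DataFrame    # mean, variance, zero fraction per species

    @property
    def max_morans_i(self) -> float:
        return max(self.morans_i.values())


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _species_codes(n: int) -> tuple[str, ...]:
    base = default_schema().species
    if n <= len(base):
        return tuple(base[:n])
    return tuple(base) + tuple(f"SP{i:02d}" for i in range(n - len(base)))


def generate_landscape(config: GeneratorConfig,
                       rng: np.random.Generator | None = None) -> Landscape:
    """Draw subplot coordinates, latent abiotic axes, and soil measurements.

    Soil values are constant across years by construction (they are drawn
    once per subplot). Cluster members load on a shared factor with loading
    sqrt(r), giving pairwise rank correlation ~= r between members.
    """
    rng = rng or np.random.default_rng(config.seed)
    nr, nc = config.grid
    n_sub = nr * nc
    rows = []
    for p in range(config.n_plots):
        x0 = p * config.plot_spacing
        for s in range(n_sub):
            i, j = divmod(s, nc)
            rows.append({"plot": f"P{p + 1}", "subplot": f"S{s + 1:02d}",
                         "x": x0 + j * 1.0 + 0.5, "y": i * 1.0 + 0.5})
    sites = pd.DataFrame(rows)
    n = len(sites)
    grad = np.repeat(np.linspace(-1.0, 1.0, config.n_plots), n_sub)

    # latent axes (one value per subplot)
    factors = pd.DataFrame({
        "salinity_axis": config.salinity_gradient * grad
                         + config.subplot_noise * rng.standard_normal(n),
        "fertility": 0.25 * grad + config.subplot_noise * rng.standard_normal(n),
        "carbonates_axis": config.carbonates_gradient * grad
                           + config.subplot_noise * rng.standard_normal(n),
        "p_axis": config.subplot_noise * rng.standard_normal(n),
    })

    cluster_of = {}
    factor_for_cluster = {"salinity": "salinity_axis", "C": "fertility"}
    for cl in config.clusters:
        # the factor is the axis behind the cluster's lead member, if any
        lead = next((m for m in cl.members if m in factor_for_cluster), None)
        fac = (factors[factor_for_cluster[lead]].to_numpy() if lead
               else rng.standard_normal(n))
        fac = (fac - fac.mean()) / fac.std()
        for m in cl.members:
            cluster_of[m] = (fac, cl.correlation)

    for var, (mean, sd) in config.soil_scales.items():
        if var in cluster_of:
            fac, r = cluster_of[var]
            lat = np.sqrt(r) * fac + np.sqrt(1 - r) * rng.standard_normal(n)
        elif var == "carbonates":
            lat = (np.sqrt(0.9) * factors["carbonates_axis"]
                   / factors["carbonates_axis"].std()
                   + np.sqrt(0.1) * rng.standard_normal(n))
        elif var == "P":
            lat = (np.sqrt(0.9) * factors["p_axis"] / factors["p_axis"].std()
                   + np.sqrt(0.1) * rng.standard_normal(n))
        else:
            lat = rng.standard_normal(n)    # pH, Ca, Mg: no effect on species
        sites[var] = mean + sd * np.asarray(lat)
    return Landscape(sites=sites, factors=factors)


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

@dataclass
class _SpeciesParams:
    base: np.ndarray
    coef: np.ndarray
    width: np.ndarray
    optimum: np.ndarray
    precip: np.ndarray
    alpha: np.ndarray
    dispersion: np.ndarray
    patchiness: np.ndarray
    rank: np.ndarray
    hurdle_offset: np.ndarray


def _interp(pair, t):
    lo, hi = float(pair[0]), float(pair[-1])
    return lo + (hi - lo) * t


def _draw_species_params(config: GeneratorConfig,
                         rng: np.random.Generator) -> _SpeciesParams:
    m = config.n_species
    lo, hi = config.base_log_abundance
    base = rng.uniform(lo, hi, m)
    t = (base - lo) / (hi - lo) if hi > lo else np.zeros(m)
    scale = _interp(config.response_scale, t)
    coef = scale[:, None] * rng.standard_normal((m, len(RESPONSE_VARIABLES)))
    width = _interp(config.niche_width, t)
    optimum = rng.uniform(*config.niche_optimum, m)
    precip = _interp(config.precipitation_effect, t) * rng.choice([-1.0, 1.0], m)
    mask = rng.random((m, m)) < config.competition_density
    alpha = mask * rng.exponential(config.competition_strength, (m, m))
    # dominant species are the strong competitors: their sharply structured
    # stands carve the realised niches of everything else
    alpha *= (0.3 + 2.0 * t)[None, :]
    alpha[np.diag_indices(m)] += config.self_regulation
    dispersion = _interp(config.nb_dispersion[::-1], t)
    patchiness = np.maximum(
        0.0, _interp(config.patchiness, t)
        + config.patchiness_jitter * rng.uniform(-1.0, 1.0, m))
    hurdle_offset = config.hurdle.intercept_jitter * rng.uniform(-1.0, 1.0, m)
    # generalists: broadly tolerant, evenly spread species with high occupancy
    # and near-Poisson counts; their low variance-at-mean puts them below the
    # Taylor trend, as the ubiquitous grasses of real surveys do
    n_gen = int(round(config.generalist_fraction * m))
    gen = np.zeros(m, bool)
    mid = np.where((t > 0.25) & (t < 0.8))[0]   # generalists are mid-common species
    if len(mid) == 0:
        mid = np.arange(m)
    gen[rng.choice(mid, min(n_gen, len(mid)), replace=False)] = True
    coef[gen] *= 0.25
    width[gen] *= 0.2
    precip[gen] *= 0.3
    patchiness[gen] = 0.0
    dispersion[gen] = 4.0
    hurdle_offset[gen] += 1.2
    # a couple of clumped specialists sit above the Taylor trend, balancing
    # the generalists below it
    rest = np.where(~gen & (t > 0.25) & (t < 0.8))[0]
    if len(rest):
        clump = rng.choice(rest, min(2, len(rest)), replace=False)
        patchiness[clump] = 1.3
        hurdle_offset[clump] -= 2.0
    return _SpeciesParams(base, coef, width, optimum, precip, alpha,
                          dispersion, patchiness, t, hurdle_offset)


def _standardized(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    return (col - col.mean()) / (sd if sd else 1.0)


def _latent_means(config: GeneratorConfig, landscape: Landscape,
                  params: _SpeciesParams):
    """K and N for every (community, species); communities = subplot x year.

    Species respond to the standardised *measured* soil values (so the
    abundance surface is, in principle, fully recoverable from the data
    a survey would record), with a quadratic niche on salinity.
    """
    axes = np.column_stack([
        _standardized(landscape.sites[v].to_numpy(float))
        for v in RESPONSE_VARIABLES])
    sal = _standardized(landscape.sites["salinity"].to_numpy(float))
    precip = np.asarray(config.precipitation, float)
    zp = (precip - precip.mean()) / (precip.std() if precip.std() else 1.0)

    env_site = (axes @ params.coef.T
                - params.width[None, :] * (sal[:, None] - params.optimum[None, :]) ** 2)
    if not np.all(np.isfinite(env_site)):
        bad = np.where(~np.isfinite(env_site))[1][0]
        raise ConfigError(f"non-finite latent mean for species index {bad}")
    # saturate the spatial log-suitability (stands plateau at a carrying
    # density instead of growing exponentially with favourability); the
    # year effect multiplies recruitment and is not capped
    cap = config.niche_saturation
    site_term = params.base[None, :] + cap * np.tanh(env_site / cap)
    blocks = [site_term + (zp[t] * params.precip)[None, :]
              for t in range(len(config.years))]
    K = np.exp(np.vstack(blocks))               # (n_sub * n_years, n_species)
    # scale alpha by mean interaction-free abundance so denominators are O(1)
    kbar = K.mean(axis=0)
    alpha_eff = params.alpha / (kbar[None, :] + 1e-9)
    N = K / (1.0 + K @ alpha_eff.T)
    return K, N


def generate_abundances(config: GeneratorConfig, landscape: Landscape,
                        rng: np.random.Generator | None = None,
                        params_rng: np.random.Generator | None = None,
                        ) -> tuple[CommunityTable, GroundTruth]:
    """Draw the hurdle-negative-binomial counts and assemble the table."""
    rng = rng or np.random.default_rng(config.seed + 1)
    params_rng = params_rng or np.random.default_rng(config.seed + 2)
    params = _draw_species_params(config, params_rng)
    K, N = _latent_means(config, landscape, params)

    h = config.hurdle
    h0 = _interp(np.atleast_1d(np.asarray(h.intercept, float)),
                 params.rank) + params.hurdle_offset
    # establishment succeeds only in a species' better-than-typical sites:
    # the occupancy logit is driven by suitability relative to the species'
    # own median, so dominants form dense stands in their best subplots
    logN = np.log(np.maximum(N, 1e-12))
    rel = logN - np.median(logN, axis=0, keepdims=True)
    p_occ = (1.0 - h.structural_zero_prob) * expit(h0[None, :] + h.slope * rel)
    # lognormal micro-site aggregation (clumped recruitment), mean-corrected
    sig = params.patchiness[None, :]
    mu = N * np.exp(sig * rng.standard_normal(N.shape) - 0.5 * sig ** 2)

    k = params.dispersion[None, :]
    occupied = rng.random(p_occ.shape) < p_occ
    counts = rng.negative_binomial(k, k / (k + mu))
    counts = np.where(occupied, counts, 0).astype(np.int64)

    species = _species_codes(config.n_species)
    soil_cols = [c for c in SOIL_VARIABLES if c in landscape.sites.columns]
    blocks = []
    for t, year in enumerate(config.years):
        block = landscape.sites[["plot", "subplot", "x", "y"] + soil_cols].copy()
        block["year"] = year
        block[PRECIPITATION] = config.precipitation[t]
        n_sub = len(landscape.sites)
        for j, sp in enumerate(species):
            block[sp] = counts[t * n_sub:(t + 1) * n_sub, j]
        blocks.append(block)
    df = pd.concat(blocks, ignore_index=True)

    schema = CommunitySchema(species=species, soil_variables=tuple(soil_cols))
    table = CommunityTable(df, schema)
    truth = GroundTruth(
        latent_mean=p_occ * N, interaction_free=K, occupancy=p_occ,
        base_log_abundance=params.base, axis_coefficients=params.coef,
        niche_width=params.width, niche_optimum=params.optimum,
        precipitation_effect=params.precip, competition=params.alpha,
        species=species)
    return table, truth


def generate_dataset(config: GeneratorConfig | None = None, seed: int | None = None,
                     ) -> tuple[CommunityTable, GroundTruth]:
    """Landscape + abundances in one call; bit-identical under fixed seed."""
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else int(seed)
    ss = np.random.SeedSequence(seed)
    r_land, r_counts, r_params = (np.random.default_rng(s) for s in ss.spawn(3))
    landscape = generate_landscape(config, r_land)
    return generate_abundances(config, landscape, r_counts, r_params)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def taylor_fit(table: CommunityTable) -> tuple[float, float, pd.DataFrame]:
    """OLS of log10(variance) on log10(mean) across species.

    Returns (slope, adjusted R^2, per-species summary). Species with zero
    mean or zero variance cannot enter the log-log fit and are excluded.
    """
    counts = table.abundance_matrix()
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    summary = pd.DataFrame({"species": table.species, "mean": mean,
                            "variance": var,
                            "zero_fraction": (counts == 0).mean(axis=0)})
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 2:
        raise ValueError("degenerate abundance distribution: "
                         "fewer than 2 species with positive mean and variance")
    res = stats.linregress(np.log10(mean[ok]), np.log10(var[ok]))
    n = int(ok.sum())
    adj_r2 = 1.0 - (1.0 - res.rvalue ** 2) * (n - 1) / (n - 2)
    return float(res.slope), float(adj_r2), summary


def calibration_report(table: CommunityTable) -> CalibrationReport:
    """Zero fraction, Taylor's-law fit and per-species Moran's I."""
    counts = table.abundance_matrix()
    if counts.size == 0 or (counts == 0).all():
        raise ValueError("degenerate abundance distribution: all zeros")
    slope, adj_r2, summary = taylor_fit(table)
    morans = per_species_morans_i(table)
    return CalibrationReport(
        zero_fraction=float((counts == 0).mean()),
        taylor_slope=slope, taylor_adj_r2=adj_r2,
        morans_i=morans, species_summary=summary)
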