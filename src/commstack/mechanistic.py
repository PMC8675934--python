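"""Covariate-modulated annual-plant competition model (Beverton-Holt form).

The phenomenological backbone is the classic annual-plant map: expected
output of species ``i`` scales as its intrinsic fecundity divided by one
plus a weighted sum of competitor densities,

    E[X_i] = lambda_i(E) * X_i / (1 + sum_j alpha_ij(E) * X_j),

with an abiotic covariate ``E`` (e.g. soil carbonates) allowed to
modulate both fecundity (log-linearly, lambda_i(E) = lambda_i *
exp(beta_i * E)) and the pairwise interactions (additively,
alpha_ij(E) = max(0, alpha_ij + gamma_ij * E); interactions are clipped
at zero rather than soft-plussed, and this choice is part of the model
definition).

Fitting is a within-season snapshot: the focal abundance is regressed on
co-occurring competitor abundances and the covariate,

    X_i ~ lambda_i(E) / (1 + sum_{j != i} alpha_ij(E) * X_j),

by penalised least squares on log1p abundances with a ridge penalty on
the interaction terms, one focal species at a time. Germination and
seed-survival fractions are not modelled (they are not observable in a
single-season census).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import CommunityTable


@dataclass
class AnnualPlantParams:
    """Per-species fecundities, pairwise interactions, covariate effects."""
    species: tuple[str, ...]
    lambda_: np.ndarray                  # (m,) intrinsic fecundities > 0
    alpha: np.ndarray                    # (m, m) interaction coefficients >= 0
    beta: np.ndarray | None = None       # (m,) log-lambda covariate slopes
    gamma: np.ndarray | None = None      # (m, m) alpha covariate slopes
    covariate: str | None = None
    covariate_center: float = 0.0        # covariate is centred before use

    def __post_init__(self):
        m = len(self.species)
        self.lambda_ = np.asarray(self.lambda_, float)
        self.alpha = np.asarray(self.alpha, float)
        if self.beta is None:
            self.beta = np.zeros(m)
        if self.gamma is None:
            self.gamma = np.zeros((m, m))
        self.beta = np.asarray(self.beta, float)
        self.gamma = np.asarray(self.gamma, float)
        if np.any(self.lambda_ <= 0):
            raise ValueError("lambda_ must be positive")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be non-negative")

    def fecundity(self, covariate_values) -> np.ndarray:
        e = np.atleast_1d(np.asarray(covariate_values, float)) - self.covariate_center
        return self.lambda_[None, :] * np.exp(np.outer(e, self.beta))

    def interactions(self, covariate_value: float) -> np.ndarray:
        e = float(covariate_value) - self.covariate_center
        return np.maximum(0.0, self.alpha + self.gamma * e)


def predict_mechanistic(params: AnnualPlantParams, abundances,
                        covariate_values=0.0) -> np.ndarray:
    """Expected next-generation abundances from current counts.

    ``abundances`` is (n_sites, m); ``covariate_values`` is scalar or
    (n_sites,). Returns (n_sites, m) expectations of the annual-plant map.
    """
    X = np.atleast_2d(np.asarray(abundances, float))
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    e = np.broadcast_to(np.asarray(covariate_values, float), (X.shape[0],))
    lam = params.fecundity(e)
    out = np.empty_like(X)
    for s in range(X.shape[0]):
        a = params.interactions(e[s])
        out[s] = lam[s] * X[s] / (1.0 + a @ X[s])
    return out


def snapshot_expectation(params: AnnualPlantParams, abundances,
                         covariate_values=0.0) -> np.ndarray:
    """Within-season expectation: focal ~ fecundity / (1 + competitor load).

    The focal species' own abundance is excluded from its competitor sum
    (it is the response, not a predictor).
    """
    X = np.atleast_2d(np.asarray(abundances, float))
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    e = np.broadcast_to(np.asarray(covariate_values, float), (X.shape[0],))
    lam = params.fecundity(e)
    out = np.empty_like(X)
    for s in range(X.shape[0]):
        a = params.interactions(e[s]).copy()
        np.fill_diagonal(a, 0.0)
        out[s] = lam[s] / (1.0 + a @ X[s])
    return out


def simulate_equilibrium(params: AnnualPlantParams, covariate_values,
                         max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Self-consistent snapshot communities by damped fixed-point iteration.

    Solves X_i = lambda_i(E) / (1 + sum_{j != i} alpha_ij(E) X_j) at each
    site. Used to manufacture noise-free test communities with known
    parameters.
    """
    e = np.atleast_1d(np.asarray(covariate_values, float))
    m = len(params.species)
    X = np.ones((e.size, m))
    for _ in range(max_iter):
        target = snapshot_expectation(params, X, e)
        new = 0.5 * X + 0.5 * target
        if np.max(np.abs(new - X)) < tol:
            return new
        X = new
    return X


@dataclass
class MechanisticFit:
    params: AnnualPlantParams
    train_rmse: float
    holdout_rmse: float


def _fit_focal(i, X, e, with_cov, ridge):
    """Penalised least squares on log1p abundances for one focal species."""
    n, m = X.shape
    comp = np.delete(X, i, axis=1)            # (n, m-1) competitor abundances
    y = np.log1p(X[:, i])
    k = m - 1

    def unpack(theta):
        loglam, rest = theta[0], theta[1:]
        if with_cov:
            beta, alpha, gamma = rest[0], rest[1:1 + k], rest[1 + k:]
        else:
            beta, alpha, gamma = 0.0, rest, np.zeros(k)
        return loglam, beta, alpha, gamma

    def residuals(theta):
        loglam, beta, alpha, gamma = unpack(theta)
        a_eff = np.maximum(0.0, alpha[None, :] + np.outer(e, gamma))
        pred = np.exp(loglam + beta * e) / (1.0 + (a_eff * comp).sum(axis=1))
        res = np.log1p(pred) - y
        pen = np.sqrt(ridge) * np.concatenate([alpha, gamma]) if with_cov \
            else np.sqrt(ridge) * alpha
        return np.concatenate([res, pen])

    x0 = np.concatenate([[np.log(X[:, i].mean() + 1.0)],
                         [0.0] if with_cov else [],
                         np.full(k, 1e-3),
                         np.zeros(k) if with_cov else []])
    lo = np.concatenate([[-10.0], [-5.0] if with_cov else [],
                         np.zeros(k),
                         np.full(k, -np.inf) if with_cov else []])
    hi = np.concatenate([[20.0], [5.0] if with_cov else [],
                         np.full(k, np.inf),
                         np.full(k, np.inf) if with_cov else []])
    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        max_nfev=8000)
    if not sol.success and sol.status <= 0:
        raise RuntimeError(f"mechanistic fit did not converge for focal {i}: "
                           f"{sol.message}")
    return unpack(sol.x)


def fit_mechanistic(table: CommunityTable, covariate: str | None = None,
                    ridge: float = 0.1, test_fraction: float = 0.2,
                    seed: int = 0, focals=None) -> MechanisticFit:
    """Estimate annual-plant parameters from a community table.

    With ``covariate=None`` the biotic-only model is fitted (beta and
    gamma fixed at 0). ``focals`` optionally restricts the fit to a
    subset of focal species (their parameter rows; other rows keep
    lambda = 1, alpha = 0). The reported errors are natural-scale RMSEs
    of the snapshot expectation over the fitted focals, on the training
    and held-out communities.
    """
    species = table.species
    if len(species) < 1:
        raise ValueError("table has no species")
    X = table.abundance_matrix().astype(float)
    if covariate is not None:
        if covariate not in table.schema.abiotic_variables:
            raise ValueError(f"covariate {covariate!r} not in table")
        e_raw = table.data[covariate].to_numpy(float)
        center = float(e_raw.mean())
        scale = float(e_raw.std()) or 1.0
        e = (e_raw - center) / scale
    else:
        e = np.zeros(len(X))
        center, scale = 0.0, 1.0

    rng = np.random.default_rng(seed)
    n = len(X)
    n_test = max(1, int(round(n * test_fraction)))
    perm = rng.permutation(n)
    test, train = perm[:n_test], perm[n_test:]

    m = len(species)
    focal_idx = (list(range(m)) if focals is None
                 else [species.index(f) for f in focals])
    lam = np.ones(m)
    beta = np.zeros(m)
    alpha = np.zeros((m, m))
    gamma = np.zeros((m, m))
    with_cov = covariate is not None
    for i in focal_idx:
        loglam, b, a, g = _fit_focal(i, X[train], e[train], with_cov, ridge)
        lam[i] = np.exp(loglam)
        beta[i] = b
        idx = [j for j in range(m) if j != i]
        alpha[i, idx] = a
        gamma[i, idx] = g

    # fold the internal standardisation back into the covariate slopes
    params = AnnualPlantParams(species=species, lambda_=lam, alpha=alpha,
                               beta=beta / scale, gamma=gamma / scale,
                               covariate=covariate, covariate_center=center)

    def rmse_on(idx):
        e_nat = table.data[covariate].to_numpy(float)[idx] if with_cov \
            else np.zeros(len(idx))
        pred = snapshot_expectation(params, X[idx], e_nat)
        diff = (X[idx] - pred)[:, focal_idx]
        return float(np.sqrt(np.mean(diff ** 2)))

    return MechanisticFit(params=params, train_rmse=rmse_on(train),
                          holdout_rmse=rmse_on(test))
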