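"""Synthetic covariate fields and coupled-species observations.

Stands in for the study's survey and ocean-model products: smooth spatially
autocorrelated biophysical fields in two climate scenarios, and two coupled
species surfaces generated from the joint BYM model itself — shared smooth
covariate effects, a shared intrinsic-CAR spatial trend with per-species
scaling, iid heterogeneity, gamma-distributed positive densities, and
optional hurdle (excess-zero) structure — so every downstream stage has a
known ground truth.

Covariate fields are sampled from a scaled ICAR-plus-nugget precision on the
lattice (reusing the adjacency machinery); ``range_cells`` controls the
nugget weight and hence the correlation range.  Requested cross-field
correlations are imposed exactly by empirical whitening and re-colouring.
All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.special import expit

from .gmrf import icar_structure, sample_gmrf
from .grid import LatticeGrid, SpeciesSurface, build_adjacency

__all__ = [
    "CovariateField",
    "SimulationTruth",
    "simulate_covariates",
    "shift_scenario",
    "simulate_joint_species",
    "bump_field",
    "smooth_spatial_field",
    "icar_field",
    "default_truth",
]

COVARIATE_NAMES = ("BT", "CHL", "NPP", "PEA", "SP")


@dataclass(frozen=True)
class CovariateField:
    """One biophysical field on the active cells of a grid."""

    name: str
    season: str
    scenario: str
    grid: LatticeGrid
    values: np.ndarray
    standardization: tuple[float, float] | None = None  # (mean, sd) removed

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_active,):
            raise ValueError("covariate values must match the active cells")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in covariate {self.name}")
        object.__setattr__(self, "values", v)


@dataclass
class SimulationTruth:
    """Generative parameters behind one synthetic species pair."""

    intercepts: dict                       # species -> alpha_s
    smooths: Mapping[str, Callable]        # covariate -> f_k (centered at gen time)
    z: np.ndarray                          # shared spatial trend, sums to zero
    delta: dict                            # species -> scaling of z
    het_sd: float                          # iid heterogeneity sd
    shapes: dict                           # species -> gamma shape a_s
    occupancy_intercepts: dict = field(default_factory=dict)  # hurdle species
    occupancy_prob: dict = field(default_factory=dict)        # filled by simulator
    linear_predictor: dict = field(default_factory=dict)      # filled by simulator
    z_residualized: bool = False   # set once z is orthogonalised to the smooths
    seed: int = 0


def _grf_precision(grid: LatticeGrid, range_cells: float) -> sp.csc_matrix:
    adj = build_adjacency(grid, "queen")
    r = icar_structure(adj)
    kappa = 2.0 / float(range_cells) ** 2
    return (r + kappa * sp.eye(r.shape[0])).tocsc()


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def simulate_covariates(grid: LatticeGrid, names: Sequence[str],
                        correlation: np.ndarray | None = None,
                        range_cells: float = 8.0, seed: int = 0,
                        season: str = "summer") -> list[CovariateField]:
    """Smooth standardized Gaussian random fields with exact cross-correlations.

    Each field is sampled from an ICAR+nugget precision, standardized to mean
    0 / sd 1 over active cells.  When ``correlation`` (a positive-semidefinite
    matrix over the requested names) is given, the fields are whitened and
    re-coloured so their sample correlation matrix equals it.
    """
    if range_cells < 1:
        raise ValueError("range_cells must be >= 1")
    m = len(names)
    rng = np.random.default_rng(seed)
    q = _grf_precision(grid, range_cells)
    x = sample_gmrf(q, m, rng).T          # (n, m)
    x = np.column_stack([_standardize(x[:, j]) for j in range(m)])
    if correlation is not None and m > 1:
        corr = np.asarray(correlation, float)
        if corr.shape != (m, m):
            raise ValueError("correlation matrix shape must match names")
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-10:
            raise ValueError("requested correlation matrix is not positive semidefinite")
        # empirical whitening, then colouring with the target Cholesky factor
        xc = x - x.mean(axis=0)
        s = xc.T @ xc / xc.shape[0]
        x = xc @ np.linalg.inv(sla.cholesky(s, lower=True)).T
        x = x @ sla.cholesky(corr + 1e-12 * np.eye(m), lower=True).T
        x = np.column_stack([_standardize(x[:, j]) for j in range(m)])
    return [
        CovariateField(name=nm, season=season, scenario="present", grid=grid,
                       values=x[:, j], standardization=(0.0, 1.0))
        for j, nm in enumerate(names)
    ]


def shift_scenario(fld: CovariateField, mean_shift: float = 0.0,
                   pattern_shift_fraction: float = 0.0, seed: int = 0,
                   range_cells: float = 8.0) -> CovariateField:
    """Future-scenario version of a covariate field.

    The future field adds a uniform ``mean_shift`` and mixes in an independent
    smooth field with weight ``pattern_shift_fraction``, rescaled so the
    marginal sd matches the present field; with fraction ``w`` the
    present/future correlation is ``1 / sqrt(1 + w^2)``.
    """
    w = float(pattern_shift_fraction)
    if not 0.0 <= w <= 1.0:
        raise ValueError("pattern_shift_fraction must lie in [0, 1]")
    present = fld.values
    if w == 0.0:
        future = present + mean_shift
    else:
        rng = np.random.default_rng(seed)
        g = sample_gmrf(_grf_precision(fld.grid, range_cells), 1, rng)[0]
        pc = present - present.mean()
        # orthogonalise the innovation against the present anomaly
        g = g - g.mean()
        g = g - (g @ pc) / (pc @ pc) * pc
        g = g / g.std() * pc.std()
        future = present.mean() + mean_shift + (pc + w * g) / np.sqrt(1.0 + w * w)
    return CovariateField(name=fld.name, season=fld.season, scenario="future",
                          grid=fld.grid, values=future,
                          standardization=fld.standardization)


def _residualize_trend(z: np.ndarray, cov_values: Mapping[str, np.ndarray],
                       n_bins: int = 25) -> np.ndarray:
    """Project z onto the orthogonal complement of the binned covariate
    smooths (plus the constant), rescaling to the original sd."""
    if not cov_values:
        return z - z.mean()
    cols = [np.ones((z.size, 1))]
    for v in cov_values.values():
        v = np.asarray(v, float)
        edges = np.linspace(v.min(), v.max(), n_bins + 1)
        idx = np.clip(((v - edges[0]) / (edges[-1] - edges[0]) * n_bins)
                      .astype(int), 0, n_bins - 1)
        b = np.zeros((z.size, n_bins))
        b[np.arange(z.size), idx] = 1.0
        cols.append(b)
    x = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(x, z, rcond=None)
    resid = z - x @ beta
    resid = resid - resid.mean()
    s = resid.std()
    if s > 0 and z.std() > 0:
        resid = resid / s * z.std()
    return resid


def bump_field(grid: LatticeGrid, center_rowcol=None, width_cells: float = 5.0,
               height: float = 1.0) -> np.ndarray:
    """Centered (sum-to-zero) Gaussian bump over the active cells."""
    ids = grid.active_ids
    rows, cols = grid.rowcol(ids)
    if center_rowcol is None:
        center_rowcol = (grid.n_rows / 3.0, grid.n_cols / 3.0)
    d2 = (rows - center_rowcol[0]) ** 2 + (cols - center_rowcol[1]) ** 2
    z = height * np.exp(-0.5 * d2 / width_cells**2)
    return z - z.mean()


def smooth_spatial_field(grid: LatticeGrid, range_cells: float = 6.0,
                         sd: float = 0.5, seed: int = 0) -> np.ndarray:
    """Centered smooth random field scaled to a target marginal sd."""
    rng = np.random.default_rng(seed)
    z = sample_gmrf(_grf_precision(grid, range_cells), 1, rng)[0]
    z = z - z.mean()
    s = z.std()
    if s > 0:
        z = z / s * sd
    return z


def icar_field(grid: LatticeGrid, sd: float = 0.6, seed: int = 0,
               contiguity: str = "queen") -> np.ndarray:
    """Sum-to-zero intrinsic-CAR draw scaled to a target marginal sd.

    This is a draw from the fitted model's own spatial prior (up to scale),
    the self-consistent choice for parameter-recovery simulations.
    """
    rng = np.random.default_rng(seed)
    adj = build_adjacency(grid, contiguity)
    r = icar_structure(adj)
    q = (r + 1e-6 * sp.eye(r.shape[0])).tocsc()
    z = sample_gmrf(q, 1, rng)[0]
    z = z - z.mean()
    s = z.std()
    if s > 0:
        z = z / s * sd
    return z


def default_truth(grid: LatticeGrid, covariate_names=("PEA", "NPP"),
                  species=("predator", "prey"), hurdle_species=("prey",),
                  z: np.ndarray | None = None, z_sd: float = 0.6,
                  delta_2: float = 1.0, het_sd: float = 0.05,
                  seed: int = 0) -> SimulationTruth:
    """Canonical study conditions for the synthetic pair.

    The predator follows a gamma likelihood; the prey has sandeel-like excess
    zeros (hurdle).  The stratification proxy (PEA) acts negatively — the
    dominant relationship in shelf-sea habitat models — and primary production
    (NPP) has an interior optimum.  Unused names get a zero effect.
    """
    # log-scale effect sizes chosen so densities span a realistic range
    # (roughly one decade across the covariate field, not thousands-fold)
    effects: dict[str, Callable] = {
        "PEA": lambda x: -0.6 * x,
        "NPP": lambda x: 0.25 - 0.35 * (x - 0.1) ** 2,
        "CHL": lambda x: 0.4 * x,
        "BT": lambda x: -0.3 * x,
        "SP": lambda x: np.zeros_like(x),
    }
    smooths = {k: effects.get(k, lambda x: np.zeros_like(x)) for k in covariate_names}
    if z is None:
        z = icar_field(grid, sd=z_sd, seed=seed + 101)
    s1, s2 = species
    return SimulationTruth(
        intercepts={s1: 1.0, s2: 0.5},
        smooths=smooths,
        z=np.asarray(z, float),
        delta={s1: 1.0, s2: float(delta_2)},
        het_sd=float(het_sd),
        shapes={s1: 3.0, s2: 2.0},
        occupancy_intercepts={s: 1.0 for s in hurdle_species},
        seed=seed,
    )


def simulate_joint_species(grid: LatticeGrid,
                           covariates: Mapping[str, CovariateField],
                           truth: SimulationTruth,
                           hurdle_flags: Mapping[str, bool] | None = None,
                           seed: int | None = None) -> dict[str, SpeciesSurface]:
    """Draw the coupled species surfaces from the joint generative model.

    For each species ``s`` and cell ``i``: ``eta = alpha_s + sum_k f_k(x_ki)
    + delta_s z_i + v_si`` with ``v_si ~ N(0, het_sd^2)``; positive densities
    are Gamma(shape ``a_s``, mean ``exp(eta)``); hurdle species multiply by a
    Bernoulli occupancy draw whose logit shares the covariate smooths and the
    scaled trend but has its own intercept.  Smooth effects are centered over
    active cells so the intercepts keep their meaning.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = grid.n_active
    z = np.asarray(truth.z, float)
    if z.shape != (n,):
        raise ValueError("truth.z does not conform to the grid's active cells")
    if abs(z.sum()) > 1e-8 * max(1.0, np.abs(z).max()) * n:
        raise ValueError("truth.z must sum to zero over active cells")
    # The shared trend is *residual* spatial autocorrelation by definition:
    # orthogonalise the generative field against the span of the binned
    # covariate smooths (very smooth lattice fields can otherwise be almost
    # exactly a function of equally smooth covariate fields, making the
    # trend-vs-covariate split in the truth ill-defined).  Done once per
    # truth object so repeated simulation is bit-deterministic.
    if not truth.z_residualized:
        z = _residualize_trend(z, {k: covariates[k].values for k in truth.smooths},
                               n_bins=25)
        truth.z = z
        truth.z_residualized = True
    else:
        z = truth.z
    species = list(truth.intercepts)
    if hurdle_flags is None:
        hurdle_flags = {s: s in truth.occupancy_intercepts for s in species}
    for k in truth.smooths:
        if k not in covariates:
            raise ValueError(f"truth smooth {k!r} has no covariate field")

    # centered covariate contributions, shared across the pair
    contrib = np.zeros(n)
    for k, f in truth.smooths.items():
        fx = np.asarray(f(covariates[k].values), float)
        contrib = contrib + (fx - fx.mean())

    out: dict[str, SpeciesSurface] = {}
    truth.occupancy_prob = {}
    truth.linear_predictor = {}
    for s in species:
        v = rng.normal(0.0, truth.het_sd, size=n) if truth.het_sd > 0 else np.zeros(n)
        eta = truth.intercepts[s] + contrib + truth.delta[s] * z + v
        truth.linear_predictor[s] = eta
        a = float(truth.shapes[s])
        positive = rng.gamma(shape=a, scale=np.exp(eta) / a, size=n)
        if hurdle_flags.get(s, False):
            if s not in truth.occupancy_intercepts:
                raise ValueError(f"hurdle flag set for {s} but no occupancy "
                                 "intercept in the truth")
            zeta = truth.occupancy_intercepts[s] + contrib + truth.delta[s] * z
            pi = expit(zeta)
            truth.occupancy_prob[s] = pi
            occ = rng.random(n) < pi
            values = np.where(occ, positive, 0.0)
            family = "hurdle-gamma"
        else:
            values = positive
            family = "gamma"
        out[s] = SpeciesSurface(grid=grid, values=values, family=family,
                                scenario="present", name=s)
    return out
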