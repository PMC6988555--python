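"""Empirical-Bayes Laplace backend for single and joint BYM hurdle/gamma models.

Model, for species ``s`` at active cell ``i``::

    eta_si = alpha_s + sum_k f_k(x_ki) + delta_s * z_i + v_si

with ``f_k`` binned random-walk (RW1/RW2) smooths shared across the coupled
species, ``z`` a shared intrinsic-CAR spatial field (sum-to-zero; the "common
spatial trend"), ``delta_1 = 1`` and ``delta_2`` free, and ``v_s`` iid
heterogeneity.  Positive densities are Gamma with mean ``exp(eta)`` and shape
``a_s``; hurdle species add a Bernoulli occupancy part on a logit predictor
``zeta_si = alpha^o_s + sum_k f_k(x_ki) + delta_s z_i`` sharing the smooths
and spatial trend.  A Gaussian identity-link family is also supported (used
by exactness oracles).

Inference: conditional on hyperparameters the model is latent-Gaussian; the
latent posterior is approximated by a Gaussian at its mode (Newton iterations
on the sparse precision, linear constraints imposed by conditioning), and
hyperparameters are estimated by maximising the Laplace approximation to
their marginal posterior.  Hyperparameter uncertainty is summarised by a
finite-difference Hessian at the mode.  With a Gaussian likelihood the
approximation is exact.  All Monte-Carlo summaries (DIC's expected deviance,
predictive densities) use seeded draws from the Gaussian approximation, so
fits are deterministic given their configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.optimize as sopt
import scipy.sparse as sp
from scipy.special import expit, gammaln

from .gmrf import ConstrainedGaussian, SPDFactor, icar_structure, rw_structure
from .grid import Adjacency, LatticeGrid, SpeciesSurface, build_adjacency
from .model import BYMField, JointFit, ModelSpec, PosteriorSurface, SmoothEffect

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054

__all__ = ["InferenceConfig", "fit", "dic", "extract_common_trend", "predict_missing"]


@dataclass(frozen=True)
class InferenceConfig:
    """Budget, priors and numerical knobs for one fit."""

    seed: int = 0
    contiguity: str = "queen"
    n_bins: int = 25
    max_opt_evals: int = 150
    newton_max_iter: int = 50
    newton_tol: float = 1e-8
    n_samples: int = 300
    estimate_hyperparameter_uncertainty: bool = True
    skew_correction: bool = True
    fixed_hyperparameters: Mapping[str, float] = field(default_factory=dict)
    tie_smooth_precisions: bool = True
    tie_heterogeneity_precisions: bool = True
    intercept_precision: float = 1e-6
    jitter: float = 1e-6
    # Gamma(shape, rate) prior on each precision (historical INLA default)
    precision_prior_shape: float = 1.0
    precision_prior_rate: float = 5e-5
    log_shape_prior_sd: float = 10.0
    delta_prior_sd: float = 10.0


# ---------------------------------------------------------------------------
# likelihoods: log-density, d/deta, and negative second derivative (weight)
# ---------------------------------------------------------------------------

def _gamma_ll(y, eta, a):
    em = np.exp(np.clip(-eta, -60.0, 60.0))
    ll = a * np.log(a) - gammaln(a) + (a - 1.0) * np.log(y) - a * eta - a * y * em
    return ll, a * (y * em - 1.0), a * y * em


def _bernoulli_ll(y, eta, _):
    p = expit(eta)
    ll = y * eta - np.logaddexp(0.0, eta)
    return ll, y - p, np.maximum(p * (1.0 - p), 1e-12)


def _gaussian_ll(y, eta, tau):
    r = y - eta
    ll = 0.5 * np.log(tau / (2.0 * np.pi)) - 0.5 * tau * r * r
    return ll, tau * r, np.full_like(eta, tau)


_FAMLL = {"gamma": _gamma_ll, "bernoulli": _bernoulli_ll, "gaussian": _gaussian_ll}


# ---------------------------------------------------------------------------
# latent layout and design assembly
# ---------------------------------------------------------------------------

class _Layout:
    """Index bookkeeping for the latent vector."""

    def __init__(self):
        self.slices: dict[str, slice] = {}
        self.dim = 0

    def add(self, name: str, size: int) -> slice:
        s = slice(self.dim, self.dim + size)
        self.slices[name] = s
        self.dim += size
        return s

    def idx(self, name: str) -> np.ndarray:
        s = self.slices[name]
        return np.arange(s.start, s.stop)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, int]:
    """Equal-width bin index with boundary clamping; returns (idx, n_clamped)."""
    nb = edges.size - 1
    width = edges[-1] - edges[0]
    raw = np.floor((values - edges[0]) / width * nb).astype(int)
    clamped = int(np.sum((raw < 0) | (raw > nb - 1)))
    # values exactly at the max edge belong to the last bin, not "clamped"
    clamped -= int(np.sum(values == edges[-1]))
    return np.clip(raw, 0, nb - 1), max(clamped, 0)


class _Group:
    """One observation group: a likelihood family over one linear predictor."""

    def __init__(self, kind: str, species: str, y: np.ndarray,
                 a_fixed: sp.csr_matrix, a_z: sp.csr_matrix | None):
        self.kind = kind
        self.species = species
        self.y = y
        self.a_fixed = a_fixed
        self.a_z = a_z   # unit entries into the z block, scaled by delta_s
        self._cache: tuple[float, sp.csr_matrix] | None = None

    def design(self, delta: float) -> sp.csr_matrix:
        if self.a_z is None:
            return self.a_fixed
        if self._cache is None or self._cache[0] != delta:
            self._cache = (delta, (self.a_fixed + delta * self.a_z).tocsr())
        return self._cache[1]


class _ModelData:
    """Everything assembled once per fit: layout, designs, constraints."""

    def __init__(self, spec: ModelSpec, surfaces: Mapping[str, SpeciesSurface],
                 covariates: Mapping[str, np.ndarray], grid: LatticeGrid,
                 adjacency: Adjacency | None, config: InferenceConfig):
        self.spec = spec
        self.grid = grid
        self.config = config
        self.n = grid.n_active
        self.species = list(spec.species)
        self.hurdle = [s for s in self.species if spec.family[s] == "hurdle-gamma"]

        self.cov_values = {k: np.asarray(covariates[k], float) for k in spec.covariates}
        for k, v in self.cov_values.items():
            if v.shape != (self.n,):
                raise ValueError(f"covariate {k} has {v.shape}, expected ({self.n},)")
        self.edges = {}
        for k, v in self.cov_values.items():
            lo, hi = float(v.min()), float(v.max())
            if hi <= lo:
                raise ValueError(f"covariate {k} is constant; cannot bin")
            self.edges[k] = np.linspace(lo, hi, config.n_bins + 1)

        lay = _Layout()
        for s in self.species:
            lay.add(f"alpha:{s}", 1)
        for s in self.hurdle:
            lay.add(f"alpha_b:{s}", 1)
        for k in spec.covariates:
            lay.add(f"f:{k}", config.n_bins)
        if spec.include_spatial:
            lay.add("z", self.n)
        if spec.include_heterogeneity:
            for s in self.species:
                lay.add(f"v:{s}", self.n)
        self.layout = lay

        if spec.include_spatial:
            if adjacency is None:
                adjacency = build_adjacency(grid, config.contiguity)
            if adjacency.matrix.nnz == 0:
                raise ValueError("all active cells are isolated: ICAR precision singular")
        self.adjacency = adjacency
        self.icar = icar_structure(adjacency) if spec.include_spatial else None

        # constraints: cell-weighted sum-to-zero for each smooth (each bin
        # weighted by how many active cells fall in it, so the smooth level
        # and the intercept separate on the data scale), plain sum-to-zero
        # for the spatial trend
        rows = []
        d = lay.dim
        for k in spec.covariates:
            idx, _ = _bin_index(self.cov_values[k], self.edges[k])
            counts = np.bincount(idx, minlength=config.n_bins).astype(float)
            r = np.zeros(d)
            r[lay.slices[f"f:{k}"]] = counts / counts.sum()
            rows.append(r)
        if spec.include_spatial:
            r = np.zeros(d)
            r[lay.slices["z"]] = 1.0 / self.n
            rows.append(r)
        self.constraints = np.array(rows) if rows else np.zeros((0, d))

        # observation groups
        self.groups: list[_Group] = []
        for s in self.species:
            surf = surfaces[s]
            fam = spec.family[s]
            if fam == "gaussian":
                cells = np.arange(self.n)
                self.groups.append(self._make_group(
                    "gaussian", s, surf.values, cells, occupancy=False))
                continue
            pos_cells = np.flatnonzero(surf.values > 0)
            if fam == "hurdle-gamma":
                if not np.any(surf.values == 0):
                    raise ValueError(
                        f"species {s}: hurdle-gamma family requires exact zeros "
                        "in the data; use 'gamma' for all-positive surfaces")
                occ = (surf.values > 0).astype(float)
                self.groups.append(self._make_group(
                    "bernoulli", s, occ, np.arange(self.n), occupancy=True))
            if pos_cells.size == 0:
                raise ValueError(f"species {s} has no positive observations")
            self.groups.append(self._make_group(
                "gamma", s, surf.values[pos_cells], pos_cells, occupancy=False))

    # -- designs ---------------------------------------------------------
    def _make_group(self, kind, s, y, cells, occupancy):
        a_fixed, a_z = self.design_rows(s, cells, occupancy=occupancy)
        return _Group(kind, s, np.asarray(y, float), a_fixed, a_z)

    def design_rows(self, species: str, cells: np.ndarray, *, occupancy: bool,
                    cov_values: Mapping[str, np.ndarray] | None = None):
        """Sparse design rows for one predictor over given active-cell indices.

        ``cov_values`` overrides the fitted covariate fields (future-scenario
        prediction); values outside the binned range clamp to boundary bins.
        Returns ``(A_fixed, A_z)`` with the z-block separated so it can be
        scaled by ``delta_s``.
        """
        lay = self.layout
        m = cells.size
        rows_ix, cols_ix, vals = [], [], []

        def put(r, c, v=1.0):
            rows_ix.append(r)
            cols_ix.append(c)
            vals.append(v)

        rr = np.arange(m)
        a_name = f"alpha_b:{species}" if occupancy else f"alpha:{species}"
        put(rr, np.full(m, lay.slices[a_name].start))
        n_clamped = 0
        for k in self.spec.covariates:
            v = (cov_values or self.cov_values)[k]
            idx, nc = _bin_index(np.asarray(v, float)[cells], self.edges[k])
            n_clamped += nc
            put(rr, lay.slices[f"f:{k}"].start + idx)
        if self.spec.include_heterogeneity and not occupancy:
            put(rr, lay.slices[f"v:{species}"].start + cells)
        rows_ix = np.concatenate([np.atleast_1d(r) for r in rows_ix])
        cols_ix = np.concatenate([np.atleast_1d(np.broadcast_to(c, (m,)))
                                  for c in cols_ix])
        data = np.ones(rows_ix.size)
        a_fixed = sp.csr_matrix((data, (rows_ix, cols_ix)), shape=(m, lay.dim))
        a_z = None
        if self.spec.include_spatial:
            a_z = sp.csr_matrix(
                (np.ones(m), (rr, lay.slices["z"].start + cells)),
                shape=(m, lay.dim))
        if n_clamped and cov_values is not None:
            logger.warning("%d covariate values outside the fitted range were "
                           "clamped to boundary bins (species %s)", n_clamped, species)
        return a_fixed, a_z

    # -- hyperparameters -------------------------------------------------
    def hyper_names(self) -> list[str]:
        names = []
        cfg, spec = self.config, self.spec
        if spec.covariates:
            if cfg.tie_smooth_precisions:
                names.append("tau_f")
            else:
                names += [f"tau_f:{k}" for k in spec.covariates]
        if spec.include_spatial:
            names.append("tau_z")
        if spec.include_heterogeneity:
            if cfg.tie_heterogeneity_precisions:
                names.append("tau_v")
            else:
                names += [f"tau_v:{s}" for s in self.species]
        for s in self.species:
            if spec.family[s] in ("gamma", "hurdle-gamma"):
                names.append(f"shape:{s}")
            elif spec.family[s] == "gaussian":
                names.append(f"tau_obs:{s}")
        if len(self.species) == 2 and spec.include_spatial:
            names.append("delta2")
        return names

    def initial_hypers(self, surfaces) -> dict[str, float]:
        init = {}
        for name in self.hyper_names():
            if name.startswith("tau_f"):
                init[name] = 5.0
            elif name == "tau_z":
                init[name] = 1.0
            elif name.startswith("tau_v"):
                init[name] = 20.0
            elif name.startswith("shape:"):
                s = name.split(":", 1)[1]
                y = surfaces[s].values
                y = y[y > 0]
                cv2 = np.var(y) / np.mean(y) ** 2 if y.size > 1 else 1.0
                init[name] = float(np.clip(1.0 / max(cv2, 1e-3), 0.1, 100.0))
            elif name.startswith("tau_obs:"):
                s = name.split(":", 1)[1]
                init[name] = float(1.0 / max(np.var(surfaces[s].values), 1e-6))
            elif name == "delta2":
                init[name] = 1.0
        return init

    def delta_for(self, species: str, hypers: Mapping[str, float]) -> float:
        if len(self.species) == 2 and species == self.species[1] \
                and self.spec.include_spatial:
            return float(hypers.get("delta2", 1.0))
        return 1.0

    def shape_or_tau(self, g: _Group, hypers) -> float:
        if g.kind == "gamma":
            return float(hypers[f"shape:{g.species}"])
        if g.kind == "gaussian":
            return float(hypers[f"tau_obs:{g.species}"])
        return 0.0

    def tau_v_for(self, species: str, hypers) -> float:
        if self.config.tie_heterogeneity_precisions:
            return float(hypers["tau_v"])
        return float(hypers[f"tau_v:{species}"])

    def tau_f_for(self, cov: str, hypers) -> float:
        if self.config.tie_smooth_precisions:
            return float(hypers["tau_f"])
        return float(hypers[f"tau_f:{cov}"])

    def prior_precision(self, hypers: Mapping[str, float]) -> sp.csc_matrix:
        cfg, spec, lay = self.config, self.spec, self.layout
        blocks = []
        for s in self.species:
            blocks.append(sp.eye(1) * cfg.intercept_precision)
        for s in self.hurdle:
            blocks.append(sp.eye(1) * cfg.intercept_precision)
        for k in spec.covariates:
            tau = self.tau_f_for(k, hypers)
            kmat = rw_structure(cfg.n_bins, spec.smooth_order[k])
            blocks.append(tau * kmat + cfg.jitter * sp.eye(cfg.n_bins))
        if spec.include_spatial:
            tau = float(hypers["tau_z"])
            blocks.append(tau * self.icar + cfg.jitter * sp.eye(self.n))
        if spec.include_heterogeneity:
            for s in self.species:
                blocks.append(self.tau_v_for(s, hypers) * sp.eye(self.n))
        qp = sp.block_diag(blocks, format="csc")
        assert qp.shape == (lay.dim, lay.dim)
        return qp


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

def _data_loglik(md: _ModelData, x: np.ndarray, hypers) -> float:
    total = 0.0
    for g in md.groups:
        eta = g.design(md.delta_for(g.species, hypers)) @ x
        ll, _, _ = _FAMLL[g.kind](g.y, eta, md.shape_or_tau(g, hypers))
        total += float(ll.sum())
    return total


def _quad_model(md: _ModelData, x: np.ndarray, hypers, qp: sp.csc_matrix):
    """Quadratic (Newton) model of the penalised log-likelihood at x."""
    d = md.layout.dim
    q = qp.copy()
    b = np.zeros(d)
    ll_total = 0.0
    for g in md.groups:
        a = g.design(md.delta_for(g.species, hypers))
        eta = a @ x
        ll, grad, w = _FAMLL[g.kind](g.y, eta, md.shape_or_tau(g, hypers))
        ll_total += float(ll.sum())
        aw = a.T.multiply(w)
        q = q + (aw @ a).tocsc()
        b = b + a.T @ (w * eta + grad)
    return q, b, ll_total


def _penalized(md, x, hypers, qp) -> float:
    return _data_loglik(md, x, hypers) - 0.5 * float(x @ (qp @ x))


def _find_mode(md: _ModelData, hypers, x0: np.ndarray,
               constraints: np.ndarray | None = None,
               e: np.ndarray | None = None):
    """Constrained Newton ascent; returns (x*, cg_at_mode, qp, diagnostics)."""
    cfg = md.config
    if constraints is None:
        constraints = md.constraints
    qp = md.prior_precision(hypers)
    x = x0.copy()
    pll = _penalized(md, x, hypers, qp)
    converged = False
    n_iter = 0
    cg = None
    for n_iter in range(1, cfg.newton_max_iter + 1):
        q, b, _ = _quad_model(md, x, hypers, qp)
        cg = ConstrainedGaussian(q, b, constraints, e=e)
        xn = cg.mean
        step = xn - x
        t = 1.0
        accepted = False
        for _ in range(30):
            xc = x + t * step
            pll_c = _penalized(md, xc, hypers, qp)
            if pll_c >= pll - 1e-10:
                accepted = pll_c > pll + 1e-12 or np.max(np.abs(t * step)) < cfg.newton_tol
                x, pll = xc, pll_c
                break
            t *= 0.5
        else:
            break
        scale = 1.0 + np.max(np.abs(x))
        if np.max(np.abs(t * step)) < cfg.newton_tol * scale:
            converged = True
            break
        if not accepted and t < 1e-6:
            break
    if converged and cg is not None and t == 1.0:
        # full step below tolerance: the quadratic model built this iteration
        # is the model at the mode to within the step size; reuse it
        ll_mode = _data_loglik(md, x, hypers)
    else:
        q, b, ll_mode = _quad_model(md, x, hypers, qp)
        cg = ConstrainedGaussian(q, b, constraints, e=e)
    diag = {"newton_iterations": n_iter, "newton_converged": converged,
            "penalized_loglik": pll}
    return x, cg, qp, ll_mode, diag


def _log_marginal(md: _ModelData, hypers, x0,
                  constraints: np.ndarray | None = None,
                  e: np.ndarray | None = None):
    """Constrained Laplace approximation to log p(y | hyperparameters)."""
    x, cg, qp, ll_mode, diag = _find_mode(md, hypers, x0, constraints, e)
    fp = SPDFactor(qp)
    quad_prior = float(x @ (qp @ x))
    c = md.constraints if constraints is None else constraints
    val = ll_mode - 0.5 * quad_prior + 0.5 * fp.logdet - 0.5 * cg.factor.logdet
    if c.size:
        sp_cc = c @ fp.solve(c.T)
        val += 0.5 * _logdet_small(sp_cc) - 0.5 * _logdet_small(cg.s_cc)
        ev = cg.e
        val += 0.5 * float(ev @ np.linalg.solve(sp_cc, ev))
        m = cg.mean_unconstrained
        cm = c @ m - ev
        val -= 0.5 * float(cm @ np.linalg.solve(cg.s_cc, cm))
    r = x - cg.mean_unconstrained
    val += 0.5 * float(r @ (cg.q @ r))
    return val, x, cg, qp, diag


def _logdet_small(a: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(a)
    if sign <= 0:
        raise np.linalg.LinAlgError("constraint Gram matrix not positive definite")
    return float(ld)


def _gamma_d3(y, eta, a):
    return a * y * np.exp(np.clip(-eta, -60.0, 60.0))


def _bernoulli_d3(y, eta, _):
    p = expit(eta)
    return -p * (1.0 - p) * (1.0 - 2.0 * p)


_FAMD3 = {"gamma": _gamma_d3, "bernoulli": _bernoulli_d3, "gaussian": None}


def _skew_correction(md: _ModelData, hypers, x_mode, cg) -> np.ndarray:
    """Third-order (simplified-Laplace) mean correction for the latent field.

    The joint mode of a latent Gaussian model with skewed likelihoods sits
    below the marginal posterior means; expanding the log-posterior to third
    order around the mode and taking expectations gives the mean shift
    ``delta = Sigma A' (T * s / 2)`` with ``T_i`` the third derivative of the
    log-likelihood in its linear predictor and ``s_i`` the predictor's
    posterior variance.  Exactly zero for Gaussian likelihoods.
    """
    rhs = np.zeros(md.layout.dim)
    any_skew = False
    for g in md.groups:
        d3f = _FAMD3[g.kind]
        if d3f is None:
            continue
        any_skew = True
        a = g.design(md.delta_for(g.species, hypers))
        eta = a @ x_mode
        t3 = d3f(g.y, eta, md.shape_or_tau(g, hypers))
        s = cg.var_linear(a)
        rhs += a.T @ (0.5 * t3 * s)
    if not any_skew:
        return np.zeros(md.layout.dim)
    delta = cg.factor.solve(rhs)
    if cg.c.size:
        delta = delta - cg.qinv_ct @ np.linalg.solve(cg.s_cc, cg.c @ delta)
    return delta


def _optimize_hypers(objective, psi0, max_evals):
    """Hybrid hyperparameter optimiser on the transformed scale.

    Marginal-posterior surfaces here are near-separable but can put optima
    many log-units from any generic start (precision posteriors pile up at
    their prior mode when a variance component vanishes), which plain
    Nelder-Mead reaches very slowly.  Strategy: bounded golden-section sweeps
    along each coordinate (wide first sweep, narrowing) followed by a
    Nelder-Mead polish with the remaining budget.
    """
    count = [0]

    def f(psi):
        count[0] += 1
        return objective(psi)

    psi = np.asarray(psi0, float).copy()
    best = f(psi)
    widths = (8.0, 2.0, 0.6)
    for width in widths:
        if count[0] >= max_evals * 0.6:
            break
        for i in range(psi.size):
            lo, hi = psi[i] - width, psi[i] + width

            def f1(t, i=i):
                p = psi.copy()
                p[i] = t
                return f(p)

            res = sopt.minimize_scalar(
                f1, bounds=(lo, hi), method="bounded",
                options={"maxiter": 10, "xatol": max(0.02, width / 50)})
            if res.fun < best:
                best = res.fun
                psi[i] = res.x
    remaining = max(max_evals - count[0], 5 * psi.size)
    res = sopt.minimize(
        f, psi, method="Nelder-Mead",
        options={"maxfev": int(remaining), "xatol": 2e-2, "fatol": 5e-3,
                 "adaptive": psi.size > 4,
                 "initial_simplex": psi + 0.15 * np.eye(psi.size + 1, psi.size)})
    if res.fun <= best:
        best, psi = res.fun, res.x
    return psi, {"n_evals": count[0], "optimizer_converged": bool(res.success),
                 "optimizer_message": str(res.message)}


# -- hyperparameter transform and priors ------------------------------------

_PSI_BOUNDS = {"tau": (np.log(1e-6), np.log(1e8)),
               "shape": (np.log(1e-2), np.log(1e5)),
               "delta": (-25.0, 25.0)}


def _to_psi(name: str, value: float) -> float:
    return float(value) if name == "delta2" else float(np.log(value))


def _from_psi(name: str, psi: float) -> float:
    if name == "delta2":
        lo, hi = _PSI_BOUNDS["delta"]
        return float(np.clip(psi, lo, hi))
    key = "shape" if name.startswith("shape") else "tau"
    lo, hi = _PSI_BOUNDS[key]
    return float(np.exp(np.clip(psi, lo, hi)))


def _log_hyper_prior(name: str, value: float, cfg: InferenceConfig) -> float:
    if name == "delta2":
        return -0.5 * (value / cfg.delta_prior_sd) ** 2
    psi = np.log(value)
    if name.startswith("shape"):
        return -0.5 * (psi / cfg.log_shape_prior_sd) ** 2
    # precision ~ Gamma(a0, b0), density in psi = log tau includes the Jacobian
    a0, b0 = cfg.precision_prior_shape, cfg.precision_prior_rate
    return a0 * psi - b0 * value


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

class _Backend:
    """Private handle kept on JointFit for prediction and diagnostics."""

    def __init__(self, md, hypers, x_mode, cg, config, mean_shift=None):
        self.md = md
        self.hypers = hypers
        self.x_mode = x_mode
        self.cg = cg
        self.config = config
        self.mean_shift = mean_shift if mean_shift is not None else 0.0

    def release(self):
        self.cg.release()


def fit(spec: ModelSpec, surfaces: Mapping[str, SpeciesSurface],
        covariates: Mapping[str, object], config: InferenceConfig | None = None,
        adjacency: Adjacency | None = None) -> JointFit:
    """Fit the model and return posterior summaries.

    ``surfaces`` maps species name to its present-scenario surface;
    ``covariates`` maps covariate name to values on active cells (arrays or
    objects with a ``values`` attribute).  Seed-deterministic given
    ``config``; non-convergence is flagged in the result, not raised.
    """
    config = config or InferenceConfig()
    t0 = time.perf_counter()
    grids = {s.grid.n_active for s in surfaces.values()}
    if len(grids) != 1:
        raise ValueError("all surfaces must share one grid")
    grid = next(iter(surfaces.values())).grid
    cov_arrays = {k: getattr(v, "values", v) for k, v in covariates.items()}
    md = _ModelData(spec, surfaces, cov_arrays, grid, adjacency, config)

    hypers = md.initial_hypers(surfaces)
    hypers.update(config.fixed_hyperparameters)
    free = [n for n in md.hyper_names() if n not in config.fixed_hyperparameters]
    x_warm = np.zeros(md.layout.dim)
    opt_info = {"n_evals": 0, "optimizer_converged": True}

    def objective(psi_vec):
        h = dict(hypers)
        for n, p in zip(free, psi_vec):
            h[n] = _from_psi(n, p)
        ll, x_new, _, _, _ = _log_marginal(md, h, x_warm)
        x_warm[:] = x_new
        opt_info["n_evals"] += 1
        lp = sum(_log_hyper_prior(n, h[n], config) for n in free)
        return -(ll + lp)

    if free:
        psi0 = np.array([_to_psi(n, hypers[n]) for n in free])
        psi_hat, info = _optimize_hypers(objective, psi0, config.max_opt_evals)
        for n, p in zip(free, psi_hat):
            hypers[n] = _from_psi(n, p)
        opt_info.update(info)
    else:
        psi_hat = np.zeros(0)

    # final mode and Gaussian approximation at the hyperparameter estimates
    x_mode, cg, qp, ll_mode, newton_diag = _find_mode(md, hypers, x_warm)

    mean_shift = np.zeros(md.layout.dim)
    if config.skew_correction:
        mean_shift = _skew_correction(md, hypers, x_mode, cg)

    hyper_sd: dict[str, float] = {}
    latent_extra_var = None
    if free and config.estimate_hyperparameter_uncertainty:
        hyper_sd, latent_extra_var = _hyper_uncertainty(
            md, hypers, free, psi_hat, x_mode, config)

    fit_obj = _summarize(md, hypers, hyper_sd, x_mode, cg, config,
                         ll_mode, newton_diag, opt_info,
                         latent_extra_var=latent_extra_var,
                         mean_shift=mean_shift)
    fit_obj.diagnostics["wall_time_s"] = time.perf_counter() - t0
    return fit_obj


def _hyper_uncertainty(md, hypers, free, psi_hat, x_mode, config):
    """Hyperparameter sds and latent-uncertainty propagation.

    Builds a finite-difference Hessian of the negative log marginal posterior
    over the transformed free hyperparameters (delta-method sds), and, from
    the latent modes at the axial evaluation points, the sensitivity
    ``G = dx*/dpsi`` used to add the hyperparameter contribution
    ``diag(G Cov(psi) G')`` to the latent marginal variances — the
    plug-in-free part of integrating the latent posterior over the
    hyperparameter posterior.
    """
    x_warm = x_mode.copy()
    cache: dict[tuple, tuple] = {}

    def f(psi_vec):
        key = tuple(np.round(psi_vec, 12))
        if key in cache:
            return cache[key]
        h = dict(hypers)
        for n, p_ in zip(free, psi_vec):
            h[n] = _from_psi(n, p_)
        ll, x_new, _, _, _ = _log_marginal(md, h, x_warm)
        x_warm[:] = x_new
        lp = sum(_log_hyper_prior(n, h[n], config) for n in free)
        val = (-(ll + lp), x_new.copy())
        cache[key] = val
        return val

    p = len(free)
    step = 0.05
    hess = np.zeros((p, p))
    f0, _ = f(psi_hat)
    fp_ = np.zeros(p)
    fm_ = np.zeros(p)
    g_sens = np.zeros((md.layout.dim, p))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = step
        fp_[i], xp = f(psi_hat + ei)
        fm_[i], xm = f(psi_hat - ei)
        hess[i, i] = (fp_[i] - 2 * f0 + fm_[i]) / step**2
        g_sens[:, i] = (xp - xm) / (2 * step)
    for i in range(p):
        for j in range(i + 1, p):
            eij = np.zeros(p)
            eij[i] = step
            eij[j] = step
            fij, _ = f(psi_hat + eij)
            hess[i, j] = hess[j, i] = (fij - fp_[i] - fp_[j] + f0) / step**2
    try:
        cov = np.linalg.inv(hess)
        w, v = np.linalg.eigh(cov)
        cov = (v * np.maximum(w, 0.0)) @ v.T   # clip stray negative curvature
        var = np.diag(cov)
        latent_extra = np.einsum("dp,pq,dq->d", g_sens, cov, g_sens)
    except np.linalg.LinAlgError:
        var = np.full(p, np.nan)
        latent_extra = None
    out = {}
    for i, n in enumerate(free):
        vi = var[i]
        out[n] = float(np.sqrt(vi)) if np.isfinite(vi) and vi > 0 else float("nan")
    return out, latent_extra


def _summarize(md: _ModelData, hypers, hyper_sd, x_mode, cg, config,
               ll_mode, newton_diag, opt_info, latent_extra_var=None,
               mean_shift=None) -> JointFit:
    lay = md.layout
    spec = md.spec
    rng = np.random.default_rng(config.seed)
    extra = latent_extra_var if latent_extra_var is not None \
        else np.zeros(lay.dim)
    # posterior mean = mode + third-order skewness correction
    x_post = x_mode if mean_shift is None else x_mode + mean_shift

    def _sd(idx: np.ndarray) -> np.ndarray:
        base = cg.marginal_sd(idx)
        return np.sqrt(base * base + extra[idx])

    def _alpha_summary(name: str) -> tuple[float, float]:
        i = lay.slices[name].start
        return float(x_post[i]), float(_sd(np.array([i]))[0])

    intercepts = {s: _alpha_summary(f"alpha:{s}") for s in md.species}
    occupancy_intercepts = {s: _alpha_summary(f"alpha_b:{s}") for s in md.hurdle}

    smooths = {}
    for k in spec.covariates:
        idx = lay.idx(f"f:{k}")
        sd = _sd(idx)
        edges = md.edges[k]
        smooths[k] = SmoothEffect(
            covariate=k, order=spec.smooth_order[k], bin_edges=edges,
            bin_mid=0.5 * (edges[:-1] + edges[1:]),
            mean=x_post[idx].copy(), sd=sd,
            precision=md.tau_f_for(k, hypers),
        )

    fields = {}
    for s in md.species:
        if spec.include_heterogeneity:
            idx = lay.idx(f"v:{s}")
            vm, vs = x_post[idx].copy(), _sd(idx)
            tau_v = md.tau_v_for(s, hypers)
        else:
            vm = np.zeros(md.n)
            vs = np.zeros(md.n)
            tau_v = float("inf")
        fields[s] = BYMField(spatial_scaling=md.delta_for(s, hypers),
                             heterogeneity_mean=vm, heterogeneity_sd=vs,
                             tau_v=tau_v)

    cst = None
    if spec.include_spatial:
        idx = lay.idx("z")
        zm = x_post[idx].copy()
        zs = _sd(idx)
        cst = PosteriorSurface(grid=md.grid, mean=zm, sd=zs,
                               q2_5=zm - Z975 * zs, q97_5=zm + Z975 * zs)

    # deviance summaries: D-bar by seeded MC over the (skew-shifted) Gaussian
    # approximation; the plug-in deviance uses the corrected posterior mean
    d_hat = -2.0 * _data_loglik(md, x_post, hypers)
    shift = x_post - x_mode
    samples = cg.sample(config.n_samples, rng) + shift
    devs = np.array([-2.0 * _data_loglik(md, s_, hypers) for s_ in samples])
    d_bar = float(devs.mean())
    p_d = d_bar - d_hat
    dic_val = d_bar + p_d

    converged = bool(newton_diag["newton_converged"])
    diagnostics = {**newton_diag, **opt_info,
                   "constraint_residual": float(
                       np.max(np.abs(md.constraints @ x_mode))
                       if md.constraints.size else 0.0)}
    if not converged:
        logger.warning("fit did not converge: %s", diagnostics)

    return JointFit(
        spec=spec, grid=md.grid,
        intercepts=intercepts, occupancy_intercepts=occupancy_intercepts,
        smooths=smooths, fields=fields, cst=cst,
        hyperparameters=dict(hypers), hyperparameter_sd=hyper_sd,
        deviance_mean=d_bar, deviance_at_mean=d_hat, p_d=p_d, dic=dic_val,
        converged=converged, diagnostics=diagnostics,
        _backend=_Backend(md, hypers, x_post, cg, config, shift),
    )


def dic(fit_result: JointFit) -> float:
    """Deviance information criterion of a fitted model."""
    return float(fit_result.dic)


def extract_common_trend(fit_result: JointFit) -> PosteriorSurface:
    """Posterior of the shared spatial trend z of a two-species joint fit."""
    if len(fit_result.spec.species) != 2:
        raise ValueError("common spatial trend requires a 2-species joint fit")
    if fit_result.cst is None:
        raise ValueError("fit has no spatial component")
    return fit_result.cst


def predict_missing(fit_result: JointFit,
                    future_covariates: Mapping[str, object] | None,
                    n_samples: int | None = None,
                    seed: int | None = None) -> dict:
    """Expected-density posteriors per species for present and future scenarios.

    Prediction follows the missing-response convention: rows with unobserved
    responses contribute no likelihood, so the future posterior is the fitted
    latent posterior pushed through the future covariates — shared smooths
    evaluated at the future values (clamped to the binned range, with a
    warning), plus the same spatial trend and heterogeneity fields.  Expected
    density is ``mu = exp(eta)`` for gamma species and ``pi * mu`` for hurdle
    species.  Summaries are seeded Monte-Carlo over the latent Gaussian
    approximation.
    """
    be: _Backend = fit_result._backend
    md, hypers, cg = be.md, be.hypers, be.cg
    config = be.config
    n_samples = n_samples or config.n_samples
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    samples = cg.sample(n_samples, rng) + be.mean_shift
    cells = np.arange(md.n)
    scenarios = {"present": None}
    if future_covariates is not None:
        scenarios["future"] = {k: getattr(v, "values", v)
                               for k, v in future_covariates.items()}
    out: dict[str, dict[str, PosteriorSurface]] = {}
    for scen, cov in scenarios.items():
        per_species = {}
        for s in md.species:
            a_fixed, a_z = md.design_rows(s, cells, occupancy=False, cov_values=cov)
            delta = md.delta_for(s, hypers)
            a = a_fixed if a_z is None else (a_fixed + delta * a_z).tocsr()
            eta = (a @ samples.T).T
            mu = np.exp(np.clip(eta, -60, 60))
            if md.spec.family[s] == "hurdle-gamma":
                b_fixed, b_z = md.design_rows(s, cells, occupancy=True, cov_values=cov)
                b = b_fixed if b_z is None else (b_fixed + delta * b_z).tocsr()
                zeta = (b @ samples.T).T
                mu = mu * expit(zeta)
            mean = mu.mean(axis=0)
            sd = mu.std(axis=0)
            q = np.quantile(mu, [0.025, 0.975], axis=0)
            per_species[s] = PosteriorSurface(
                grid=md.grid, mean=mean, sd=sd,
                q2_5=np.minimum(q[0], mean), q97_5=np.maximum(q[1], mean))
        out[scen] = per_species
    return out
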