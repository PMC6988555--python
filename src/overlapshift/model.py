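"""Model specifications, posterior containers, and DIC-based selection.

A ``ModelSpec`` names the species (one or two), the covariate subset, the
random-walk order of each covariate smooth, and the likelihood family per
species.  Candidate specs are enumerated over all covariate subsets whose
pairwise Pearson correlation never exceeds a threshold (|r| > 0.5 pairs are
excluded by default).  Fitted models are ranked by the deviance information
criterion: the second-best model is reported when it is within 2 DIC units of
the best (single-species convention), and a joint winner is flagged decisive
when it beats the runner-up by at least 5 units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import LatticeGrid

__all__ = [
    "ModelSpec",
    "SmoothEffect",
    "BYMField",
    "PosteriorSurface",
    "JointFit",
    "screen_correlations",
    "enumerate_candidate_specs",
    "select_models",
    "deviance_explained",
]

DEFAULT_CORRELATION_THRESHOLD = 0.5
SECOND_BEST_DELTA = 2.0   # single-species reporting rule
DECISIVE_DELTA = 5.0      # joint-model decisive rule


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a single-species or joint two-species model."""

    species: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    smooth_order: Mapping[str, int] = field(default_factory=dict)
    family: Mapping[str, str] = field(default_factory=dict)
    include_spatial: bool = True
    include_heterogeneity: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.species) not in (1, 2):
            raise ValueError("ModelSpec needs 1 or 2 species")
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        order = {k: int(self.smooth_order.get(k, 2)) for k in self.covariates}
        for k, o in order.items():
            if o not in (1, 2):
                raise ValueError(f"smooth order for {k} must be 1 (RW1) or 2 (RW2)")
        object.__setattr__(self, "smooth_order", order)
        fam = {s: self.family.get(s, "gamma") for s in self.species}
        for s, f in fam.items():
            if f not in ("gamma", "hurdle-gamma", "gaussian"):
                raise ValueError(f"unknown family {f!r} for species {s}")
        object.__setattr__(self, "family", fam)

    @property
    def is_joint(self) -> bool:
        return len(self.species) == 2

    @property
    def label(self) -> str:
        sp = "+".join(self.species)
        cov = ",".join(self.covariates) if self.covariates else "intercept"
        return f"{sp}~{cov}"

    @staticmethod
    def create(species, covariate_values: Mapping[str, np.ndarray],
               covariates: Sequence[str], *,
               correlation_threshold: float = DEFAULT_CORRELATION_THRESHOLD,
               **kwargs) -> "ModelSpec":
        """Build a spec, enforcing the pairwise-correlation screen on the
        chosen covariate subset (values on active cells, present scenario)."""
        corr = screen_correlations({k: covariate_values[k] for k in covariates})
        bad = [
            (a, b) for a, b in itertools.combinations(covariates, 2)
            if abs(corr.loc[a, b]) > correlation_threshold
        ]
        if bad:
            raise ValueError(
                f"covariate pairs exceed |r| > {correlation_threshold}: {bad}"
            )
        return ModelSpec(species=tuple(species), covariates=tuple(covariates), **kwargs)


@dataclass
class SmoothEffect:
    """Binned random-walk covariate smooth with posterior summaries."""

    covariate: str
    order: int
    bin_edges: np.ndarray      # (n_bins + 1,)
    bin_mid: np.ndarray        # (n_bins,)
    mean: np.ndarray           # posterior mean per bin
    sd: np.ndarray
    precision: float           # tau_f point estimate

    @property
    def n_bins(self) -> int:
        return self.mean.size


@dataclass
class BYMField:
    """Per-species random effects: scaled shared spatial part + iid part."""

    spatial_scaling: float      # delta_s (1 for the first species)
    heterogeneity_mean: np.ndarray
    heterogeneity_sd: np.ndarray
    tau_v: float


@dataclass
class PosteriorSurface:
    """Per-active-cell posterior summary of a latent field or prediction."""

    grid: LatticeGrid
    mean: np.ndarray
    sd: np.ndarray
    q2_5: np.ndarray
    q97_5: np.ndarray

    def __post_init__(self):
        n = self.grid.n_active
        for name in ("mean", "sd", "q2_5", "q97_5"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            object.__setattr__(self, name, arr)
        if np.any(self.q2_5 > self.mean + 1e-9) or np.any(self.q97_5 < self.mean - 1e-9):
            raise ValueError("quantiles must bracket the posterior mean")

    @property
    def significant(self) -> np.ndarray:
        """CI excludes zero (for latent fields)."""
        return (self.q2_5 > 0) | (self.q97_5 < 0)

    @property
    def significant_positive(self) -> np.ndarray:
        return self.q2_5 > 0

    def to_frame(self) -> pd.DataFrame:
        ids = self.grid.active_ids
        return pd.DataFrame({
            "cell_id": ids,
            "lon": self.grid.lon[ids],
            "lat": self.grid.lat[ids],
            "mean": self.mean, "sd": self.sd,
            "q2.5": self.q2_5, "q97.5": self.q97_5,
            "significant": self.significant.astype(int),
        })


@dataclass
class JointFit:
    """A fitted single-species or joint model (posterior summaries)."""

    spec: ModelSpec
    grid: LatticeGrid
    intercepts: dict            # species -> (mean, sd)
    occupancy_intercepts: dict  # hurdle species -> (mean, sd)
    smooths: dict               # covariate -> SmoothEffect
    fields: dict                # species -> BYMField
    cst: PosteriorSurface | None   # shared spatial trend posterior (z)
    hyperparameters: dict       # name -> point estimate
    hyperparameter_sd: dict     # name -> sd (delta method), may be empty
    deviance_mean: float        # D-bar
    deviance_at_mean: float     # D(theta-hat)
    p_d: float
    dic: float
    converged: bool
    diagnostics: dict
    # private handles used by prediction (posterior object, layout, designs)
    _backend: object = None

    @property
    def delta_2(self) -> float | None:
        return self.hyperparameters.get("delta2")


def screen_correlations(covariate_values: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson correlations of covariates over active cells."""
    names = list(covariate_values)
    data = np.column_stack([np.asarray(covariate_values[k], float) for k in names])
    if data.shape[1] == 1:
        corr = np.ones((1, 1))
    else:
        corr = np.corrcoef(data, rowvar=False)
    return pd.DataFrame(corr, index=names, columns=names)


def enumerate_candidate_specs(covariate_values: Mapping[str, np.ndarray],
                              max_set_size: int | None = None,
                              correlation_threshold: float = DEFAULT_CORRELATION_THRESHOLD,
                              ) -> list[tuple[str, ...]]:
    """All non-empty covariate subsets passing the pairwise |r| screen.

    Subsets are returned in a deterministic order: by size, then
    lexicographically within size.
    """
    names = sorted(covariate_values)
    if not names:
        raise ValueError("need at least one covariate")
    if max_set_size is None:
        max_set_size = len(names)
    corr = screen_correlations(covariate_values)
    out: list[tuple[str, ...]] = []
    for size in range(1, max_set_size + 1):
        for subset in itertools.combinations(names, size):
            ok = all(
                abs(corr.loc[a, b]) <= correlation_threshold
                for a, b in itertools.combinations(subset, 2)
            )
            if ok:
                out.append(subset)
    return out


def select_models(entries: Sequence[tuple], *,
                  second_best_delta: float = SECOND_BEST_DELTA,
                  decisive_delta: float = DECISIVE_DELTA) -> pd.DataFrame:
    """Rank fitted models by DIC ascending.

    ``entries`` is a sequence of ``(label, covariates, dic)`` tuples (or
    ``(spec, fit)`` pairs).  Ties are broken by fewer covariates, then by
    label.  The returned frame carries ``rank``, ``delta_dic``, ``is_best``,
    ``report_second_best`` (True on the runner-up when it lies within
    ``second_best_delta`` of the best), and ``decisive`` (True on the best
    when the runner-up is at least ``decisive_delta`` worse).
    """
    rows = []
    for e in entries:
        if len(e) == 2 and isinstance(e[0], ModelSpec):
            spec, fit = e
            rows.append((spec.label, spec.covariates, float(fit.dic)))
        else:
            label, covs, dic = e
            rows.append((str(label), tuple(covs), float(dic)))
    if len(rows) < 2:
        raise ValueError("model selection needs at least 2 candidates")
    rows.sort(key=lambda r: (r[2], len(r[1]), r[0]))
    best_dic = rows[0][2]
    runner_delta = rows[1][2] - best_dic
    table = pd.DataFrame(rows, columns=["label", "covariates", "dic"])
    table["rank"] = np.arange(1, len(rows) + 1)
    table["delta_dic"] = table["dic"] - best_dic
    table["is_best"] = table["rank"] == 1
    table["report_second_best"] = (table["rank"] == 2) & (runner_delta < second_best_delta)
    table["decisive"] = (table["rank"] == 1) & (runner_delta >= decisive_delta)
    return table


def deviance_explained(null_deviance: float, reduced_deviance: float) -> float:
    """Percent of the null deviance explained: (null - reduced)/null * 100.

    May be negative when the reduced model fits worse than the intercept-only
    model; callers flag such values rather than clipping them.
    """
    if null_deviance == 0:
        raise ValueError("null deviance is zero")
    return float((null_deviance - reduced_deviance) / null_deviance * 100.0)
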