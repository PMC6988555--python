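"""Ecological-cost metrics comparing present and future density surfaces.

Four methods, applied to pairs of surfaces on the same masked lattice:

1. relative population change — percent change of the total density;
2. overall spatial percentage difference — share of cells whose value changed
   by more than one third, categorised by the "thirds rule of thumb";
3. local loss/gain — Getis–Ord G* hot/cold-spot transitions for single-species
   surfaces, and significant sign changes of the common spatial trend for
   joint models;
4. weighted-centroid displacement — haversine distance and 8-wind compass
   bearing between the first moments of the two surfaces.

RMSE and the Bhattacharyya distance between (positive-part normalised)
surfaces are provided as conventional cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .grid import Adjacency, LatticeGrid, SpeciesSurface, EARTH_RADIUS_KM

__all__ = [
    "CentroidResult",
    "CostReport",
    "relative_population_change",
    "overall_percent_difference",
    "gstar_z",
    "hot_cold_transitions",
    "cst_sign_change",
    "weighted_centroid",
    "haversine_km",
    "bearing_and_sector",
    "rmse_surfaces",
    "bhattacharyya_distance",
    "single_species_costs",
    "build_cost_report",
]

SIMILARITY_CATEGORIES = ("fairly similar", "fairly different", "very different")
_SECTORS = ("North", "Northeast", "East", "Southeast",
            "South", "Southwest", "West", "Northwest")


def _values(x) -> np.ndarray:
    if isinstance(x, SpeciesSurface):
        return x.values
    return np.asarray(x, dtype=float)


def relative_population_change(present, future) -> float:
    """Percent change of total density: 100 (sum F - sum P) / sum P."""
    p, f = _values(present), _values(future)
    if p.shape != f.shape:
        raise ValueError("surfaces must share the same active-cell layout")
    total = p.sum()
    if total == 0:
        raise ValueError("present surface has zero total density")
    return float(100.0 * (f.sum() - total) / total)


def similarity_category(percent_of_area: float) -> str:
    """Thirds-rule category for the share of cells exceeding the one-third change.

    The source convention gives <33 / 34–66 / >67; the gaps (33,34) and (66,67)
    are closed with contiguous bins [0,33] / (33,67) / [67,100].
    """
    if percent_of_area <= 33.0:
        return "fairly similar"
    if percent_of_area < 67.0:
        return "fairly different"
    return "very different"


def overall_percent_difference(present, future, cell_threshold_pct: float = 33.0,
                               floor: float = 0.0):
    """Share of cells whose absolute percent change exceeds the threshold.

    Per-cell change is ``100 |F_i - P_i| / max(|P_i|, floor)``.  A zero present
    value with ``floor=0`` is an error: small denominators inflate percent
    changes, so the caller must choose an explicit floor.

    Returns ``(percent_of_area, category)``.
    """
    p, f = _values(present), _values(future)
    if p.shape != f.shape:
        raise ValueError("surfaces must share the same active-cell layout")
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    denom = np.maximum(np.abs(p), floor)
    if np.any(denom == 0):
        raise ValueError(
            "present surface has zero-valued cells; pass a positive floor "
            "(e.g. a low quantile of the positive present values)"
        )
    pct = 100.0 * np.abs(f - p) / denom
    share = float(100.0 * np.mean(pct > cell_threshold_pct))
    return share, similarity_category(share)


def gstar_z(surface, adjacency: Adjacency, include_self: bool = True) -> np.ndarray:
    """Getis–Ord G*_i z-scores with binary weights over {i} + neighbours.

    z_i = (sum_j w_ij x_j - xbar W_i) / (S sqrt[(n sum_j w_ij^2 - W_i^2)/(n-1)])
    with xbar, S the global (population) mean and sd over all n active cells.
    """
    x = _values(surface)
    n = x.size
    if n < 3:
        raise ValueError("G* needs at least 3 active cells")
    if adjacency.n_active != n:
        raise ValueError("adjacency does not match surface layout")
    xbar = x.mean()
    s = math.sqrt(np.mean(x * x) - xbar * xbar)
    if s == 0:
        raise ValueError("constant surface: G* undefined (zero variance)")
    w = adjacency.matrix
    wx = np.asarray(w @ x).ravel()
    wi = adjacency.degrees.astype(float)
    if include_self:
        wx = wx + x
        wi = wi + 1.0
    # binary weights: sum w^2 == sum w
    denom = s * np.sqrt((n * wi - wi * wi) / (n - 1))
    return (wx - xbar * wi) / denom


def hot_cold_transitions(present_z, future_z, z_crit: float = 1.96):
    """Percentages of active cells flipping hot→cold and cold→hot.

    Hot: z > z_crit; cold: z < -z_crit.  Percentages are relative to all
    active cells.  Returns ``(hot_to_cold_pct, cold_to_hot_pct, labels)`` with
    labels in {"hot->cold", "cold->hot", "other"} per cell.
    """
    zp, zf = _values(present_z), _values(future_z)
    if zp.shape != zf.shape:
        raise ValueError("z-score surfaces must share the same layout")
    n = zp.size
    h2c = (zp > z_crit) & (zf < -z_crit)
    c2h = (zp < -z_crit) & (zf > z_crit)
    labels = np.where(h2c, "hot->cold", np.where(c2h, "cold->hot", "other"))
    return float(100.0 * h2c.sum() / n), float(100.0 * c2h.sum() / n), labels


def cst_sign_change(present_cst, future_cst):
    """Significant sign changes of the common spatial trend.

    Loss cells: significantly positive in the present and significantly
    negative in the future; gain cells the reverse.  Percentages are relative
    to the number of significantly positive present cells (the present common
    trend area); cells non-significant in either scenario never count.
    Returns ``(decrease_pct, increase_pct, labels)``; percentages are NaN when
    there is no significantly positive present cell.
    """
    sp_pos = (present_cst.q2_5 > 0)
    sp_neg = (present_cst.q97_5 < 0)
    sf_pos = (future_cst.q2_5 > 0)
    sf_neg = (future_cst.q97_5 < 0)
    if sp_pos.shape != sf_pos.shape:
        raise ValueError("trend surfaces must share the same layout")
    loss = sp_pos & sf_neg
    gain = sp_neg & sf_pos
    labels = np.where(loss, "loss", np.where(gain, "gain", "other"))
    denom = int(sp_pos.sum())
    if denom == 0:
        return float("nan"), float("nan"), labels
    return float(100.0 * loss.sum() / denom), float(100.0 * gain.sum() / denom), labels


@dataclass(frozen=True)
class CentroidResult:
    lon: float
    lat: float
    total_weight: float


def weighted_centroid(surface, grid: LatticeGrid | None = None,
                      positive_only: bool = True) -> CentroidResult:
    """First moment of a density surface (negatives zeroed when positive_only)."""
    if isinstance(surface, SpeciesSurface):
        grid = surface.grid
    if grid is None:
        raise ValueError("grid required when passing a bare value array")
    w = _values(surface).astype(float).copy()
    if positive_only:
        w[w < 0] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("no positive weight: centroid undefined")
    ids = grid.active_ids
    lon = float(np.dot(w, grid.lon[ids]) / total)
    lat = float(np.dot(w, grid.lat[ids]) / total)
    return CentroidResult(lon=lon, lat=lat, total_weight=float(total))


def haversine_km(a, b, earth_radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between (lon, lat) points, in km."""
    lon1, lat1 = np.deg2rad(a)
    lon2, lat2 = np.deg2rad(b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return float(2 * earth_radius_km * math.asin(min(1.0, math.sqrt(h))))


def bearing_and_sector(a, b, winds: int = 8):
    """Initial great-circle bearing from a to b, with compass sector.

    Bearing in [0, 360) degrees clockwise from north; sector bins are half-open
    and centered on the winds (North = [337.5, 22.5) for 8 winds).
    """
    if tuple(a) == tuple(b):
        raise ValueError("identical points: bearing undefined")
    lon1, lat1 = np.deg2rad(a)
    lon2, lat2 = np.deg2rad(b)
    dlon = lon2 - lon1
    y = math.sin(dlon) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    bearing = math.degrees(math.atan2(y, x)) % 360.0
    if winds == 8:
        names = _SECTORS
    elif winds == 16:
        names = ("N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
                 "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW")
    else:
        raise ValueError("winds must be 8 or 16")
    width = 360.0 / winds
    idx = int(((bearing + width / 2) % 360.0) // width)
    return bearing, names[idx]


def rmse_surfaces(a, b) -> float:
    """Root mean square difference over active cells."""
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError("surfaces must share the same layout")
    return float(np.sqrt(np.mean((av - bv) ** 2)))


def bhattacharyya_distance(a, b, normalization: str = "positive-part") -> float:
    """-ln of the Bhattacharyya coefficient between two normalised surfaces.

    ``positive-part`` zeroes negative values before normalising to sum 1
    (signed trend surfaces are compared on their positive support, mirroring
    the positive-values centroid convention); ``min-shift`` instead subtracts
    the smaller of the two minima from both surfaces.  Disjoint supports give
    BC = 0 and distance +inf.
    """
    av, bv = _values(a).astype(float).copy(), _values(b).astype(float).copy()
    if av.shape != bv.shape:
        raise ValueError("surfaces must share the same layout")
    if normalization == "positive-part":
        av[av < 0] = 0.0
        bv[bv < 0] = 0.0
    elif normalization == "min-shift":
        shift = min(av.min(), bv.min())
        if shift < 0:
            av -= shift
            bv -= shift
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    sa, sb = av.sum(), bv.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("surface has no positive mass after normalization")
    bc = float(np.sum(np.sqrt((av / sa) * (bv / sb))))
    bc = min(bc, 1.0)  # guard rounding above 1
    if bc == 0.0:
        return float("inf")
    return -math.log(bc)


@dataclass
class CostReport:
    """All ecological-cost metrics for one present/future surface pair."""

    pair: str
    relative_population_change_pct: float
    overall_percent_difference_pct: float
    similarity_category: str
    hot_to_cold_pct: float
    cold_to_hot_pct: float
    common_space_decrease_pct: float
    common_space_increase_pct: float
    common_space_decrease_pct_total_area: float
    common_space_increase_pct_total_area: float
    centroid_distance_km: float
    bearing_deg: float
    compass_sector: str
    rmse: float
    bhattacharyya_distance: float
    n_active_cells: int
    n_significant_positive_present: int
    warnings: list = field(default_factory=list)

    def to_row(self) -> dict:
        d = asdict(self)
        d["warnings"] = ";".join(self.warnings)
        return d

    @staticmethod
    def from_row(row: dict) -> "CostReport":
        row = dict(row)
        w = row.get("warnings", "")
        row["warnings"] = [] if (not isinstance(w, str) or w == "") else w.split(";")
        return CostReport(**row)


def single_species_costs(present_density, future_density,
                         grid: LatticeGrid, adjacency: Adjacency,
                         z_crit: float = 1.96, floor: float = 0.0,
                         cell_threshold_pct: float = 33.0) -> dict:
    """Methods 1–4 for one species' present/future density surfaces.

    Returns a flat dict (one row of the single-species cost table): relative
    population change, overall percent difference with its category, G*
    hot/cold transition percentages, and the weighted-centroid displacement.
    """
    rel = relative_population_change(present_density, future_density)
    share, category = overall_percent_difference(
        present_density, future_density, cell_threshold_pct=cell_threshold_pct,
        floor=floor)
    zp = gstar_z(present_density, adjacency)
    zf = gstar_z(future_density, adjacency)
    h2c, c2h, _ = hot_cold_transitions(zp, zf, z_crit=z_crit)
    cp = weighted_centroid(present_density, grid=grid)
    cf = weighted_centroid(future_density, grid=grid)
    dist = haversine_km((cp.lon, cp.lat), (cf.lon, cf.lat))
    return {
        "relative_population_change_pct": rel,
        "overall_percent_difference_pct": share,
        "similarity_category": category,
        "hot_to_cold_pct": h2c,
        "cold_to_hot_pct": c2h,
        "centroid_distance_km": dist,
    }


def build_cost_report(pair: str,
                      present_density, future_density,
                      present_cst, future_cst,
                      grid: LatticeGrid, adjacency: Adjacency,
                      z_crit: float = 1.96, floor_quantile: float = 0.05,
                      cell_threshold_pct: float = 33.0) -> CostReport:
    """Assemble the full cost report for one species pair (joint-table row).

    Population change and hot/cold transitions run on the (combined) density
    surfaces; the overall percent difference, sign-change percentages,
    centroid displacement, RMSE and Bhattacharyya distance run on the two
    common-spatial-trend posteriors.  Because trend values are signed and can
    be near zero, the per-cell percent-change denominator is floored at a low
    quantile of |present trend| (recorded in the report warnings).
    """
    warnings: list[str] = []
    pm = np.asarray(present_cst.mean, float)
    fm = np.asarray(future_cst.mean, float)
    nz = np.abs(pm[pm != 0])
    floor = float(np.quantile(nz, floor_quantile)) if nz.size else 0.0
    if np.array_equal(pm, fm):
        share, category = 0.0, similarity_category(0.0)
    else:
        if floor > 0:
            warnings.append(f"trend percent-difference floor={floor:.6g} "
                            f"(quantile {floor_quantile} of |present trend|)")
        share, category = overall_percent_difference(
            pm, fm, cell_threshold_pct=cell_threshold_pct, floor=floor)
    rel = relative_population_change(present_density, future_density)
    zp = gstar_z(present_density, adjacency)
    zf = gstar_z(future_density, adjacency)
    h2c, c2h, _ = hot_cold_transitions(zp, zf, z_crit=z_crit)
    dec, inc, labels = cst_sign_change(present_cst, future_cst)
    n = grid.n_active
    dec_total = 100.0 * float(np.sum(labels == "loss")) / n
    inc_total = 100.0 * float(np.sum(labels == "gain")) / n
    n_sig_pos = int(np.sum(present_cst.q2_5 > 0))
    if math.isnan(dec):
        warnings.append("no significantly positive present common-trend cells; "
                        "sign-change percentages undefined")
    c_present = weighted_centroid(present_cst.mean, grid=grid, positive_only=True)
    c_future = weighted_centroid(future_cst.mean, grid=grid, positive_only=True)
    dist = haversine_km((c_present.lon, c_present.lat), (c_future.lon, c_future.lat))
    if dist > 0:
        bearing, sector = bearing_and_sector((c_present.lon, c_present.lat),
                                             (c_future.lon, c_future.lat))
    else:
        bearing, sector = float("nan"), "none"
        warnings.append("identical centroids: bearing undefined")
    rmse = rmse_surfaces(present_cst.mean, future_cst.mean)
    bd = bhattacharyya_distance(present_cst.mean, future_cst.mean)
    return CostReport(
        pair=pair,
        relative_population_change_pct=rel,
        overall_percent_difference_pct=share,
        similarity_category=category,
        hot_to_cold_pct=h2c,
        cold_to_hot_pct=c2h,
        common_space_decrease_pct=dec,
        common_space_increase_pct=inc,
        common_space_decrease_pct_total_area=dec_total,
        common_space_increase_pct_total_area=inc_total,
        centroid_distance_km=dist,
        bearing_deg=bearing,
        compass_sector=sector,
        rmse=rmse,
        bhattacharyya_distance=bd,
        n_active_cells=n,
        n_significant_positive_present=n_sig_pos,
        warnings=warnings,
    )


def reports_to_csv(reports, path) -> None:
    pd.DataFrame([r.to_row() for r in reports]).to_csv(path, index=False,
                                                       float_format="%.17g")


def reports_from_csv(path):
    df = pd.read_csv(path, keep_default_na=False,
                     na_values=["nan", "NaN", ""]).fillna({"warnings": ""})
    out = []
    for _, row in df.iterrows():
        d = row.to_dict()
        d["warnings"] = d.get("warnings", "") or ""
        out.append(CostReport.from_row(d))
    return out
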