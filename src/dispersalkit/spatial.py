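"""Spatial natal dispersal: net displacement against a home-range threshold.

Spatial dispersal is defined against the scale of an adult-female home range:
a calf has dispersed spatially when its net displacement (Euclidean distance
from its first detection) ends up beyond the radius of a circle with the mean
adult-female 95% kernel home-range area of its natal community.  Because
young animals also make temporary long-range forays ("sorties"), a final
position beyond the threshold is confirmed by fitting a smoothed line to the
displacement-versus-age series: only individuals for which more than half of
the detections after the smoothed line first exceeds the threshold are
actually beyond it count as spatial dispersers; the rest are non-dispersers
that made sorties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "project_coordinates",
    "displacement_series",
    "DisplacementSeries",
    "kernel_home_range",
    "HomeRangeEstimate",
    "threshold_radii",
    "classify_spatial",
    "SpatialOutcome",
    "combine_outcomes",
    "DispersalRecord",
    "home_range_equivalents",
]

# WGS84
_A_KM = 6378.137
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)

#: sorties before this age are attributed to travel with the mother
WITH_MOTHER_AGE_MONTHS = 8.0


def _meridian_arc(phi):
    e2, e4, e6 = _E2, _E2**2, _E2**3
    return _A_KM * (
        (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * np.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * np.sin(4 * phi)
        - (35 * e6 / 3072) * np.sin(6 * phi)
    )


def _tm_forward(lon, lat, lon0, lat0):
    """Ellipsoidal transverse-Mercator forward projection (km), k0 = 1."""
    phi = np.radians(lat)
    lam = np.radians(lon)
    lam0 = np.radians(lon0)
    phi0 = np.radians(lat0)

    n = _A_KM / np.sqrt(1 - _E2 * np.sin(phi) ** 2)
    t = np.tan(phi) ** 2
    c = _EP2 * np.cos(phi) ** 2
    a = (lam - lam0) * np.cos(phi)
    m = _meridian_arc(phi)
    m0 = _meridian_arc(phi0)

    x = n * (a + (1 - t + c) * a**3 / 6
             + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a**5 / 120)
    y = (m - m0) + n * np.tan(phi) * (
        a**2 / 2
        + (5 - t + 9 * c + 4 * c**2) * a**4 / 24
        + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a**6 / 720
    )
    return x, y


def _tm_inverse(x, y, lon0, lat0):
    """Inverse of :func:`_tm_forward`."""
    m0 = _meridian_arc(np.radians(lat0))
    m = m0 + y
    mu = m / (_A_KM * (1 - _E2 / 4 - 3 * _E2**2 / 64 - 5 * _E2**3 / 256))
    e1 = (1 - np.sqrt(1 - _E2)) / (1 + np.sqrt(1 - _E2))
    phi1 = (
        mu
        + (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
        + (151 * e1**3 / 96) * np.sin(6 * mu)
        + (1097 * e1**4 / 512) * np.sin(8 * mu)
    )
    c1 = _EP2 * np.cos(phi1) ** 2
    t1 = np.tan(phi1) ** 2
    n1 = _A_KM / np.sqrt(1 - _E2 * np.sin(phi1) ** 2)
    r1 = _A_KM * (1 - _E2) / (1 - _E2 * np.sin(phi1) ** 2) ** 1.5
    d = x / n1

    phi = phi1 - (n1 * np.tan(phi1) / r1) * (
        d**2 / 2
        - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24
        + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2 - 3 * c1**2) * d**6 / 720
    )
    lam = np.radians(lon0) + (
        d
        - (1 + 2 * t1 + c1) * d**3 / 6
        + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2 + 24 * t1**2) * d**5 / 120
    ) / np.cos(phi1)
    return np.degrees(lam), np.degrees(phi)


def project_coordinates(detections: pd.DataFrame, lon0=None, lat0=None) -> pd.DataFrame:
    """Attach planar ``x_km`` / ``y_km`` coordinates to a detection table.

    Geographic input (``lon`` / ``lat`` columns) is projected with a local
    transverse-Mercator projection centred on the data (or on ``lon0`` /
    ``lat0``); planar input (``x_km`` / ``y_km`` already present, no
    geographic columns) passes through unchanged.  Mixing rows with and
    without geographic coordinates is an error.
    """
    out = detections.copy()
    has_geo = {"lon", "lat"}.issubset(out.columns)
    has_planar = {"x_km", "y_km"}.issubset(out.columns)
    if not has_geo:
        if not has_planar:
            raise ValueError("need either lon/lat or x_km/y_km columns")
        return out
    lon = out["lon"].to_numpy(dtype=float)
    lat = out["lat"].to_numpy(dtype=float)
    if np.isnan(lon).any() or np.isnan(lat).any():
        if has_planar and not (np.isnan(lon).all() and np.isnan(lat).all()):
            raise ValueError("mixed planar/geographic input")
        raise ValueError("missing coordinates in lon/lat columns")
    if lon0 is None:
        lon0 = float(np.mean(lon))
    if lat0 is None:
        lat0 = float(np.mean(lat))
    x, y = _tm_forward(lon, lat, lon0, lat0)
    out["x_km"] = x
    out["y_km"] = y
    out.attrs["projection_origin"] = (lon0, lat0)
    return out


@dataclass
class DisplacementSeries:
    """Net displacement of one calf from its first detection location."""

    calf_id: object
    table: pd.DataFrame  # columns: occasion, age_months, distance_km
    final_km: float
    max_km: float


def displacement_series(calf_detections: pd.DataFrame) -> DisplacementSeries:
    """Net-displacement series for one calf: distance from first detection.

    ``calf_detections`` needs ``x_km``, ``y_km``, ``occasion`` and
    ``age_months`` columns; rows are sorted chronologically by occasion.
    """
    if len(calf_detections) < 2:
        raise ValueError("need at least 2 detections for a displacement series")
    d = calf_detections.sort_values("occasion")
    xy = d[["x_km", "y_km"]].to_numpy(dtype=float)
    dist = np.hypot(xy[:, 0] - xy[0, 0], xy[:, 1] - xy[0, 1])
    cid = d["id"].iloc[0] if "id" in d.columns else None
    table = pd.DataFrame(
        {
            "occasion": d["occasion"].to_numpy(),
            "age_months": d["age_months"].to_numpy(dtype=float),
            "distance_km": dist,
        }
    )
    return DisplacementSeries(cid, table, float(dist[-1]), float(dist.max()))


@dataclass
class HomeRangeEstimate:
    individual_id: object
    area_km2: float
    bandwidth_km: tuple
    n_locations: int


def kernel_home_range(
    locations,
    individual_id=None,
    min_locations: int = 10,
    isopleth: float = 0.95,
    grid_size: int = 200,
    variance_corrected: bool = True,
) -> HomeRangeEstimate:
    """95% kernel home range from an (n, 2) array of planar locations (km).

    A Gaussian product kernel with the bivariate-normal reference bandwidth
    ``h_j = sigma_j * n**(-1/6)`` is evaluated on a ``grid_size``-squared grid
    padded by three bandwidths, and the area of the smallest set of cells
    holding ``isopleth`` of the density mass is returned.

    With ``variance_corrected`` (default), locations are shrunk about their
    centroid by ``sqrt(1 - n**(-1/3))`` before smoothing so that the
    dispersion of the smoothed density matches the sample dispersion; without
    the correction the kernel inflates every axis variance by ``h_j**2`` and
    the isopleth area is biased upward by ~``n**(-1/3)``.
    """
    pts = np.asarray(locations, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("locations must be (n, 2)")
    n = pts.shape[0]
    if n < min_locations:
        raise ValueError(f"need at least {min_locations} locations, got {n}")
    sd = pts.std(axis=0, ddof=1)
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise ValueError("degenerate location cloud (zero variance)")

    h = sd * n ** (-1.0 / 6.0)
    if variance_corrected:
        shrink = np.sqrt(1.0 - n ** (-1.0 / 3.0))
        pts = pts.mean(axis=0) + (pts - pts.mean(axis=0)) * shrink

    lo = pts.min(axis=0) - 3.0 * h
    hi = pts.max(axis=0) + 3.0 * h
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])

    # separable Gaussian kernel: density = Kx @ Ky^T accumulated over points
    ux = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / h[0]) ** 2)
    uy = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / h[1]) ** 2)
    dens = ux @ uy.T  # (grid_size, grid_size), unnormalised
    mass = dens.ravel()
    mass = mass / mass.sum()
    order = np.argsort(mass)[::-1]
    csum = np.cumsum(mass[order])
    n_cells = int(np.searchsorted(csum, isopleth) + 1)
    area = n_cells * cell_area
    return HomeRangeEstimate(individual_id, float(area), (float(h[0]), float(h[1])), n)


def threshold_radii(
    home_ranges: pd.DataFrame, membership: dict
) -> pd.DataFrame:
    """Per-community spatial-dispersal threshold radii.

    The threshold for a community is the radius of a circle with the mean
    member 95% home-range area: ``r = sqrt(mean_area / pi)``.

    Parameters
    ----------
    home_ranges : DataFrame with columns ``id`` and ``area_km2``.
    membership : mapping individual id -> community label.

    Returns
    -------
    DataFrame indexed by community with ``mean_area_km2``, ``radius_km`` and
    ``n_members``.  Communities with no usable member estimate get the global
    mean radius, with a warning.
    """
    hr = home_ranges.copy()
    hr["community"] = hr["id"].map(membership)
    hr = hr.dropna(subset=["community"])
    communities = sorted(set(membership.values()))
    global_mean = float(hr["area_km2"].mean()) if len(hr) else np.nan
    rows = []
    for comm in communities:
        sub = hr[hr["community"] == comm]
        if len(sub) == 0:
            warnings.warn(
                f"community {comm!r} has no usable home-range estimate; "
                "using global mean area"
            )
            area = global_mean
        else:
            area = float(sub["area_km2"].mean())
        rows.append(
            {
                "community": comm,
                "mean_area_km2": area,
                "radius_km": float(np.sqrt(area / np.pi)),
                "n_members": int(len(sub)),
            }
        )
    return pd.DataFrame(rows).set_index("community")


@dataclass
class SpatialOutcome:
    """Spatial-dispersal classification of one calf."""

    calf_id: object
    final_km: float
    max_km: float
    threshold_km: float
    spatial_dispersal: int
    dispersal_age_months: float | None = None
    sortie_ages: list = field(default_factory=list)
    post_crossing_fraction: float | None = None
    low_confidence: bool = False

    def first_sortie_age(self, exclude_with_mother: bool = True) -> float | None:
        """Age of first sortie; by default sorties before weaning onset
        (< 8 months, likely travel with the mother) are excluded."""
        ages = [
            a
            for a in self.sortie_ages
            if not (exclude_with_mother and a < WITH_MOTHER_AGE_MONTHS)
        ]
        return min(ages) if ages else None


def _excursion_starts(beyond: np.ndarray, ages: np.ndarray) -> list:
    """Ages at which maximal runs of beyond-threshold detections start."""
    starts = []
    prev = False
    for b, a in zip(beyond, ages):
        if b and not prev:
            starts.append(float(a))
        prev = b
    return starts


def classify_spatial(
    series: DisplacementSeries,
    threshold_km: float,
    span: float = 0.5,
) -> SpatialOutcome:
    """Classify spatial dispersal from a net-displacement series.

    If the final detection is within the threshold the calf is not a spatial
    disperser and every beyond-threshold excursion is recorded as a sortie.
    Otherwise a local-linear (tricube-weighted) smoother with the given span
    is fitted to distance versus age; detections from the start of the
    smoothed line's final above-threshold spell onward are counted, and the
    calf is a spatial disperser only when more than half of them are beyond
    the threshold.  (Anchoring on the final spell rather than the first
    crossing keeps early scatter while still travelling with the mother from
    backdating the dispersal.)  Dispersal age is the age of the first
    observed exceedance at or after that crossing; earlier exceedances are
    sorties.  With fewer than 4 detections the smoother is skipped and the
    final-distance rule decides, flagged low-confidence.
    """
    t = series.table
    ages = t["age_months"].to_numpy(dtype=float)
    dist = t["distance_km"].to_numpy(dtype=float)
    beyond = dist > threshold_km

    def _sorties(mask=None):
        m = beyond if mask is None else (beyond & mask)
        return _excursion_starts(m, ages)

    if series.final_km <= threshold_km:
        return SpatialOutcome(
            series.calf_id, series.final_km, series.max_km, threshold_km,
            spatial_dispersal=0, sortie_ages=_sorties(),
        )

    if len(t) < 4:
        return SpatialOutcome(
            series.calf_id, series.final_km, series.max_km, threshold_km,
            spatial_dispersal=1, dispersal_age_months=float(ages[beyond][0]),
            low_confidence=True,
        )

    fitted = lowess(dist, ages, frac=span, it=0, return_sorted=False)
    over = fitted > threshold_km
    if not over.any():
        # smoothed line never sustains an excursion: sorties only
        return SpatialOutcome(
            series.calf_id, series.final_km, series.max_km, threshold_km,
            spatial_dispersal=0, sortie_ages=_sorties(),
        )
    # start of the last maximal above-threshold run of the fitted line
    idx_over = np.flatnonzero(over)
    run_breaks = np.flatnonzero(np.diff(idx_over) > 1)
    start_idx = int(idx_over[run_breaks[-1] + 1] if run_breaks.size else idx_over[0])
    cross_age = float(ages[start_idx])
    post = ages >= cross_age
    frac = float(beyond[post].mean())
    if frac > 0.5:
        first_beyond = ages[beyond & post][0] if (beyond & post).any() else cross_age
        return SpatialOutcome(
            series.calf_id, series.final_km, series.max_km, threshold_km,
            spatial_dispersal=1, dispersal_age_months=float(first_beyond),
            sortie_ages=_sorties(~post), post_crossing_fraction=frac,
        )
    return SpatialOutcome(
        series.calf_id, series.final_km, series.max_km, threshold_km,
        spatial_dispersal=0, sortie_ages=_sorties(), post_crossing_fraction=frac,
    )


#: order of the four dispersal classes used throughout
DISPERSAL_CLASSES = ("none", "social", "spatial", "social-and-spatial")


@dataclass
class DispersalRecord:
    """Final four-way dispersal classification of one calf."""

    calf_id: object
    dispersal_class: str
    social_flag: int
    spatial_flag: int
    final_km: float
    max_km: float
    social_age_months: float | None
    spatial_age_months: float | None
    sortie_ages: list
    natal_community: object
    undetermined: bool = False
    single_terminal_social: bool = False


def combine_outcomes(social, spatial: SpatialOutcome) -> DispersalRecord:
    """Combine social and spatial outcomes into the four-way classification:
    none / social / spatial / social-and-spatial."""
    s = int(social.social_dispersal) if social.social_dispersal is not None else 0
    p = int(spatial.spatial_dispersal)
    cls = {
        (0, 0): "none",
        (1, 0): "social",
        (0, 1): "spatial",
        (1, 1): "social-and-spatial",
    }[(s, p)]
    return DispersalRecord(
        calf_id=spatial.calf_id,
        dispersal_class=cls,
        social_flag=s,
        spatial_flag=p,
        final_km=spatial.final_km,
        max_km=spatial.max_km,
        social_age_months=social.dispersal_age_months,
        spatial_age_months=spatial.dispersal_age_months,
        sortie_ages=list(spatial.sortie_ages),
        natal_community=social.natal_community,
        undetermined=bool(getattr(social, "undetermined", False)),
        single_terminal_social=bool(getattr(social, "single_terminal", False)),
    )


def home_range_equivalents(total_area_km2: float, mean_home_range_km2: float) -> int:
    """Number of non-overlapping mean home ranges fitting in a study area."""
    if mean_home_range_km2 <= 0:
        raise ValueError("home-range area must be positive")
    return int(round(total_area_km2 / mean_home_range_km2))
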