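"""Great-circle distances, Matern spatial covariance, and area blocks.

The spatial random effect assumes trait similarity decays with
great-circle distance following a Matern correlation function

    rho(d) = (2^(1-kappa) / Gamma(kappa)) * (d/phi)^kappa * K_kappa(d/phi)

with range ``phi`` and smoothness ``kappa`` (K is the modified Bessel
function of the second kind).  Two canonical parameter sets are
provided: a "local" set (phi = 1.25, kappa = 1) under which correlation
is negligible beyond roughly 1000 km, and a "regional" set (phi = 17,
kappa = 1) allowing diffusion over several thousand kilometres.
Distances are measured in great-circle degree-equivalents
(1 degree = 111.195 km), so phi is on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.special import kv

from .covariance import CovarianceStructure
from .errors import IntegrityError, NumericalError

EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = 111.195

#: canonical Matern parameter sets
LOCAL_PARAMS = None  # set below, after SpatialParams is defined
REGIONAL_PARAMS = None


@dataclass(frozen=True)
class SpatialParams:
    """Matern range (phi, degree-equivalents) and smoothness (kappa)."""

    phi: float
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.phi <= 0 or self.kappa <= 0:
            raise ValueError("phi and kappa must be > 0")


LOCAL_PARAMS = SpatialParams(phi=1.25, kappa=1.0)
REGIONAL_PARAMS = SpatialParams(phi=17.0, kappa=1.0)


def _check_coords(coords: pd.DataFrame) -> pd.DataFrame:
    required = {"taxon", "latitude", "longitude"}
    if not required.issubset(coords.columns):
        raise ValueError(f"coordinates need columns {sorted(required)}")
    if coords["taxon"].duplicated().any():
        raise IntegrityError("duplicate taxon in coordinates")
    lat = coords["latitude"].to_numpy(float)
    lon = coords["longitude"].to_numpy(float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon <= -180) | (lon > 180)):
        raise ValueError("longitude out of (-180, 180]")
    return coords


def greatcircle_distances(coords: pd.DataFrame, planar: bool = False) -> pd.DataFrame:
    """Pairwise distances in degree-equivalents (haversine / 111.195 km).

    ``planar=True`` switches to naive Euclidean distance on (lat, lon)
    degrees, kept only for sensitivity checks.
    """
    coords = _check_coords(coords)
    taxa = coords["taxon"].tolist()
    lat = np.radians(coords["latitude"].to_numpy(float))
    lon = np.radians(coords["longitude"].to_numpy(float))
    if planar:
        dlat = coords["latitude"].to_numpy(float)
        dlon = coords["longitude"].to_numpy(float)
        D = np.sqrt(
            (dlat[:, None] - dlat[None, :]) ** 2
            + (dlon[:, None] - dlon[None, :]) ** 2
        )
    else:
        sin_dlat = np.sin((lat[:, None] - lat[None, :]) / 2.0)
        sin_dlon = np.sin((lon[:, None] - lon[None, :]) / 2.0)
        a = sin_dlat**2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * sin_dlon**2
        a = np.clip(a, 0.0, 1.0)
        km = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
        D = km / KM_PER_DEGREE
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=taxa, columns=taxa)


def matern_correlation(d, p: SpatialParams) -> np.ndarray:
    """Matern correlation at distance(s) ``d`` (same units as phi)."""
    d = np.asarray(d, float)
    scaled = d / p.phi
    out = np.ones_like(scaled)
    pos = scaled > 0
    with np.errstate(over="ignore", invalid="ignore"):
        val = (
            (2.0 ** (1.0 - p.kappa) / gamma_fn(p.kappa))
            * scaled[pos] ** p.kappa
            * kv(p.kappa, scaled[pos])
        )
    if not np.all(np.isfinite(val)):
        raise NumericalError("non-finite Bessel evaluation in Matern correlation")
    out[pos] = val
    return out


def matern_covariance(d: pd.DataFrame, p: SpatialParams, name: str = "spatial") -> CovarianceStructure:
    """Matern correlation matrix (unit diagonal) as a spatial structure."""
    D = d.to_numpy(float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix must have zero diagonal")
    taxa = list(d.index) if isinstance(d, pd.DataFrame) else [str(i) for i in range(len(D))]
    C = matern_correlation(D, p)
    np.fill_diagonal(C, 1.0)
    return CovarianceStructure(name=name, kind="spatial", taxa=taxa, matrix=C)


def area_effect_structure(g: pd.DataFrame | dict, name: str = "areas") -> CovarianceStructure:
    """Exchangeable within-area covariance: 1 if same area, else 0.

    Equivalent to an iid area-level intercept; geographic distances
    between areas are deliberately ignored.
    """
    if isinstance(g, dict):
        g = pd.DataFrame({"taxon": list(g.keys()), "area": list(g.values())})
    if not {"taxon", "area"}.issubset(g.columns):
        raise ValueError("group structure needs columns 'taxon' and 'area'")
    if g["taxon"].duplicated().any():
        raise IntegrityError("duplicate taxon in area assignment")
    missing = g["area"].isna()
    if missing.any():
        raise IntegrityError(
            f"unlabeled taxa: {g.loc[missing, 'taxon'].tolist()[:5]}"
        )
    taxa = g["taxon"].tolist()
    codes = pd.Categorical(g["area"]).codes
    C = (codes[:, None] == codes[None, :]).astype(float)
    return CovarianceStructure(name=name, kind="group", taxa=taxa, matrix=C)
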