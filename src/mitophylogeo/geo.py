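"""Ordinary kriging of per-site scalars (haplogroup frequencies, diversity).

Sampling sites are sparse and irregular (population samples scattered from
Europe to Iran), so interpolated surfaces come from ordinary kriging: at
every grid cell the prediction is a weighted mean of the observations,
with weights solving the variogram-based linear system under a unit-sum
constraint.  Distances are great-circle (haversine), not planar.

The variogram is estimated empirically in distance bins and fitted by
weighted least squares (weights = pair counts) to a spherical or
exponential model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoSample:
    lon: float
    lat: float
    value: float
    label: str = ""
    is_frequency: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValueError("coordinates must be finite")
        if self.is_frequency and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"frequency value {self.value} outside [0, 1]")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in kilometres (vectorised)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass(frozen=True)
class VariogramModel:
    """Bounded variogram: gamma(0)=0, rising from the nugget to the sill."""

    family: str            # "spherical" or "exponential"
    nugget: float
    sill: float
    range_km: float

    def __post_init__(self) -> None:
        if self.family not in ("spherical", "exponential"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_km <= 0:
            raise ValueError("need 0 <= nugget <= sill and range > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        if self.family == "spherical":
            x = np.clip(h / self.range_km, 0, 1)
            struct = psill * (1.5 * x - 0.5 * x**3)
        else:
            struct = psill * (1.0 - np.exp(-3.0 * h / self.range_km))
        out = np.where(h > 0, self.nugget + struct, 0.0)
        return out


def empirical_variogram(
    samples: Sequence[GeoSample], n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned (distance, semivariance, pair count) from all sample pairs.

    gamma(h) = mean over pairs in the bin of half the squared value
    difference, with great-circle distances.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    lons = np.array([s.lon for s in samples])
    lats = np.array([s.lat for s in samples])
    vals = np.array([s.value for s in samples])
    iu = np.triu_indices(len(samples), k=1)
    h = haversine_km(lons[iu[0]], lats[iu[0]], lons[iu[1]], lats[iu[1]])
    sv = 0.5 * (vals[iu[0]] - vals[iu[1]]) ** 2
    if np.all(h == 0):
        raise ValueError("all samples co-located")
    edges = np.linspace(0, h.max() * (1 + 1e-9), n_bins + 1)
    which = np.digitize(h, edges) - 1
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            gammas.append(float(sv[mask].mean()))
            counts.append(int(mask.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(
    samples: Sequence[GeoSample],
    family: str = "exponential",
    n_bins: int = 10,
    nugget: float | None = None,
) -> VariogramModel:
    """Weighted least-squares fit of a variogram model to the empirical bins
    (weights = pair counts).  ``nugget`` may be fixed; default fits it."""
    h, g, c = empirical_variogram(samples, n_bins=n_bins)
    w = np.sqrt(c)
    g_max = max(g.max(), 1e-12)
    h_max = max(h.max(), 1e-9)

    fixed_nugget = nugget

    def residual(theta):
        if fixed_nugget is None:
            n0, psill, rng = theta
        else:
            psill, rng = theta
            n0 = fixed_nugget
        model = VariogramModel(family, max(n0, 0), max(n0, 0) + max(psill, 1e-15), max(rng, 1e-6))
        return w * (model(h) - g)

    if fixed_nugget is None:
        x0 = [0.0, g_max, h_max / 2]
        lb = [0.0, 1e-15, 1e-6]
        ub = [g_max + 1e-12, 10 * g_max + 1e-9, 10 * h_max]
    else:
        x0 = [g_max, h_max / 2]
        lb = [1e-15, 1e-6]
        ub = [10 * g_max + 1e-9, 10 * h_max]
    sol = least_squares(residual, x0, bounds=(lb, ub))
    if fixed_nugget is None:
        n0, psill, rng = sol.x
    else:
        psill, rng = sol.x
        n0 = fixed_nugget
    return VariogramModel(family, float(n0), float(n0 + psill), float(rng))


@dataclass
class GeoSurface:
    lons: np.ndarray       # grid longitudes (nx,)
    lats: np.ndarray       # grid latitudes (ny,)
    values: np.ndarray     # (ny, nx)
    mask: np.ndarray       # (ny, nx) True where the cell has no support
    weight_sum_error: float = 0.0

    def clipped(self, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
        """Reporting-layer clip for frequency surfaces."""
        return np.clip(self.values, lo, hi)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("lat\\lon\t" + "\t".join(f"{x:.4f}" for x in self.lons) + "\n")
            for lat, row, mrow in zip(self.lats, self.values, self.mask):
                cells = ["NA" if m else f"{v:.6g}" for v, m in zip(row, mrow)]
                fh.write(f"{lat:.4f}\t" + "\t".join(cells) + "\n")


def ordinary_krige(
    samples: Sequence[GeoSample],
    model: VariogramModel,
    grid_lons: np.ndarray,
    grid_lats: np.ndarray,
    support_radius_km: float | None = None,
    jitter_duplicates: bool = False,
) -> GeoSurface:
    """Ordinary kriging on a lon/lat grid.

    Per cell, weights solve ``[[Gamma, 1], [1', 0]] [w, mu] = [gamma0, 1]``
    where Gamma holds pairwise sample semivariances.  With a zero nugget
    the surface honours the data exactly at sample locations.  Duplicate
    sample locations make the system singular; the default is to fail,
    optionally they are jittered by ~1 m.
    """
    lons = np.array([s.lon for s in samples], dtype=float)
    lats = np.array([s.lat for s in samples], dtype=float)
    vals = np.array([s.value for s in samples], dtype=float)
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to krige")

    dmat = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    off_diag = dmat[~np.eye(n, dtype=bool)]
    if np.any(off_diag == 0):
        if not jitter_duplicates:
            raise ValueError(
                "duplicate sample locations make the kriging system singular; "
                "pass jitter_duplicates=True or deduplicate"
            )
        rng = np.random.default_rng(0)
        lons = lons + rng.normal(0, 1e-5, n)
        lats = lats + rng.normal(0, 1e-5, n)
        dmat = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])

    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = model(dmat)
    A[:n, n] = 1.0
    A[n, :n] = 1.0

    grid_lons = np.asarray(grid_lons, dtype=float)
    grid_lats = np.asarray(grid_lats, dtype=float)
    values = np.zeros((grid_lats.size, grid_lons.size))
    mask = np.zeros_like(values, dtype=bool)
    if support_radius_km is None:
        support_radius_km = np.inf
    max_weight_err = 0.0
    lu_piv = None
    from scipy.linalg import lu_factor, lu_solve

    lu_piv = lu_factor(A)
    for iy, glat in enumerate(grid_lats):
        d0 = haversine_km(grid_lons, np.full_like(grid_lons, glat), lons[:, None], lats[:, None])
        # d0 shape: (n, nx)
        for ix in range(grid_lons.size):
            rhs = np.empty(n + 1)
            rhs[:n] = model(d0[:, ix])
            rhs[n] = 1.0
            sol = lu_solve(lu_piv, rhs)
            w = sol[:n]
            max_weight_err = max(max_weight_err, abs(w.sum() - 1.0))
            values[iy, ix] = float(w @ vals)
            if d0[:, ix].min() > support_radius_km:
                mask[iy, ix] = True
    return GeoSurface(
        lons=grid_lons, lats=grid_lats, values=values, mask=mask,
        weight_sum_error=max_weight_err,
    )


def default_grid(
    samples: Sequence[GeoSample], n: int = 25, margin: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """A lattice covering the samples' bounding box plus a fractional margin."""
    lons = np.array([s.lon for s in samples])
    lats = np.array([s.lat for s in samples])
    dx = max(lons.max() - lons.min(), 1e-3) * margin
    dy = max(lats.max() - lats.min(), 1e-3) * margin
    return (
        np.linspace(lons.min() - dx, lons.max() + dx, n),
        np.linspace(lats.min() - dy, lats.max() + dy, n),
    )


def read_geosamples_tsv(path: str, is_frequency: bool = False) -> list[GeoSample]:
    """TSV columns: label, lon, lat, value (header optional)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("label", "site"):
                continue
            label, lon, lat, value = parts[:4]
            out.append(
                GeoSample(
                    lon=float(lon), lat=float(lat), value=float(value),
                    label=label, is_frequency=is_frequency,
                )
            )
    return out
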