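"""Multi-radius covariate summaries around survey-grid centroids.

Covariate rasters are summarised as mean pixel values within a ladder of
buffer radii (0 m at the centroid pixel up to 10 km by default, 100-m
steps).  The resulting :class:`BufferStack` is the substrate for the
continuous scale-of-effect parameters: a radius anywhere inside the ladder
is served by piecewise-linear interpolation between the tabulated radii.

Also hosts the collinearity screens applied before model fitting: the
pairwise Pearson screen at three reference radii and variance inflation
factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_RADII = np.arange(0, 10_100, 100, dtype=float)  # 101 radii, 0..10 km
#: radius used for covariates that do not get scale selection (m)
FIXED_RADIUS = 564.0
#: reference radii for the pairwise correlation screen (m)
SCREEN_RADII = (200.0, 5000.0, 10_000.0)


# ---------------------------------------------------------------------------
# rasters


@dataclass
class CovariateRaster:
    """Single-band raster on a regular grid in projected coordinates.

    ``values[0, 0]`` is the north-west pixel; ``origin`` is the coordinate
    of the *outer corner* of that pixel (west edge, north edge), matching
    the ESRI ASCII grid convention used by :mod:`avitrend.io`.
    """

    name: str
    year: int
    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]  # (west, north)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        valid = self.values != self.nodata
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError(f"raster {self.name!r} has non-finite data pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (easting, northing) arrays of pixel-center coordinates."""
        nrow, ncol = self.shape
        west, north = self.origin
        x = west + (np.arange(ncol) + 0.5) * self.cell_size
        y = north - (np.arange(nrow) + 0.5) * self.cell_size
        return x, y

    def contains(self, easting: float, northing: float) -> bool:
        nrow, ncol = self.shape
        west, north = self.origin
        return (
            west <= easting <= west + ncol * self.cell_size
            and north - nrow * self.cell_size <= northing <= north
        )

    def value_at(self, easting: float, northing: float) -> float:
        """Value of the pixel containing (easting, northing)."""
        nrow, ncol = self.shape
        west, north = self.origin
        col = int(min((easting - west) // self.cell_size, ncol - 1))
        row = int(min((north - northing) // self.cell_size, nrow - 1))
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ValueError(f"point ({easting}, {northing}) outside raster {self.name!r}")
        v = self.values[row, col]
        return math.nan if v == self.nodata else float(v)


def buffer_means(
    raster: CovariateRaster,
    easting: float,
    northing: float,
    radii: np.ndarray,
) -> np.ndarray:
    """Mean of non-nodata pixel values whose center lies within each radius.

    Radius 0 returns the value of the pixel containing the point.  A radius
    whose disc contains no valid pixel yields NaN.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    if not raster.contains(easting, northing):
        raise ValueError(
            f"centroid ({easting}, {northing}) outside raster {raster.name!r}"
        )
    x, y = raster.pixel_centers()
    dx = x[None, :] - easting
    dy = y[:, None] - northing
    dist2 = dx * dx + dy * dy
    valid = raster.values != raster.nodata
    vals = raster.values

    out = np.full(radii.shape, np.nan)
    for i, r in enumerate(radii):
        if r == 0:
            out[i] = raster.value_at(easting, northing)
            continue
        mask = (dist2 <= r * r) & valid
        if mask.any():
            out[i] = vals[mask].mean()
    return out


def summarize_buffers(
    raster: CovariateRaster,
    centroids: pd.DataFrame,
    radii: np.ndarray = DEFAULT_RADII,
) -> pd.DataFrame:
    """Buffer-mean table for one covariate-year raster.

    Parameters
    ----------
    centroids
        Frame with columns ``grid_id``, ``easting``, ``northing``.
    radii
        Ascending radii in meters; 0 means "centroid pixel".

    Returns
    -------
    Tidy frame (grid_id, year, covariate, radius_m, value).
    """
    rows = []
    for rec in centroids.itertuples(index=False):
        means = buffer_means(raster, float(rec.easting), float(rec.northing), radii)
        for r, v in zip(radii, means):
            rows.append((rec.grid_id, raster.year, raster.name, float(r), v))
    return pd.DataFrame(
        rows, columns=["grid_id", "year", "covariate", "radius_m", "value"]
    )


# ---------------------------------------------------------------------------
# buffer stacks


@dataclass
class BufferStack:
    """Per-(grid, year, covariate) buffer means on a shared radius ladder.

    ``values`` is indexed ``[covariate, grid, year, radius]``.  Standardized
    copies (zero mean, unit SD over all finite grid-year-radius entries of a
    covariate) live alongside the raw values; the centring constants are
    kept so model-scale quantities can be mapped back.
    """

    grid_ids: list
    years: list
    covariates: list
    radii: np.ndarray
    values: np.ndarray
    center: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        expect = (len(self.covariates), len(self.grid_ids), len(self.years), len(self.radii))
        if self.values.shape != expect:
            raise ValueError(f"values shape {self.values.shape} != {expect}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_tidy(cls, frame: pd.DataFrame) -> "BufferStack":
        """Build from a tidy (grid_id, year, covariate, radius_m, value) frame."""
        grids = sorted(frame["grid_id"].unique())
        years = sorted(frame["year"].unique())
        covs = list(dict.fromkeys(frame["covariate"]))
        radii = np.sort(frame["radius_m"].unique())
        cube = np.full((len(covs), len(grids), len(years), len(radii)), np.nan)
        gi = {g: i for i, g in enumerate(grids)}
        yi = {y: i for i, y in enumerate(years)}
        ci = {c: i for i, c in enumerate(covs)}
        ri = {r: i for i, r in enumerate(radii)}
        cube[
            frame["covariate"].map(ci),
            frame["grid_id"].map(gi),
            frame["year"].map(yi),
            frame["radius_m"].map(ri),
        ] = frame["value"].to_numpy()
        return cls(grids, years, covs, radii, cube)

    def to_tidy(self) -> pd.DataFrame:
        c, g, y, r = np.meshgrid(
            np.arange(len(self.covariates)),
            np.arange(len(self.grid_ids)),
            np.arange(len(self.years)),
            np.arange(len(self.radii)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "grid_id": np.asarray(self.grid_ids, dtype=object)[g.ravel()],
                "year": np.asarray(self.years)[y.ravel()],
                "covariate": np.asarray(self.covariates, dtype=object)[c.ravel()],
                "radius_m": self.radii[r.ravel()],
                "value": self.values[c.ravel(), g.ravel(), y.ravel(), r.ravel()],
            }
        )

    # -- standardization ----------------------------------------------------

    def standardize(self) -> "BufferStack":
        """Center/scale each covariate jointly over all grid-year-radius cells."""
        out = self.values.copy()
        center, scale = {}, {}
        for j, cov in enumerate(self.covariates):
            block = self.values[j]
            finite = np.isfinite(block)
            mu = float(block[finite].mean())
            sd = float(block[finite].std())
            if sd == 0:
                sd = 1.0
            out[j] = (block - mu) / sd
            center[cov], scale[cov] = mu, sd
        return BufferStack(
            self.grid_ids, self.years, self.covariates, self.radii, out, center, scale
        )

    def destandardize(self) -> "BufferStack":
        if not self.center:
            raise ValueError("stack is not standardized")
        out = self.values.copy()
        for j, cov in enumerate(self.covariates):
            out[j] = out[j] * self.scale[cov] + self.center[cov]
        return BufferStack(self.grid_ids, self.years, self.covariates, self.radii, out)

    # -- interpolation ------------------------------------------------------

    def cov_index(self, covariate: str) -> int:
        try:
            return self.covariates.index(covariate)
        except ValueError:
            raise KeyError(f"unknown covariate {covariate!r}") from None

    def interpolate_at_scale(self, covariate: str, scale_m: float) -> np.ndarray:
        """Covariate values at a continuous radius, all grids x years.

        Piecewise-linear between the tabulated radii; exact at a knot.
        """
        r = self.radii
        if not (r[0] <= scale_m <= r[-1]):
            raise ValueError(
                f"scale {scale_m} m outside tabulated range [{r[0]}, {r[-1]}]"
            )
        j = self.cov_index(covariate)
        hi = int(np.searchsorted(r, scale_m, side="left"))
        if r[hi] == scale_m:
            return self.values[j, :, :, hi].copy()
        lo = hi - 1
        w = (scale_m - r[lo]) / (r[hi] - r[lo])
        return (1 - w) * self.values[j, :, :, lo] + w * self.values[j, :, :, hi]

    def at_radius(self, covariate: str, radius_m: float) -> np.ndarray:
        """Stored values at a tabulated radius (no interpolation)."""
        j = self.cov_index(covariate)
        idx = np.flatnonzero(self.radii == radius_m)
        if idx.size == 0:
            raise KeyError(f"radius {radius_m} m is not tabulated")
        return self.values[j, :, :, int(idx[0])].copy()


def interpolation_weights(radii: np.ndarray, scale_m: float) -> tuple[int, int, float]:
    """(lo, hi, w) such that v(scale) = (1-w)*v[lo] + w*v[hi]."""
    radii = np.asarray(radii, dtype=float)
    if not (radii[0] <= scale_m <= radii[-1]):
        raise ValueError(f"scale {scale_m} outside [{radii[0]}, {radii[-1]}]")
    hi = int(np.searchsorted(radii, scale_m, side="left"))
    if radii[hi] == scale_m:
        return hi, hi, 0.0
    lo = hi - 1
    return lo, hi, float((scale_m - radii[lo]) / (radii[hi] - radii[lo]))


# ---------------------------------------------------------------------------
# collinearity screens


def correlation_screen(
    matrices: dict[str, dict[float, np.ndarray]],
    scales: tuple[float, ...] = SCREEN_RADII,
    threshold: float = 0.6,
) -> dict:
    """Pairwise Pearson screen at the three reference radii.

    Parameters
    ----------
    matrices
        ``{covariate: {scale_m: vector of per-observation values}}``.
        Covariates without scale selection should supply the same vector
        under every scale key (their centroid or 564-m values).
    threshold
        A pair is flagged at a scale iff ``r >= threshold`` there; a
        covariate is proposed for removal iff some pair containing it is
        flagged at >= 2 of the scales.

    Returns
    -------
    dict with keys ``flags`` (frame: cov_a, cov_b, scale_m, r, flagged),
    ``drop`` (list of covariates proposed for removal) and ``degenerate``
    (zero-variance covariates excluded from the screen).
    """
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least two covariates to screen")

    degenerate = []
    for name in names:
        for s in scales:
            v = np.asarray(matrices[name][s], dtype=float)
            ok = np.isfinite(v)
            if ok.sum() < 2 or np.std(v[ok]) == 0:
                degenerate.append(name)
                break
    usable = [n for n in names if n not in degenerate]

    rows = []
    pair_scale_flags: dict[tuple[str, str], int] = {}
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            nflag = 0
            for s in scales:
                va = np.asarray(matrices[a][s], dtype=float)
                vb = np.asarray(matrices[b][s], dtype=float)
                ok = np.isfinite(va) & np.isfinite(vb)  # pairwise-complete
                r = float(np.corrcoef(va[ok], vb[ok])[0, 1])
                flagged = abs(r) >= threshold
                nflag += flagged
                rows.append((a, b, s, r, flagged))
            pair_scale_flags[(a, b)] = nflag

    drop = sorted(
        {
            cov
            for (a, b), n in pair_scale_flags.items()
            if n >= 2
            for cov in (a, b)
        }
    )
    flags = pd.DataFrame(rows, columns=["cov_a", "cov_b", "scale_m", "r", "flagged"])
    return {"flags": flags, "drop": drop, "degenerate": degenerate}


def vif(design: np.ndarray, names: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    Exact collinearity yields ``inf``.  Columns are assumed standardized
    (an intercept is added internally for the auxiliary regressions).
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("design must be 2-D with >= 2 columns")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        tss = np.sum((yj - yj.mean()) ** 2)
        if tss == 0:
            raise ValueError(f"column {names[j]!r} has zero variance")
        r2 = 1.0 - np.sum(resid**2) / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=names, name="vif")


def gap_fill_year(before: CovariateRaster, after: CovariateRaster) -> CovariateRaster:
    """Average two bracketing years pixelwise to fill a missing product year."""
    if before.shape != after.shape or before.cell_size != after.cell_size:
        raise ValueError("bracketing rasters must share a grid")
    vals = np.where(
        (before.values == before.nodata) | (after.values == after.nodata),
        before.nodata,
        0.5 * (before.values + after.values),
    )
    return CovariateRaster(
        name=before.name,
        year=(before.year + after.year) // 2,
        values=vals,
        cell_size=before.cell_size,
        origin=before.origin,
        nodata=before.nodata,
    )
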