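"""Posterior post-processing: trend classification, density conversion,
prediction surfaces with QA masks, and the successional-phase helper.

A regional population is called *increasing* (*decreasing*) when at least
90% of posterior trend draws correspond to a >= +1% (<= -1%) annual rate
of change; everything else is *neither*.  Densities come from dividing
predicted individuals per point count by the effective sampled area
``pi * r^2`` with ``r`` the 90% truncation distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.special import expit

from .covariates import CovariateRaster

TREND_PROB_THRESHOLD = 0.90
TREND_RATE_THRESHOLD = 1.0  # percent per year

MASK_OK = 0
MASK_FLAGGED = 1


def percent_change(mu_r):
    """Annual trend slope (log scale) to percent change per year."""
    return 100.0 * (np.exp(np.asarray(mu_r, dtype=float)) - 1.0)


@dataclass
class TrendClassification:
    species: str
    bcr: object
    mean: float
    lcri: float
    ucri: float
    pr_increase: float
    pr_decrease: float
    label: str


def classify_trend(draws, species: str = "", bcr=None) -> TrendClassification:
    """Classify a species-BCR trend from posterior slope draws."""
    mu = np.asarray(draws, dtype=float).ravel()
    if mu.size < 100:
        raise ValueError("need >= 100 posterior draws to classify a trend")
    pct = percent_change(mu)
    pr_up = float(np.mean(pct >= TREND_RATE_THRESHOLD))
    pr_dn = float(np.mean(pct <= -TREND_RATE_THRESHOLD))
    if pr_up >= TREND_PROB_THRESHOLD:
        label = "increasing"
    elif pr_dn >= TREND_PROB_THRESHOLD:
        label = "decreasing"
    else:
        label = "neither"
    return TrendClassification(
        species=species,
        bcr=bcr,
        mean=float(mu.mean()),
        lcri=float(np.quantile(mu, 0.025)),
        ucri=float(np.quantile(mu, 0.975)),
        pr_increase=pr_up,
        pr_decrease=pr_dn,
        label=label,
    )


def classify_trend_from_summary(mean: float, pr_one_percent: float) -> str:
    """Decision rule applied to a published posterior summary.

    ``pr_one_percent`` is the posterior probability of a >= 1% annual
    change in the direction of the posterior mean (the convention used in
    reported summary tables).
    """
    if not (0.0 <= pr_one_percent <= 1.0):
        raise ValueError("probability outside [0, 1]")
    if pr_one_percent >= TREND_PROB_THRESHOLD:
        return "increasing" if mean > 0 else "decreasing"
    return "neither"


def classify_trend_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify_trend_from_summary` over a summary frame
    with columns ``species, bcr, mean, pr_one_percent``."""
    out = summary.copy()
    out["label"] = [
        classify_trend_from_summary(m, p)
        for m, p in zip(out["mean"], out["pr_one_percent"])
    ]
    return out


def published_trend_summary() -> pd.DataFrame:
    """Published per-species-BCR trend posterior summaries shipped with the
    package (columns species, bcr, mean, lcri, ucri, pr_one_percent)."""
    from importlib import resources

    with resources.files("avitrend").joinpath(
        "data/trend_posterior_summary.csv"
    ).open() as fh:
        t = pd.read_csv(fh, comment="#")
    t["pr_one_percent"] = t.pop("pr_pct") / 100.0
    return t


def classify_posterior(samples, species: str = "") -> pd.DataFrame:
    """One classification row per BCR from a fitted PosteriorSamples."""
    rows = []
    for name in samples.names:
        if not name.startswith("mu["):
            continue
        bcr = name[3:-1]
        tc = classify_trend(samples.extract(name), species=species, bcr=bcr)
        rows.append(
            {
                "species": tc.species,
                "bcr": tc.bcr,
                "mean": tc.mean,
                "lcri": tc.lcri,
                "ucri": tc.ucri,
                "pct_per_year": percent_change(tc.mean),
                "pr_increase": tc.pr_increase,
                "pr_decrease": tc.pr_decrease,
                "label": tc.label,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# density conversion


def density_from_prediction(n_pred, truncation_m: float):
    """Individuals per point count -> birds per square kilometer.

    Divides by the effective sampled area ``pi * r^2`` of one point count,
    with ``r`` the 90% truncation distance in kilometers.
    """
    if truncation_m <= 0:
        raise ValueError("truncation distance must be positive")
    r_km = truncation_m / 1000.0
    return np.asarray(n_pred, dtype=float) / (math.pi * r_km**2)


def scale_posterior_mode(scale_draws, bin_width: float = 100.0) -> float:
    """Posterior mode of a scale parameter via a histogram on the knot grid."""
    s = np.asarray(scale_draws, dtype=float).ravel()
    edges = np.arange(0.0, s.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(s, bins=edges)
    i = int(counts.argmax())
    return float(0.5 * (edges[i] + edges[i + 1]))


# ---------------------------------------------------------------------------
# prediction surfaces


def moving_window_mean(raster: CovariateRaster, radius_m: float) -> np.ndarray:
    """Focal mean with a center-in disc kernel (FFT convolution).

    Radius 0 (or below one cell) returns the raster values unchanged.
    Nodata pixels are excluded from the averaging and stay NaN.
    """
    vals = np.where(raster.values == raster.nodata, np.nan, raster.values)
    if radius_m < raster.cell_size:
        return vals
    ncell = int(radius_m // raster.cell_size)
    ax = np.arange(-ncell, ncell + 1) * raster.cell_size
    kern = (ax[:, None] ** 2 + ax[None, :] ** 2) <= radius_m**2
    kern = kern.astype(float)
    valid = np.isfinite(vals).astype(float)
    filled = np.where(np.isfinite(vals), vals, 0.0)
    num = fftconvolve(filled, kern, mode="same")
    den = fftconvolve(valid, kern, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.5, num / den, np.nan)
    return out


@dataclass
class DensitySurface:
    """Per-pixel median density with its two masks (0 = usable)."""

    density: np.ndarray           # birds / km^2, NaN where masked
    disturbance_mask: np.ndarray  # 1 where point disturbance exceeded training max
    qa_mask: np.ndarray           # 1 where any covariate outside training quantiles
    cell_size: float
    origin: tuple[float, float]
    nodata: float = -9999.0


def predict_density_map(
    samples,
    basis,
    rasters: dict[str, CovariateRaster],
    spec,
    maxd: float,
    standardizers: dict[str, tuple[float, float]] | None = None,
    training_quantiles: dict[str, tuple[float, float]] | None = None,
    disturbance_covariate: str | None = None,
    max_pixels: int = 250_000,
) -> DensitySurface:
    """Median predicted density per pixel from the retained draws.

    Parameters
    ----------
    samples
        Fitted :class:`~avitrend.inference.PosteriorSamples`.
    basis
        The :class:`~avitrend.abundance.TpsBasis` used in fitting
        (evaluated at new pixel coordinates for the suitability field).
    rasters
        One raw :class:`CovariateRaster` per model covariate (all scaled
        and fixed covariates must be present; missing ones raise).
    spec
        Model spec used in fitting.
    maxd
        Truncation distance in meters (defines the effective area).
    standardizers
        ``{covariate: (center, scale)}`` applied to the moving-window
        surfaces so pixels are on the model's standardized scale.
    training_quantiles
        ``{covariate: (lo, hi)}`` 2.5/97.5% bounds of the *standardized*
        training values; pixels outside any bound are QA-masked.

    Notes
    -----
    Moving windows use the posterior mode of each scale parameter
    (564 m for covariates without scale selection).  The survey random
    effect is excluded; the offset is zero, so predictions are individuals
    per point count, converted by ``pi * maxd^2``.
    """
    needed = list(spec.scaled) + list(spec.fixed)
    for name in needed:
        if name not in rasters:
            raise ValueError(f"missing covariate raster: {name!r}")
    ref = rasters[needed[0]]
    npix = ref.shape[0] * ref.shape[1]
    if npix > max_pixels:
        raise ValueError(f"prediction extent too large ({npix} pixels)")

    std = standardizers or {}

    # per-covariate moving-window surfaces on the model (standardized) scale
    surfaces = {}
    for name in spec.scaled:
        mode_r = scale_posterior_mode(samples.extract(f"scale[{name}]"))
        surf = moving_window_mean(rasters[name], mode_r)
        surfaces[name] = _standardize_surface(surf, std, name)
    for name in spec.fixed:
        surf = moving_window_mean(rasters[name], 564.0)
        surfaces[name] = _standardize_surface(surf, std, name)

    nrow, ncol = ref.shape
    flat = {k: v.ravel() for k, v in surfaces.items()}
    valid = np.ones(nrow * ncol, dtype=bool)
    for v in flat.values():
        valid &= np.isfinite(v)

    qa = np.zeros(nrow * ncol, dtype=np.int8)
    if training_quantiles:
        for name, (lo, hi) in training_quantiles.items():
            if name in flat:
                qa |= ((flat[name] < lo) | (flat[name] > hi)) & valid
    dist_mask = np.zeros(nrow * ncol, dtype=np.int8)
    if disturbance_covariate and disturbance_covariate in flat:
        tq = training_quantiles or {}
        hi = tq.get(disturbance_covariate, (None, None))[1]
        if hi is not None:
            dist_mask |= (flat[disturbance_covariate] > hi) & valid

    # design matrices per pixel
    x_cols = [flat[n] for n in spec.fixed]
    x_cols += [flat[n] ** 2 for n in spec.fixed_quadratic]
    X = np.column_stack(x_cols) if x_cols else np.zeros((nrow * ncol, 0))
    w_cols = [flat[n] for n in spec.scaled]
    w_cols += [flat[n] ** 2 for n in spec.scaled_quadratic]
    W = np.column_stack(w_cols) if w_cols else np.zeros((nrow * ncol, 0))

    # pixel coordinates for the suitability field
    x, y = ref.pixel_centers()
    px = np.repeat(y[:, None], ncol, axis=1).ravel()  # northing rows
    pe = np.tile(x[None, :], (nrow, 1)).ravel()
    coords = np.column_stack([pe, px])
    Z = basis.design(coords)

    lay_names = samples.names
    idx = {n: i for i, n in enumerate(lay_names)}
    theta = samples.theta.reshape(-1, samples.theta.shape[-1])  # [draws, p]
    n_draws = theta.shape[0]
    dens = np.full(nrow * ncol, np.nan)

    # median over draws, chunked over pixels to bound memory
    chunk = max(1, int(5e6 // max(n_draws, 1)))
    beta_cols = [idx[f"beta[{n}]"] for n in spec.beta_names]
    gamma_cols = [idx[f"gamma[{n}]"] for n in spec.gamma_names]
    # prediction uses the mean BCR intercept level (mu_wish) so a map can
    # span regions; trend year defaults to the last training year
    b0 = samples.mu_wish.reshape(-1, 2)[:, 0]
    a0 = theta[:, idx["a0"]]
    spl_cols = [idx[n] for n in lay_names if n.startswith("spl[")]
    for start in range(0, nrow * ncol, chunk):
        sl = slice(start, start + chunk)
        if not valid[sl].any():
            continue
        eta = b0[None, :] + X[sl] @ theta[:, beta_cols].T
        if gamma_cols:
            eta = eta + W[sl] @ theta[:, gamma_cols].T
        lam = np.exp(np.clip(eta, -300, 300))
        psi = expit(a0[None, :] + Z[sl] @ theta[:, spl_cols].T)
        dens[sl] = np.median(psi * lam, axis=1)
    dens = density_from_prediction(dens, maxd)
    dens[~valid] = np.nan
    dens[(qa == 1) | (dist_mask == 1)] = np.nan
    return DensitySurface(
        density=dens.reshape(nrow, ncol),
        disturbance_mask=dist_mask.reshape(nrow, ncol),
        qa_mask=qa.reshape(nrow, ncol),
        cell_size=ref.cell_size,
        origin=ref.origin,
    )


def _standardize_surface(surf, std, name):
    if name in std:
        mu, sd = std[name]
        return (surf - mu) / sd
    return surf


def training_quantile_bounds(values: np.ndarray, lo: float = 0.025, hi: float = 0.975):
    """(2.5%, 97.5%) bounds of training covariate values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return float(np.quantile(v, lo)), float(np.quantile(v, hi))


# ---------------------------------------------------------------------------
# successional-phase helper


def phase_expectation(sagebrush: float, pinyon_juniper: float, herbaceous: float) -> str:
    """Expected community of peak density from coefficient signs.

    +sage & -PJ -> sagebrush; +sage & +PJ -> early-successional woodland
    (Phase I-II); +PJ & (-sage or -herb) -> late-successional woodland
    (Phase III); otherwise none.
    """
    if sagebrush > 0 and pinyon_juniper <= 0:
        return "sagebrush"
    if sagebrush > 0 and pinyon_juniper > 0:
        return "early-successional PJ (Phase I-II)"
    if pinyon_juniper > 0 and (sagebrush <= 0 or herbaceous <= 0):
        return "late-successional PJ (Phase III)"
    return "none"
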