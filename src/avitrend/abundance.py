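"""Latent abundance state: zero-inflated Poisson counts with a log-linear
habitat model, BCR random intercepts/trends, survey-level overdispersion
and a 2-D spline on the suitability (zero-inflation) probability.

The marginalized likelihood sums the latent true abundance N and the
per-grid suitability indicator out of the model.  The binomial thinning
identity (N ~ Poisson(lam), d | N ~ Binomial(N, p)  =>  d ~ Poisson(lam p))
reduces each survey's count term to a Poisson pmf; the suitability
indicator, shared by all years of a grid, turns each grid's contribution
into a two-component mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln, expit

TREND_ORIGIN_YEAR = 2008
DEFAULT_WISHART_R = np.diag([500.0, 1.0])
DEFAULT_WISHART_DF = 3.0


# ---------------------------------------------------------------------------
# linear predictor


def log_mu_lambda(beta0_r, beta, x, gamma, w, mu_r, year, offset,
                  origin_year: int = TREND_ORIGIN_YEAR):
    """Log expected abundance for one or many surveys.

    log mu.lambda = beta0[bcr] + beta.x + gamma.w + mu[bcr]*(t - 2008) + offset

    ``beta0_r`` and ``mu_r`` are the survey's (already indexed) BCR
    intercept and trend; ``x`` and ``w`` carry a trailing covariate axis.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    year = np.asarray(year, dtype=float)
    fixed = x @ beta if beta.size else 0.0
    scaled = w @ gamma if gamma.size else 0.0
    return (
        np.asarray(beta0_r, dtype=float)
        + fixed
        + scaled
        + np.asarray(mu_r, dtype=float) * (year - origin_year)
        + np.asarray(offset, dtype=float)
    )


def survey_effect(mu_lambda, sd_survey: float, rng: np.random.Generator | None = None,
                  eps=None):
    """Survey-level overdispersion applied on the log scale.

    log lambda = log mu.lambda + eps,  eps ~ Normal(0, sd_survey); the
    log-scale placement keeps lambda positive (a deliberate deviation from
    a Normal perturbation of lambda itself, which admits negative means).
    With ``sd_survey == 0`` lambda equals mu.lambda exactly.
    """
    if sd_survey < 0:
        raise ValueError("sd_survey must be >= 0")
    mu_lambda = np.asarray(mu_lambda, dtype=float)
    if eps is None:
        if sd_survey == 0:
            return mu_lambda.copy() if mu_lambda.ndim else float(mu_lambda)
        if rng is None:
            raise ValueError("need rng or explicit eps when sd_survey > 0")
        eps = rng.normal(0.0, sd_survey, size=mu_lambda.shape)
    return np.exp(np.log(mu_lambda) + np.asarray(eps, dtype=float))


# ---------------------------------------------------------------------------
# zero-inflated marginal count likelihood


def _pois_logpmf(d, lam):
    d = np.asarray(d, dtype=float)
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = d * np.log(lam) - lam - gammaln(d + 1.0)
    return np.where((lam == 0) & (d == 0), 0.0, out)


def zip_marginal_loglik(d, lam, pmarg, psi):
    """Single-survey marginal log-likelihood, N and Active summed out.

    log[ (1 - psi) 1{d = 0} + psi Poisson(d; lam * pmarg) ].
    """
    d = np.asarray(d)
    if np.any(d < 0) or not np.issubdtype(np.asarray(d).dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    lam = np.asarray(lam, dtype=float)
    pm = np.asarray(pmarg, dtype=float)
    if np.any((pm <= 0) | (pm > 1)):
        raise ValueError("pmarg must lie in (0, 1]")
    psi = np.asarray(psi, dtype=float)
    lp_pois = _pois_logpmf(d, lam * pm)
    spike = np.where(d == 0, 1.0 - psi, 0.0)
    out = np.log(spike + psi * np.exp(lp_pois))
    return float(out) if out.ndim == 0 else out


def zip_grid_loglik(d_panel, lam_panel, pmarg_panel, psi, mask=None):
    """Grid-panel marginal log-likelihood with the suitability indicator
    shared across years.

    Parameters are (n_grids, n_years) arrays; ``mask`` marks surveyed
    cells (unsurveyed cells contribute nothing).  Per grid:

    log[ (1 - psi_g) 1{all d = 0} + psi_g exp(sum_t logPois(d; lam p)) ].
    """
    d = np.asarray(d_panel, dtype=float)
    lam = np.asarray(lam_panel, dtype=float)
    pm = np.asarray(pmarg_panel, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if mask is None:
        mask = np.ones_like(d, dtype=bool)
    lp = np.where(mask, _pois_logpmf(d, np.where(mask, lam * pm, 1.0)), 0.0)
    lp_active = lp.sum(axis=1)
    all_zero = ((d == 0) | ~mask).all(axis=1)
    # log( (1-psi) [all zero] + psi exp(lp_active) ), stable for lp_active << 0
    with np.errstate(divide="ignore"):
        log_spike = np.where(all_zero, np.log1p(-psi), -np.inf)
    log_occ = np.log(psi) + lp_active
    return np.logaddexp(log_spike, log_occ).sum()


def cell_loglik_detections(minute, dclass, pi_a, pa, pi_d, pd):
    """Conditional categorical log-likelihood of minute / distance cells.

    ``minute`` and ``dclass`` are 1-based indices per detection; the cell
    arrays carry one row per detection (or are shared 1-D vectors).
    A detection landing in a zero-probability cell yields -inf.
    """
    minute = np.asarray(minute, dtype=int) - 1
    dclass = np.asarray(dclass, dtype=int) - 1
    pi_a = np.atleast_2d(np.asarray(pi_a, dtype=float))
    pi_d = np.atleast_2d(np.asarray(pi_d, dtype=float))
    pa = np.atleast_1d(np.asarray(pa, dtype=float))
    pd_ = np.atleast_1d(np.asarray(pd, dtype=float))
    n = minute.size
    rows_a = np.zeros(n, dtype=int) if pi_a.shape[0] == 1 else np.arange(n)
    rows_d = np.zeros(n, dtype=int) if pi_d.shape[0] == 1 else np.arange(n)
    pa_i = pa[rows_a] if pa.size > 1 else pa[0]
    pd_i = pd_[rows_d] if pd_.size > 1 else pd_[0]
    ca = pi_a[rows_a, minute] / pa_i
    cd = pi_d[rows_d, dclass] / pd_i
    with np.errstate(divide="ignore"):
        return float(np.log(ca).sum() + np.log(cd).sum())


# ---------------------------------------------------------------------------
# BCR random-effect prior


def bcr_random_effects_prior(
    beta0_r,
    mu_r,
    mu_wish,
    sigma_w,
    R: np.ndarray = DEFAULT_WISHART_R,
    df: float = DEFAULT_WISHART_DF,
) -> float:
    """Log prior of the (intercept, trend) pairs and their covariance.

    (beta0_r, mu_r) ~ MVN(mu_wish, Sigma_w) per BCR;
    Sigma_w ~ InverseWishart(df, R).
    """
    sigma_w = np.asarray(sigma_w, dtype=float)
    if sigma_w.shape != (2, 2) or not np.allclose(sigma_w, sigma_w.T):
        raise ValueError("Sigma_w must be symmetric 2x2")
    try:
        L = np.linalg.cholesky(sigma_w)
    except np.linalg.LinAlgError:
        raise ValueError("Sigma_w must be positive-definite") from None
    pairs = np.column_stack([np.atleast_1d(beta0_r), np.atleast_1d(mu_r)])
    # MVN log-density by hand (robust to near-singular but PD covariances)
    dev = pairs - np.asarray(mu_wish, dtype=float)
    z = np.linalg.solve(L, dev.T)
    n_pairs = pairs.shape[0]
    lp = float(
        -n_pairs * (np.log(2 * np.pi) + np.log(np.diag(L)).sum()) - 0.5 * np.sum(z**2)
    )
    lp += float(stats.invwishart.logpdf(sigma_w, df=df, scale=R))
    return lp


# ---------------------------------------------------------------------------
# 2-D suitability spline


@dataclass
class TpsBasis:
    """Thin-plate-style radial basis over grid centroids.

    Columns are r^2 log(r) radial functions around K-1 space-filling knots,
    column-standardized; smoothing acts as an iid Gaussian precision omega
    on the coefficients.  ``a0`` (the intercept) is carried separately.
    """

    knots: np.ndarray
    col_center: np.ndarray
    col_scale: np.ndarray
    train_coords: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        return self.knots.shape[0] + 1  # K includes the intercept

    def design(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        d = np.sqrt(
            ((coords[:, None, :] - self.knots[None, :, :]) ** 2).sum(axis=2)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = np.where(d > 0, d**2 * np.log(d), 0.0)
        return (Z - self.col_center) / self.col_scale

    def penalty(self) -> np.ndarray:
        """Identity precision on the spline coefficients (a0 unpenalized)."""
        return np.eye(self.knots.shape[0])


def tps_basis(coords: np.ndarray, k: int, seed: int = 0) -> tuple[TpsBasis, np.ndarray]:
    """Build the K-dimensional suitability basis over grid centroids.

    Knots (K-1 of them) are chosen by k-means space-filling over the
    coordinates.  Returns the basis object and the (n, K-1) design matrix
    evaluated at the training coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    if k < 3:
        raise ValueError("need K >= 3 basis dimensions")
    uniq = np.unique(coords, axis=0)
    if uniq.shape[0] < k:
        dupes = coords.shape[0] - uniq.shape[0]
        raise ValueError(
            f"only {uniq.shape[0]} distinct coordinates for K={k} "
            f"({dupes} duplicated rows)"
        )
    knots = _kmeans_knots(uniq, k - 1, seed)
    d = np.sqrt(((coords[:, None, :] - knots[None, :, :]) ** 2).sum(axis=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(d > 0, d**2 * np.log(d), 0.0)
    center = Z.mean(axis=0)
    scale = Z.std(axis=0)
    scale[scale == 0] = 1.0
    basis = TpsBasis(knots, center, scale, coords)
    return basis, (Z - center) / scale


def _kmeans_knots(coords: np.ndarray, n_knots: int, seed: int) -> np.ndarray:
    """Plain Lloyd's k-means (deterministic given seed); centers as knots."""
    rng = np.random.default_rng(seed)
    n = coords.shape[0]
    if n_knots >= n:
        return coords.copy()
    centers = coords[rng.choice(n, n_knots, replace=False)].copy()
    for _ in range(50):
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new = centers.copy()
        for j in range(n_knots):
            pts = coords[labels == j]
            if len(pts):
                new[j] = pts.mean(axis=0)
        if np.allclose(new, centers):
            break
        centers = new
    return centers


def suitability(a0: float, spline_coefs: np.ndarray, design: np.ndarray) -> np.ndarray:
    """psi per grid: inverse-logit of a0 + design @ coefs."""
    eta = a0 + design @ np.asarray(spline_coefs, dtype=float)
    return expit(np.clip(eta, -35, 35))


def fit_suitability_field(
    design: np.ndarray, target_logit: np.ndarray, omega: float
) -> tuple[float, np.ndarray]:
    """Penalized least-squares fit of (a0, coefs) to a logit-scale target.

    Minimizes ||a0 + Z b - y||^2 + omega ||b||^2.  Utility for testing and
    for initializing the sampler; the posterior treats omega as unknown.
    """
    Z = np.asarray(design, dtype=float)
    y = np.asarray(target_logit, dtype=float)
    n, p = Z.shape
    X = np.hstack([np.ones((n, 1)), Z])
    P = np.zeros((p + 1, p + 1))
    P[1:, 1:] = omega * np.eye(p)
    coef = np.linalg.solve(X.T @ X + P, X.T @ y)
    return float(coef[0]), coef[1:]
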