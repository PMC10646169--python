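"""Observation process for point counts.

Two multiplicative components:

* **availability** — a removal process over 1-minute intervals.  With
  per-minute availability ``a`` the probability of first becoming available
  in minute ``m`` is geometric, ``a (1-a)^(m-1)``, and the probability of
  being available at least once in an M-minute count is ``1 - (1-a)^M``.
  ``a`` follows a logit-linear model in (standardized) ordinal date with a
  linear and a quadratic term.

* **detectability** — a half-normal function of distance evaluated on 10
  evenly spaced distance bins out to the truncation distance, combined with
  the triangular pdf of radial distances under uniform density
  (rectangular-rule integral approximation).  The half-normal scale is
  log-linear in observer experience and mean minutes since sunrise.

The product ``pmarg = pa * pd`` thins the latent Poisson abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_DISTANCE_BINS = 10
TRUNCATION_QUANTILE = 0.90


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# availability (removal model)


def removal_cells(a, M: int):
    """Per-minute availability cells and their sum.

    Returns ``(pi_a, pa)`` with ``pi_a[m-1] = a (1-a)^(m-1)`` and
    ``pa = 1 - (1-a)^M``.  ``a`` may be scalar or an array (cells get a
    trailing minute axis).
    """
    a = np.asarray(a, dtype=float)
    if np.any((a <= 0) | (a >= 1)):
        raise ValueError("per-minute availability must lie in (0, 1)")
    if M < 1:
        raise ValueError("count duration must be >= 1 minute")
    m = np.arange(1, M + 1)
    pi_a = a[..., None] * (1.0 - a[..., None]) ** (m - 1)
    pa = 1.0 - (1.0 - a) ** M
    if pi_a.ndim == 1:
        return pi_a, float(pa)
    return pi_a, pa


@dataclass
class AvailabilityParams:
    """Logit-scale intercept and ordinal-date (linear, quadratic) effects."""

    alpha: float
    a_date: tuple[float, float] = (0.0, 0.0)

    def per_minute(self, ord_date):
        """Per-minute availability a(E) for standardized ordinal date E."""
        E = np.asarray(ord_date, dtype=float)
        eta = self.alpha + self.a_date[0] * E + self.a_date[1] * E**2
        return _expit(np.clip(eta, -35, 35))


def availability_from_date(params: AvailabilityParams, ord_date, M: int):
    """(a, pa) for a survey with standardized ordinal date and M minutes."""
    a = params.per_minute(ord_date)
    pa = 1.0 - (1.0 - a) ** M
    return a, pa


# ---------------------------------------------------------------------------
# detectability (binned half-normal distance function)


def distance_cells(sigma, maxd: float, n_bins: int = N_DISTANCE_BINS):
    """Distance-bin cells under the rectangular rule.

    delta = maxd / B, midpoints r_b = (b - 1/2) delta,
    g(r_b) = exp(-r_b^2 / 2 sigma^2),  f(r_b) = 2 r_b delta / maxd^2,
    pi_d[b] = g(r_b) f(r_b),  pd = sum_b pi_d[b].

    ``sigma`` may be scalar or array (cells get a trailing bin axis).
    """
    if n_bins < 1:
        raise ValueError("need at least one distance bin")
    if maxd <= 0:
        raise ValueError("truncation distance must be positive")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("half-normal scale must be positive")
    delta = maxd / n_bins
    r = (np.arange(1, n_bins + 1) - 0.5) * delta
    g = np.exp(-(r**2) / (2.0 * sigma[..., None] ** 2))
    f = 2.0 * r * delta / maxd**2
    pi_d = g * f
    pd = pi_d.sum(axis=-1)
    if pi_d.ndim == 1:
        return pi_d, float(pd)
    return pi_d, pd


@dataclass
class DistanceParams:
    """Log-scale intercept, observer-experience and minutes-since-sunrise effects."""

    log_sigma0: float
    tau_experience: float = 0.0
    tau_sunrise: float = 0.0

    def sigma(self, experienced, min_since_sunrise):
        return sigma_from_covariates(
            (self.log_sigma0, self.tau_experience, self.tau_sunrise),
            experienced,
            min_since_sunrise,
        )


def sigma_from_covariates(tau, experienced, min_since_sunrise):
    """sigma = exp(tau . z) with z = (1, experienced, minutes-since-sunrise)."""
    t0, t1, t2 = (float(v) for v in tau)
    z1 = np.asarray(experienced, dtype=float)
    z2 = np.asarray(min_since_sunrise, dtype=float)
    eta = np.clip(t0 + t1 * z1 + t2 * z2, -300, 300)
    out = np.exp(eta)
    return float(out) if out.ndim == 0 else out


def pmarg(pa, pd):
    """Joint probability of being available and then detected."""
    pa = np.asarray(pa, dtype=float)
    pd_ = np.asarray(pd, dtype=float)
    if np.any((pa <= 0) | (pa > 1)) or np.any((pd_ <= 0) | (pd_ > 1)):
        raise ValueError("pa and pd must lie in (0, 1]")
    out = pa * pd_
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# distance truncation


def truncate_detections(
    distances: np.ndarray, q: float = TRUNCATION_QUANTILE
) -> tuple[float, np.ndarray]:
    """Drop the farthest (1-q) fraction of detections.

    Returns ``(maxd, keep_mask)`` where ``maxd`` is the type-7
    (linear-interpolation) empirical q-quantile of the distances and the
    mask retains records with distance <= maxd.
    """
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d)] if d.size else d
    if d.size == 0:
        raise ValueError("no finite detection distances to truncate")
    maxd = float(np.quantile(np.asarray(distances, dtype=float), q))
    keep = np.asarray(distances, dtype=float) <= maxd
    return maxd, keep


def assign_distance_bins(distances, maxd: float, n_bins: int = N_DISTANCE_BINS):
    """1-based bin index for each distance in [0, maxd]."""
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0) or np.any(d > maxd):
        raise ValueError("distances outside [0, maxd]")
    b = np.minimum((d / (maxd / n_bins)).astype(int) + 1, n_bins)
    return b
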