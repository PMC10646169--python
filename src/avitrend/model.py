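"""Assembly of survey panels, detection records and buffer stacks into the
joint model, and the marginalized log-posterior used by the sampler.

Parameter blocks (the latent suitability indicator and true abundance are
marginalized out; survey overdispersion uses a non-centered ``sd * eta``
parameterization):

==============  =============================================================
block           contents
==============  =============================================================
``bcr``         per-BCR intercepts ``beta0[r]`` and trends ``mu[r]``
``beta``        fixed-covariate coefficients
``gamma``       scale-selected covariate coefficients (incl. quadratics)
``scales``      continuous buffer radii, one per scale-selected covariate,
                carried on an unconstrained logistic scale
``avail``       availability: intercept + ordinal-date linear/quadratic
``dist``        detection: log-sigma intercept + experience + sunrise
``spline``      suitability intercept ``a0`` + spline coefficients
``log_omega``   log smoothing precision of the spline, Uniform(-12, 12)
``sd_survey``   survey-effect SD, Uniform(0, 5)
==============  =============================================================

Hyperparameters ``mu_wish`` (2) and ``Sigma_w`` (2x2) of the BCR
random-effect distribution are conjugate and sampled by Gibbs steps in
:mod:`avitrend.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, log_expit

from . import abundance, detection
from .covariates import BufferStack, FIXED_RADIUS, interpolation_weights

COEF_PRIOR_VAR = 1.0e4  # beta, gamma, A, tau ~ Normal(0, 1e4)
# weakly-informative prior on the suitability intercept: the likelihood is
# flat in a0 once psi ~ 1, so a vague prior lets chains wander; sd ~ 3.2 on
# the logit scale still spans psi ~ (0.002, 0.998)
A0_PRIOR_VAR = 10.0
LOG_OMEGA_BOUNDS = (-12.0, 12.0)
SD_SURVEY_BOUNDS = (0.0, 5.0)


@dataclass
class ModelSpec:
    """Which covariates enter where, and structural switches."""

    fixed: list[str] = field(default_factory=list)
    fixed_quadratic: list[str] = field(default_factory=list)
    scaled: list[str] = field(default_factory=list)
    scaled_quadratic: list[str] = field(default_factory=list)
    k_spline: int = 100
    include_survey_effect: bool = True
    n_distance_bins: int = detection.N_DISTANCE_BINS
    trend_origin_year: int = abundance.TREND_ORIGIN_YEAR
    wishart_r: np.ndarray = field(
        default_factory=lambda: abundance.DEFAULT_WISHART_R.copy()
    )
    wishart_df: float = abundance.DEFAULT_WISHART_DF

    def __post_init__(self) -> None:
        for q in self.fixed_quadratic:
            if q not in self.fixed:
                raise ValueError(f"quadratic term {q!r} lacks a linear term")
        for q in self.scaled_quadratic:
            if q not in self.scaled:
                raise ValueError(f"quadratic term {q!r} lacks a linear term")

    @property
    def gamma_names(self) -> list[str]:
        return list(self.scaled) + [f"{c}^2" for c in self.scaled_quadratic]

    @property
    def beta_names(self) -> list[str]:
        return list(self.fixed) + [f"{c}^2" for c in self.fixed_quadratic]


@dataclass
class ModelData:
    """Dense arrays for one species' data set.

    Shapes: G grids, T years, J scale-selected covariates, Rn radii,
    P fixed covariates, n detections.
    """

    grid_ids: list
    years: np.ndarray            # [T] calendar years
    bcr_ids: list                # distinct BCR labels
    bcr_index: np.ndarray        # [G] index into bcr_ids
    d: np.ndarray                # [G, T] summed detections
    mask: np.ndarray             # [G, T] surveyed?
    offset: np.ndarray           # [G, T] log n_points (0 where unsurveyed)
    minutes: np.ndarray          # [G, T] count duration (5 or 6)
    ord_date: np.ndarray         # [G, T] standardized ordinal date
    min_sunrise: np.ndarray      # [G, T] standardized mean minutes since sunrise
    experienced: np.ndarray      # [G, T] observer-experience flag
    x_fixed: np.ndarray          # [G, T, P] standardized fixed covariates
    stack_values: np.ndarray     # [J, G, T, Rn] standardized buffer means
    radii: np.ndarray            # [Rn]
    scaled_quad: np.ndarray      # [Jq] indices into stack covariates with quadratics
    spline_design: np.ndarray    # [G, K-1]
    coords: np.ndarray           # [G, 2] centroids (easting, northing)
    det_g: np.ndarray            # [n] detection grid index
    det_t: np.ndarray            # [n] detection year index
    det_minute: np.ndarray       # [n] 1-based
    det_bin: np.ndarray          # [n] 1-based distance bin
    maxd: float                  # truncation distance (m)
    standardizers: dict = field(default_factory=dict)

    @property
    def n_grids(self) -> int:
        return self.d.shape[0]

    @property
    def n_years(self) -> int:
        return self.d.shape[1]

    @property
    def n_bcrs(self) -> int:
        return len(self.bcr_ids)


def _standardize(v: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(v[mask].mean())
    sd = float(v[mask].std())
    if sd == 0:
        sd = 1.0
    out = np.where(mask, (v - mu) / sd, 0.0)
    return out, mu, sd


def build_model_data(
    surveys,
    detections,
    stack: BufferStack,
    spec: ModelSpec,
    basis_seed: int = 0,
):
    """Assemble dense model arrays from tidy inputs.

    Parameters
    ----------
    surveys
        Survey panel frame: grid_id, year, n_points, ordinal_date,
        mean_min_since_sunrise, observer_experienced, bcr_id, easting,
        northing.
    detections
        Detection frame: grid_id, year, distance_m, minute.  Distance
        truncation (90%) and binning happen here.
    stack
        Standardized buffer stack holding every covariate named in the
        spec; covariates without scale selection must be present at the
        564-m radius or be radius-degenerate.

    Returns
    -------
    (ModelData, TpsBasis)
    """
    if not stack.center:
        stack = stack.standardize()

    grids = sorted(surveys["grid_id"].unique())
    years = np.array(sorted(surveys["year"].unique()))
    gi = {g: i for i, g in enumerate(grids)}
    yi = {y: i for i, y in enumerate(years)}
    G, T = len(grids), len(years)

    mask = np.zeros((G, T), dtype=bool)
    offset = np.zeros((G, T))
    minutes = np.full((G, T), 6, dtype=int)
    ord_date = np.zeros((G, T))
    sunrise = np.zeros((G, T))
    exper = np.zeros((G, T))
    bcr_of_grid: dict = {}
    coords = np.zeros((G, 2))
    for rec in surveys.itertuples(index=False):
        g, t = gi[rec.grid_id], yi[rec.year]
        mask[g, t] = True
        offset[g, t] = np.log(float(rec.n_points))
        minutes[g, t] = int(getattr(rec, "minutes", 6))
        ord_date[g, t] = float(rec.ordinal_date)
        sunrise[g, t] = float(rec.mean_min_since_sunrise)
        exper[g, t] = float(rec.observer_experienced)
        bcr_of_grid[rec.grid_id] = rec.bcr_id
        coords[g] = (float(rec.easting), float(rec.northing))

    bcr_ids = sorted(set(bcr_of_grid.values()))
    bi = {b: i for i, b in enumerate(bcr_ids)}
    bcr_index = np.array([bi[bcr_of_grid[g]] for g in grids])

    std = {}
    ord_date, mu_e, sd_e = _standardize(ord_date, mask)
    std["ordinal_date"] = (mu_e, sd_e)
    sunrise, mu_s, sd_s = _standardize(sunrise, mask)
    std["min_since_sunrise"] = (mu_s, sd_s)

    # detections: truncate, bin, tabulate counts
    dist = detections["distance_m"].to_numpy(dtype=float)
    maxd, keep = detection.truncate_detections(dist)
    det = detections.loc[keep].reset_index(drop=True)
    det_g = det["grid_id"].map(gi).to_numpy(dtype=int)
    det_t = det["year"].map(yi).to_numpy(dtype=int)
    det_minute = det["minute"].to_numpy(dtype=int)
    det_bin = detection.assign_distance_bins(
        det["distance_m"].to_numpy(dtype=float), maxd, spec.n_distance_bins
    )
    d = np.zeros((G, T), dtype=int)
    np.add.at(d, (det_g, det_t), 1)
    if np.any(d[~mask] > 0):
        raise ValueError("detections recorded for unsurveyed grid-years")

    # fixed covariates from the stack (564-m or radius-degenerate)
    P = len(spec.beta_names)
    x_fixed = np.zeros((G, T, P))
    col = 0
    lin_cols = {}
    for name in spec.fixed:
        vals = _fixed_covariate(stack, name)
        x_fixed[:, :, col] = _reindex(vals, stack, grids, years)
        lin_cols[name] = col
        col += 1
    for name in spec.fixed_quadratic:
        x_fixed[:, :, col] = x_fixed[:, :, lin_cols[name]] ** 2
        col += 1

    # scale-selected covariates keep the whole radius ladder
    J = len(spec.scaled)
    stack_values = np.zeros((J, G, T, len(stack.radii)))
    for j, name in enumerate(spec.scaled):
        k = stack.cov_index(name)
        stack_values[j] = _reindex_cube(stack.values[k], stack, grids, years)
    scaled_quad = np.array(
        [spec.scaled.index(c) for c in spec.scaled_quadratic], dtype=int
    )

    basis, design = abundance.tps_basis(coords, spec.k_spline, seed=basis_seed)

    data = ModelData(
        grid_ids=grids,
        years=years,
        bcr_ids=bcr_ids,
        bcr_index=bcr_index,
        d=d,
        mask=mask,
        offset=offset,
        minutes=minutes,
        ord_date=ord_date,
        min_sunrise=sunrise,
        experienced=exper,
        x_fixed=x_fixed,
        stack_values=stack_values,
        radii=stack.radii,
        scaled_quad=scaled_quad,
        spline_design=design,
        coords=coords,
        det_g=det_g,
        det_t=det_t,
        det_minute=det_minute,
        det_bin=det_bin,
        maxd=maxd,
        standardizers=std,
    )
    return data, basis


def _fixed_covariate(stack: BufferStack, name: str) -> np.ndarray:
    j = stack.cov_index(name)
    if FIXED_RADIUS in stack.radii:
        return stack.at_radius(name, FIXED_RADIUS)
    block = stack.values[j]
    finite_r = np.isfinite(block).any(axis=(0, 1))
    if finite_r.sum() == 1:
        return block[:, :, int(np.flatnonzero(finite_r)[0])]
    # fall back to nearest tabulated radius below 564 m
    idx = int(np.searchsorted(stack.radii, FIXED_RADIUS)) - 1
    return block[:, :, max(idx, 0)]


def _reindex(values: np.ndarray, stack: BufferStack, grids, years) -> np.ndarray:
    gsel = [stack.grid_ids.index(g) for g in grids]
    ysel = [stack.years.index(y) for y in years]
    return values[np.ix_(gsel, ysel)]


def _reindex_cube(values: np.ndarray, stack: BufferStack, grids, years) -> np.ndarray:
    gsel = [stack.grid_ids.index(g) for g in grids]
    ysel = [stack.years.index(y) for y in years]
    return values[np.ix_(gsel, ysel, range(len(stack.radii)))]


# ---------------------------------------------------------------------------
# parameter vector layout


class ParamLayout:
    """Mapping between named parameter blocks and a flat vector."""

    def __init__(self, spec: ModelSpec, data: ModelData):
        self.spec = spec
        self.blocks: dict[str, slice] = {}
        self.names: list[str] = []
        R = data.n_bcrs
        self._add("bcr", [f"beta0[{b}]" for b in data.bcr_ids] + [f"mu[{b}]" for b in data.bcr_ids])
        if spec.beta_names:
            self._add("beta", [f"beta[{n}]" for n in spec.beta_names])
        if spec.gamma_names:
            self._add("gamma", [f"gamma[{n}]" for n in spec.gamma_names])
        if spec.scaled:
            self._add("scales", [f"scale_u[{n}]" for n in spec.scaled])
        self._add("avail", ["alpha", "A_date", "A_date2"])
        self._add("dist", ["tau0", "tau_exp", "tau_sun"])
        self._add("spline", ["a0"] + [f"spl[{k}]" for k in range(data.spline_design.shape[1])])
        self._add("log_omega", ["log_omega"])
        if spec.include_survey_effect:
            self._add("sd_survey", ["sd_survey"])
        self.size = len(self.names)
        self.n_bcrs = R

    def _add(self, block: str, names: list[str]) -> None:
        start = len(self.names)
        self.names.extend(names)
        self.blocks[block] = slice(start, len(self.names))

    def get(self, theta: np.ndarray, block: str) -> np.ndarray:
        return theta[self.blocks[block]]


def scale_from_u(u, radii) -> np.ndarray:
    """Map unconstrained u to a radius in [radii[0], radii[-1]]."""
    lo, hi = float(radii[0]), float(radii[-1])
    return lo + (hi - lo) * expit(np.asarray(u, dtype=float))


def u_from_scale(s, radii) -> np.ndarray:
    lo, hi = float(radii[0]), float(radii[-1])
    p = (np.asarray(s, dtype=float) - lo) / (hi - lo)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


# ---------------------------------------------------------------------------
# joint log posterior


class Posterior:
    """Marginalized log-posterior of one species' model.

    ``eta`` holds the non-centered survey-effect draws (standard-normal a
    priori); ``mu_wish``/``sigma_w`` are the BCR hyperparameters updated by
    Gibbs outside this class.
    """

    def __init__(self, data: ModelData, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.layout = ParamLayout(spec, data)
        # the sampler carries intercepts at the centered time origin
        # (beta0c = beta0 + mu * t_center) to decorrelate intercept and
        # trend random walks; reporting converts back to the 2008 origin
        yrs = np.broadcast_to(data.years[None, :], data.mask.shape)
        self.t_center = float(
            (yrs[data.mask] - spec.trend_origin_year).mean()
        )

    # -- pieces -------------------------------------------------------------

    def availability(self, theta):
        alpha, a1, a2 = self.layout.get(theta, "avail")
        d = self.data
        eta = alpha + a1 * d.ord_date + a2 * d.ord_date**2
        a = expit(np.clip(eta, -35, 35))
        a = np.clip(a, 1e-12, 1 - 1e-12)
        pa = 1.0 - (1.0 - a) ** d.minutes
        return a, pa

    def distance(self, theta):
        tau = self.layout.get(theta, "dist")
        d = self.data
        sigma = detection.sigma_from_covariates(tau, d.experienced, d.min_sunrise)
        pi_d, pd = detection.distance_cells(sigma, d.maxd, self.spec.n_distance_bins)
        return pi_d, pd

    def interpolated_w(self, theta):
        """[G, T, J + Jq] scale-interpolated (plus quadratic) covariates."""
        d = self.data
        if not self.spec.scaled:
            return np.zeros((d.n_grids, d.n_years, 0))
        u = self.layout.get(theta, "scales")
        s = scale_from_u(u, d.radii)
        cols = []
        for j in range(len(self.spec.scaled)):
            lo, hi, wgt = interpolation_weights(d.radii, float(s[j]))
            v = (1 - wgt) * d.stack_values[j, :, :, lo] + wgt * d.stack_values[j, :, :, hi]
            cols.append(v)
        w = np.stack(cols, axis=-1)
        if d.scaled_quad.size:
            w = np.concatenate([w, w[:, :, d.scaled_quad] ** 2], axis=-1)
        return w

    def log_lambda(self, theta, eta):
        d = self.data
        lay = self.layout
        bcr = lay.get(theta, "bcr")
        R = d.n_bcrs
        beta0c = bcr[:R][d.bcr_index]
        mu = bcr[R:][d.bcr_index]
        lin = beta0c[:, None] + mu[:, None] * (
            d.years[None, :] - self.spec.trend_origin_year - self.t_center
        )
        if self.spec.beta_names:
            lin = lin + d.x_fixed @ lay.get(theta, "beta")
        w = self.interpolated_w(theta)
        if w.shape[-1]:
            lin = lin + w @ lay.get(theta, "gamma")
        lin = lin + d.offset
        if self.spec.include_survey_effect:
            sd = float(lay.get(theta, "sd_survey")[0])
            lin = lin + sd * eta
        return lin

    def psi(self, theta):
        spl = self.layout.get(theta, "spline")
        p = expit(np.clip(spl[0] + self.data.spline_design @ spl[1:], -35, 35))
        return np.clip(p, 1e-12, 1 - 1e-12)

    # -- log densities ------------------------------------------------------

    def count_loglik_by_grid(self, theta, eta):
        d = self.data
        a, pa = self.availability(theta)
        _, pd = self.distance(theta)
        lam = np.exp(np.clip(self.log_lambda(theta, eta), -300, 300))
        psi = self.psi(theta)
        return _zip_by_grid(d.d, lam, pa * pd, psi, d.mask)

    def cells_loglik(self, theta):
        d = self.data
        if d.det_g.size == 0:
            return 0.0
        a, pa = self.availability(theta)
        pi_d, pd = self.distance(theta)
        ag = a[d.det_g, d.det_t]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_min = np.log(ag) + (d.det_minute - 1) * np.log1p(-ag) - np.log(pa[d.det_g, d.det_t])
            ll_dst = np.log(pi_d[d.det_g, d.det_t, d.det_bin - 1]) - np.log(pd[d.det_g, d.det_t])
        total = ll_min.sum() + ll_dst.sum()
        return float(total) if np.isfinite(total) else -np.inf

    def log_prior(self, theta, eta, mu_wish, sigma_w):
        lay = self.layout
        lp = 0.0
        # BCR pairs ~ MVN(mu_wish, Sigma_w); IW hyperprior handled here too.
        # Prior lives on the 2008-origin intercepts (Jacobian of the
        # centering shift is 1)
        bcr = lay.get(theta, "bcr")
        R = self.data.n_bcrs
        beta0 = bcr[:R] - self.t_center * bcr[R:]
        lp += abundance.bcr_random_effects_prior(
            beta0, bcr[R:], mu_wish, sigma_w,
            R=self.spec.wishart_r, df=self.spec.wishart_df,
        )
        for block in ("beta", "gamma", "avail", "dist"):
            if block in lay.blocks:
                v = lay.get(theta, block)
                lp += float(-0.5 * np.sum(v**2) / COEF_PRIOR_VAR)
        if "scales" in lay.blocks:
            # uniform on the radius scale => logistic Jacobian on u
            u = lay.get(theta, "scales")
            lp += float(np.sum(log_expit(u) + log_expit(-u)))
        lo, hi = LOG_OMEGA_BOUNDS
        lw = float(lay.get(theta, "log_omega")[0])
        if not (lo <= lw <= hi):
            return -np.inf
        omega = np.exp(lw)
        spl = lay.get(theta, "spline")[1:]
        k = spl.size
        lp += float(0.5 * k * lw - 0.5 * omega * np.sum(spl**2))
        lp += float(-0.5 * np.sum(lay.get(theta, "spline")[0] ** 2) / A0_PRIOR_VAR)
        if self.spec.include_survey_effect:
            sd = float(lay.get(theta, "sd_survey")[0])
            if not (SD_SURVEY_BOUNDS[0] <= sd <= SD_SURVEY_BOUNDS[1]):
                return -np.inf
            lp += float(-0.5 * np.sum(eta**2))
        return lp

    def log_post(self, theta, eta, mu_wish, sigma_w):
        lp = self.log_prior(theta, eta, mu_wish, sigma_w)
        if not np.isfinite(lp):
            return -np.inf
        ll = float(self.count_loglik_by_grid(theta, eta).sum())
        ll += self.cells_loglik(theta)
        return lp + ll

    # -- helpers for reporting ---------------------------------------------

    # -- latent-N (data augmentation) path, mirroring the original JAGS-style
    # construction; used for fidelity cross-checks of the marginalized path

    def latent_count_loglik(self, theta, eta, N, active):
        """log p(N | lam, Active) + log p(d | N, pmarg) + log p(Active | psi)."""
        d = self.data
        _, pa = self.availability(theta)
        _, pd_ = self.distance(theta)
        pm = pa * pd_
        lam = np.exp(np.clip(self.log_lambda(theta, eta), -300, 300))
        lam_eff = lam * active[:, None]
        m = d.mask
        with np.errstate(divide="ignore", invalid="ignore"):
            lp_n = np.where(
                lam_eff > 0,
                N * np.log(np.where(lam_eff > 0, lam_eff, 1.0)) - lam_eff - gammaln(N + 1.0),
                np.where(N == 0, 0.0, -np.inf),
            )
        lp_bin = (
            gammaln(N + 1.0)
            - gammaln(d.d + 1.0)
            - gammaln(N - d.d + 1.0)
            + d.d * np.log(pm)
            + (N - d.d) * np.log1p(-np.clip(pm, 0, 1 - 1e-12))
        )
        psi = self.psi(theta)
        lp_act = np.where(active == 1, np.log(psi), np.log1p(-psi))
        return float(lp_n[m].sum() + lp_bin[m].sum() + lp_act.sum())

    def log_post_latent(self, theta, eta, N, active, mu_wish, sigma_w):
        lp = self.log_prior(theta, eta, mu_wish, sigma_w)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.latent_count_loglik(theta, eta, N, active) + self.cells_loglik(theta)

    def gibbs_latent_states(self, theta, eta, N, active, rng):
        """Exact full-conditional draws of N and the suitability indicator.

        Given Active = 1, N - d ~ Poisson(lam (1 - pmarg)); Active is forced
        to 1 wherever any count is positive, otherwise Bernoulli with odds
        psi exp(-sum lam pmarg) : (1 - psi).
        """
        d = self.data
        _, pa = self.availability(theta)
        _, pd_ = self.distance(theta)
        pm = pa * pd_
        lam = np.exp(np.clip(self.log_lambda(theta, eta), -300, 300))
        m = d.mask
        # Active | rest
        sum_lam_pm = np.where(m, lam * pm, 0.0).sum(axis=1)
        any_pos = (d.d * m).sum(axis=1) > 0
        psi = self.psi(theta)
        log_odds = np.log(psi) - np.log1p(-psi) - sum_lam_pm
        p_active = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -300, 300)))
        active = np.where(any_pos, 1, (rng.random(d.n_grids) < p_active).astype(int))
        # N | rest
        extra = rng.poisson(np.where(m, lam * (1 - pm), 0.0))
        N = np.where(m, d.d + extra * active[:, None], 0)
        return N, active

    def scales_m(self, theta) -> np.ndarray:
        if "scales" not in self.layout.blocks:
            return np.zeros(0)
        return scale_from_u(self.layout.get(theta, "scales"), self.data.radii)

    def expected_counts(self, theta, eta) -> np.ndarray:
        """psi-weighted expected survey counts E[d] = psi lam pmarg."""
        _, pa = self.availability(theta)
        _, pd = self.distance(theta)
        lam = np.exp(np.clip(self.log_lambda(theta, eta), -300, 300))
        return self.psi(theta)[:, None] * lam * pa * pd


def _zip_by_grid(d, lam, pm, psi, mask) -> np.ndarray:
    """Per-grid marginal count log-likelihood (suitability summed out)."""
    lp = np.where(mask, abundance._pois_logpmf(d, np.where(mask, lam * pm, 1.0)), 0.0)
    lp_active = lp.sum(axis=1)
    all_zero = ((d == 0) | ~mask).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_spike = np.where(all_zero, np.log1p(-psi), -np.inf)
        return np.logaddexp(log_spike, np.log(psi) + lp_active)
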