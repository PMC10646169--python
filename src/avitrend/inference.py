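"""MCMC fitting and diagnostics.

The sampler is blockwise adaptive random-walk Metropolis on the
marginalized log posterior (true abundance and the suitability indicator
summed out), with

* conjugate Gibbs steps for the BCR random-effect hyperparameters
  (``mu_wish`` via a normal draw, ``Sigma_w`` via inverse-Wishart),
* vectorized per-grid Metropolis updates of the non-centered survey
  random effects, and
* Robbins-Monro step-size adaptation during warmup only (frozen
  afterwards, so the retained draws target the exact posterior).

Diagnostics follow the usual practice: split-chain Gelman-Rubin R-hat,
a simple autocorrelation-based effective sample size, and a chi-square
discrepancy posterior predictive check yielding a Bayesian p-value.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelData, ModelSpec, Posterior

CHISQ_EPS = 0.5  # added to expected counts in the discrepancy statistic


@dataclass
class MCMCConfig:
    """Desk-scale defaults (the source analysis ran 1e5-6.5e5 iterations;
    here 4 x 500 retained draws mirror its 2000-sample inference set)."""

    n_chains: int = 4
    n_warmup: int = 2500
    n_iter: int = 4000
    thin: int = 8
    n_global_updates: int = 4
    target_accept_block: float = 0.30
    target_accept_scalar: float = 0.44
    init_jitter: float = 0.2

    @property
    def n_draws_per_chain(self) -> int:
        return self.n_iter // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws with chain structure.

    ``theta`` is [chain, draw, p] over the monitored parameter vector
    (see ``names``); scale parameters are stored unconstrained and exposed
    in meters through :meth:`to_frame` / :meth:`extract`.
    """

    names: list[str]
    theta: np.ndarray
    eta: np.ndarray | None
    mu_wish: np.ndarray
    sigma_w: np.ndarray
    seed: int
    config: MCMCConfig
    scale_names: list[str] = field(default_factory=list)
    radii: np.ndarray | None = None
    t_center: float = 0.0

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def extract(self, name: str) -> np.ndarray:
        """Draws [chain, draw] for a named parameter (meters for scales).

        BCR intercepts are stored internally at the centered time origin
        and converted back to the trend-origin scale here.
        """
        if name.startswith("scale[") and name.endswith("]"):
            cov = name[len("scale["):-1]
            u = self.theta[:, :, self.names.index(f"scale_u[{cov}]")]
            from .model import scale_from_u

            return scale_from_u(u, self.radii)
        if name.startswith("beta0[") and self.t_center:
            bcr = name[len("beta0["):-1]
            b0c = self.theta[:, :, self.names.index(name)]
            mu = self.theta[:, :, self.names.index(f"mu[{bcr}]")]
            return b0c - self.t_center * mu
        return self.theta[:, :, self.names.index(name)]

    def monitored(self) -> dict[str, np.ndarray]:
        out = {n: self.extract(n) for n in self.names}
        for cov in self.scale_names:
            out[f"scale[{cov}]"] = self.extract(f"scale[{cov}]")
        out["mu_wish[0]"] = self.mu_wish[:, :, 0]
        out["mu_wish[1]"] = self.mu_wish[:, :, 1]
        out["Sigma_w[0,0]"] = self.sigma_w[:, :, 0, 0]
        out["Sigma_w[0,1]"] = self.sigma_w[:, :, 0, 1]
        out["Sigma_w[1,1]"] = self.sigma_w[:, :, 1, 1]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, draw, parameter, value) frame."""
        rows = []
        for name, arr in self.monitored().items():
            c, d = np.meshgrid(
                np.arange(self.n_chains), np.arange(self.n_draws), indexing="ij"
            )
            rows.append(
                pd.DataFrame(
                    {
                        "chain": c.ravel(),
                        "draw": d.ravel(),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PosteriorSamples":
        """Rebuild a minimal container (theta only) from a tidy frame."""
        names = list(dict.fromkeys(frame["parameter"]))
        nc = frame["chain"].max() + 1
        nd = frame["draw"].max() + 1
        theta = np.full((nc, nd, len(names)), np.nan)
        ni = {n: i for i, n in enumerate(names)}
        theta[frame["chain"], frame["draw"], frame["parameter"].map(ni)] = frame[
            "value"
        ].to_numpy()
        return cls(
            names=names,
            theta=theta,
            eta=None,
            mu_wish=np.zeros((nc, nd, 2)),
            sigma_w=np.tile(np.eye(2), (nc, nd, 1, 1)),
            seed=-1,
            config=MCMCConfig(),
        )


# ---------------------------------------------------------------------------
# sampler


def _initial_theta(post: Posterior, rng: np.random.Generator, jitter: float):
    data, lay = post.data, post.layout
    theta = np.zeros(lay.size)
    R = data.n_bcrs
    mean_count = max(data.d[data.mask].mean(), 0.05)
    base = np.log(mean_count) - data.offset[data.mask].mean()
    b = lay.blocks["bcr"]
    theta[b] = np.concatenate(
        [np.full(R, base), np.zeros(R)]
    ) + jitter * rng.standard_normal(2 * R)
    for block in ("beta", "gamma"):
        if block in lay.blocks:
            s = lay.blocks[block]
            theta[s] = 0.1 * jitter * rng.standard_normal(s.stop - s.start)
    if "scales" in lay.blocks:
        s = lay.blocks["scales"]
        theta[s] = jitter * rng.standard_normal(s.stop - s.start)
    av = lay.blocks["avail"]
    theta[av.start] = -0.5 + jitter * rng.standard_normal()
    dt = lay.blocks["dist"]
    theta[dt.start] = np.log(max(data.maxd, 1.0) / 2.0) + 0.1 * jitter * rng.standard_normal()
    sp = lay.blocks["spline"]
    theta[sp.start] = 1.0 + jitter * rng.standard_normal()
    theta[lay.blocks["log_omega"].start] = 1.0 + jitter * rng.standard_normal()
    if "sd_survey" in lay.blocks:
        theta[lay.blocks["sd_survey"].start] = 0.1 + 0.05 * rng.random()
    return theta


def _gibbs_hyper(theta, post: Posterior, rng: np.random.Generator):
    """Conjugate draws of (mu_wish, Sigma_w) given the BCR pairs."""
    lay = post.layout
    R = post.data.n_bcrs
    bcr = lay.get(theta, "bcr")
    # intercepts are carried at the centered origin; the random-effect
    # distribution lives on the 2008-origin scale
    beta0 = bcr[:R] - post.t_center * bcr[R:]
    pairs = np.column_stack([beta0, bcr[R:]])
    # Sigma_w | pairs, mu_wish handled jointly: first Sigma given current mu
    # then mu given new Sigma (one scan of a two-block Gibbs step)
    spec = post.spec
    mu = pairs.mean(axis=0)

    def draw_sigma(mu_wish):
        dev = pairs - mu_wish
        S = spec.wishart_r + dev.T @ dev
        return stats.invwishart.rvs(df=spec.wishart_df + R, scale=S, random_state=rng)

    sigma_w = draw_sigma(mu)
    prec = R * np.linalg.inv(sigma_w) + np.eye(2) / 1.0e4
    cov = np.linalg.inv(prec)
    mean = cov @ np.linalg.inv(sigma_w) @ pairs.sum(axis=0)
    mu_wish = rng.multivariate_normal(mean, cov)
    sigma_w = draw_sigma(mu_wish)
    return mu_wish, sigma_w


def _log_logistic_jac(u: float) -> float:
    """log density of u when expit(u) is uniform on (0, 1)."""
    from scipy.special import log_expit

    return float(log_expit(u) + log_expit(-u))


def _accept_prob(log_ratio: float) -> float:
    """Metropolis acceptance probability, NaN-safe (NaN -> reject)."""
    if not np.isfinite(log_ratio):
        return 0.0 if (np.isnan(log_ratio) or log_ratio < 0) else 1.0
    return float(np.exp(min(log_ratio, 0.0)))


def _gibbs_omega(theta, post: Posterior, rng: np.random.Generator) -> None:
    """Conjugate draw of the spline smoothing precision.

    With coefficients b ~ N(0, 1/omega) and a log-uniform prior on omega,
    omega | b ~ Gamma(k/2, rate = sum(b^2)/2), truncated to the prior box
    (which essentially never binds); updates theta in place.
    """
    from .model import LOG_OMEGA_BOUNDS

    lay = post.layout
    spl = lay.get(theta, "spline")[1:]
    k = spl.size
    rate = 0.5 * float(np.sum(spl**2)) + 1e-12
    lo, hi = np.exp(LOG_OMEGA_BOUNDS[0]), np.exp(LOG_OMEGA_BOUNDS[1])
    omega = rng.gamma(0.5 * k, 1.0 / rate)
    for _ in range(20):
        if lo <= omega <= hi:
            break
        omega = rng.gamma(0.5 * k, 1.0 / rate)
    theta[lay.blocks["log_omega"].start] = np.log(np.clip(omega, lo, hi))


def run_mcmc(
    data: ModelData,
    spec: ModelSpec,
    seed: int,
    config: MCMCConfig | None = None,
    latent_n: bool = False,
) -> PosteriorSamples:
    """Fit the model; reproducible bitwise for a fixed seed and config.

    ``latent_n=True`` switches to the data-augmented path (explicit latent
    abundance and suitability indicators with exact Gibbs full
    conditionals), kept for fidelity cross-checks of the marginalized
    default; it requires ``include_survey_effect=False``.
    """
    config = config or MCMCConfig()
    if latent_n and spec.include_survey_effect:
        raise ValueError("latent-N path does not support the survey random effect")
    post = Posterior(data, spec)
    lay = post.layout
    G, T = data.n_grids, data.n_years

    all_theta, all_eta, all_mu, all_sig = [], [], [], []
    for chain in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        theta = _initial_theta(post, rng, config.init_jitter)
        eta = np.zeros((G, T))
        mu_wish = np.array([theta[lay.blocks["bcr"].start], 0.0])
        sigma_w = np.diag([1.0, 0.01])
        N = data.d.copy()
        active = ((data.d * data.mask).sum(axis=1) >= 0).astype(int)  # init all 1

        def cur_log_post(th):
            if latent_n:
                return post.log_post_latent(th, eta, N, active, mu_wish, sigma_w)
            return post.log_post(th, eta, mu_wish, sigma_w)

        lp = cur_log_post(theta)
        if not np.isfinite(lp):
            raise RuntimeError("non-finite log posterior at initialization")

        # the smoothing precision has a conjugate Gamma full conditional
        # (log-uniform prior), so it is Gibbs-sampled rather than MH-updated
        blocks = [b for b in lay.blocks if b != "log_omega"]
        log_step = {b: np.log(0.1) for b in blocks}
        log_step["_eta"] = np.log(0.3)
        log_step["_global"] = np.log(0.3)
        log_step["_rescale"] = np.log(1.0)
        # running moments (Welford) for pre-conditioning: component scales
        # for the block scans plus a full covariance for a global adaptive
        # Metropolis update that handles cross-block correlations
        run_mean = theta.copy()
        run_var = np.ones(lay.size) * 0.01
        run_cov = np.eye(lay.size) * 0.01
        n_seen = 1
        chol = None

        c_theta, c_eta, c_mu, c_sig = [], [], [], []
        total = config.n_warmup + config.n_iter
        for it in range(total):
            warm = it < config.n_warmup
            for b in blocks:
                s = lay.blocks[b]
                dim = s.stop - s.start
                prop = theta.copy()
                step = (np.sqrt(run_var[s]) + 1e-8) * rng.standard_normal(dim)
                prop[s] = theta[s] + np.exp(log_step[b]) * step
                lp_prop = cur_log_post(prop)
                acc = _accept_prob(lp_prop - lp)
                if rng.random() < acc:
                    theta, lp = prop, lp_prop
                if warm:
                    target = (
                        config.target_accept_scalar
                        if dim == 1
                        else config.target_accept_block
                    )
                    log_step[b] += (acc - target) / (it + 1) ** 0.6

            # global correlated updates once the covariance is informed
            if it >= min(200, config.n_warmup // 3):
                if warm and (chol is None or it % 50 == 0):
                    cov = run_cov / max(n_seen - 1, 1)
                    cov = cov + 1e-9 * np.eye(lay.size)
                    chol = np.linalg.cholesky(cov)
                for _ in range(config.n_global_updates):
                    prop = theta + (
                        np.exp(log_step["_global"])
                        * (2.38 / np.sqrt(lay.size))
                        * (chol @ rng.standard_normal(lay.size))
                    )
                    lp_prop = cur_log_post(prop)
                    acc = _accept_prob(lp_prop - lp)
                    if rng.random() < acc:
                        theta, lp = prop, lp_prop
                    if warm:
                        log_step["_global"] += (acc - 0.234) / (it + 1) ** 0.6

            if spec.include_survey_effect:
                # vectorized per-grid update of eta rows
                cur = post.count_loglik_by_grid(theta, eta)
                step = np.exp(log_step["_eta"])
                prop_eta = eta + step * rng.standard_normal((G, T))
                new = post.count_loglik_by_grid(theta, prop_eta)
                dprior = -0.5 * (prop_eta**2 - eta**2).sum(axis=1)
                delta = np.nan_to_num(new - cur + dprior, nan=-np.inf)
                accept = rng.random(G) < np.exp(np.minimum(delta, 0.0))
                eta[accept] = prop_eta[accept]
                lp += float(delta[accept].sum())
                if warm:
                    acc_rate = float(np.mean(np.exp(np.minimum(delta, 0.0))))
                    log_step["_eta"] += (acc_rate - config.target_accept_block) / (it + 1) ** 0.6

            if latent_n:
                N, active = post.gibbs_latent_states(theta, eta, N, active, rng)
            mu_wish, sigma_w = _gibbs_hyper(theta, post, rng)
            _gibbs_omega(theta, post, rng)
            lp = cur_log_post(theta)

            # independence proposals on the scale radii (uniform over the
            # ladder): lets chains hop between modes of the scale posterior
            if "scales" in lay.blocks:
                s_sc = lay.blocks["scales"]
                for j in range(s_sc.start, s_sc.stop):
                    prop = theta.copy()
                    u_draw = rng.uniform(1e-9, 1.0 - 1e-9)
                    u_new = float(np.log(u_draw / (1.0 - u_draw)))
                    prop[j] = u_new
                    lp_prop = cur_log_post(prop)
                    # proposal density equals the prior's logistic Jacobian,
                    # which is part of lp: correct for it on both sides
                    q_old = _log_logistic_jac(theta[j])
                    q_new = _log_logistic_jac(u_new)
                    log_acc = (lp_prop - q_new) - (lp - q_old)
                    if rng.random() < _accept_prob(log_acc):
                        theta, lp = prop, lp_prop

            # interweaved rescaling of (omega, spline coefs): breaks the
            # funnel between the smoothing precision and coefficient scale
            s_spl = lay.blocks["spline"]
            i_om = lay.blocks["log_omega"].start
            k_spl = s_spl.stop - s_spl.start - 1
            prop = theta.copy()
            d_lw = np.exp(log_step["_rescale"]) * rng.standard_normal()
            prop[i_om] = theta[i_om] + d_lw
            prop[s_spl.start + 1 : s_spl.stop] *= np.exp(-0.5 * d_lw)
            lp_prop = cur_log_post(prop)
            # Jacobian of b -> b * sqrt(omega/omega')
            log_acc = lp_prop - lp - 0.5 * k_spl * d_lw
            acc = _accept_prob(log_acc)
            if rng.random() < acc:
                theta, lp = prop, lp_prop
            if warm:
                log_step["_rescale"] += (acc - config.target_accept_scalar) / (it + 1) ** 0.6

            if warm:
                n_seen += 1
                delta_m = theta - run_mean
                run_mean += delta_m / n_seen
                new_dev = theta - run_mean
                run_var += (delta_m * new_dev - run_var) / n_seen
                run_cov += (np.outer(delta_m, new_dev) - run_cov) / n_seen
            elif (it - config.n_warmup + 1) % config.thin == 0:
                c_theta.append(theta.copy())
                c_eta.append(eta.copy())
                c_mu.append(mu_wish.copy())
                c_sig.append(sigma_w.copy())

        all_theta.append(np.array(c_theta))
        all_eta.append(np.array(c_eta))
        all_mu.append(np.array(c_mu))
        all_sig.append(np.array(c_sig))

    return PosteriorSamples(
        names=list(lay.names),
        theta=np.array(all_theta),
        eta=np.array(all_eta) if spec.include_survey_effect else None,
        mu_wish=np.array(all_mu),
        sigma_w=np.array(all_sig),
        seed=seed,
        config=config,
        scale_names=list(spec.scaled),
        radii=data.radii.copy(),
        t_center=post.t_center,
    )


# ---------------------------------------------------------------------------
# diagnostics


def rhat(draws: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``draws`` is [chain, iteration].  Returns NaN for degenerate (zero
    within-chain variance) parameters rather than pretending convergence.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need [chain, draw] with >=2 chains and >=4 draws")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return float("nan")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def ess(draws: np.ndarray) -> float:
    """Effective sample size via Geyer's initial monotone sequence."""
    x = np.asarray(draws, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    nc, n = x.shape
    if np.allclose(x.var(), 0):
        return float("nan")
    acov = np.zeros(n)
    for c in range(nc):
        xc = x[c] - x[c].mean()
        f = np.fft.rfft(np.concatenate([xc, np.zeros(n)]))
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += ac
    acov /= nc
    rho = acov / acov[0]
    # pairwise sums; stop at first negative pair
    tau = 1.0
    t = 1
    prev = np.inf
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)  # enforce monotone decrease
        tau += 2.0 * pair
        prev = pair
        t += 2
    return float(nc * n / tau)


def bayes_pvalue_chisq(
    samples: PosteriorSamples,
    data: ModelData,
    spec: ModelSpec,
    seed: int = 0,
    eps: float = CHISQ_EPS,
) -> float:
    """Chi-square discrepancy posterior predictive check.

    For each retained draw: expected survey counts e = psi * lambda * pmarg,
    observed discrepancy T(y) = sum (d - e)^2 / (e + eps); a replicate data
    set is drawn from the fitted observation model (suitability indicator
    then thinned Poisson) and scored the same way.  Returns
    Pr[T(y_rep) >= T(y)].
    """
    post = Posterior(data, spec)
    rng = np.random.default_rng(seed)
    mask = data.mask
    d_obs = data.d
    exceed = 0
    total = 0
    for c in range(samples.n_chains):
        for i in range(samples.n_draws):
            theta = samples.theta[c, i]
            eta = samples.eta[c, i] if samples.eta is not None else np.zeros_like(d_obs, dtype=float)
            _, pa = post.availability(theta)
            _, pd_ = post.distance(theta)
            lam = np.exp(np.clip(post.log_lambda(theta, eta), -300, 300))
            psi = post.psi(theta)
            e = psi[:, None] * lam * pa * pd_
            t_obs = float((((d_obs - e) ** 2 / (e + eps))[mask]).sum())
            active = rng.random(data.n_grids) < psi
            d_rep = rng.poisson(lam * pa * pd_ * active[:, None])
            t_rep = float((((d_rep - e) ** 2 / (e + eps))[mask]).sum())
            exceed += t_rep >= t_obs
            total += 1
    return exceed / total


@dataclass
class FitReport:
    """Convergence and fit summary for one model run."""

    rhat: dict[str, float]
    ess: dict[str, float]
    bayes_p: float | None
    runtime_s: float
    seed: int
    n_chains: int
    n_draws_per_chain: int

    @property
    def max_rhat(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return max(vals) if vals else float("nan")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self) | {"max_rhat": self.max_rhat}, fh, indent=2)


def diagnose(
    samples: PosteriorSamples,
    data: ModelData | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> FitReport:
    """R-hat / ESS for every monitored parameter, plus the PPC if data given."""
    t0 = time.time()
    rh, es = {}, {}
    for name, arr in samples.monitored().items():
        rh[name] = rhat(arr)
        es[name] = ess(arr)
    p = None
    if data is not None and spec is not None:
        p = bayes_pvalue_chisq(samples, data, spec, seed=seed)
    return FitReport(
        rhat=rh,
        ess=es,
        bayes_p=p,
        runtime_s=time.time() - t0,
        seed=samples.seed,
        n_chains=samples.n_chains,
        n_draws_per_chain=samples.n_draws,
    )
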