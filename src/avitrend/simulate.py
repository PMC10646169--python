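"""Forward simulation of complete synthetic point-count studies.

Generates everything the analysis consumes — covariate rasters, a survey
panel, detection records — by running the generative model forward:
smooth covariate fields summarized at the true scale radii drive expected
abundance, a smooth spatial field drives suitability, true abundance is
zero-inflated Poisson, and each simulated individual is pushed through the
removal/distance observation process as an explicit agent, so the summed
detections can never exceed the latent abundance.

Covariate fields are sums of low-frequency cosine surfaces plus white
pixel noise: their buffer means are brute-force checkable and vary enough
across radii to make scale parameters identifiable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import BufferStack, CovariateRaster, summarize_buffers

SIZES = {
    "tiny": (20, 2, 1),
    "small": (300, 5, 2),
    "medium": (1000, 8, 3),
}


@dataclass
class SimConfig:
    """True parameter values and design of one synthetic study."""

    n_grids: int = 20
    n_years: int = 2
    n_bcrs: int = 1
    start_year: int = 2008
    species: str = "SYNTH"
    n_points_range: tuple[int, int] = (10, 16)
    cell_size: float = 150.0
    radii: tuple = tuple(np.arange(0.0, 3100.0, 100.0))
    grid_spacing: float = 1200.0
    max_distance_m: float = 400.0
    pixel_noise_sd: float = 0.25
    experience_frac: float = 0.5
    survey_prob: float = 1.0
    # abundance truth
    beta0: tuple = (0.6,)
    mu: tuple = (0.0,)
    beta: dict = dc_field(default_factory=dict)        # fixed covariate -> coef
    gamma: dict = dc_field(default_factory=dict)       # scaled covariate -> coef
    true_scales: dict = dc_field(default_factory=dict)  # scaled covariate -> radius m
    sd_survey: float = 0.0
    # suitability truth (smooth logit field)
    psi_logit_mean: float = 2.0
    psi_logit_amplitude: float = 0.0
    # observation truth
    alpha: float = -0.3
    a_date: tuple[float, float] = (0.2, -0.15)
    tau: tuple[float, float, float] = (5.0, 0.15, -0.1)
    seed_fields: int = 0

    def __post_init__(self) -> None:
        if len(self.beta0) != self.n_bcrs or len(self.mu) != self.n_bcrs:
            raise ValueError("beta0 / mu must have one entry per BCR")
        for cov, s in self.true_scales.items():
            if cov not in self.gamma:
                raise ValueError(f"scale given for unknown covariate {cov!r}")
            if not (min(self.radii) <= s <= max(self.radii)):
                raise ValueError(f"true scale {s} outside radius ladder")
        for p in (self.experience_frac, self.survey_prob):
            if not (0 < p <= 1):
                raise ValueError("fractions must lie in (0, 1]")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["radii"] = [float(r) for r in self.radii]
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("beta0", "mu", "a_date", "tau", "n_points_range", "radii"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticStudy:
    surveys: pd.DataFrame
    detections: pd.DataFrame
    rasters: dict              # {covariate: {year: CovariateRaster}}
    stack: BufferStack         # standardized
    truth: dict
    config: SimConfig


# ---------------------------------------------------------------------------
# smooth fields


class CosineField:
    """Sum of random plane-wave cosines; roughly unit variance."""

    def __init__(self, rng: np.random.Generator, n_waves: int = 6,
                 wavelength_range: tuple[float, float] = (2500.0, 12_000.0)):
        self.theta = rng.uniform(0, np.pi, n_waves)
        lo, hi = wavelength_range
        self.wavelength = np.exp(rng.uniform(np.log(lo), np.log(hi), n_waves))
        self.phase = rng.uniform(0, 2 * np.pi, n_waves)
        self.amp = rng.uniform(0.5, 1.0, n_waves)
        self.amp /= np.sqrt(0.5 * np.sum(self.amp**2))

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        arg = (
            2.0
            * np.pi
            * (x * np.cos(self.theta) + y * np.sin(self.theta))
            / self.wavelength
            + self.phase
        )
        return (self.amp * np.cos(arg)).sum(axis=-1)


def _place_centroids(rng, n, spacing, lo, hi):
    pts = []
    attempts = 0
    while len(pts) < n:
        p = rng.uniform(lo, hi, 2)
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= spacing**2 for q in pts):
            pts.append(p)
        attempts += 1
        if attempts > 500 * n:
            raise RuntimeError("cannot place centroids with requested spacing")
    return np.array(pts)


# ---------------------------------------------------------------------------
# main generator


def simulate_study(config: SimConfig, seed: int) -> SyntheticStudy:
    """Run the generative model forward; retains the full latent truth."""
    rng = np.random.default_rng(seed)
    field_rng = np.random.default_rng(config.seed_fields or seed)
    radii = np.asarray(config.radii, dtype=float)
    margin = radii.max() + config.cell_size
    side = max(np.sqrt(config.n_grids) * config.grid_spacing * 2.0, 4 * config.grid_spacing)
    lo, hi = margin, margin + side
    coords = _place_centroids(rng, config.n_grids, config.grid_spacing, lo, hi)
    grid_ids = [f"G{i:04d}" for i in range(config.n_grids)]
    years = np.arange(config.start_year, config.start_year + config.n_years)

    # BCR membership: vertical slabs of easting
    edges = np.quantile(coords[:, 0], np.linspace(0, 1, config.n_bcrs + 1))
    bcr_index = np.clip(
        np.searchsorted(edges, coords[:, 0], side="right") - 1, 0, config.n_bcrs - 1
    )
    bcr_ids = [10 + 2 * r for r in range(config.n_bcrs)]

    # rasters for scale-selected covariates
    extent = hi + margin
    ncell = int(np.ceil(extent / config.cell_size))
    px = (np.arange(ncell) + 0.5) * config.cell_size
    py = extent - (np.arange(ncell) + 0.5) * config.cell_size
    PX, PY = np.meshgrid(px, py)

    rasters: dict = {}
    tidy_frames = []
    centro = pd.DataFrame(
        {"grid_id": grid_ids, "easting": coords[:, 0], "northing": coords[:, 1]}
    )
    for cov in config.gamma:
        base = CosineField(field_rng)
        rasters[cov] = {}
        for yr in years:
            wiggle = CosineField(field_rng)
            vals = base(PX, PY) + 0.3 * wiggle(PX, PY)
            vals = vals + config.pixel_noise_sd * rng.standard_normal(vals.shape)
            rast = CovariateRaster(
                name=cov, year=int(yr), values=vals,
                cell_size=config.cell_size, origin=(0.0, extent),
            )
            rasters[cov][int(yr)] = rast
            tidy_frames.append(summarize_buffers(rast, centro, radii))

    # fixed covariates: smooth centroid values, radius-degenerate in the
    # stack; the smooth field is also rasterized so prediction maps have
    # every model covariate available
    for cov in config.beta:
        f = CosineField(field_rng)
        vals = f(coords[:, 0], coords[:, 1])
        rasters[cov] = {}
        field_px = f(PX, PY)
        for yr in years:
            rasters[cov][int(yr)] = CovariateRaster(
                name=cov, year=int(yr), values=field_px.copy(),
                cell_size=config.cell_size, origin=(0.0, extent),
            )
            yearly = vals + 0.1 * rng.standard_normal(config.n_grids)
            frame = pd.DataFrame(
                {
                    "grid_id": np.repeat(grid_ids, len(radii)),
                    "year": int(yr),
                    "covariate": cov,
                    "radius_m": np.tile(radii, config.n_grids),
                    "value": np.repeat(yearly, len(radii)),
                }
            )
            tidy_frames.append(frame)

    stack = BufferStack.from_tidy(pd.concat(tidy_frames, ignore_index=True)).standardize()

    # survey design
    rows = []
    for g, gid in enumerate(grid_ids):
        for yr in years:
            if rng.random() > config.survey_prob:
                continue
            rows.append(
                {
                    "grid_id": gid,
                    "year": int(yr),
                    "n_points": int(rng.integers(*config.n_points_range, endpoint=True)),
                    "minutes": 5 if yr <= 2009 else 6,
                    "ordinal_date": float(rng.uniform(140, 200)),
                    "mean_min_since_sunrise": float(rng.uniform(0, 300)),
                    "observer_experienced": int(rng.random() < config.experience_frac),
                    "bcr_id": bcr_ids[bcr_index[g]],
                    "easting": float(coords[g, 0]),
                    "northing": float(coords[g, 1]),
                }
            )
    surveys = pd.DataFrame(rows)

    # truth: linear predictor per survey
    e_raw = surveys["ordinal_date"].to_numpy()
    e_std = (e_raw - e_raw.mean()) / (e_raw.std() or 1.0)
    s_raw = surveys["mean_min_since_sunrise"].to_numpy()
    s_std = (s_raw - s_raw.mean()) / (s_raw.std() or 1.0)
    gi = {g: i for i, g in enumerate(grid_ids)}
    yi = {int(y): i for i, y in enumerate(years)}
    sg = surveys["grid_id"].map(gi).to_numpy()
    sy = surveys["year"].map(yi).to_numpy()

    log_mu = np.array([config.beta0[bcr_index[g]] for g in sg])
    log_mu += np.array(
        [config.mu[bcr_index[g]] for g in sg]
    ) * (surveys["year"].to_numpy() - config.start_year)
    for cov, coef in config.beta.items():
        v = stack.values[stack.cov_index(cov), sg, sy, 0]
        log_mu += coef * v
    w_true = {}
    for cov, coef in config.gamma.items():
        s_m = config.true_scales.get(cov, 564.0)
        grid_year = stack.interpolate_at_scale(cov, s_m)
        w_true[cov] = grid_year[sg, sy]
        log_mu += coef * w_true[cov]
    log_mu += np.log(surveys["n_points"].to_numpy(dtype=float))

    eps = (
        rng.normal(0.0, config.sd_survey, len(surveys))
        if config.sd_survey > 0
        else np.zeros(len(surveys))
    )
    lam = np.exp(log_mu + eps)

    psi_field = CosineField(field_rng)
    psi_logit = config.psi_logit_mean + config.psi_logit_amplitude * psi_field(
        coords[:, 0], coords[:, 1]
    )
    psi = expit(psi_logit)
    active = (rng.random(config.n_grids) < psi).astype(int)

    a = expit(config.alpha + config.a_date[0] * e_std + config.a_date[1] * e_std**2)
    M = surveys["minutes"].to_numpy()
    pa = 1.0 - (1.0 - a) ** M
    t0, t1, t2 = config.tau
    sigma = np.exp(t0 + t1 * surveys["observer_experienced"].to_numpy() + t2 * s_std)

    # agent-level observation process
    N = rng.poisson(lam * active[sg])
    det_rows = []
    d_gt = np.zeros(len(surveys), dtype=int)
    for i in range(len(surveys)):
        n = int(N[i])
        if n == 0:
            continue
        minutes_avail = _first_available_minute(rng, a[i], int(M[i]), n)
        r = config.max_distance_m * np.sqrt(rng.random(n))
        detect_p = np.exp(-(r**2) / (2.0 * sigma[i] ** 2))
        seen = (minutes_avail > 0) & (rng.random(n) < detect_p)
        d_gt[i] = int(seen.sum())
        for m_det, dist in zip(minutes_avail[seen], r[seen]):
            det_rows.append(
                {
                    "grid_id": surveys["grid_id"].iloc[i],
                    "year": int(surveys["year"].iloc[i]),
                    "species": config.species,
                    "distance_m": float(dist),
                    "minute": int(m_det),
                    "observer_experienced": int(surveys["observer_experienced"].iloc[i]),
                }
            )
    detections = pd.DataFrame(
        det_rows,
        columns=["grid_id", "year", "species", "distance_m", "minute", "observer_experienced"],
    )

    pd_bins = _pd_true(sigma, config.max_distance_m)
    truth = {
        "coords": coords,
        "bcr_index": bcr_index,
        "bcr_ids": bcr_ids,
        "N": N,
        "d": d_gt,
        "active": active,
        "psi": psi,
        "lambda": lam,
        "log_mu": log_mu,
        "eps": eps,
        "a": a,
        "pa": pa,
        "sigma": sigma,
        "pd_true": pd_bins,
        "w_true": w_true,
        "ord_date_std": e_std,
        "sunrise_std": s_std,
    }
    return SyntheticStudy(surveys, detections, rasters, stack, truth, config)


def _first_available_minute(rng, a: float, M: int, n: int) -> np.ndarray:
    """Geometric first-availability minute per individual (0 = never)."""
    g = rng.geometric(a, n)
    return np.where(g <= M, g, 0)


def _pd_true(sigma, maxd):
    """Exact (continuous) detection probability given availability."""
    from scipy.integrate import quad

    sigma = np.atleast_1d(sigma)
    out = np.array(
        [
            quad(lambda r, s=s: 2 * r / maxd**2 * np.exp(-(r**2) / (2 * s**2)), 0, maxd)[0]
            for s in sigma
        ]
    )
    return out


# ---------------------------------------------------------------------------
# canned configurations / fixtures


def default_sim_config(size: str, rng: np.random.Generator) -> SimConfig:
    """Draw a reasonable random truth for a named fixture size."""
    if size not in SIZES:
        raise ValueError(f"unknown size {size!r}; pick from {sorted(SIZES)}")
    n_grids, n_years, n_bcrs = SIZES[size]
    radii = tuple(np.arange(0.0, 3100.0, 100.0))
    interior = np.arange(300.0, 2800.0, 100.0)
    scaled = ["sagebrush", "pj_cover"]
    fixed = ["elevation"]
    return SimConfig(
        n_grids=n_grids,
        n_years=n_years,
        n_bcrs=n_bcrs,
        radii=radii,
        beta0=tuple(np.round(rng.normal(0.6, 0.25, n_bcrs), 3)),
        mu=tuple(np.round(rng.normal(0.0, 0.04, n_bcrs), 3)),
        beta={c: round(float(rng.normal(0, 0.3)), 3) for c in fixed},
        gamma={c: round(float(rng.choice([-1, 1]) * rng.uniform(0.4, 0.7)), 3) for c in scaled},
        true_scales={c: float(rng.choice(interior)) for c in scaled},
        sd_survey=round(float(rng.uniform(0.1, 0.25)), 3),
        psi_logit_mean=round(float(rng.uniform(1.0, 2.0)), 3),
        psi_logit_amplitude=1.0,
        alpha=round(float(rng.normal(-0.3, 0.15)), 3),
        a_date=(0.2, -0.15),
        tau=(round(float(np.log(150.0)), 3), 0.15, -0.1),
        seed_fields=int(rng.integers(1, 2**31)),
    )


def fixture_suite(size: str, seed: int, out_dir) -> SyntheticStudy:
    """Generate a named fixture and write it through the io module."""
    from . import io as avio

    rng = np.random.default_rng(seed)
    config = default_sim_config(size, rng)
    study = simulate_study(config, seed=seed + 1)
    avio.write_study(study, out_dir, seed=seed)
    return study


def load_fixture(path) -> SyntheticStudy:
    from . import io as avio

    return avio.read_study(path)


def manifest_roundtrip(config: SimConfig) -> SimConfig:
    return SimConfig.from_manifest(json.loads(json.dumps(config.to_manifest())))
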