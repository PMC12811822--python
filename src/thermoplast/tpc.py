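"""Kamykowski thermal-performance-curve model and hierarchical Bayesian fit.

A thermal performance curve (TPC) maps body temperature to a performance
measure (here sprint speed, m/s). The Kamykowski form is an asymmetric
double exponential

    P(T) = a * (1 - exp(-b*(T - tmin))) * (1 - exp(-c*(tmax - T)))

clamped to non-negative values, which is exactly zero at the critical
thermal limits ``tmin`` (CTmin) and ``tmax`` (CTmax). Critical-limit
measurements enter the fit as zero-performance anchor observations.

The hierarchical model places population-level locations and spreads on a
logit-reparameterised (bounded) scale and expresses individual deviations
non-centredly as scaled standard normals. Sampling uses an affine-invariant
ensemble MCMC (:mod:`emcee`); each configured chain is an independent
ensemble, and convergence is summarised by split R-hat and effective sample
size (:mod:`arviz`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

__all__ = [
    "TPCParams",
    "ParamBounds",
    "MCMCConfig",
    "PosteriorDraws",
    "DerivedTPC",
    "PARAM_NAMES",
    "kamykowski_performance",
    "estimate_start_bounds",
    "fit_hierarchical_tpc",
    "derive_pmax_topt",
    "posterior_curve_bands",
    "to_unconstrained",
    "to_bounded",
]

PARAM_NAMES = ("tmin", "tmax", "a", "b", "c")

#: columns expected in a trait table (long format, one row per observation)
TRAIT_COLUMNS = (
    "individual_id",
    "group",
    "kind",
    "temperature_c",
    "performance_ms",
    "ramp_rate_c_per_min",
)

OBS_KINDS = ("sprint", "ctmin_anchor", "ctmax_anchor")


@dataclass(frozen=True)
class TPCParams:
    """Kamykowski curve parameters.

    tmin, tmax : lower/upper zero-performance temperatures (°C)
    a : performance scale (m/s); b, c : rise and fall rates (1/°C)
    """

    tmin: float
    tmax: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.tmin < self.tmax:
            raise ValueError(f"tmin ({self.tmin}) must be < tmax ({self.tmax})")
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.tmin, self.tmax, self.a, self.b, self.c])


@dataclass(frozen=True)
class ParamBounds:
    """Per-parameter (init, lower, upper) triples, all with L < init < U."""

    init: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]

    def __post_init__(self) -> None:
        for k in PARAM_NAMES:
            L, i, U = self.lower[k], self.init[k], self.upper[k]
            if not (L < i < U):
                raise ValueError(f"bounds for {k} violate L < init < U: {L}, {i}, {U}")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        get = lambda d: np.array([d[k] for k in PARAM_NAMES])
        return get(self.init), get(self.lower), get(self.upper)


def kamykowski_performance(T, params: TPCParams):
    """Evaluate the clamped Kamykowski curve at temperature(s) ``T`` (°C).

    Returns max(0, a*(1-exp(-b*(T-tmin)))*(1-exp(-c*(tmax-T)))); exactly 0
    at the critical limits and 0 (clamped) outside them.
    """
    T = np.asarray(T, dtype=float)
    with np.errstate(over="ignore"):
        raw = (
            params.a
            * (1.0 - np.exp(-params.b * (T - params.tmin)))
            * (1.0 - np.exp(-params.c * (params.tmax - T)))
        )
    out = np.maximum(0.0, np.nan_to_num(raw, nan=0.0, posinf=0.0, neginf=0.0))
    return out if out.ndim else float(out)


def _curve_raw(T, tmin, tmax, a, b, c):
    # broadcast-friendly clamped curve on plain arrays
    with np.errstate(over="ignore"):
        raw = a * (1.0 - np.exp(-b * (T - tmin))) * (1.0 - np.exp(-c * (tmax - T)))
    return np.maximum(0.0, np.nan_to_num(raw, nan=0.0, posinf=0.0, neginf=0.0))


def to_unconstrained(theta, lower, upper):
    """Map bounded parameter values to the unconstrained (logit) scale."""
    theta, lower, upper = map(np.asarray, (theta, lower, upper))
    return logit((theta - lower) / (upper - lower))


def to_bounded(eta, lower, upper):
    """Inverse of :func:`to_unconstrained`: L + (U-L)*inv_logit(eta)."""
    eta, lower, upper = map(np.asarray, (eta, lower, upper))
    return lower + (upper - lower) * expit(eta)


def estimate_start_bounds(obs: pd.DataFrame) -> ParamBounds:
    """Heuristic initial values and box bounds from the observations.

    tmin/tmax initial values are the anchor means with ±10 °C boxes; the
    scale ``a`` starts at the maximum observed performance with a
    (0.1·init, 10·init] box; the rate parameters start at 0.1 /°C inside
    (1e-3, 10).
    """
    missing = [
        k
        for k in ("ctmin_anchor", "ctmax_anchor")
        if not (obs["kind"] == k).any()
    ]
    if missing:
        raise ValueError(f"missing anchor observations of kind(s): {missing}")
    sprint = obs[obs["kind"] == "sprint"]
    if len(sprint) < 3:
        raise ValueError("need at least 3 sprint observations")

    tmin0 = float(obs.loc[obs["kind"] == "ctmin_anchor", "temperature_c"].mean())
    tmax0 = float(obs.loc[obs["kind"] == "ctmax_anchor", "temperature_c"].mean())
    a0 = float(obs["performance_ms"].max())
    if a0 <= 0:
        raise ValueError("all observed performances are zero; cannot scale the curve")
    init = {"tmin": tmin0, "tmax": tmax0, "a": a0, "b": 0.1, "c": 0.1}
    lower = {"tmin": tmin0 - 10, "tmax": tmax0 - 10, "a": 0.1 * a0, "b": 1e-3, "c": 1e-3}
    upper = {"tmin": tmin0 + 10, "tmax": tmax0 + 10, "a": 10 * a0, "b": 10.0, "c": 10.0}
    return ParamBounds(init=init, lower=lower, upper=upper)


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-MCMC settings; one independent ensemble per chain."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    walkers: int | None = None  # default: ~2.5x the free-parameter count
    rhat_threshold: float = 1.05
    #: if True, the likelihood mean is the clamped curve; the default uses
    #: the raw curve so zero-performance anchors constrain the critical
    #: limits from both sides (predictions elsewhere are always clamped)
    clamp_likelihood_mean: bool = False


@dataclass
class PosteriorDraws:
    """Posterior draws with chain metadata and convergence diagnostics.

    Arrays are indexed (chain, draw, ...); ``theta_pop`` and ``theta_ind``
    are on the natural (bounded) scale; ``mu``/``sigma`` live on the
    unconstrained logit scale of the reparameterisation.
    """

    mu: np.ndarray  # (C, D, 5)
    sigma: np.ndarray  # (C, D, 5)
    z: np.ndarray  # (C, D, n_ind, 5)
    sigma_obs: np.ndarray  # (C, D)
    theta_pop: np.ndarray  # (C, D, 5) natural scale
    theta_ind: np.ndarray  # (C, D, n_ind, 5) natural scale
    individual_ids: list
    bounds: ParamBounds
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    divergences: int = 0
    converged: bool = True

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    def pop_params_flat(self) -> np.ndarray:
        """Population-scale parameters, flattened to (chains*draws, 5)."""
        return self.theta_pop.reshape(-1, 5)

    def summary(self) -> pd.DataFrame:
        flat = self.pop_params_flat()
        rows = []
        for k, name in enumerate(PARAM_NAMES):
            q = np.quantile(flat[:, k], [0.025, 0.5, 0.975])
            rows.append(
                {
                    "parameter": name,
                    "median": q[1],
                    "ci2.5": q[0],
                    "ci97.5": q[2],
                    "rhat": self.rhat.get(f"theta_pop_{name}", np.nan),
                    "ess": self.ess.get(f"theta_pop_{name}", np.nan),
                }
            )
        return pd.DataFrame(rows)


def _unpack(x: np.ndarray, n_ind: int):
    """Split a walker matrix (W, dim) into model blocks."""
    mu = x[:, 0:5]
    log_sigma = x[:, 5:10]
    z = x[:, 10 : 10 + 5 * n_ind].reshape(x.shape[0], n_ind, 5)
    log_sigma_obs = x[:, 10 + 5 * n_ind]
    return mu, log_sigma, z, log_sigma_obs


def _make_log_prob(T, y, ind_idx, n_ind, lower, upper, mu_prior_loc, sd_y, clamp_mean):
    """Vectorised log posterior over walker matrices (W, dim)."""

    def log_prob(x):
        x = np.atleast_2d(x)
        mu, log_sigma, z, log_sigma_obs = _unpack(x, n_ind)
        sigma = np.exp(log_sigma)
        sigma_obs = np.exp(log_sigma_obs)

        # priors: mu ~ N(unconstrained init, 1.5); sigma ~ half-N(0, 0.5)
        # with log-scale Jacobian; sigma_obs ~ half-N(0, sd(y)); z ~ N(0, 1)
        lp = -0.5 * np.sum(((mu - mu_prior_loc) / 1.5) ** 2, axis=1)
        lp += np.sum(-0.5 * (sigma / 0.5) ** 2 + log_sigma, axis=1)
        lp += -0.5 * (sigma_obs / sd_y) ** 2 + log_sigma_obs
        lp += -0.5 * np.sum(z**2, axis=(1, 2))

        # non-centred individual parameters on the unconstrained scale
        eta = mu[:, None, :] + sigma[:, None, :] * z  # (W, n_ind, 5)
        theta = lower + (upper - lower) * expit(eta)
        th = theta[:, ind_idx, :]  # (W, n_obs, 5)
        with np.errstate(over="ignore"):
            mean = (
                th[..., 2]
                * (1.0 - np.exp(-th[..., 3] * (T - th[..., 0])))
                * (1.0 - np.exp(-th[..., 4] * (th[..., 1] - T)))
            )
        mean = np.clip(np.nan_to_num(mean, nan=-1e6, posinf=1e6, neginf=-1e6), -1e6, 1e6)
        if clamp_mean:
            mean = np.maximum(0.0, mean)
        resid = y - mean
        n_obs = T.shape[0]
        ll = -0.5 * np.sum((resid / sigma_obs[:, None]) ** 2, axis=1)
        ll -= n_obs * np.log(sigma_obs)
        out = lp + ll
        out[~np.isfinite(out)] = -np.inf
        return out

    return log_prob


def fit_hierarchical_tpc(
    obs: pd.DataFrame,
    bounds: ParamBounds | None = None,
    mcmc_cfg: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Fit the hierarchical Kamykowski model to one group's observations.

    ``obs`` is a long trait table (see :data:`TRAIT_COLUMNS`) containing
    sprint rows and zero-performance anchor rows for ≥2 individuals. Anchors
    enter the likelihood as ordinary y = 0 observations. Each bounded
    parameter θ is represented as L + (U−L)·inv_logit(η); individual η are
    non-centred, η_i = μ + σ·z_i. The Gaussian likelihood uses the clamped
    curve mean (the mean, not the noise, is clamped).

    If any split R-hat exceeds the configured threshold the result is
    returned with ``converged=False`` (flagged, never silently dropped).
    """
    cfg = mcmc_cfg or MCMCConfig()
    if bounds is None:
        bounds = estimate_start_bounds(obs)

    ids = list(pd.unique(obs["individual_id"]))
    if len(ids) < 2:
        raise ValueError("hierarchical fit requires at least 2 individuals")
    y = obs["performance_ms"].to_numpy(dtype=float)
    if np.all(y == 0):
        raise ValueError("degenerate data: every observed performance is zero")
    T = obs["temperature_c"].to_numpy(dtype=float)
    ind_idx = pd.Categorical(obs["individual_id"], categories=ids).codes
    n_ind = len(ids)

    init, lower, upper = bounds.arrays()
    mu0 = to_unconstrained(init, lower, upper)
    sd_y = float(np.std(y)) or 1.0
    log_prob = _make_log_prob(
        T, y, ind_idx, n_ind, lower, upper, mu0, sd_y, cfg.clamp_likelihood_mean
    )

    dim = 11 + 5 * n_ind
    n_walkers = cfg.walkers or max(int(2.5 * dim) // 2 * 2, 2 * dim + 2)

    # posterior mode as a common starting point for all ensembles
    x0 = np.concatenate([mu0, np.log(np.full(5, 0.2)), np.zeros(5 * n_ind), [np.log(sd_y / 2)]])
    opt = optimize.minimize(
        lambda v: -float(log_prob(v[None, :])[0]),
        x0,
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    x_map = opt.x if np.isfinite(opt.fun) else x0

    chains_mu, chains_sigma, chains_z, chains_so = [], [], [], []
    for chain in range(cfg.chains):
        rs = np.random.RandomState((cfg.seed * 1000003 + chain * 7919) % (2**31 - 1))
        p0 = x_map[None, :] + 0.1 * rs.standard_normal((n_walkers, dim))
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(n_walkers, dim, log_prob, vectorize=True, moves=moves)
        sampler.random_state = rs.get_state()
        state = sampler.run_mcmc(p0, cfg.warmup, progress=False)
        sampler.reset()
        n_steps = max(int(np.ceil(cfg.draws / n_walkers)) * 4, 20)
        sampler.run_mcmc(state, n_steps, progress=False)
        chain_flat = sampler.get_chain().reshape(n_steps * n_walkers, dim)
        # evenly spaced thinning down to the configured number of draws
        take = np.linspace(0, chain_flat.shape[0] - 1, cfg.draws).astype(int)
        xs = chain_flat[take]
        mu, log_sigma, z, log_so = _unpack(xs, n_ind)
        chains_mu.append(mu)
        chains_sigma.append(np.exp(log_sigma))
        chains_z.append(z)
        chains_so.append(np.exp(log_so))

    mu = np.stack(chains_mu)  # (C, D, 5)
    sigma = np.stack(chains_sigma)
    z = np.stack(chains_z)
    sigma_obs = np.stack(chains_so)
    theta_pop = to_bounded(mu, lower, upper)
    eta_ind = mu[:, :, None, :] + sigma[:, :, None, :] * z
    theta_ind = to_bounded(eta_ind, lower, upper)

    # split R-hat / ESS per stored population-level quantity
    rhat, ess = {}, {}
    named = {f"theta_pop_{nm}": theta_pop[..., k] for k, nm in enumerate(PARAM_NAMES)}
    named.update({f"sigma_{nm}": sigma[..., k] for k, nm in enumerate(PARAM_NAMES)})
    named["sigma_obs"] = sigma_obs
    for name, arr in named.items():
        da = az.convert_to_dataset({name: arr})
        rhat[name] = float(az.rhat(da)[name].values)
        ess[name] = float(az.ess(da)[name].values)

    converged = all(np.isnan(v) or v <= cfg.rhat_threshold for v in rhat.values())
    if not converged:
        warnings.warn(
            "split R-hat above threshold for: "
            + ", ".join(k for k, v in rhat.items() if v > cfg.rhat_threshold),
            RuntimeWarning,
        )
    return PosteriorDraws(
        mu=mu,
        sigma=sigma,
        z=z,
        sigma_obs=sigma_obs,
        theta_pop=theta_pop,
        theta_ind=theta_ind,
        individual_ids=ids,
        bounds=bounds,
        rhat=rhat,
        ess=ess,
        divergences=0,
        converged=converged,
    )


@dataclass(frozen=True)
class GridConfig:
    coarse: int = 50
    fine: int = 100


@dataclass
class DerivedTPC:
    """Per-draw maximum performance and optimal temperature."""

    pmax: np.ndarray  # (n_draws,)
    topt: np.ndarray  # (n_draws,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pmax": self.pmax, "topt": self.topt})


def _two_stage_argmax(theta: np.ndarray, coarse: int, fine: int):
    """Vectorised two-stage grid maximisation of the population curve.

    theta: (N, 5) rows (tmin, tmax, a, b, c). Returns (pmax, topt) arrays.
    """
    tmin, tmax, a, b, c = (theta[:, k][:, None] for k in range(5))
    frac = np.linspace(0.0, 1.0, coarse)[None, :]
    Tc = tmin + (tmax - tmin) * frac
    Pc = _curve_raw(Tc, tmin, tmax, a, b, c)
    j = np.argmax(Pc, axis=1)
    rows = np.arange(theta.shape[0])
    lo = Tc[rows, np.maximum(j - 1, 0)]
    hi = Tc[rows, np.minimum(j + 1, coarse - 1)]
    frac_f = np.linspace(0.0, 1.0, fine)[None, :]
    Tf = lo[:, None] + (hi - lo)[:, None] * frac_f
    Pf = _curve_raw(Tf, tmin, tmax, a, b, c)
    jf = np.argmax(Pf, axis=1)
    return Pf[rows, jf], Tf[rows, jf]


def derive_pmax_topt(
    draws: PosteriorDraws | np.ndarray, grid_cfg: GridConfig | None = None
) -> DerivedTPC:
    """Two-stage grid search for P_max and T_opt per posterior draw.

    A 50-point coarse grid over [tmin, tmax] locates the bracket (one coarse
    step either side of the argmax, clipped at the limits); a 100-point fine
    grid over the bracket yields T_opt (argmax) and P_max (its value). Uses
    the population-level curve of each draw.
    """
    cfg = grid_cfg or GridConfig()
    theta = draws.pop_params_flat() if isinstance(draws, PosteriorDraws) else np.atleast_2d(draws)
    if theta.size == 0:
        raise ValueError("no posterior draws supplied")
    pmax, topt = _two_stage_argmax(np.asarray(theta, dtype=float), cfg.coarse, cfg.fine)
    return DerivedTPC(pmax=pmax, topt=topt)


def posterior_curve_bands(draws: PosteriorDraws | np.ndarray, T_grid) -> pd.DataFrame:
    """Pointwise posterior quantiles of the population curve.

    Returns a frame with columns temperature_c, q2.5, q25, median, q75,
    q97.5; the 95% band contains the 50% band contains the median at every
    grid point by construction of quantiles.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0:
        raise ValueError("empty temperature grid")
    theta = draws.pop_params_flat() if isinstance(draws, PosteriorDraws) else np.atleast_2d(draws)
    tmin, tmax, a, b, c = (theta[:, k][:, None] for k in range(5))
    P = _curve_raw(T_grid[None, :], tmin, tmax, a, b, c)  # (N, G)
    qs = np.quantile(P, [0.025, 0.25, 0.5, 0.75, 0.975], axis=0)
    return pd.DataFrame(
        {
            "temperature_c": T_grid,
            "q2.5": qs[0],
            "q25": qs[1],
            "median": qs[2],
            "q75": qs[3],
            "q97.5": qs[4],
        }
    )
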