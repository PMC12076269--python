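"""Probabilistic power-law hemolysis model: priors, likelihood, sampling.

The observation model treats each measured hemolysis index as a draw from a
Student's t distribution centred on the power-law prediction:

    HI_i ~ t( mu = C * tau_i^beta * t_i^alpha,  scale = sigma,  dof = nu )

with uninformed priors: C ~ Uniform(0, 1) (or fixed), alpha and beta ~
Normal(0, 1), sigma ~ HalfNormal(1) and nu ~ Exponential(mean 30) (or
fixed).  sigma absorbs the replicate scatter the deterministic parameters
cannot explain; nu lets the likelihood tolerate outliers.

Usage follows the Model/Results convention::

    model = HemolysisModel(dataset, priors=PriorSpec(c_prior=("fixed", 1.228e-5)))
    res = model.fit(SamplerConfig.quick(seed=1))
    res.summary()            # medians, 5-95% intervals, R-hat
    res.correlations()       # pooled pairwise posterior correlations
    res.fit_truncated_lognormal("alpha")

Sampling uses the affine-invariant ensemble sampler (emcee): each requested
chain is an independent ensemble run whose flattened draws are thinned to
exactly ``n_draws`` retained samples, so the draw bookkeeping matches the
chains x draws contract of gradient-based samplers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .datasets import ShearDataset
from .powerlaw import PowerLawParams

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "LogNormalFit",
    "HemolysisModel",
    "HemolysisResults",
    "build_posterior_model",
    "sample_posterior",
    "gelman_rubin",
    "posterior_summary",
    "parameter_correlations",
    "fit_truncated_lognormal",
]

PARAM_ORDER = ("C", "alpha", "beta", "sigma", "nu")


@dataclass(frozen=True)
class PriorSpec:
    """Prior specification for the free parameters.

    ``c_prior`` is ``("uniform", low, high)`` (default (0, 1)) or
    ``("fixed", value)``; ``alpha_prior``/``beta_prior`` are
    ``("normal", mean, sd)``; ``sigma_prior`` is ``("halfnormal", sd)``;
    ``nu_prior`` is ``("exponential", mean)`` (default mean 30, i.e. rate
    1/30) or ``("fixed", value)``.
    """

    c_prior: tuple = ("uniform", 0.0, 1.0)
    alpha_prior: tuple = ("normal", 0.0, 1.0)
    beta_prior: tuple = ("normal", 0.0, 1.0)
    sigma_prior: tuple = ("halfnormal", 1.0)
    nu_prior: tuple = ("exponential", 30.0)

    def __post_init__(self) -> None:
        if self.c_prior[0] not in ("uniform", "fixed"):
            raise ValueError("c_prior must be uniform or fixed")
        if self.c_prior[0] == "fixed" and self.c_prior[1] <= 0:
            raise ValueError("fixed C must be > 0")
        if self.c_prior[0] == "uniform" and not (
            0 <= self.c_prior[1] < self.c_prior[2]
        ):
            raise ValueError("uniform C prior needs 0 <= low < high")
        for name in ("alpha_prior", "beta_prior"):
            p = getattr(self, name)
            if p[0] != "normal" or p[2] <= 0:
                raise ValueError(f"{name} must be ('normal', mean, sd>0)")
        if self.sigma_prior[0] != "halfnormal" or self.sigma_prior[1] <= 0:
            raise ValueError("sigma_prior must be ('halfnormal', sd>0)")
        if self.nu_prior[0] not in ("exponential", "fixed"):
            raise ValueError("nu_prior must be exponential or fixed")
        if self.nu_prior[1] <= 0:
            raise ValueError("nu hyperparameter must be > 0")

    def fix_c(self, value: float) -> "PriorSpec":
        return replace(self, c_prior=("fixed", float(value)))

    @property
    def free_names(self) -> tuple[str, ...]:
        names = []
        if self.c_prior[0] != "fixed":
            names.append("C")
        names += ["alpha", "beta", "sigma"]
        if self.nu_prior[0] != "fixed":
            names.append("nu")
        return tuple(names)


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration.

    The reference configuration samples 4 chains x 50,000 retained draws
    after a 1,000-step burn-in at target acceptance 0.95; ``quick()`` is a
    reduced 4 x 2,000 configuration for tests and inner loops.
    ``target_accept`` is advisory for the ensemble sampler (no step-size
    adaptation); ``n_walkers`` is the ensemble size per chain.
    """

    n_chains: int = 4
    n_draws: int = 50_000
    n_tune: int = 1_000
    target_accept: float = 0.95
    seed: int = 0
    n_walkers: int = 32
    min_acceptance_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_draws < 1 or self.n_tune < 0:
            raise ValueError("counts must be >= 1 (n_tune >= 0)")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")
        if self.n_walkers < 12:
            raise ValueError("n_walkers must be >= 12")

    @classmethod
    def quick(cls, seed: int = 0, n_chains: int = 4, n_draws: int = 2_000,
              n_tune: int = 1_000) -> "SamplerConfig":
        return cls(n_chains=n_chains, n_draws=n_draws, n_tune=n_tune, seed=seed)


@dataclass(frozen=True)
class LogNormalFit:
    """Truncated log-normal fit of a posterior marginal.

    ``shape`` is the log-sd, ``scale`` the median (location fixed at 0);
    ``trunc_low``/``trunc_high`` are the fitted distribution's 1% and 99%
    quantiles, used as hard sampling bounds downstream.
    """

    shape: float
    scale: float
    trunc_low: float
    trunc_high: float
    location: float = 0.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be > 0")
        if not self.trunc_low < self.trunc_high:
            raise ValueError("trunc_low must be < trunc_high")

    def frozen(self):
        """The underlying (untruncated) scipy distribution."""
        return stats.lognorm(self.shape, loc=0.0, scale=self.scale)

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "LogNormalFit":
        samples = np.asarray(samples, dtype=float).ravel()
        if np.any(samples <= 0):
            raise ValueError("log-normal fit requires strictly positive samples")
        shape, _, scale = stats.lognorm.fit(samples, floc=0.0)
        dist = stats.lognorm(shape, loc=0.0, scale=scale)
        return cls(
            shape=float(shape),
            scale=float(scale),
            trunc_low=float(dist.ppf(0.01)),
            trunc_high=float(dist.ppf(0.99)),
        )

    @classmethod
    def point_mass(cls, value: float, rel_width: float = 1e-9) -> "LogNormalFit":
        """Degenerate fit concentrated at ``value`` (for limit checks)."""
        dist = stats.lognorm(rel_width, loc=0.0, scale=value)
        return cls(
            shape=rel_width,
            scale=float(value),
            trunc_low=float(dist.ppf(0.01)),
            trunc_high=float(dist.ppf(0.99)),
        )


def _student_t_logpdf(x, mu, sigma, nu):
    z = (x - mu) / sigma
    return (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
        - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)
    )


class HemolysisModel:
    """Bayesian power-law hemolysis model bound to a calibration dataset."""

    def __init__(self, dataset: ShearDataset, priors: Optional[PriorSpec] = None):
        if len(dataset) == 0:
            raise ValueError("dataset must be non-empty")
        self.dataset = dataset
        self.priors = priors if priors is not None else PriorSpec()
        self.free_names = self.priors.free_names
        self._tau = dataset.tau
        self._t = dataset.t_exp
        self._hi = dataset.hi

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, priors: Optional[PriorSpec] = None,
                       label: str = "") -> "HemolysisModel":
        return cls(ShearDataset.from_frame(df, label=label), priors=priors)

    # -- log-posterior ----------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        theta = np.atleast_2d(theta)
        vals = {}
        j = 0
        for name in self.free_names:
            vals[name] = theta[:, j]
            j += 1
        if "C" not in vals:
            vals["C"] = np.full(theta.shape[0], self.priors.c_prior[1])
        if "nu" not in vals:
            vals["nu"] = np.full(theta.shape[0], self.priors.nu_prior[1])
        return vals

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalised log-posterior; accepts (ndim,) or (m, ndim)."""
        theta = np.asarray(theta, dtype=float)
        scalar = theta.ndim == 1
        v = self._unpack(theta)
        m = v["alpha"].shape[0]
        logp = np.zeros(m)

        ok = (v["sigma"] > 0) & (v["nu"] > 0)
        if self.priors.c_prior[0] == "uniform":
            lo, hi = self.priors.c_prior[1], self.priors.c_prior[2]
            ok &= (v["C"] > lo) & (v["C"] < hi) & (v["C"] > 0)
            logp += -np.log(hi - lo)
        logp = np.where(ok, logp, -np.inf)
        if not np.any(ok):
            return float(logp[0]) if scalar else logp

        for name, prior in (
            ("alpha", self.priors.alpha_prior),
            ("beta", self.priors.beta_prior),
        ):
            mu, sd = prior[1], prior[2]
            logp += -0.5 * np.log(2 * np.pi * sd**2) - (v[name] - mu) ** 2 / (2 * sd**2)

        sd = self.priors.sigma_prior[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            logp += np.where(
                ok,
                0.5 * np.log(2 / (np.pi * sd**2)) - v["sigma"] ** 2 / (2 * sd**2),
                -np.inf,
            )
            if self.priors.nu_prior[0] == "exponential":
                rate = 1.0 / self.priors.nu_prior[1]
                logp += np.where(ok, np.log(rate) - rate * v["nu"], -np.inf)

            # Student-t likelihood around the power-law mean
            pred = (
                v["C"][:, None]
                * self._tau[None, :] ** v["beta"][:, None]
                * self._t[None, :] ** v["alpha"][:, None]
            )
            ll = _student_t_logpdf(
                self._hi[None, :],
                pred,
                v["sigma"][:, None],
                v["nu"][:, None],
            ).sum(axis=1)
        logp = np.where(ok & np.isfinite(ll), logp + np.where(ok, ll, 0.0), -np.inf)
        return float(logp[0]) if scalar else logp

    # -- initialisation ---------------------------------------------------

    def _regression_start(self) -> dict[str, float]:
        """Log-log least-squares start point (plus residual scale)."""
        mask = self._hi > 0
        ln_hi = np.log(self._hi[mask])
        ln_tau = np.log(self._tau[mask])
        ln_t = np.log(self._t[mask])
        c_fixed = self.priors.c_prior[0] == "fixed"
        if c_fixed:
            c0 = self.priors.c_prior[1]
            X = np.column_stack([ln_tau, ln_t])
            coef, *_ = np.linalg.lstsq(X, ln_hi - np.log(c0), rcond=None)
            beta0, alpha0 = coef
        else:
            X = np.column_stack([np.ones(mask.sum()), ln_tau, ln_t])
            coef, *_ = np.linalg.lstsq(X, ln_hi, rcond=None)
            c0 = float(np.clip(np.exp(coef[0]), 1e-12, self.priors.c_prior[2] * 0.999))
            beta0, alpha0 = coef[1], coef[2]
        p = PowerLawParams(max(c0, 1e-300), float(alpha0), float(beta0))
        resid = self._hi - p.c_coeff * self._tau**p.beta * self._t**p.alpha
        sigma0 = float(max(np.std(resid), 1e-6))
        start = {"C": c0, "alpha": float(alpha0), "beta": float(beta0),
                 "sigma": sigma0, "nu": 10.0}
        return start

    def map_estimate(self, maxiter: int = 2000) -> dict[str, float]:
        """Posterior-mode estimate (Nelder-Mead from the regression start)."""
        start = self._regression_start()
        x0 = np.array([start[n] for n in self.free_names])

        def neg(theta):
            lp = self.log_posterior(theta)
            return -lp if np.isfinite(lp) else 1e300

        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-10},
        )
        x = res.x if np.isfinite(self.log_posterior(res.x)) else x0
        out = dict(zip(self.free_names, (float(v) for v in x)))
        return out

    def _initial_walkers(self, cfg: SamplerConfig, rng: np.random.Generator
                         ) -> np.ndarray:
        center = self.map_estimate()
        x0 = np.array([center[n] for n in self.free_names])
        ndim = len(self.free_names)
        scale = 1e-3 * np.abs(x0) + 1e-9
        walkers = x0[None, :] + scale[None, :] * rng.standard_normal(
            (cfg.n_walkers, ndim)
        )
        for j, name in enumerate(self.free_names):
            if name in ("sigma", "nu"):
                walkers[:, j] = np.abs(walkers[:, j]) + 1e-12
            if name == "C":
                lo, hi = self.priors.c_prior[1], self.priors.c_prior[2]
                walkers[:, j] = np.clip(np.abs(walkers[:, j]), 1e-300, hi * 0.999999)
        return walkers

    # -- sampling ---------------------------------------------------------

    def fit(self, cfg: Optional[SamplerConfig] = None) -> "HemolysisResults":
        """Sample the posterior and return a results object.

        Each chain is an independent ensemble run seeded from
        ``cfg.seed + chain index``; the flattened post-burn-in draws are
        thinned to exactly ``cfg.n_draws`` retained samples per chain.
        """
        cfg = cfg if cfg is not None else SamplerConfig()
        ndim = len(self.free_names)
        steps = -(-cfg.n_draws // cfg.n_walkers)  # ceil
        draws = {n: np.empty((cfg.n_chains, cfg.n_draws)) for n in self.free_names}
        acc_fractions = []
        for chain in range(cfg.n_chains):
            seed = (int(cfg.seed) + 997 * chain) % (2**31 - 1)
            rng = np.random.default_rng(seed)
            p0 = self._initial_walkers(cfg, rng)
            sampler = emcee.EnsembleSampler(
                cfg.n_walkers, ndim, self.log_posterior, vectorize=True
            )
            sampler.random_state = np.random.RandomState(seed).get_state()
            state = sampler.run_mcmc(p0, cfg.n_tune + steps, progress=False)
            del state
            chain_draws = sampler.get_chain(discard=cfg.n_tune)  # (steps, nw, ndim)
            flat = chain_draws.reshape(-1, ndim)[-cfg.n_draws:, :]
            for j, name in enumerate(self.free_names):
                draws[name][chain] = flat[:, j]
            acc_fractions.append(float(np.mean(sampler.acceptance_fraction)))

        warnings_list = []
        if min(acc_fractions) < cfg.min_acceptance_fraction:
            msg = (
                f"low ensemble acceptance fraction "
                f"(min {min(acc_fractions):.3f} < {cfg.min_acceptance_fraction}); "
                "posterior may be poorly mixed"
            )
            warnings_list.append(msg)
            warnings.warn(msg)
        metadata = {
            "dataset_label": self.dataset.label,
            "priors": self.priors,
            "sampler_config": cfg,
            "sampler": "emcee affine-invariant ensemble",
            "acceptance_fractions": acc_fractions,
            "warnings": warnings_list,
        }
        return HemolysisResults(model=self, draws=draws, metadata=metadata)


@dataclass
class HemolysisResults:
    """Posterior sample container with diagnostics and summaries.

    ``draws`` maps each free parameter name to a (n_chains, n_draws) array.
    """

    model: HemolysisModel
    draws: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.draws.values()}
        if len(shapes) != 1:
            raise ValueError("all parameters must share one (chains, draws) shape")
        if "sigma" in self.draws and np.any(self.draws["sigma"] <= 0):
            raise ValueError("sigma draws must be > 0")
        if "nu" in self.draws and np.any(self.draws["nu"] <= 0):
            raise ValueError("nu draws must be > 0")

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(self.draws.keys())

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated, shape (n_chains * n_draws,)."""
        return self.draws[name].reshape(-1)

    # -- diagnostics ------------------------------------------------------

    def gelman_rubin(self) -> dict[str, float]:
        """Split-chain potential scale reduction factor per parameter."""
        if self.n_chains < 2:
            raise ValueError("Gelman-Rubin requires at least 2 chains")
        idata = az.from_dict(posterior={k: v for k, v in self.draws.items()})
        rhat = az.rhat(idata)
        return {k: float(rhat[k].values) for k in self.draws}

    def posterior_summary(self) -> pd.DataFrame:
        """Pooled median and 5-95% interval per parameter."""
        rows = {}
        for name, arr in self.draws.items():
            pooled = arr.reshape(-1)
            q05, med, q95 = np.quantile(pooled, [0.05, 0.5, 0.95])
            rows[name] = {"median": med, "q05": q05, "q95": q95}
        return pd.DataFrame(rows).T[["median", "q05", "q95"]]

    def correlations(self) -> pd.DataFrame:
        """Pairwise linear correlations of the pooled draws.

        Zero-variance parameters yield NaN entries (flagged as undefined
        rather than raising).
        """
        names = list(self.draws)
        if len(names) < 2:
            raise ValueError("need at least 2 free parameters")
        mat = np.vstack([self.pooled(n) for n in names])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(mat)
        return pd.DataFrame(corr, index=names, columns=names)

    def fit_truncated_lognormal(self, name: str) -> LogNormalFit:
        """ML log-normal fit (location 0) of one marginal, 1%/99% truncated."""
        return LogNormalFit.from_samples(self.pooled(name))

    def summary(self) -> pd.DataFrame:
        """Summary table: median, 5-95% interval and R-hat per parameter."""
        tab = self.posterior_summary()
        if self.n_chains >= 2:
            rhat = self.gelman_rubin()
            tab["r_hat"] = [rhat[n] for n in tab.index]
        return tab

    # -- export -----------------------------------------------------------

    def to_csv_dir(self, outdir) -> None:
        """One CSV per parameter (columns = chains) plus a JSON sidecar."""
        from .io import write_posterior  # local import to avoid cycle

        write_posterior(self, outdir)


# -- spec-surface functional wrappers -------------------------------------

def build_posterior_model(dataset: ShearDataset,
                          priors: Optional[PriorSpec] = None) -> HemolysisModel:
    """Construct the model (an evaluable unnormalised log-posterior)."""
    return HemolysisModel(dataset, priors=priors)


def sample_posterior(model: HemolysisModel, cfg: SamplerConfig) -> HemolysisResults:
    return model.fit(cfg)


def gelman_rubin(results: HemolysisResults) -> dict[str, float]:
    return results.gelman_rubin()


def posterior_summary(results: HemolysisResults) -> pd.DataFrame:
    return results.posterior_summary()


def parameter_correlations(results: HemolysisResults) -> pd.DataFrame:
    return results.correlations()


def fit_truncated_lognormal(results: HemolysisResults, name: str) -> LogNormalFit:
    return results.fit_truncated_lognormal(name)
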