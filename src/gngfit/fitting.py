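"""Hierarchical type-II maximum-likelihood (empirical-Bayes) model fitting.

Each subject's parameters are assumed to be drawn from independent normal
population distributions on a transformed, unconstrained scale (logit for
learning rates, log for outcome impacts, identity for bias and Pavlovian
weight). Fitting alternates:

* E-step: per-subject MAP estimation of the transformed parameters under
  the current population prior (multi-start L-BFGS-B), with the posterior
  curvature at the mode obtained by central finite differences (the Laplace
  approximation);
* M-step: moment updates of the hyperparameters — the population mean is
  the mean of the subject MAPs, the population variance the mean squared
  deviation from that mean plus the mean Laplace variance (floored to avoid
  prior collapse).

Iteration stops when the hyperparameters move less than a tolerance. The
per-iteration Laplace approximation to the total log evidence is traced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from ._kernels import neg_log_posterior, neg_log_posterior_grad
from .models import ModelSpec, ParamVector
from .task import session_to_arrays

__all__ = [
    "Direction",
    "FitConfig",
    "PopulationPrior",
    "SubjectFit",
    "FitResult",
    "FittingError",
    "transform_params",
    "to_unconstrained",
    "to_natural",
    "map_estimate",
    "em_fit",
]

logger = logging.getLogger(__name__)


class FittingError(RuntimeError):
    """Optimization failed in a way the caller must see."""


class Direction(Enum):
    TO_UNCONSTRAINED = "to_unconstrained"
    TO_NATURAL = "to_natural"


# --------------------------------------------------------------------------
# parameter transforms
# --------------------------------------------------------------------------

def _transform_one(name: str, value: float, direction: Direction) -> float:
    if name.startswith("eps"):
        if direction is Direction.TO_UNCONSTRAINED:
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name}={value} outside (0, 1)")
            return math.log(value / (1.0 - value))
        return 1.0 / (1.0 + math.exp(-value))
    if name.startswith("rho"):
        if direction is Direction.TO_UNCONSTRAINED:
            if value <= 0.0:
                raise ValueError(f"{name}={value} must be positive")
            return math.log(value)
        return math.exp(value)
    return value  # bias and pavlovian weight: identity


def to_unconstrained(spec: ModelSpec, named: dict[str, float]) -> np.ndarray:
    """Natural-scale named parameters -> free vector in canonical order."""
    return np.array([
        _transform_one(n, named[n], Direction.TO_UNCONSTRAINED) for n in spec.param_names
    ])


def to_natural(spec: ModelSpec, x: np.ndarray) -> dict[str, float]:
    """Free vector -> natural-scale named parameters."""
    return {
        n: _transform_one(n, float(v), Direction.TO_NATURAL)
        for n, v in zip(spec.param_names, x)
    }


def transform_params(p: ParamVector, direction: Direction) -> ParamVector:
    """Apply the per-parameter transform elementwise to a full ParamVector.

    The returned object carries transformed values in the same slots (so its
    ``eps`` entries are logits, ``rho`` entries logs under TO_UNCONSTRAINED);
    domain checks are bypassed on the transformed copy.
    """
    eps = {k: _transform_one("eps", v, direction) for k, v in p.eps.items()}
    rho = {k: _transform_one("rho", v, direction) for k, v in p.rho.items()}
    out = object.__new__(ParamVector)
    out.eps, out.rho, out.bias, out.pav = eps, rho, p.bias, p.pav
    return out


def _bounds(spec: ModelSpec) -> list[tuple[float, float]]:
    # wide enough to be effectively unconstrained, tight enough to avoid overflow
    out = []
    for name in spec.param_names:
        if name.startswith("eps"):
            out.append((-16.0, 16.0))
        elif name.startswith("rho"):
            out.append((-10.0, 10.0))
        else:
            out.append((-20.0, 20.0))
    return out


# --------------------------------------------------------------------------
# configuration and result containers
# --------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Tunables for MAP estimation, EM and iBIC scoring.

    Loadable from YAML/JSON (see :func:`FitConfig.from_file`).
    """

    n_restarts: int = 10          # multi-start count for cold MAP estimation
    n_restarts_warm: int = 2      # fresh prior draws added to warm starts in later E-steps
    em_tol: float = 1e-3          # max |delta mu|, |delta sigma2| to declare convergence
    em_max_iter: int = 200
    variance_floor: float = 1e-6  # M-step floor on population variances
    init_sigma2: float = 3.0      # vague initial population variance (transformed scale)
    hess_step: float = 1e-4       # central-difference step for the Laplace curvature
    hess_floor: float = 1e-6      # floor on Hessian diagonal before inversion
    optimizer_maxiter: int = 200
    k_samples: int = 1000         # Monte-Carlo draws for iBIC
    ibic_param_factor: int = 2    # population-level params per model param (2: mean+var)

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown fit-config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "FitConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PopulationPrior:
    """Independent normal priors per parameter on the transformed scale."""

    param_names: tuple[str, ...]
    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape or self.mu.ndim != 1:
            raise ValueError("mu and sigma2 must be 1-D arrays of equal length")
        if len(self.param_names) != self.mu.size:
            raise ValueError("param_names length must match mu")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 entries must be positive")

    @classmethod
    def vague(cls, spec: ModelSpec, sigma2: float = 3.0) -> "PopulationPrior":
        n = spec.n_params
        return cls(spec.param_names, np.zeros(n), np.full(n, float(sigma2)))

    def sample(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """(k, n_params) transformed-scale draws."""
        z = rng.standard_normal((k, self.mu.size))
        return self.mu + np.sqrt(self.sigma2) * z

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "mu": self.mu.tolist(),
            "sigma2": self.sigma2.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationPrior":
        return cls(tuple(d["param_names"]), np.asarray(d["mu"]), np.asarray(d["sigma2"]))


@dataclass
class SubjectFit:
    """MAP estimate of one subject with its Laplace curvature."""

    theta: np.ndarray              # transformed-scale MAP
    params: ParamVector            # natural-scale MAP
    natural: dict[str, float]      # natural-scale named values
    hessian: np.ndarray            # curvature of the negative log-posterior at the MAP
    laplace_var: np.ndarray        # diagonal of the inverse Hessian (posterior variances)
    log_det_hessian: float
    log_posterior: float           # log posterior (incl. prior normalization) at the MAP
    loglik: float                  # data log-likelihood at the MAP
    n_trials: int

    @property
    def hess_diag(self) -> np.ndarray:
        return np.diag(self.hessian)

    @property
    def log_evidence(self) -> float:
        """Laplace approximation to log p(data | prior) for this subject."""
        d = self.theta.size
        return float(
            self.log_posterior + 0.5 * d * math.log(2.0 * math.pi)
            - 0.5 * self.log_det_hessian
        )


@dataclass
class FitResult:
    """Output of :func:`em_fit`: fitted prior, per-subject fits, EM trace."""

    spec: ModelSpec
    prior: PopulationPrior
    subjects: list[SubjectFit]
    em_trace: list[dict]
    converged: bool
    n_obs: int

    def params_frame(self):
        """Tidy per-subject natural-scale parameter table (pandas DataFrame)."""
        import pandas as pd

        rows = [dict(subject=i, **sf.natural) for i, sf in enumerate(self.subjects)]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "spec": self.spec.to_string(),
            "prior": self.prior.to_dict(),
            "converged": self.converged,
            "n_obs": self.n_obs,
            "em_trace": self.em_trace,
        }


# --------------------------------------------------------------------------
# MAP estimation
# --------------------------------------------------------------------------

def _compile(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(trials, tuple) and len(trials) == 4:
        return trials
    return session_to_arrays(trials)


def _prior_logpdf_full(prior: PopulationPrior, theta: np.ndarray) -> float:
    d = theta - prior.mu
    return float(
        -0.5 * np.sum(d * d / prior.sigma2)
        - 0.5 * np.sum(np.log(2.0 * math.pi * prior.sigma2))
    )


def map_estimate(trials, spec: ModelSpec, prior: PopulationPrior,
                 n_restarts: int = 10, seed: int = 0,
                 x0: np.ndarray | None = None,
                 config: FitConfig | None = None) -> SubjectFit:
    """Multi-start MAP estimation of one subject's transformed parameters.

    Starts from ``x0`` (if given), the prior mean, and prior draws until
    ``n_restarts`` start points are used; returns the best optimum. The
    Laplace curvature is the central-difference diagonal Hessian of the
    negative log-posterior at the MAP (floored before inversion).
    """
    cfg = config or FitConfig()
    if prior.param_names != spec.param_names:
        raise ValueError("prior parameters do not match the model spec")
    arrays = _compile(trials)
    codes = spec.codes
    args = (*codes, prior.mu, prior.sigma2, *arrays)
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    starts.append(prior.mu.copy())
    while len(starts) < max(n_restarts, 1) + (x0 is not None):
        starts.append(prior.sample(1, rng)[0])

    bounds = _bounds(spec)
    best = None
    diagnostics = []
    for s in starts:
        res = minimize(neg_log_posterior_grad, s, args=args, jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": cfg.optimizer_maxiter, "ftol": 1e-11, "gtol": 1e-7})
        diagnostics.append((res.status, res.message, float(res.fun)))
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FittingError(f"all {len(starts)} restarts failed: {diagnostics}")

    theta = np.asarray(best.x, dtype=float)
    f0 = float(best.fun)
    # full Laplace curvature: central differences of the analytic gradient.
    # The posterior is correlated across parameters (e.g. learning rates with
    # the outcome impact), so the marginal variances come from the inverse of
    # the full Hessian, not from inverted diagonal entries.
    h = cfg.hess_step
    n = theta.size
    hess = np.empty((n, n))
    for i in range(n):
        xp = theta.copy()
        xm = theta.copy()
        xp[i] += h
        xm[i] -= h
        gp = neg_log_posterior_grad(xp, *args)[1]
        gm = neg_log_posterior_grad(xm, *args)[1]
        hess[:, i] = (gp - gm) / (2.0 * h)
    hess = 0.5 * (hess + hess.T)
    w, v = np.linalg.eigh(hess)
    w = np.maximum(w, cfg.hess_floor)  # floor curvature before inversion
    hess = (v * w) @ v.T
    laplace_var = np.einsum("ij,j,ij->i", v, 1.0 / w, v)
    log_det = float(np.sum(np.log(w)))

    natural = to_natural(spec, theta)
    params = ParamVector.from_named(spec, natural)
    # log posterior including the prior normalization (used in the evidence)
    penalty = 0.5 * float(np.sum((theta - prior.mu) ** 2 / prior.sigma2))
    loglik = -f0 + penalty
    log_post = loglik + _prior_logpdf_full(prior, theta)
    return SubjectFit(
        theta=theta, params=params, natural=natural, hessian=hess,
        laplace_var=laplace_var, log_det_hessian=log_det,
        log_posterior=log_post, loglik=loglik, n_trials=arrays[0].size,
    )


# --------------------------------------------------------------------------
# EM
# --------------------------------------------------------------------------

def e_step(sessions, spec: ModelSpec, prior: PopulationPrior, config: FitConfig,
           seeds: Sequence[int], x0s: Sequence[np.ndarray | None] | None = None,
           n_restarts: int | None = None) -> list[SubjectFit]:
    """One E-step: MAP + Laplace for every subject under the current prior."""
    x0s = x0s if x0s is not None else [None] * len(sessions)
    n_restarts = config.n_restarts if n_restarts is None else n_restarts
    fits = []
    for i, (sess, sd, x0) in enumerate(zip(sessions, seeds, x0s)):
        try:
            fits.append(map_estimate(sess, spec, prior, n_restarts=n_restarts,
                                     seed=sd, x0=x0, config=config))
        except FittingError as exc:
            raise FittingError(f"subject {i}: {exc}") from exc
        if not np.isfinite(fits[-1].loglik):
            raise FittingError(f"subject {i}: non-finite likelihood at MAP")
    return fits


def m_step(fits: Sequence[SubjectFit], prior: PopulationPrior,
           variance_floor: float) -> PopulationPrior:
    """Moment update: mu <- mean(MAP); sigma2 <- mean((MAP-mu)^2 + Laplace var)."""
    thetas = np.stack([f.theta for f in fits])
    lvars = np.stack([f.laplace_var for f in fits])
    mu = thetas.mean(axis=0)
    sigma2 = ((thetas - mu) ** 2 + lvars).mean(axis=0)
    sigma2 = np.maximum(sigma2, variance_floor)
    return PopulationPrior(prior.param_names, mu, sigma2)


def _is_degenerate(arrays) -> bool:
    action = arrays[2]
    return bool(np.all(action == action[0]))


def em_fit(sessions, spec: ModelSpec, config: FitConfig | None = None,
           seed: int = 0, init_prior: PopulationPrior | None = None) -> FitResult:
    """Fit one model spec to a cohort by EM with the Laplace approximation.

    ``sessions`` is a sequence of per-subject trial sequences (or
    pre-compiled array tuples). Returns the fitted population prior, the
    final per-subject MAP fits, and the per-iteration hyperparameter and
    approximate-evidence trace.
    """
    cfg = config or FitConfig()
    compiled = [_compile(s) for s in sessions]
    if len(compiled) < 2:
        raise ValueError(f"em_fit needs at least 2 subjects, got {len(compiled)}")
    for i, arr in enumerate(compiled):
        if _is_degenerate(arr):
            logger.warning("subject %d has a degenerate session (single action); "
                           "the population prior will regularize its fit", i)

    prior = init_prior if init_prior is not None else PopulationPrior.vague(spec, cfg.init_sigma2)
    if prior.param_names != spec.param_names:
        raise ValueError("init_prior parameters do not match the model spec")
    master = np.random.default_rng(seed)
    n_obs = int(sum(arr[0].size for arr in compiled))

    trace: list[dict] = []
    fits: list[SubjectFit] = []
    converged = False
    x0s: list[np.ndarray | None] | None = None
    for it in range(cfg.em_max_iter):
        seeds = master.integers(2**31, size=len(compiled))
        if it == 0:
            fits = e_step(compiled, spec, prior, cfg, seeds, None, cfg.n_restarts)
        else:
            fits = e_step(compiled, spec, prior, cfg, seeds, x0s, cfg.n_restarts_warm)
        x0s = [f.theta for f in fits]
        evidence = float(sum(f.log_evidence for f in fits))
        new_prior = m_step(fits, prior, cfg.variance_floor)
        trace.append({
            "iteration": it,
            "mu": new_prior.mu.tolist(),
            "sigma2": new_prior.sigma2.tolist(),
            "evidence": evidence,
        })
        d_mu = float(np.max(np.abs(new_prior.mu - prior.mu)))
        d_s2 = float(np.max(np.abs(new_prior.sigma2 - prior.sigma2)))
        prior = new_prior
        if it > 0 and d_mu < cfg.em_tol and d_s2 < cfg.em_tol:
            converged = True
            break
    # final E-step so the returned subject fits are consistent with the
    # returned (post-M-step) prior
    seeds = master.integers(2**31, size=len(compiled))
    fits = e_step(compiled, spec, prior, cfg, seeds, x0s, cfg.n_restarts_warm)
    return FitResult(spec=spec, prior=prior, subjects=fits, em_trace=trace,
                     converged=converged, n_obs=n_obs)
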