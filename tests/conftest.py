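"""Shared fixtures and independent naive oracle implementations.

The oracles re-implement the session likelihood and the Monte-Carlo
marginal likelihood with plain Python dict/loop code, independent of the
package's compiled kernels, so kernel results can be checked against a
second derivation of the same model.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from gngfit import (
    Action, Condition, Domain, LRSplit, ModelSpec, ParamVector, RhoSplit,
    generate_schedule, simulate_agent,
)
from gngfit.fitting import PopulationPrior


# --------------------------------------------------------------------------
# naive per-trial likelihood oracle (independent of gngfit._kernels)
# --------------------------------------------------------------------------

def naive_session_loglik(spec: ModelSpec, named: dict[str, float], trials) -> float:
    """Plain-Python per-trial loop over the same model equations."""
    q = {(c, a): 0.0 for c in Condition for a in ("go", "nogo")}
    v = {c: 0.0 for c in Condition}

    def eps_for(cond: Condition, delta: float) -> float:
        sign = "P" if delta >= 0 else "N"
        if spec.lr_split == LRSplit.SINGLE:
            return named["eps"]
        if spec.lr_split == LRSplit.BY_PE_SIGN:
            return named[f"eps_{sign}"]
        dom = "G" if cond.domain == Domain.GAIN else "L"
        return named[f"eps_{dom}{sign}"]

    def rho_for(cond: Condition) -> float:
        if spec.rho_split == RhoSplit.SINGLE:
            return named["rho"]
        return named["rho_G"] if cond.domain == Domain.GAIN else named["rho_L"]

    ll = 0.0
    for tr in trials:
        cond = Condition(tr.condition)
        w_go = q[(cond, "go")]
        if spec.has_bias:
            w_go += named["b"]
        if spec.has_pavlovian:
            w_go += named["pi"] * v[cond]
        w_ng = q[(cond, "nogo")]
        p_go = math.exp(w_go) / (math.exp(w_go) + math.exp(w_ng))
        ll += math.log(p_go if tr.action == Action.GO else 1.0 - p_go)
        a = "go" if tr.action == Action.GO else "nogo"
        rr = rho_for(cond) * tr.outcome
        delta = rr - q[(cond, a)]
        q[(cond, a)] += eps_for(cond, delta) * delta
        if spec.has_pavlovian:
            dv = rr - v[cond]
            v[cond] += eps_for(cond, dv) * dv
    return ll


def naive_natural_from_free(spec: ModelSpec, x) -> dict[str, float]:
    out = {}
    for name, val in zip(spec.param_names, x):
        if name.startswith("eps"):
            out[name] = 1.0 / (1.0 + math.exp(-val))
        elif name.startswith("rho"):
            out[name] = math.exp(val)
        else:
            out[name] = float(val)
    return out


def naive_ibic(sessions, spec: ModelSpec, prior: PopulationPrior, k: int,
               seed: int, param_factor: int = 2) -> tuple[float, float]:
    """(log_marginal, value) by naive loops, same seed stream as gngfit.ibic."""
    rng = np.random.default_rng(seed)
    draws = prior.mu + np.sqrt(prior.sigma2) * rng.standard_normal((k, prior.mu.size))
    total = 0.0
    n_obs = 0
    for trials in sessions:
        n_obs += len(trials)
        lls = [naive_session_loglik(spec, naive_natural_from_free(spec, row), trials)
               for row in draws]
        m = max(lls)
        total += m + math.log(sum(math.exp(ll - m) for ll in lls) / k)
    value = -2.0 * total + param_factor * spec.n_params * math.log(n_obs)
    return total, value


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

def random_spec(rng: np.random.Generator) -> ModelSpec:
    return ModelSpec(
        lr_split=LRSplit([1, 2, 4][rng.integers(3)]),
        rho_split=RhoSplit([1, 2][rng.integers(2)]),
        has_bias=bool(rng.integers(2)),
        has_pavlovian=bool(rng.integers(2)),
    )


def random_named(spec: ModelSpec, rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for name in spec.param_names:
        if name.startswith("eps"):
            out[name] = float(rng.uniform(0.05, 0.95))
        elif name.startswith("rho"):
            out[name] = float(rng.uniform(0.5, 3.0))
        else:
            out[name] = float(rng.uniform(-1.0, 1.0))
    return out


@pytest.fixture(scope="session")
def winning_params() -> tuple[ModelSpec, ParamVector]:
    from gngfit import WINNING_SPEC

    named = {"eps_GP": 0.17, "eps_GN": 0.16, "eps_LP": 0.40, "eps_LN": 0.16,
             "rho": 2.0, "b": 0.3, "pi": 0.4}
    return WINNING_SPEC, ParamVector.from_named(WINNING_SPEC, named)


@pytest.fixture(scope="session")
def small_session(winning_params):
    spec, params = winning_params
    rng = np.random.default_rng(42)
    return simulate_agent(params, spec, generate_schedule(60, 7), rng)
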