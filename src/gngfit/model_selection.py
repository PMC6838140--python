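"""Integrated-BIC scoring and stepwise forward search over the model lattice.

The integrated BIC (iBIC) scores a fitted model by a Monte-Carlo estimate
of the log marginal likelihood: parameters are drawn from the fitted
population distributions, each subject's session likelihood is averaged
over the draws (log-mean-exp), the per-subject values are summed, and a
BIC-style penalty ``|M| * log(n_obs)`` is added, where ``n_obs`` is the
total number of choices in the cohort and ``|M|`` counts population-level
free parameters (by default two per model parameter: a mean and a
variance; configurable to one). Smaller iBIC is better.

The stepwise search starts from the base model (one learning rate, one
outcome impact) and repeatedly tries every single refinement of the
incumbent — add the action bias, add the Pavlovian term, split the
learning rate one level (single -> by PE sign -> by sign and domain),
split the outcome impact by domain — refits each candidate, and accepts
the one that decreases iBIC the most, stopping when no candidate improves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._kernels import ll_free_batch
from .fitting import FitConfig, FitResult, PopulationPrior, em_fit
from .models import LRSplit, ModelSpec, RhoSplit
from .task import session_to_arrays

__all__ = [
    "IBICScore",
    "CandidateResult",
    "SelectionStep",
    "SelectionTrace",
    "ibic",
    "candidate_moves",
    "embed_prior",
    "stepwise_select",
]

#: iBIC differences smaller than this are ties, broken toward the smaller model.
TIE_TOL = 1e-6


@dataclass
class IBICScore:
    log_marginal: float   # sum over subjects of log mean likelihood under the prior
    n_params: int         # model parameters
    n_pop_params: int     # population-level free parameters |M| entering the penalty
    n_obs: int            # total choices across subjects
    value: float          # -2*log_marginal + |M|*log(n_obs)
    k_samples: int


def _compile(trials):
    if isinstance(trials, tuple) and len(trials) == 4:
        return trials
    return session_to_arrays(trials)


def ibic(sessions, spec: ModelSpec, prior: PopulationPrior, k_samples: int = 1000,
         seed: int = 0, param_factor: int = 2) -> IBICScore:
    """Monte-Carlo integrated BIC of ``spec`` under a fitted population prior.

    Draws ``k_samples`` transformed-scale parameter vectors from the prior
    (one shared draw matrix for all subjects), computes each subject's
    log-mean likelihood by log-sum-exp minus log k, sums across subjects,
    and applies the parameter-count penalty.
    """
    if k_samples < 2:
        raise ValueError(f"k_samples must be >= 2, got {k_samples}")
    if prior.param_names != spec.param_names:
        raise ValueError("prior parameters do not match the model spec")
    compiled = [_compile(s) for s in sessions]
    rng = np.random.default_rng(seed)
    draws = prior.sample(k_samples, rng)
    codes = spec.codes
    total = 0.0
    for arr in compiled:
        lls = ll_free_batch(draws, *codes, *arr)
        total += float(logsumexp(lls) - math.log(k_samples))
    n_obs = int(sum(arr[0].size for arr in compiled))
    n_pop = spec.n_params * param_factor
    value = -2.0 * total + n_pop * math.log(n_obs)
    return IBICScore(log_marginal=total, n_params=spec.n_params, n_pop_params=n_pop,
                     n_obs=n_obs, value=value, k_samples=k_samples)


# --------------------------------------------------------------------------
# stepwise forward selection
# --------------------------------------------------------------------------

def candidate_moves(spec: ModelSpec) -> list[ModelSpec]:
    """Single-refinement extensions of ``spec`` in the model lattice."""
    moves = []
    if spec.lr_split == LRSplit.SINGLE:
        moves.append(ModelSpec(LRSplit.BY_PE_SIGN, spec.rho_split, spec.has_bias, spec.has_pavlovian))
    elif spec.lr_split == LRSplit.BY_PE_SIGN:
        moves.append(ModelSpec(LRSplit.BY_SIGN_AND_DOMAIN, spec.rho_split, spec.has_bias, spec.has_pavlovian))
    if spec.rho_split == RhoSplit.SINGLE:
        moves.append(ModelSpec(spec.lr_split, RhoSplit.BY_DOMAIN, spec.has_bias, spec.has_pavlovian))
    if not spec.has_bias:
        moves.append(ModelSpec(spec.lr_split, spec.rho_split, True, spec.has_pavlovian))
    if not spec.has_pavlovian:
        moves.append(ModelSpec(spec.lr_split, spec.rho_split, spec.has_bias, True))
    return moves


_SPLIT_PARENT = {
    "eps_P": "eps", "eps_N": "eps",
    "eps_GP": "eps_P", "eps_GN": "eps_N", "eps_LP": "eps_P", "eps_LN": "eps_N",
    "rho_G": "rho", "rho_L": "rho",
}


def embed_prior(prior: PopulationPrior, to_spec: ModelSpec,
                init_sigma2: float = 3.0) -> PopulationPrior:
    """Map a fitted prior into a refined spec's parameter space.

    Split children inherit the parent parameter's mean; newly added bias /
    Pavlovian parameters start at zero. Variances are reset to the vague
    ``init_sigma2`` for every parameter — inheriting the incumbent's small
    fitted variances would pin subject estimates near the incumbent solution
    and keep split parameters from differentiating. Used to warm-start
    candidate fits during the stepwise search.
    """
    have = dict(zip(prior.param_names, prior.mu))
    mu = []
    for name in to_spec.param_names:
        src = name
        while src not in have and src in _SPLIT_PARENT:
            src = _SPLIT_PARENT[src]
        mu.append(float(have.get(src, 0.0)))
    n = to_spec.n_params
    return PopulationPrior(to_spec.param_names, np.array(mu), np.full(n, float(init_sigma2)))


@dataclass
class CandidateResult:
    spec: str
    n_params: int
    ibic: float
    log_marginal: float


@dataclass
class SelectionStep:
    incumbent: str
    candidates: list[CandidateResult]
    accepted: str | None


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    winner: str
    winner_score: IBICScore
    winner_fit: FitResult | None = field(default=None, repr=False)

    @property
    def winner_spec(self) -> ModelSpec:
        return ModelSpec.from_string(self.winner)

    def accepted_values(self) -> list[float]:
        """iBIC of the incumbent after each accepted step (strictly decreasing)."""
        out = []
        for step in self.steps:
            if step.accepted is None:
                continue
            out.append(next(c.ibic for c in step.candidates if c.spec == step.accepted))
        return out

    def to_json_dict(self) -> dict:
        return {
            "winner": self.winner,
            "winner_ibic": self.winner_score.value,
            "steps": [
                {
                    "incumbent": s.incumbent,
                    "accepted": s.accepted,
                    "candidates": [vars(c) for c in s.candidates],
                }
                for s in self.steps
            ],
        }

    def table(self) -> str:
        """Human-readable model-comparison table (spec, #params, iBIC)."""
        lines = [f"{'model spec':<28}{'#params':>8}{'iBIC':>14}  note"]
        for i, step in enumerate(self.steps):
            for c in sorted(step.candidates, key=lambda c: c.ibic):
                mark = "accepted" if c.spec == step.accepted else ""
                lines.append(f"{c.spec:<28}{c.n_params:>8}{c.ibic:>14.2f}  step {i} {mark}".rstrip())
        lines.append(f"winner: {self.winner}  iBIC={self.winner_score.value:.2f}")
        return "\n".join(lines)


def stepwise_select(sessions, seed: int = 0, config: FitConfig | None = None) -> SelectionTrace:
    """Greedy forward search over the model lattice scored by iBIC.

    All candidates within one run are scored with the same Monte-Carlo seed
    stream for comparability. Ties within ``TIE_TOL`` keep the smaller
    (incumbent) model.
    """
    cfg = config or FitConfig()
    compiled = [_compile(s) for s in sessions]
    master = np.random.default_rng(seed)
    ibic_seed = int(master.integers(2**31))

    def fit_and_score(spec: ModelSpec, init_prior=None) -> tuple[FitResult, IBICScore]:
        fit = em_fit(compiled, spec, config=cfg, seed=int(master.integers(2**31)),
                     init_prior=init_prior)
        score = ibic(compiled, spec, fit.prior, k_samples=cfg.k_samples,
                     seed=ibic_seed, param_factor=cfg.ibic_param_factor)
        return fit, score

    incumbent = ModelSpec()  # base model: one eps, one rho
    try:
        inc_fit, inc_score = fit_and_score(incumbent)
    except Exception as exc:
        raise type(exc)(f"candidate {incumbent.to_string()}: {exc}") from exc

    steps: list[SelectionStep] = []
    while True:
        moves = candidate_moves(incumbent)
        if not moves:
            break
        results = []
        for cand in moves:
            init = embed_prior(inc_fit.prior, cand, cfg.init_sigma2)
            try:
                fit, score = fit_and_score(cand, init)
            except Exception as exc:
                raise type(exc)(f"candidate {cand.to_string()}: {exc}") from exc
            results.append((cand, fit, score))
        best_cand, best_fit, best_score = min(results, key=lambda r: r[2].value)
        cand_rows = [CandidateResult(c.to_string(), c.n_params, s.value, s.log_marginal)
                     for c, _, s in results]
        if best_score.value < inc_score.value - TIE_TOL:
            steps.append(SelectionStep(incumbent.to_string(), cand_rows, best_cand.to_string()))
            incumbent, inc_fit, inc_score = best_cand, best_fit, best_score
        else:
            steps.append(SelectionStep(incumbent.to_string(), cand_rows, None))
            break
    return SelectionTrace(steps=steps, winner=incumbent.to_string(),
                          winner_score=inc_score, winner_fit=inc_fit)
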