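"""Nested delta-rule reinforcement-learning model family for go/no-go choice.

The agent assigns an action value Q(a, s) to each (go / no-go, stimulus)
pair. After each trial the chosen action's value is updated by the delta
rule Q <- Q + eps * delta with prediction error delta = rho*r - Q, where r
is the coded outcome in {-1, 0, +1} and rho the subjective impact of the
outcome (rho sets the effective value scale; there is no separate inverse
temperature). Choice probabilities come from a softmax over action weights
W: the no-go weight is the bare Q, while the go weight may add a constant
action bias b and a Pavlovian term pi * V(s), where the stimulus value V is
updated by the same delta rule applied to the stimulus (on every trial,
whatever the action).

Model variants form a lattice: the learning rate may be single, split by
prediction-error sign (eps_P / eps_N), or further split by gain/loss domain
(eps_GP, eps_GN, eps_LP, eps_LN); the outcome impact may be single or split
by domain (rho_G / rho_L); bias and Pavlovian terms are optional. The base
model has one eps and one rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

from . import task
from ._kernels import ll_core
from .task import Action, Condition, Domain, Schedule, TrialRecord

__all__ = [
    "LRSplit",
    "RhoSplit",
    "PESign",
    "ModelSpec",
    "ParamVector",
    "AgentState",
    "BASE_SPEC",
    "WINNING_SPEC",
    "prediction_error",
    "select_learning_rate",
    "update_q",
    "update_v",
    "action_weights",
    "choice_prob_go",
    "session_loglik",
    "simulate_agent",
]


class LRSplit(IntEnum):
    """How many learning rates the model carries (1, 2 by PE sign, 4 by sign x domain)."""

    SINGLE = 1
    BY_PE_SIGN = 2
    BY_SIGN_AND_DOMAIN = 4


class RhoSplit(IntEnum):
    SINGLE = 1
    BY_DOMAIN = 2


class PESign(Enum):
    POS = "P"
    NEG = "N"


#: learning-rate cell keys in kernel order [GP, GN, LP, LN]
EPS_KEYS = ("GP", "GN", "LP", "LN")
RHO_KEYS = ("G", "L")

_LR_NAMES = {
    LRSplit.SINGLE: ("eps",),
    LRSplit.BY_PE_SIGN: ("eps_P", "eps_N"),
    LRSplit.BY_SIGN_AND_DOMAIN: ("eps_GP", "eps_GN", "eps_LP", "eps_LN"),
}
_RHO_NAMES = {RhoSplit.SINGLE: ("rho",), RhoSplit.BY_DOMAIN: ("rho_G", "rho_L")}


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters a model variant includes and how they are split."""

    lr_split: LRSplit = LRSplit.SINGLE
    rho_split: RhoSplit = RhoSplit.SINGLE
    has_bias: bool = False
    has_pavlovian: bool = False

    @property
    def param_names(self) -> tuple[str, ...]:
        names = list(_LR_NAMES[self.lr_split]) + list(_RHO_NAMES[self.rho_split])
        if self.has_bias:
            names.append("b")
        if self.has_pavlovian:
            names.append("pi")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def to_string(self) -> str:
        """Compact config string, e.g. ``lr=4,rho=1,bias=1,pav=1``."""
        return (
            f"lr={int(self.lr_split)},rho={int(self.rho_split)},"
            f"bias={int(self.has_bias)},pav={int(self.has_pavlovian)}"
        )

    @classmethod
    def from_string(cls, text: str) -> "ModelSpec":
        fields = {}
        for token in text.split(","):
            token = token.strip()
            if "=" not in token:
                raise ValueError(f"malformed model-spec token {token!r}")
            key, _, val = token.partition("=")
            key = key.strip()
            if key not in ("lr", "rho", "bias", "pav"):
                raise ValueError(f"unknown model-spec key {key!r}")
            if key in fields:
                raise ValueError(f"duplicate model-spec key {key!r}")
            try:
                fields[key] = int(val)
            except ValueError as exc:
                raise ValueError(f"malformed model-spec token {token!r}") from exc
        try:
            return cls(
                lr_split=LRSplit(fields.get("lr", 1)),
                rho_split=RhoSplit(fields.get("rho", 1)),
                has_bias=bool(fields.get("bias", 0)),
                has_pavlovian=bool(fields.get("pav", 0)),
            )
        except ValueError as exc:
            raise ValueError(f"invalid model-spec value in {text!r}: {exc}") from exc

    # kernel codes
    @property
    def codes(self) -> tuple[int, int, int, int]:
        return (int(self.lr_split), int(self.rho_split), int(self.has_bias), int(self.has_pavlovian))


BASE_SPEC = ModelSpec()
WINNING_SPEC = ModelSpec(
    lr_split=LRSplit.BY_SIGN_AND_DOMAIN,
    rho_split=RhoSplit.SINGLE,
    has_bias=True,
    has_pavlovian=True,
)


@dataclass
class ParamVector:
    """One agent's parameters on the natural scale.

    ``eps`` always holds all four (sign, domain) cells and ``rho`` both
    domains; under collapsed splits the tied cells carry the same value.
    ``bias`` / ``pav`` are ``None`` when the model omits them.
    """

    eps: dict[str, float] = field(default_factory=lambda: {k: 0.5 for k in EPS_KEYS})
    rho: dict[str, float] = field(default_factory=lambda: {k: 1.0 for k in RHO_KEYS})
    bias: float | None = None
    pav: float | None = None

    def __post_init__(self) -> None:
        for key, val in self.eps.items():
            if not 0.0 < val < 1.0:
                raise ValueError(f"learning rate eps_{key}={val} outside (0, 1)")
        for key, val in self.rho.items():
            if val <= 0.0:
                raise ValueError(f"outcome impact rho_{key}={val} must be positive")

    # --- natural-scale named-vector packing -------------------------------
    @classmethod
    def from_named(cls, spec: ModelSpec, values: dict[str, float]) -> "ParamVector":
        """Build a full ParamVector from per-name natural values for ``spec``."""
        missing = set(spec.param_names) - set(values)
        if missing:
            raise ValueError(f"missing parameters {sorted(missing)} for spec {spec.to_string()}")
        eps = {}
        if spec.lr_split == LRSplit.SINGLE:
            eps = {k: values["eps"] for k in EPS_KEYS}
        elif spec.lr_split == LRSplit.BY_PE_SIGN:
            eps = {"GP": values["eps_P"], "LP": values["eps_P"],
                   "GN": values["eps_N"], "LN": values["eps_N"]}
        else:
            eps = {k: values[f"eps_{k}"] for k in EPS_KEYS}
        if spec.rho_split == RhoSplit.SINGLE:
            rho = {k: values["rho"] for k in RHO_KEYS}
        else:
            rho = {"G": values["rho_G"], "L": values["rho_L"]}
        return cls(
            eps=eps,
            rho=rho,
            bias=values["b"] if spec.has_bias else None,
            pav=values["pi"] if spec.has_pavlovian else None,
        )

    def to_named(self, spec: ModelSpec) -> dict[str, float]:
        """Collapse back to per-name natural values; tied cells must agree."""
        out: dict[str, float] = {}
        if spec.lr_split == LRSplit.SINGLE:
            self._require_tied(self.eps, EPS_KEYS, "eps")
            out["eps"] = self.eps["GP"]
        elif spec.lr_split == LRSplit.BY_PE_SIGN:
            self._require_tied(self.eps, ("GP", "LP"), "eps_P")
            self._require_tied(self.eps, ("GN", "LN"), "eps_N")
            out["eps_P"] = self.eps["GP"]
            out["eps_N"] = self.eps["GN"]
        else:
            for k in EPS_KEYS:
                out[f"eps_{k}"] = self.eps[k]
        if spec.rho_split == RhoSplit.SINGLE:
            self._require_tied(self.rho, RHO_KEYS, "rho")
            out["rho"] = self.rho["G"]
        else:
            out["rho_G"] = self.rho["G"]
            out["rho_L"] = self.rho["L"]
        if spec.has_bias:
            if self.bias is None:
                raise ValueError("spec includes bias but ParamVector.bias is None")
            out["b"] = self.bias
        if spec.has_pavlovian:
            if self.pav is None:
                raise ValueError("spec includes pavlovian but ParamVector.pav is None")
            out["pi"] = self.pav
        return out

    @staticmethod
    def _require_tied(mapping, keys, name):
        vals = [mapping[k] for k in keys]
        if any(v != vals[0] for v in vals):
            raise ValueError(f"cells {keys} must be tied for collapsed parameter {name}")

    # --- kernel-order arrays ---------------------------------------------
    def expanded(self, spec: ModelSpec):
        """(eps[4], rho[2], bias, pav) arrays in kernel order."""
        eps = np.array([self.eps[k] for k in EPS_KEYS])
        rho = np.array([self.rho[k] for k in RHO_KEYS])
        b = self.bias if (spec.has_bias and self.bias is not None) else 0.0
        p = self.pav if (spec.has_pavlovian and self.pav is not None) else 0.0
        return eps, rho, float(b), float(p)


@dataclass
class AgentState:
    """Action values Q (4 stimuli x {no-go, go}) and stimulus values V."""

    q: np.ndarray = field(default_factory=lambda: np.zeros((4, 2)))
    v: np.ndarray = field(default_factory=lambda: np.zeros(4))


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def prediction_error(rho: float, r: int, q: float) -> float:
    """delta = rho*r - q: outcome better than expected gives a positive PE."""
    return rho * r - q


def select_learning_rate(spec: ModelSpec, params: ParamVector, domain: Domain, delta: float) -> float:
    """Learning rate for a prediction error of this sign in this domain.

    A zero PE is treated as positive (deterministic tie-break; it can occur
    only when rho*r exactly equals the current value).
    """
    sign = "P" if delta >= 0.0 else "N"
    dom = "G" if Domain(domain) == Domain.GAIN else "L"
    return params.eps[f"{dom}{sign}"]


def update_q(q: float, eps: float, delta: float) -> float:
    """Delta-rule update of the chosen action's value."""
    return q + eps * delta


def update_v(v: float, params: ParamVector, spec: ModelSpec, domain: Domain, r: int) -> float:
    """Delta-rule update of the stimulus value V.

    Uses the domain's rho and the learning rate selected by the sign of the
    stimulus prediction error rho*r - V.
    """
    dom = "G" if Domain(domain) == Domain.GAIN else "L"
    dv = params.rho[dom] * r - v
    eps = select_learning_rate(spec, params, domain, dv)
    return v + eps * dv


def action_weights(state: AgentState, stimulus: Condition, params: ParamVector,
                   spec: ModelSpec) -> tuple[float, float]:
    """(w_go, w_nogo) for the stimulus: go may add bias and pi*V, no-go is bare Q."""
    s = int(stimulus)
    w_go = state.q[s, int(Action.GO)]
    if spec.has_bias:
        w_go = w_go + (params.bias or 0.0)
    if spec.has_pavlovian:
        w_go = w_go + (params.pav or 0.0) * state.v[s]
    w_nogo = state.q[s, int(Action.NOGO)]
    return float(w_go), float(w_nogo)


def choice_prob_go(w_go: float, w_nogo: float) -> float:
    """Softmax probability of go; numerically stable for |w| up to ~700."""
    d = w_nogo - w_go
    if d >= 0:
        e = math.exp(-d)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(d))


# --------------------------------------------------------------------------
# session likelihood and simulation
# --------------------------------------------------------------------------

def session_loglik(params: ParamVector, spec: ModelSpec, trials) -> float:
    """Log-likelihood of the recorded choices of one session.

    Q and V start at zero; the chosen action's Q (and, with a Pavlovian
    term, the stimulus's V) is updated after every trial. Always <= 0.
    """
    stim, domain, action, outcome = task.session_to_arrays(trials)
    eps, rho, b, p = params.expanded(spec)
    return float(ll_core(eps, rho, b, p, spec.has_pavlovian, stim, domain, action, outcome))


def simulate_agent(params: ParamVector, spec: ModelSpec, schedule: Schedule,
                   rng: np.random.Generator) -> list[TrialRecord]:
    """Forward-simulate one session: the generative twin of ``session_loglik``.

    Actions are drawn from the softmax choice rule, outcomes from the task's
    80/20 contingency, and the agent state is updated exactly as the
    likelihood assumes.
    """
    state = AgentState()
    records: list[TrialRecord] = []
    for t, cond in enumerate(schedule.conditions, start=1):
        w_go, w_nogo = action_weights(state, cond, params, spec)
        p_go = choice_prob_go(w_go, w_nogo)
        act = Action.GO if rng.random() < p_go else Action.NOGO
        r = task.sample_outcome(cond, act, rng)
        records.append(TrialRecord(index=t, condition=cond, action=act, outcome=r))
        s, a = int(cond), int(act)
        dom = "G" if cond.domain == Domain.GAIN else "L"
        delta = prediction_error(params.rho[dom], r, state.q[s, a])
        eps = select_learning_rate(spec, params, cond.domain, delta)
        state.q[s, a] = update_q(state.q[s, a], eps, delta)
        if spec.has_pavlovian:
            state.v[s] = update_v(state.v[s], params, spec, cond.domain, r)
    return records
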