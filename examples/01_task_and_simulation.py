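"""Simulate one agent on the go/no-go gain/loss task and summarize behavior.

Builds a 240-trial block-randomized schedule, simulates a learner with the
full model (4 learning rates, outcome impact, action bias, Pavlovian
coupling), and prints per-condition error rates. Errors should be rarest
when going for reward and most common when withholding for reward — the
Pavlovian bias at work.
"""

import numpy as np

from gngfit import ParamVector, WINNING_SPEC, generate_schedule, simulate_agent
from gngfit.stats import error_rates

params = ParamVector.from_named(WINNING_SPEC, {
    "eps_GP": 0.17, "eps_GN": 0.16, "eps_LP": 0.40, "eps_LN": 0.16,
    "rho": 2.0, "b": 0.2, "pi": 0.8,
})

schedule = generate_schedule(n_per_condition=60, seed=1)
trials = simulate_agent(params, WINNING_SPEC, schedule, np.random.default_rng(1))

summary = error_rates(trials)
print(f"{len(trials)} trials simulated")
for cond, rate in summary.rates.items():
    print(f"  {cond.label:<12} error rate {rate:.2f}  (n={summary.n_trials[cond]})")
print("error rate = fraction of trials where the agent missed the correct action")
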