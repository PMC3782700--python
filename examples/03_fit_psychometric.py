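"""Simulate one observer's session and fit psychometric functions.

The observer fully acquired both key-associated priors (learning weight 1).
Cumulative-Gaussian maximum likelihood recovers one PSE per bias condition;
their difference (downward minus upward) is negative under learning.
"""

from actionprior import (
    SimObserverParams,
    fit_cumulative_gaussian,
    pse_difference,
    simulate_session,
    tabulate_responses,
)
from actionprior.simulate import build_experiment_plan

plan, key_priors = build_experiment_plan(prior_sd=0.06, delay_s=0.0, seed=7)
params = SimObserverParams(sensory_sd=0.06, learning_weight=1.0, seed=11)
trials = simulate_session(plan, params, key_priors)

fits = {}
for cond in ("upward", "downward"):
    table = tabulate_responses(trials, condition=cond)
    fits[cond] = fit_cumulative_gaussian(table)
    f = fits[cond]
    print(f"{cond:>8}-bias: PSE {f.pse:.4f}, slope {f.slope_sd:.4f} "
          f"(n={f.n_total}, converged={f.converged})")

diff = pse_difference(fits["upward"], fits["downward"])
print(f"\nPSE difference (down - up): {diff:+.4f}")
print("With sigma_s = sigma_p = 0.06 the ideal observer predicts PSEs of 0.56 and")
print("0.44, i.e. a difference near -0.12; the fitted values recover that shift.")
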