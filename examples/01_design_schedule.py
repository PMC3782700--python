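"""Build the biased trial schedules and a randomized session.

Each response key is paired with a Gaussian distribution over the
downward-grating contrast (mean 0.44 or 0.56, SD 0.06), discretized onto an
11-level grid as exact per-level trial counts for a 200-trial condition.
"""

from actionprior import PriorSpec, build_level_grid, build_session, discretize_gaussian

schedules = []
for offset, key in ((-0.06, "Z"), (+0.06, "M")):
    prior = PriorSpec(offset, 0.06)
    grid = build_level_grid(offset, 0.03, 11)
    sched = discretize_gaussian(grid, prior, 200, key=key)
    schedules.append(sched)
    print(f"{prior.label:>8}-bias key {key}: levels {grid.levels[0]:.2f}..{grid.levels[-1]:.2f}")
    print(f"{'':>12} counts {list(sched.counts)}")

plan = build_session(schedules, delay_s=0.0, seed=42)
print(f"\nsession: {plan.n_trials} trials, first five: {plan.trial_order[:5]}")
print("Counts follow the generating Gaussian: 40 trials at the mean, 2 at the extremes;")
print("the session interleaves both keys' trials in a seeded random order.")
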