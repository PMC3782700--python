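# actionprior

An in-silico pipeline for studying how acquiring the *statistics of an
action's outcome* biases perception of that outcome. The target paradigm is a
two-alternative forced-choice (2AFC) motion-direction task: pressing one of
two keys triggers a superimposed pair of drifting gratings whose relative
contrast ω (the downward grating's contrast; the upward one has 1−ω) is drawn
from a key-specific Gaussian "prior" distribution, mean 0.5 ± 0.06 and SD
0.06 or 0.15. Observers who internalise these key-contingent distributions
show *repulsive* shifts of the point of subjective equality (PSE): the PSE
moves away from the prior mean associated with the pressed key.

The package is for computational psychophysicists who want a fully testable,
seeded replica of this experimental chain without human data: it builds the
trial schedules, simulates observer cohorts, fits psychometric functions,
derives Bayesian ideal-observer predictions, and runs the group statistics.

## Model

The ideal observer receives a noisy measurement *m* ~ N(ω, σ<sub>s</sub>) and
combines it with the acquired prior N(μ<sub>p</sub>, σ<sub>p</sub>) by
conjugate Gaussian inference. Responding "downward" whenever the posterior
mean exceeds 0.5 puts the predicted PSE at

&nbsp;&nbsp;&nbsp;&nbsp;PSE<sub>ideal</sub> = 0.5 + λ (σ<sub>s</sub>²/σ<sub>p</sub>²)(0.5 − μ<sub>p</sub>),

where λ ∈ [0, 1] is a learning weight scaling the prior precision (λ = 1:
full acquisition; λ = 0: no prior influence). Empirical PSEs come from
binomial maximum-likelihood fits of a cumulative Gaussian
Φ((ω − PSE)/σ<sub>f</sub>) to the per-level response proportions.

Three simulated experiments mirror the classic manipulations: narrow prior
(SD 0.06), wide prior (SD 0.15, which attenuates the ideal shift by
(0.06/0.15)² = 0.16), and a 2-s action-outcome delay (emulated by a small λ,
so empirical shifts collapse while ideal predictions do not).

## Worked example

```python
from actionprior import ReplicationConfig, run_replication

report = run_replication(ReplicationConfig(experiment=1, n_observers=10, master_seed=1))
print(report.stats["bias_direction_paired_t"])
print(report.group_means)
```

prints

```
{'t': 6.6195, 'df': 9, 'p': 0.0001}
{'empirical': {'upward': 0.5677, 'downward': 0.436},
 'ideal':     {'upward': 0.5587, 'downward': 0.4413}}
```

The paired t-test shows the PSE difference between the upward- and
downward-bias conditions is highly significant in the simulated cohort, and
the group-mean empirical PSEs (0.568 / 0.436) sit close to the
observer-matched ideal predictions (0.559 / 0.441): the upward-bias prior
(contrast mean 0.44) pushes the PSE *up* to ~0.56 and vice versa — the
repulsive shift. The `examples/` directory contains one short script per
capability (schedule construction, ideal-observer predictions, psychometric
fitting, the full three-experiment replication); each prints its numbers with
a line on what they mean. A thin CLI wraps the same pipeline
(`actionprior replicate --experiment 1 --seed 42`).

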