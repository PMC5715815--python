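"""Exact type-I error of the t test for one biased allocation sequence.

Builds the joint bias vector (selection bias + linear time trend) for a fixed
sequence, derives the non-centrality parameters of the t statistic, and
compares the exact analytic rejection probability with a brute-force
response-level simulation.
"""

import numpy as np

from randeval import (
    BiasModel,
    ProcedureSpec,
    SimulationConfig,
    generate_sequence,
    joint_tau,
    noncentrality,
    rejection_probability,
    simulate_rejection_rate,
)

bias = BiasModel(eta=0.5, q=0.5, trend_kind="linear", theta=0.8, sigma=1.0)
seq = generate_sequence(ProcedureSpec.cr(), 12, np.random.default_rng(3))
tau = joint_tau(seq, bias)

pair = noncentrality(seq, tau, sigma=bias.sigma)
omega = rejection_probability(pair, alpha=0.05)
rate = simulate_rejection_rate(
    seq, tau, SimulationConfig(sigma=bias.sigma, n_sim=400_000, seed=11), alpha=0.05
)

print(f"sequence            : {seq}")
print(f"bias vector tau     : {np.round(tau, 3)}")
print(f"non-centrality      : delta = {pair.delta:+.4f}, lambda = {pair.lambda_:.4f}")
print(f"exact omega         : {omega:.4f}")
print(f"simulated rejection : {rate:.4f}  (400000 trials)")
print(
    "\nomega is the probability that the nominal level-0.05 t test rejects a\n"
    "true null for THIS allocation sequence under the bias model; the\n"
    "simulation confirms the doubly non-central t computation."
)
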