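"""Sensitivity of the assessment to the assumed bias strengths, plus design aids.

Varies (eta, theta) by +/-50% around the case-study estimates for the big
stick design BSD(10), and reproduces the design-stage effect-size and
sample-size computations.
"""

from randeval import (
    ProcedureSpec,
    cr_imbalance_probability,
    pooled_effect_size,
    sample_size_two_sample_t,
    sensitivity_analysis,
)

cells = sensitivity_analysis(
    ProcedureSpec.bsd(10), 130,
    eta_values=[0.04, 0.09, 0.14], theta_values=[0.13, 0.26, 0.39],
    sigma=0.73, alpha=0.05, r=20_000, seed=42, trend_kind="linear", paired=True,
)
print("BSD(10) under 50% changes of the bias strengths:")
print(f"{'eta':>6s} {'theta':>6s} {'mean':>7s} {'P(omega<=0.05)':>15s}")
for s in cells:
    print(f"{s.eta:6.2f} {s.theta:6.2f} {s.mean_omega:7.3f} {s.p_le_alpha:15.2f}")

effect = pooled_effect_size(0.90, 0.52, 0.765)
n_group = sample_size_two_sample_t(effect, alpha=0.05, power=0.80)
print(f"\nstandardized effect size : {effect:.3f}")
print(f"per-group sample size    : {n_group} (two-sided t test, 80% power)")
print(
    f"P(|N_E - N_C| >= 13) under CR at N=50: "
    f"{cr_imbalance_probability(50, 13):.3f}"
)
print(
    "\nThe conclusion is stable across the grid; the imbalance probability\n"
    "shows why unrestricted randomization is avoided in small trials."
)
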