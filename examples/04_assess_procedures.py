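"""Case-study evaluation: which procedure best preserves the test level?

Evaluates candidate randomization procedures for a two-arm 1:1 trial with
N = 130 patients under joint selection bias (eta = 0.09) and a linear time
trend (theta = 0.26) with sigma = 0.73, by Monte Carlo over r sequences.
"""

from randeval import BiasModel, ProcedureSpec, assess_procedure

bias = BiasModel(eta=0.09, q=0.5, trend_kind="linear", theta=0.26, sigma=0.73)
r = 20_000  # raise to 100000 for 2-decimal accuracy on P(omega <= 0.05)

print(f"{'procedure':12s} {'mean type-I error':>18s} {'P(omega <= 0.05)':>17s}")
for spec in (
    ProcedureSpec.cr(),
    ProcedureSpec.rar(),
    ProcedureSpec.pbr(2),
    ProcedureSpec.bsd(5),
    ProcedureSpec.bsd(10),
    ProcedureSpec.ebc(2 / 3),
    ProcedureSpec.ud(0, 1),
):
    s = assess_procedure(spec, 130, bias, alpha=0.05, r=r, seed=42)
    print(f"{spec.label:12s} {s.mean_omega:18.3f} {s.p_le_alpha:17.2f}")

print(
    "\nA mean near 0.050 alone can hide large sequence-to-sequence variation:\n"
    "P(omega <= 0.05) is the share of sequences that actually keep the level.\n"
    "Restrictive procedures (PBR(2)) are badly inflated by selection bias,\n"
    "while CR and BSD(10) leave about half the sequences level-preserving."
)
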