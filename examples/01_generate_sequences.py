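"""Generate allocation sequences from different randomization procedures.

Draws a few sequences from complete randomization, the big stick design and
permuted block randomization, and prints them with their imbalance profiles.
"""

import numpy as np

from randeval import ProcedureSpec, generate_sequence

rng = np.random.default_rng(7)
n = 12

for spec in (ProcedureSpec.cr(), ProcedureSpec.bsd(2), ProcedureSpec.pbr(4)):
    seq = generate_sequence(spec, n, rng)
    d = seq.imbalance_profile().tolist()
    print(f"{spec.label:8s} {seq}   imbalance D(i): {d}")

print()
print(
    "Each character is one patient in enrollment order (E = experimental,\n"
    "C = control); D(i) is the running difference N_E - N_C. BSD(2) never\n"
    "lets |D| exceed 2; PBR(4) returns to balance after every block of 4."
)
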