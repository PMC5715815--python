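"""Exact sequence probabilities and full enumeration at small N.

Shows the conditional allocation probability after a given history, the exact
probability of a complete sequence, and the enumeration of every sequence a
procedure can produce.
"""

from randeval import ProcedureSpec, enumerate_sequences, next_allocation_prob, sequence_probability

# Efron's biased coin: after one E the under-represented arm is C
spec = ProcedureSpec.ebc(2 / 3)
p = next_allocation_prob(spec, "E", n=6)
print(f"EBC(2/3) after history 'E': P(next = E) = {p:.4f}  (biased toward C)")

# random allocation rule: EECC fixes both final C's
print(f"RAR: P(sequence EECC) = {sequence_probability(ProcedureSpec.rar(), 'EECC'):.4f}")

# the maximal procedure is uniform over admissible sequences
pairs = enumerate_sequences(ProcedureSpec.mp(1), 4)
print(f"\nMP(1), N=4, terminal balance: {len(pairs)} admissible sequences")
for seq, prob in pairs:
    print(f"  {seq}  probability {prob:.4f}")
print(
    "\nWith a maximum tolerated imbalance of 1 the imbalance must return to 0\n"
    "after every second patient, leaving 4 admissible sequences, each 1/4."
)
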