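"""Occurrence, co-occurrence and conditional probabilities on a tiny table.

Builds the classic asymmetric pair: unit A is common (50% of events), unit B
is rare (5%) but never appears without A.
"""

from aunet import conditional_probabilities, parse_combination_strings, unconditional_probabilities

lines = ["A+B"] * 5 + ["A"] * 45 + [""] * 50  # 100 events
table = parse_combination_strings(lines, universe=["A", "B"])

p = unconditional_probabilities(table, max_order=2)
print(f"P(A)      = {p.probability(('A',)):.2f}")
print(f"P(B)      = {p.probability(('B',)):.2f}")
print(f"P(A and B)= {p.probability(('A', 'B')):.2f}")

c = conditional_probabilities(table)
print(f"P(A|B)    = {c.probability('B', 'A'):.2f}")
print(f"P(B|A)    = {c.probability('A', 'B'):.2f}")

print(
    "\nB predicts A perfectly (P(A|B)=1) while A barely predicts B "
    "(P(B|A)=0.1): the relationship between the two units is asymmetric, "
    "which co-occurrence counts alone would hide."
)
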