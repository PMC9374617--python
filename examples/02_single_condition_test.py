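"""Which combinations form predictable units within one dataset?

Generates events where six units are each active 25-30% of the time
independently, except a planted pair (AU5, AU6) that switches on and off
together.  The fixed-margins permutation null conserves every unit's own
frequency, so only genuine coupling -- not high individual frequency --
can make a dyad significant.
"""

from aunet import generate_dataset, test_single_condition
from aunet.synthetic import GeneratorSpec

spec = GeneratorSpec(
    conditions=(("session", 60),),
    units=tuple(f"AU{i}" for i in range(1, 7)),
    shared={f"AU{i}": 0.25 for i in range(1, 7)},
    coupling=((("AU5", "AU6"), 0.3),),
    seed=4,
)
table = generate_dataset(spec)

results = test_single_condition(table, max_order=2, iterations=1000, seed=9)
print("dyad        observed  expected  effect   p(more)")
for r in results:
    if len(r.element) == 2 and r.observed_count >= 3:
        print(
            f"{'+'.join(r.element):<12}{r.observed:>7.3f}{r.expected_mean:>10.3f}"
            f"{r.effect_size:>9.3f}{r.p_increase:>9.3f}"
        )

print(
    "\nOnly the planted AU5+AU6 dyad co-occurs far above what its members'"
    "\nfrequencies predict (large positive effect, p near 0); the other"
    "\ndyads sit inside their null probability space."
)
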