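# aunet

Probabilistic co-occurrence network analysis of binary event×unit data,
built for Facial Action Coding System (FACS) datasets.

FACS decomposes facial signals into *action units* (AUs), the smallest
visible facial movements; a coded dataset is a binary matrix with one row
per *event* (a photo, a video peak frame) and one column per AU (1 =
active).  Such data violate the assumptions of the ANOVA- and PCA-style
analyses traditionally applied to them: they are binary, the units are not
independent of each other, and events are nested within individuals.
`aunet` instead treats the data the way communication research treats
vocal repertoires — as a network of co-occurring units — and asks four
kinds of question:

* **Unit level** — how specific is a unit to a condition?
  Context specificity `P(C|A)` = occurrences of A in condition C over all
  occurrences of A, paired with occurrence probability `P(A|C)`.
* **Dyad level** — which units are conditional on each other?
  `P(B|A)` = events containing both A and B over events containing A.
* **Signal level** — which units and combinations appear *more often than a
  null model expects* in a condition, and how dense/transitive is the
  resulting graph?
* **System level** — do units cluster into communities (modularity `Q =
  Σ_c (e_cc − a_c²)`, with `Q > 0.3` read as clear structure) even without
  condition labels?

Because nothing here follows a convenient parametric distribution,
significance comes from resampling. For questions within a single dataset,
**pre-network permutations**: either reshuffle which units are active while
holding each event's unit count fixed (single-unit null), or checkerboard-
swap MCMC that conserves *both* matrix margins exactly (combination null
— a dyad is significant only if it co-occurs more than its members'
frequencies force). For comparisons between conditions, a **bootstrap** of
the comparison condition (optionally drawing whole individuals, and/or
stratified on control variables) builds each element's null probability
space; elements are reduced to two one-sided p-values (proportion of null
values at least/at most the observed, ties extreme) and an effect size
(observed − null mean).

The package ships a synthetic-data generator with planted ground truth
(condition cores, shared units, coupled sets, mutually exclusive pairs,
individual biases), so the entire pipeline is testable without access to
any proprietary facial-expression database.

## Worked example

```python
from aunet import parse_combination_strings, conditional_probabilities

lines = ["A+B"] * 5 + ["A"] * 45 + [""] * 50   # 100 events
table = parse_combination_strings(lines, universe=["A", "B"])
c = conditional_probabilities(table)
print(f"P(A|B) = {c.probability('B', 'A'):.2f}")
print(f"P(B|A) = {c.probability('A', 'B'):.2f}")
```

```
P(A|B) = 1.00
P(B|A) = 0.10
```

A and B co-occur in 5% of events, which sounds unremarkable — but the
conditional view shows the relationship is completely asymmetric: B never
appears without A (`P(A|B) = 1`), while A rarely brings B along
(`P(B|A) = 0.1`). This is the kind of structure (e.g. a rare modifier unit
riding on a common base unit) that the network representation is built to
expose.

The `examples/` directory walks through each capability on generated data;
`examples/05_communities.py`, for instance, detects unit communities on
the pooled co-occurrence network while blind to the condition labels:

```
modularity: 0.36 (values above 0.3 indicate clear structure)
cluster 0: AU1, AU16, AU2, AU20, AU26, AU27, AU5
cluster 1: AU10, AU15, AU17, AU18, AU23, AU24, AU4, AU7, AU9
cluster 2: AU12, AU14, AU6
```

— the raised-brow, lowered-brow and smile blocks planted by the generator,
recovered without labels.

## Command line

```sh
aunet simulate --seed 3 --out events.csv
aunet test --input events.csv --test-condition happy --iterations 1000 --out happy.csv
aunet networks --input events.csv --condition surprise --format csv --out surprise.csv
aunet communities --input events.csv
aunet report --seed 1 --iterations 1000 --out bundle/
```

`report` writes the full bundle: per-condition test CSVs, bipartite
occurrence/specificity graphs, per-condition significance graphs with a
nodes/edges/density/transitivity table, the pooled community partition,
and a JSON summary. Reruns with the same seed are byte-identical.

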