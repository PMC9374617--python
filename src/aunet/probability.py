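"""Occurrence, co-occurrence, conditional and context-specificity probabilities.

All quantities are plain event-counting ratios over an :class:`EventTable`:

* unconditional probability of a unit or combination A --
  ``P(A) = (# events containing every unit of A) / (# events)``;
* conditional probability between units --
  ``P(B|A) = (# events containing A and B) / (# events containing A)``;
* context specificity of an element A for condition C --
  ``P(C|A) = (# occurrences of A in C) / (# occurrences of A)``, paired with
  the occurrence probability ``P(A|C) = (# occurrences of A in C) / (# events
  in C)``.

Counts are kept as integers and probabilities as exact count ratios; any
rounding happens only when tables are serialised for reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .event_table import EventTable

__all__ = [
    "CombinationKey",
    "combination_key",
    "ProbabilityTable",
    "ConditionalTable",
    "SpecificityTable",
    "unconditional_probabilities",
    "conditional_probabilities",
    "specificity",
]

#: a combination of units: sorted tuple of canonical labels, no duplicates
CombinationKey = tuple[str, ...]


def combination_key(units: Iterable[str]) -> CombinationKey:
    """Canonical key for a set of units (sorted, de-duplicated)."""
    key = tuple(sorted(set(units)))
    if not key:
        raise ValueError("a combination must contain at least one unit")
    return key


def format_key(key: CombinationKey) -> str:
    return "+".join(key)


@dataclass(frozen=True)
class ProbabilityTable:
    """Counts and unconditional probabilities of units and combinations."""

    counts: dict[CombinationKey, int]
    n_events: int
    max_order: int

    def probability(self, key: CombinationKey) -> float:
        return self.counts[key] / self.n_events

    @property
    def probabilities(self) -> dict[CombinationKey, float]:
        return {k: c / self.n_events for k, c in self.counts.items()}

    def __contains__(self, key: CombinationKey) -> bool:
        return key in self.counts

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per element, full-precision probabilities."""
        rows = [
            {
                "element": format_key(k),
                "order": len(k),
                "count": c,
                "probability": c / self.n_events,
            }
            for k, c in sorted(self.counts.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows, columns=["element", "order", "count", "probability"])


@dataclass(frozen=True)
class ConditionalTable:
    """Directed pairwise conditional probabilities P(B|A).

    Entries are keyed by the ordered pair ``(A, B)`` and hold the joint count,
    the count of the conditioning unit A, and their ratio.  Pairs whose
    conditioning unit never occurs are omitted rather than reported as
    undefined.
    """

    entries: dict[tuple[str, str], tuple[int, int, float]]

    def probability(self, a: str, b: str) -> float:
        return self.entries[(a, b)][2]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "given": a,
                "target": b,
                "joint_count": jc,
                "count_given": ca,
                "probability": p,
            }
            for (a, b), (jc, ca, p) in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["given", "target", "joint_count", "count_given", "probability"]
        )


@dataclass(frozen=True)
class SpecificityTable:
    """Context specificity P(condition|element) and occurrence P(element|condition)."""

    entries: dict[tuple[CombinationKey, str], tuple[float, float, int, int]]
    conditions: tuple[str, ...]

    def specificity(self, element: CombinationKey, condition: str) -> float:
        return self.entries[(element, condition)][0]

    def occurrence(self, element: CombinationKey, condition: str) -> float:
        return self.entries[(element, condition)][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "element": format_key(k),
                "condition": c,
                "specificity": spec,
                "occurrence": occ,
                "count_in_condition": cic,
                "count_total": ct,
            }
            for (k, c), (spec, occ, cic, ct) in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "element",
                "condition",
                "specificity",
                "occurrence",
                "count_in_condition",
                "count_total",
            ],
        )


# -- counting helpers -------------------------------------------------------


def _combination_counts(
    matrix: np.ndarray,
    units: Sequence[str],
    max_order: int,
    observed_only: bool,
) -> dict[CombinationKey, int]:
    """Count, for every combination up to ``max_order``, the events
    containing ALL of its units."""
    n_events, n_units = matrix.shape
    counts: dict[CombinationKey, int] = {}
    col_sums = matrix.sum(axis=0)
    for j, u in enumerate(units):
        c = int(col_sums[j])
        if not observed_only or c > 0:
            counts[(u,)] = c
    if max_order >= 2:
        if observed_only:
            # enumerate within events: cheap when events are sparse
            tally: dict[CombinationKey, int] = {}
            sorted_units = units
            for i in range(n_events):
                active = [sorted_units[j] for j in np.flatnonzero(matrix[i])]
                active.sort()
                for order in range(2, min(max_order, len(active)) + 1):
                    for combo in combinations(active, order):
                        tally[combo] = tally.get(combo, 0) + 1
            counts.update(tally)
        else:
            for order in range(2, max_order + 1):
                for cols in combinations(range(n_units), order):
                    key = combination_key(units[j] for j in cols)
                    counts[key] = int(matrix[:, cols].all(axis=1).sum())
    return counts


# -- public operations ------------------------------------------------------


def unconditional_probabilities(
    table: EventTable,
    max_order: int = 2,
    observed_only: bool = True,
) -> ProbabilityTable:
    """Unconditional probabilities of all combinations up to ``max_order``.

    With ``observed_only`` (default) only combinations that actually co-occur
    at least once are listed -- full enumeration over all subsets grows as
    2^k (with 27 FACS action units, billions of combinations) while analyses
    of single units and dyads rarely need more than ``max_order=2``.
    Single units are always all listed, including never-active ones.
    """
    if table.n_events == 0:
        raise ValueError("cannot compute probabilities of an empty table")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    max_order = min(max_order, table.n_units) if table.n_units else 1
    counts = _combination_counts(table.matrix, table.units, max_order, observed_only)
    # single units are reported even at count 0: their absence is informative
    for u in table.units:
        counts.setdefault((u,), 0)
    return ProbabilityTable(counts=counts, n_events=table.n_events, max_order=max_order)


def conditional_probabilities(
    table: EventTable, min_joint_count: int = 0
) -> ConditionalTable:
    """Pairwise conditional probabilities P(B|A), both directions.

    An entry ``(A, B)`` exists whenever A occurs at least once and the joint
    count reaches ``min_joint_count``; never-co-occurring pairs are reported
    with probability 0 (not omitted) as long as the threshold allows.
    """
    m = table.matrix.astype(np.int64)
    joint = m.T @ m  # joint[a, b] = co-occurrence count; diagonal = unit counts
    units = table.units
    entries: dict[tuple[str, str], tuple[int, int, float]] = {}
    for a in range(len(units)):
        ca = int(joint[a, a])
        if ca == 0:
            continue
        for b in range(len(units)):
            if a == b:
                continue
            jc = int(joint[a, b])
            if jc < min_joint_count:
                continue
            entries[(units[a], units[b])] = (jc, ca, jc / ca)
    return ConditionalTable(entries=entries)


def specificity(table: EventTable, max_order: int = 1) -> SpecificityTable:
    """Context specificity and occurrence probability per condition.

    For every element (single units by default; observed combinations up to
    ``max_order`` when raised) and every condition C, reports
    ``P(C|element)`` (specificity: how reliably the element signals the
    condition) and ``P(element|C)`` (occurrence: how common the element is
    within the condition).  Specificities of an element sum to 1 across
    conditions whenever the element occurs at all.
    """
    if table.condition is None:
        raise ValueError("specificity requires condition labels")
    conds = table.conditions()
    if len(conds) < 2:
        raise ValueError("specificity requires at least 2 conditions")

    totals = _combination_counts(table.matrix, table.units, max_order, observed_only=True)
    for u in table.units:
        totals.setdefault((u,), 0)

    labels = np.asarray([str(c) for c in table.condition])
    entries: dict[tuple[CombinationKey, str], tuple[float, float, int, int]] = {}
    for cond in conds:
        mask = labels == cond
        n_cond = int(mask.sum())
        sub = table.matrix[mask]
        cond_counts = _combination_counts(sub, table.units, max_order, observed_only=True)
        for key, total in totals.items():
            cic = cond_counts.get(key, 0)
            spec = cic / total if total > 0 else 0.0
            occ = cic / n_cond if n_cond > 0 else 0.0
            entries[(key, cond)] = (spec, occ, cic, total)
    return SpecificityTable(entries=entries, conditions=tuple(conds))
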