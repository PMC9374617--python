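"""Null models and significance tests for unit and combination probabilities.

Two families of null model are provided, matching the two kinds of question
asked of co-occurrence data:

* **Single-condition questions** ("which combinations form predictable
  units?") use *pre-network permutations* of the raw event-by-unit matrix:

  - ``permutation_event_counts`` keeps the number of active units per event
    fixed but redraws *which* units are active uniformly -- the null for
    whether single units are used more or less than chance;
  - ``permutation_fixed_margins`` shuffles the matrix while conserving both
    the per-event unit counts and the per-unit totals exactly (checkerboard
    swap MCMC) -- the null for whether units *combine* more than their
    individual frequencies predict.

* **Between-condition questions** ("is this unit more common in condition X
  than elsewhere?") use a **bootstrap** of the comparison ("null")
  condition: events are drawn with replacement, optionally whole individuals
  at a time (clustered) and/or respecting the composition of control
  variables (stratified).

Each scheme yields, per tracked element, a distribution of probabilities
across iterations; observed probabilities are reduced to two one-sided
p-values (proportion of null values at least / at most as extreme, ties
counted as extreme) and an effect size (observed minus null mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .event_table import EventTable
from .probability import (
    CombinationKey,
    ProbabilityTable,
    format_key,
    unconditional_probabilities,
)

__all__ = [
    "NullDistribution",
    "TestResult",
    "randomize_within_events",
    "randomize_fixed_margins",
    "bootstrap_resample",
    "build_null_distribution",
    "compare_to_null",
    "test_single_condition",
    "test_between_conditions",
]

SCHEMES = ("permutation_event_counts", "permutation_fixed_margins", "bootstrap")

#: swap attempts per 1-cell used for MCMC burn-in and between-sample gaps
SWAPS_PER_ONE = 5


def _substream(seed: int, counter: int) -> np.random.Generator:
    """Independent reproducible RNG stream for iteration ``counter``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(counter,)))


@dataclass(frozen=True)
class NullDistribution:
    """Per-element null probability distributions from one resampling scheme."""

    iterations: int
    values: dict[CombinationKey, np.ndarray]
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        for key, vals in self.values.items():
            if len(vals) != self.iterations:
                raise ValueError(
                    f"element {format_key(key)} has {len(vals)} values, "
                    f"expected {self.iterations}"
                )


@dataclass(frozen=True)
class TestResult:
    """Observed-vs-null comparison for one unit or combination."""

    __test__ = False  # not a pytest test class despite the name

    element: CombinationKey
    observed: float
    expected_mean: float
    effect_size: float
    p_increase: float
    p_decrease: float
    observed_count: int


def results_to_frame(results: Sequence[TestResult]):
    """Tidy DataFrame export of a sequence of test results."""
    import pandas as pd

    rows = [
        {
            "element": format_key(r.element),
            "order": len(r.element),
            "observed_prob": r.observed,
            "expected_prob": r.expected_mean,
            "effect_size": r.effect_size,
            "p_increase": r.p_increase,
            "p_decrease": r.p_decrease,
            "count": r.observed_count,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "element",
            "order",
            "observed_prob",
            "expected_prob",
            "effect_size",
            "p_increase",
            "p_decrease",
            "count",
        ],
    )


# -- randomization schemes --------------------------------------------------


def _random_rows_same_counts(
    matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random subset of units per event, conserving each row sum."""
    n, m = matrix.shape
    k = matrix.sum(axis=1)
    noise = rng.random((n, m))
    ranks = np.argsort(np.argsort(noise, axis=1), axis=1)
    return (ranks < k[:, None]).astype(np.int8)


def randomize_within_events(
    table: EventTable, rng: np.random.Generator | int | None = None
) -> EventTable:
    """Redraw which units are active in each event, keeping event sizes.

    An event that contained five units before randomisation contains five
    after; the identity of the active units is a uniform random subset of
    the unit universe.  Per-unit totals are *not* conserved -- this scheme
    asks whether individual units are over- or under-used relative to a face
    (or call, or gesture) that activates units indiscriminately.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return EventTable(
        units=table.units,
        matrix=_random_rows_same_counts(table.matrix, rng),
        event_id=table.event_id,
        condition=table.condition,
        individual_id=table.individual_id,
        strata=table.strata,
    )


class _SwapChain:
    """Checkerboard-swap MCMC state over a binary matrix.

    Rows are stored as Python integer bitmasks and the 1-cells as a flat
    list; one attempted swap picks two 1-cells (r1, c1), (r2, c2) and, when
    they form a checkerboard (M[r1, c2] = M[r2, c1] = 0 with distinct rows
    and columns), exchanges the pattern.  Every accepted swap conserves all
    row and column sums exactly.
    """

    def __init__(self, matrix: np.ndarray):
        self.n, self.m = matrix.shape
        self.row_bits = [
            sum(1 << c for c in np.flatnonzero(row).tolist()) for row in matrix
        ]
        rr, cc = np.nonzero(matrix)
        self.ones = list(zip(rr.tolist(), cc.tolist()))

    def attempt_swaps(self, n_attempts: int, rng: np.random.Generator) -> int:
        """Run ``n_attempts`` attempted swaps; returns the number accepted."""
        k = len(self.ones)
        if k < 2:
            return 0
        idx = rng.integers(0, k, size=2 * n_attempts)
        ones = self.ones
        bits = self.row_bits
        accepted = 0
        for t in range(n_attempts):
            i1 = idx[2 * t]
            i2 = idx[2 * t + 1]
            r1, c1 = ones[i1]
            r2, c2 = ones[i2]
            if r1 == r2 or c1 == c2:
                continue
            if (bits[r1] >> c2) & 1 or (bits[r2] >> c1) & 1:
                continue
            flip = (1 << c1) | (1 << c2)
            bits[r1] ^= flip
            bits[r2] ^= flip
            ones[i1] = (r1, c2)
            ones[i2] = (r2, c1)
            accepted += 1
        return accepted

    def to_matrix(self) -> np.ndarray:
        out = np.zeros((self.n, self.m), dtype=np.int8)
        for r in range(self.n):
            b = self.row_bits[r]
            c = 0
            while b:
                if b & 1:
                    out[r, c] = 1
                b >>= 1
                c += 1
        return out


def randomize_fixed_margins(
    table: EventTable,
    n_swaps: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> EventTable:
    """Shuffle the matrix conserving both row and column sums exactly.

    Uses checkerboard-swap MCMC: ``n_swaps`` attempted 2x2 swaps (default
    ``5 x number of 1-cells``, a standard burn-in heuristic).  The result is
    reachable from the input purely through margin-preserving swaps, so both
    the number of units per event and the total frequency of every unit are
    identical to the input; only *which* units co-occur changes.  A matrix
    with no checkerboard submatrix is returned unchanged.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    chain = _SwapChain(table.matrix)
    if n_swaps is None:
        n_swaps = SWAPS_PER_ONE * max(len(chain.ones), 1)
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    chain.attempt_swaps(n_swaps, rng)
    return EventTable(
        units=table.units,
        matrix=chain.to_matrix(),
        event_id=table.event_id,
        condition=table.condition,
        individual_id=table.individual_id,
        strata=table.strata,
    )


# -- bootstrap --------------------------------------------------------------


def _largest_remainder_counts(
    targets: dict[str, float], total: int
) -> dict[str, int]:
    """Integer per-level counts proportional to ``targets`` summing to
    ``total`` (largest-remainder rounding, ties broken by level order)."""
    levels = sorted(targets)
    weight = sum(targets[lv] for lv in levels)
    if weight <= 0:
        raise ValueError("strata targets must have positive total weight")
    exact = {lv: total * targets[lv] / weight for lv in levels}
    counts = {lv: int(np.floor(exact[lv])) for lv in levels}
    short = total - sum(counts.values())
    by_remainder = sorted(levels, key=lambda lv: (-(exact[lv] - counts[lv]), lv))
    for lv in by_remainder[:short]:
        counts[lv] += 1
    return counts


def _cluster_labels(table: EventTable, cluster_by: str) -> np.ndarray:
    if cluster_by in ("individual", "individual_id"):
        if table.individual_id is None:
            raise ValueError("table has no individual_id for clustered resampling")
        return np.asarray([str(x) for x in table.individual_id])
    if cluster_by in table.strata:
        return np.asarray([str(x) for x in table.strata[cluster_by]])
    raise ValueError(f"unknown cluster variable {cluster_by!r}")


def _bootstrap_rows_plain(
    rows: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    return rows[rng.integers(0, len(rows), size=size)]


def _bootstrap_rows_clustered(
    rows: np.ndarray, labels: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    clusters = sorted(set(labels[rows].tolist()))
    members = {c: rows[labels[rows] == c] for c in clusters}
    picked: list[np.ndarray] = []
    n = 0
    while n < size:
        c = clusters[int(rng.integers(0, len(clusters)))]
        picked.append(members[c])
        n += len(members[c])
    out = np.concatenate(picked)
    # the final cluster may overshoot: truncate its events in drawn order
    return out[:size]


def _bootstrap_rows(
    table: EventTable,
    sample_size: int,
    cluster_by: str | None,
    strata_by: str | None,
    strata_targets: dict[str, float] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if table.n_events == 0:
        raise ValueError("cannot bootstrap an empty table")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    all_rows = np.arange(table.n_events, dtype=np.intp)
    labels = _cluster_labels(table, cluster_by) if cluster_by else None

    if strata_by is None:
        if labels is None:
            return _bootstrap_rows_plain(all_rows, sample_size, rng)
        return _bootstrap_rows_clustered(all_rows, labels, sample_size, rng)

    if strata_by not in table.strata:
        raise ValueError(f"unknown stratum variable {strata_by!r}")
    levels = np.asarray([str(x) for x in table.strata[strata_by]])
    if strata_targets is None:
        uniq, freq = np.unique(levels, return_counts=True)
        strata_targets = {str(u): int(f) / len(levels) for u, f in zip(uniq, freq)}
    counts = _largest_remainder_counts(strata_targets, sample_size)
    chunks: list[np.ndarray] = []
    for level in sorted(counts):
        want = counts[level]
        if want == 0:
            continue
        rows = all_rows[levels == level]
        if len(rows) == 0:
            raise ValueError(f"stratum level {level!r} has no events in the null data")
        if labels is None:
            chunks.append(_bootstrap_rows_plain(rows, want, rng))
        else:
            chunks.append(_bootstrap_rows_clustered(rows, labels, want, rng))
    return np.concatenate(chunks)


def bootstrap_resample(
    null_table: EventTable,
    sample_size: int | None = None,
    cluster_by: str | None = None,
    strata_by: str | None = None,
    strata_targets: dict[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> EventTable:
    """One bootstrap resample of the null condition's events.

    Events are drawn with replacement (``sample_size`` defaults to the table
    size).  With ``cluster_by`` set, whole clusters -- individuals or any
    stratum variable -- are drawn with replacement and contribute all their
    events, the final cluster truncated in drawn order to hit ``sample_size``
    exactly; this keeps non-independence of events within a subject or video
    in the null distribution.  With ``strata_by`` set, per-level counts
    follow ``strata_targets`` proportions (largest-remainder rounding), e.g.
    to force the null resamples to match the sex ratio of the test condition.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    size = null_table.n_events if sample_size is None else sample_size
    rows = _bootstrap_rows(null_table, size, cluster_by, strata_by, strata_targets, rng)
    return null_table.take(rows, event_id=np.arange(len(rows), dtype=object))


# -- null distributions -----------------------------------------------------


def _tracked_columns(
    units: Sequence[str], track: Sequence[CombinationKey]
) -> list[np.ndarray]:
    index = {u: j for j, u in enumerate(units)}
    cols = []
    for key in track:
        try:
            cols.append(np.asarray([index[u] for u in key], dtype=np.intp))
        except KeyError as exc:
            raise ValueError(f"tracked element {format_key(key)} has unknown unit {exc}") from None
    return cols


def _tracked_probs(matrix: np.ndarray, cols: list[np.ndarray]) -> np.ndarray:
    """Probability of each tracked combination in one 0/1 matrix."""
    n = matrix.shape[0]
    out = np.empty(len(cols), dtype=np.float64)
    for i, c in enumerate(cols):
        if len(c) == 1:
            out[i] = matrix[:, c[0]].sum() / n
        else:
            out[i] = matrix[:, c].all(axis=1).sum() / n
    return out


def build_null_distribution(
    table: EventTable,
    scheme: str,
    iterations: int = 1000,
    max_order: int = 2,
    seed: int = 0,
    track: Sequence[CombinationKey] | None = None,
    sample_size: int | None = None,
    cluster_by: str | None = None,
    strata_by: str | None = None,
    strata_targets: dict[str, float] | None = None,
) -> NullDistribution:
    """Null probability distributions for tracked elements.

    One randomized/resampled table is generated per iteration (1000 by
    default) and the unconditional probability of every tracked combination
    recorded, building the probability space each element would occupy under
    the null.  ``track`` defaults to all elements observed in ``table`` up
    to ``max_order``.  Fully deterministic given ``seed``: iteration ``i``
    uses an independent substream keyed by ``i``, so results do not depend
    on evaluation order.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if track is None:
        observed = unconditional_probabilities(table, max_order=max_order, observed_only=True)
        track = sorted(observed.counts, key=lambda k: (len(k), k))
    else:
        track = list(track)
    cols = _tracked_columns(table.units, track)
    values = np.empty((iterations, len(track)), dtype=np.float64)

    if scheme == "permutation_event_counts":
        for i in range(iterations):
            rng = _substream(seed, i)
            values[i] = _tracked_probs(_random_rows_same_counts(table.matrix, rng), cols)
    elif scheme == "permutation_fixed_margins":
        chain = _SwapChain(table.matrix)
        gap = SWAPS_PER_ONE * max(len(chain.ones), 1)
        for i in range(iterations):
            rng = _substream(seed, i)
            chain.attempt_swaps(gap, rng)  # i = 0 doubles as burn-in
            values[i] = _tracked_probs(chain.to_matrix(), cols)
    else:  # bootstrap
        size = table.n_events if sample_size is None else sample_size
        for i in range(iterations):
            rng = _substream(seed, i)
            rows = _bootstrap_rows(table, size, cluster_by, strata_by, strata_targets, rng)
            values[i] = _tracked_probs(table.matrix[rows], cols)

    return NullDistribution(
        iterations=iterations,
        values={key: values[:, j].copy() for j, key in enumerate(track)},
        scheme=scheme,
        seed=seed,
    )


# -- observed-vs-null comparison --------------------------------------------


def compare_to_null(
    observed: ProbabilityTable, null: NullDistribution
) -> list[TestResult]:
    """Reduce null distributions to p-values and effect sizes.

    For each observed element, ``p_increase`` is the proportion of null
    values at least as large as the observed probability and ``p_decrease``
    the proportion at most as large; ties count as extreme on both sides, so
    the two p-values sum to at least 1 and neither can fall below
    ``1 / iterations`` when the observed value is attainable under the null.
    The effect size is the observed probability minus the null mean.
    Elements not tracked in the null compare against an all-zero sequence.
    """
    if null.iterations < 1:
        raise ValueError("null distribution has no iterations")
    zeros = np.zeros(null.iterations)
    results = []
    for key in sorted(observed.counts, key=lambda k: (len(k), k)):
        obs = observed.probability(key)
        vals = null.values.get(key, zeros)
        results.append(
            TestResult(
                element=key,
                observed=obs,
                expected_mean=float(vals.mean()),
                effect_size=float(obs - vals.mean()),
                p_increase=float((vals >= obs).mean()),
                p_decrease=float((vals <= obs).mean()),
                observed_count=observed.counts[key],
            )
        )
    return results


def _observed_nonzero(table: EventTable, max_order: int) -> ProbabilityTable:
    obs = unconditional_probabilities(table, max_order=max_order, observed_only=True)
    counts = {k: c for k, c in obs.counts.items() if c > 0}
    return ProbabilityTable(counts=counts, n_events=obs.n_events, max_order=obs.max_order)


def test_single_condition(
    table: EventTable,
    max_order: int = 2,
    iterations: int = 1000,
    seed: int = 0,
) -> list[TestResult]:
    """Which units and combinations are used more or less than chance?

    Single units are compared against the event-count-preserving permutation
    null (are they active more often than a unit chosen indiscriminately
    would be?).  Combinations of two or more units are compared against the
    fixed-margins null, which conserves every unit's own frequency, so a
    significant dyad co-occurs more often than its members' frequencies
    alone predict.  Only elements observed at least once are tested.
    """
    if table.n_events == 0:
        raise ValueError("cannot test an empty table")
    observed = _observed_nonzero(table, max_order)
    singles = {k: c for k, c in observed.counts.items() if len(k) == 1}
    combos = {k: c for k, c in observed.counts.items() if len(k) >= 2}

    results: list[TestResult] = []
    if singles:
        null_s = build_null_distribution(
            table, "permutation_event_counts", iterations, max_order=1,
            seed=seed, track=sorted(singles),
        )
        obs_s = ProbabilityTable(counts=singles, n_events=table.n_events, max_order=1)
        results.extend(compare_to_null(obs_s, null_s))
    if combos:
        null_c = build_null_distribution(
            table, "permutation_fixed_margins", iterations, max_order=max_order,
            seed=seed, track=sorted(combos, key=lambda k: (len(k), k)),
        )
        obs_c = ProbabilityTable(counts=combos, n_events=table.n_events, max_order=max_order)
        results.extend(compare_to_null(obs_c, null_c))
    return sorted(results, key=lambda r: (len(r.element), r.element))


def test_between_conditions(
    test: EventTable,
    null: EventTable,
    max_order: int = 2,
    iterations: int = 1000,
    seed: int = 0,
    cluster_by: str | None = None,
    strata_by: str | None = None,
    strata_targets: dict[str, float] | None = None,
) -> list[TestResult]:
    """Is each element more or less probable in ``test`` than in ``null``?

    The null probability space is built by bootstrapping the null condition's
    events (resample size = size of the test condition, so both sides share
    granularity); observed probabilities come from the test condition.  With
    ``strata_by`` set and no explicit targets, the resamples match the test
    condition's composition of that control variable.  Only elements
    observed in the test condition are tested.
    """
    if test.n_events == 0 or null.n_events == 0:
        raise ValueError("both test and null tables must be nonempty")
    if not set(test.units) & set(null.units):
        raise ValueError("test and null tables have disjoint unit universes")
    if set(test.units) != set(null.units):
        union = tuple(sorted(set(test.units) | set(null.units)))
        test = test.with_units(union)
        null = null.with_units(union)

    if strata_by is not None and strata_targets is None:
        if strata_by not in test.strata:
            raise ValueError(f"unknown stratum variable {strata_by!r} in test table")
        levels = np.asarray([str(x) for x in test.strata[strata_by]])
        uniq, freq = np.unique(levels, return_counts=True)
        strata_targets = {str(u): int(f) / len(levels) for u, f in zip(uniq, freq)}

    observed = _observed_nonzero(test, max_order)
    track = sorted(observed.counts, key=lambda k: (len(k), k))
    null_dist = build_null_distribution(
        null,
        "bootstrap",
        iterations,
        max_order=max_order,
        seed=seed,
        track=track,
        sample_size=test.n_events,
        cluster_by=cluster_by,
        strata_by=strata_by,
        strata_targets=strata_targets,
    )
    return compare_to_null(observed, null_dist)
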