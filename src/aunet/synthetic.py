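"""Synthetic FACS-like datasets with known ground truth.

The generator emulates the structure of posed facial-expression databases:
several labelled conditions of unequal size, each with a core set of action
units activated at high probability, units shared across conditions at a
baseline rate, rare background units, per-individual biases in unit use,
hard mutual-exclusion constraints (some movements cannot physically
co-occur), and optional coupling sets whose members switch on and off
together.  Because every effect is planted explicitly, statistical and
network operations can be validated against the ground truth without any
external database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .event_table import EventTable

__all__ = ["GeneratorSpec", "generate_dataset", "generate_null_pair", "ck_like_spec"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth recipe for one synthetic dataset.

    Per event the generator draws an individual, activates each unit
    independently with its condition probability (``core`` overriding
    ``shared``, biased per individual on the log-odds scale), then applies
    ``coupling`` (all members of a coupled set are replaced by one joint
    Bernoulli draw with the set's probability, forcing near-1 conditional
    probabilities within the set) and ``exclusive_pairs`` (if both members
    came up active, one survives, chosen uniformly).
    """

    conditions: tuple[tuple[str, int], ...]
    units: tuple[str, ...]
    core: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    shared: Mapping[str, float] = field(default_factory=dict)
    coupling: tuple[tuple[tuple[str, ...], float], ...] = ()
    exclusive_pairs: tuple[tuple[str, str], ...] = ()
    n_individuals: int = 1
    individual_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        known = set(self.units)
        for label, n in self.conditions:
            if n < 1:
                raise ValueError(f"condition {label!r} must have >= 1 events")
        for cond, probs in self.core.items():
            if cond not in {c for c, _ in self.conditions}:
                raise ValueError(f"core refers to unknown condition {cond!r}")
            self._check_probs(probs, known)
        self._check_probs(self.shared, known)
        coupled_sets = []
        for units, p in self.coupling:
            if not 0 <= p <= 1:
                raise ValueError("coupling probability must be in [0, 1]")
            unknown = set(units) - known
            if unknown:
                raise ValueError(f"coupling refers to unknown units {sorted(unknown)}")
            coupled_sets.append(frozenset(units))
        for a, b in self.exclusive_pairs:
            if a not in known or b not in known:
                raise ValueError(f"exclusive pair ({a!r}, {b!r}) uses unknown units")
            for cs in coupled_sets:
                if a in cs and b in cs:
                    raise ValueError(
                        f"units {a!r} and {b!r} are both coupled and exclusive"
                    )
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.individual_sd < 0:
            raise ValueError("individual_sd must be >= 0")

    @staticmethod
    def _check_probs(probs: Mapping[str, float], known: set[str]) -> None:
        for u, p in probs.items():
            if u not in known:
                raise ValueError(f"probability given for unknown unit {u!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {u!r} must be in [0, 1], got {p}")


def _biased_probs(base: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Per-event activation probabilities: ``base`` shifted by each event's
    individual bias on the log-odds scale (0 and 1 stay untouched)."""
    p = np.broadcast_to(base, biases.shape).astype(float).copy()
    interior = (p > 0.0) & (p < 1.0) & (biases != 0.0)
    if interior.any():
        logit = np.log(p[interior] / (1 - p[interior])) + biases[interior]
        p[interior] = 1 / (1 + np.exp(-logit))
    return p


def generate_dataset(spec: GeneratorSpec) -> EventTable:
    """Draw one dataset from a :class:`GeneratorSpec` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    units = tuple(spec.units)
    uindex = {u: j for j, u in enumerate(units)}
    n_total = sum(n for _c, n in spec.conditions)
    matrix = np.zeros((n_total, len(units)), dtype=np.int8)
    condition = np.empty(n_total, dtype=object)
    individual = np.empty(n_total, dtype=object)

    # per (individual, unit) log-odds bias, constant across that individual's events
    biases = (
        rng.normal(0.0, spec.individual_sd, size=(spec.n_individuals, len(units)))
        if spec.individual_sd > 0
        else np.zeros((spec.n_individuals, len(units)))
    )

    row = 0
    for cond, n in spec.conditions:
        core = dict(spec.core.get(cond, {}))
        base = np.array(
            [core.get(u, spec.shared.get(u, 0.0)) for u in units], dtype=float
        )
        inds = rng.integers(0, spec.n_individuals, size=n)
        p = _biased_probs(base, biases[inds])
        draw = (rng.random((n, len(units))) < p).astype(np.int8)
        for cunits, cp in spec.coupling:
            on = (rng.random(n) < cp).astype(np.int8)
            for u in cunits:
                draw[:, uindex[u]] = on
        for a, b in spec.exclusive_pairs:
            ja, jb = uindex[a], uindex[b]
            both = (draw[:, ja] == 1) & (draw[:, jb] == 1)
            keep_a = rng.random(n) < 0.5
            draw[both & keep_a, jb] = 0
            draw[both & ~keep_a, ja] = 0
        matrix[row : row + n] = draw
        condition[row : row + n] = cond
        individual[row : row + n] = [f"ind{i:03d}" for i in inds]
        row += n

    return EventTable(
        units=units,
        matrix=matrix,
        event_id=np.asarray([f"ev{i:05d}" for i in range(n_total)], dtype=object),
        condition=condition,
        individual_id=individual,
    )


def generate_null_pair(
    n1: int,
    n2: int,
    unit_probs: Mapping[str, float],
    seed: int = 0,
) -> tuple[EventTable, EventTable]:
    """Two independent tables from the identical generating process.

    Every unit is activated independently with its given probability in both
    tables -- a true null for between-condition comparisons: any detected
    difference is a false positive.
    """
    units = tuple(sorted(unit_probs))
    t1 = generate_dataset(
        GeneratorSpec(
            conditions=(("null_a", n1),),
            units=units,
            shared=dict(unit_probs),
            seed=seed,
        )
    )
    t2 = generate_dataset(
        GeneratorSpec(
            conditions=(("null_b", n2),),
            units=units,
            shared=dict(unit_probs),
            seed=seed + 1,
        )
    )
    return t1, t2


def ck_like_spec(seed: int = 0, individual_sd: float = 0.0, n_individuals: int = 100) -> GeneratorSpec:
    """Default demonstration spec mimicking a posed-expression database.

    Seven emotion conditions with the familiar unequal sample sizes
    (anger 45, contempt 18, disgust 59, fear 25, happy 69, sadness 28,
    surprise 83; 327 events in all), each built around the stereotypical
    core action units of that expression (e.g. happy: AU6+AU12 at high
    probability; surprise: AU1+2+5+27), secondary units at moderate
    probability, a low shared baseline for the remaining units, and the
    hard FACS exclusion between AU26 (jaw drop) and AU27 (mouth stretch).
    """
    units = tuple(
        f"AU{k}" for k in (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 16, 17, 18, 20, 23, 24, 26, 27)
    )
    core = {
        "anger": {"AU4": 0.97, "AU23": 0.9, "AU24": 0.9, "AU7": 0.5, "AU17": 0.45},
        "contempt": {"AU14": 0.95, "AU12": 0.2},
        "disgust": {"AU9": 0.95, "AU4": 0.65, "AU7": 0.45, "AU17": 0.4, "AU10": 0.3},
        "fear": {"AU1": 0.9, "AU2": 0.8, "AU4": 0.85, "AU5": 0.8, "AU20": 0.9,
                 "AU10": 0.2, "AU16": 0.2, "AU26": 0.25},
        "happy": {"AU6": 0.95, "AU12": 0.97},
        "sadness": {"AU1": 0.95, "AU4": 0.8, "AU15": 0.9, "AU17": 0.8, "AU2": 0.25},
        "surprise": {"AU1": 0.97, "AU2": 0.97, "AU5": 0.95, "AU27": 0.85,
                     "AU12": 0.1, "AU16": 0.1, "AU26": 0.15},
    }
    # posed databases admit events only when they display the stereotype, so
    # primary core units sit near ceiling; background activity is rare
    shared = {u: 0.01 for u in units}
    return GeneratorSpec(
        conditions=(
            ("anger", 45),
            ("contempt", 18),
            ("disgust", 59),
            ("fear", 25),
            ("happy", 69),
            ("sadness", 28),
            ("surprise", 83),
        ),
        units=units,
        core=core,
        shared=shared,
        exclusive_pairs=(("AU26", "AU27"),),
        n_individuals=n_individuals,
        individual_sd=individual_sd,
        seed=seed,
    )
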