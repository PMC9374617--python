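"""Binary event-by-unit tables with per-event metadata.

The central container is :class:`EventTable`: one row per coded observation
("event" -- a photo, a video peak frame, a bout of vocalisation), one column
per communicative unit (a FACS action unit, a syllable, a gesture), each cell
1 if the unit was active in that event and 0 otherwise.  Events may carry a
condition label (e.g. an emotion category or social context), an individual
identifier (for clustered resampling) and arbitrary stratification variables
(e.g. sex) used by stratified bootstraps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "UnitFilterReport",
    "canonical_unit_label",
    "read_event_table",
    "write_event_table",
    "parse_combination_strings",
    "filter_units",
    "subset_by_condition",
]

#: column names with a reserved metadata meaning in wide CSV files
RESERVED_COLUMNS = ("event_id", "condition", "individual_id")

_TRUTHY = {"1", "1.0", "true", "t", "yes"}
_FALSY = {"0", "0.0", "false", "f", "no"}


def canonical_unit_label(label: str) -> str:
    """Normalise a unit label to canonical form.

    Uppercases, strips non-alphanumeric characters, and prefixes ``AU`` when
    the remainder is purely numeric, so ``"au12"``, ``" AU 12 "`` and ``"12"``
    all map to ``"AU12"``.  Non-numeric labels (words, syllables) are kept as
    uppercased alphanumerics, so the container stays usable for communication
    systems other than FACS.
    """
    s = re.sub(r"[^A-Za-z0-9]", "", str(label)).upper()
    if not s:
        raise ValueError(f"unit label {label!r} is empty after normalization")
    if s.isdigit():
        s = "AU" + s
    return s


@dataclass(frozen=True)
class UnitFilterReport:
    """Record of units removed by :func:`filter_units`.

    ``removed_rare`` lists ``(unit, count)`` pairs removed because the unit
    occurred fewer than ``min_count`` times; ``removed_explicit`` lists units
    removed by name regardless of frequency.
    """

    removed_rare: tuple[tuple[str, int], ...] = ()
    removed_explicit: tuple[str, ...] = ()


@dataclass
class EventTable:
    """Events-by-units binary matrix plus per-event metadata.

    Parameters
    ----------
    units
        Ordered canonical unit labels; one matrix column each.
    matrix
        ``(n_events, n_units)`` array of 0/1 indicators.
    event_id
        Unique identifier per event.
    condition
        Optional per-event condition label.
    individual_id
        Optional per-event subject identifier (clustered resampling).
    strata
        Optional mapping of control-variable name to a per-event level array
        (stratified resampling).
    """

    units: tuple[str, ...]
    matrix: np.ndarray
    event_id: np.ndarray
    condition: np.ndarray | None = None
    individual_id: np.ndarray | None = None
    strata: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.units = tuple(str(u) for u in self.units)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if self.matrix.shape[1] != len(self.units):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but "
                f"{len(self.units)} unit labels were given"
            )
        bad = (self.matrix != 0) & (self.matrix != 1)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary value {self.matrix[r, c]} in unit column "
                f"{self.units[c]!r}, row {r}"
            )
        if len(set(self.units)) != len(self.units):
            raise ValueError("unit labels must be unique")
        n = self.matrix.shape[0]
        self.event_id = np.asarray(self.event_id, dtype=object)
        if len(self.event_id) != n:
            raise ValueError("event_id length does not match number of events")
        if len(set(self.event_id)) != n:
            dupes = pd.Series(self.event_id).value_counts()
            dupes = list(dupes.index[dupes > 1])[:3]
            raise ValueError(f"duplicate event_id values: {dupes}")
        for name, arr in [("condition", self.condition), ("individual_id", self.individual_id)]:
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length does not match number of events")
        for name, arr in self.strata.items():
            if len(arr) != n:
                raise ValueError(f"stratum {name!r} length does not match number of events")
        if self.condition is not None:
            self.condition = np.asarray(self.condition, dtype=object)
        if self.individual_id is not None:
            self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.strata = {k: np.asarray(v, dtype=object) for k, v in self.strata.items()}

    # -- basic introspection ------------------------------------------------

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_units(self) -> int:
        return self.matrix.shape[1]

    def unit_counts(self) -> dict[str, int]:
        """Total number of events in which each unit is active."""
        sums = self.matrix.sum(axis=0)
        return {u: int(s) for u, s in zip(self.units, sums)}

    def conditions(self) -> list[str]:
        """Sorted distinct condition labels (empty if no conditions set)."""
        if self.condition is None:
            return []
        return sorted({str(c) for c in self.condition})

    def unit_index(self, unit: str) -> int:
        try:
            return self.units.index(unit)
        except ValueError:
            raise KeyError(f"unknown unit {unit!r}") from None

    # -- conversion ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: metadata columns followed by unit columns in
        canonical sorted order."""
        data: dict[str, object] = {"event_id": self.event_id}
        if self.condition is not None:
            data["condition"] = self.condition
        if self.individual_id is not None:
            data["individual_id"] = self.individual_id
        for name, arr in self.strata.items():
            data[name] = arr
        order = sorted(range(self.n_units), key=lambda i: self.units[i])
        for i in order:
            data[self.units[i]] = self.matrix[:, i].astype(int)
        return pd.DataFrame(data)

    def take(self, rows: np.ndarray | Sequence[int], event_id: np.ndarray | None = None) -> "EventTable":
        """New table from a row selection.

        ``event_id`` overrides identifiers (needed when rows repeat, e.g. in
        bootstrap resamples where the same source event is drawn twice).
        """
        rows = np.asarray(rows, dtype=np.intp)
        if event_id is None:
            event_id = self.event_id[rows]
        return EventTable(
            units=self.units,
            matrix=self.matrix[rows],
            event_id=event_id,
            condition=None if self.condition is None else self.condition[rows],
            individual_id=None if self.individual_id is None else self.individual_id[rows],
            strata={k: v[rows] for k, v in self.strata.items()},
        )

    def with_units(self, units: Sequence[str]) -> "EventTable":
        """Project onto a new unit universe: existing columns are carried
        over, unknown units become all-zero columns."""
        units = tuple(units)
        mat = np.zeros((self.n_events, len(units)), dtype=np.int8)
        for j, u in enumerate(units):
            if u in self.units:
                mat[:, j] = self.matrix[:, self.units.index(u)]
        return EventTable(
            units=units,
            matrix=mat,
            event_id=self.event_id,
            condition=self.condition,
            individual_id=self.individual_id,
            strata=self.strata,
        )


# -- I/O --------------------------------------------------------------------


def _parse_binary_cell(value: object, row: object, column: str) -> int:
    if isinstance(value, float) and np.isnan(value):
        raise ValueError(f"missing value in unit column {column!r}, event {row!r}")
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return 1
    if s in _FALSY:
        return 0
    raise ValueError(
        f"non-binary value {value!r} in unit column {column!r}, event {row!r}"
    )


def read_event_table(
    source: str | IO[str],
    unit_columns: Iterable[str] | None = None,
    metadata_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> EventTable:
    """Read a wide CSV of binary events-by-units data.

    Columns named ``event_id``, ``condition`` and ``individual_id`` (or the
    columns mapped to those roles via ``metadata_map``, e.g.
    ``{"individual_id": "subject"}``) are metadata; every remaining column is
    a unit column unless ``unit_columns`` names them explicitly, in which
    case leftover columns become strata.  Unit cells accept 0/1 and
    TRUE/FALSE spellings; anything else (including a missing cell) is a
    validation error naming the offending row and column.
    """
    df = pd.read_csv(source, sep=delimiter, dtype=object)
    if df.columns.size == 0:
        raise ValueError("input has no columns (missing header?)")
    metadata_map = dict(metadata_map or {})
    role_cols = {role: metadata_map.get(role, role) for role in RESERVED_COLUMNS}

    if unit_columns is None:
        meta_names = {c for c in role_cols.values() if c in df.columns}
        unit_cols = [c for c in df.columns if c not in meta_names]
        strata_cols: list[str] = []
    else:
        unit_cols = list(unit_columns)
        missing = [c for c in unit_cols if c not in df.columns]
        if missing:
            raise ValueError(f"unit columns not found: {missing}")
        claimed = set(unit_cols) | {c for c in role_cols.values() if c in df.columns}
        strata_cols = [c for c in df.columns if c not in claimed]

    eid_col = role_cols["event_id"]
    if eid_col in df.columns:
        event_id = df[eid_col].to_numpy(dtype=object)
    else:
        event_id = np.arange(len(df), dtype=object)

    canon = [canonical_unit_label(c) for c in unit_cols]
    matrix = np.zeros((len(df), len(unit_cols)), dtype=np.int8)
    for j, col in enumerate(unit_cols):
        for i, value in enumerate(df[col]):
            matrix[i, j] = _parse_binary_cell(value, event_id[i], col)

    cond_col = role_cols["condition"]
    ind_col = role_cols["individual_id"]
    return EventTable(
        units=tuple(canon),
        matrix=matrix,
        event_id=event_id,
        condition=df[cond_col].to_numpy(dtype=object) if cond_col in df.columns else None,
        individual_id=df[ind_col].to_numpy(dtype=object) if ind_col in df.columns else None,
        strata={c: df[c].to_numpy(dtype=object) for c in strata_cols},
    )


def write_event_table(table: EventTable, target: str | IO[str], delimiter: str = ",") -> None:
    """Write the wide CSV form (units in canonical sorted order)."""
    table.to_frame().to_csv(target, sep=delimiter, index=False)


def parse_combination_strings(
    lines: Iterable[str],
    universe: Iterable[str] | None = None,
    delimiter: str = "+",
    conditions: Iterable[str] | None = None,
) -> EventTable:
    """Build an :class:`EventTable` from combination strings.

    Each line such as ``"AU1+AU4+AU15"`` is one event; the empty string is an
    event with no active units.  Duplicate mentions of a unit collapse (the
    encoding is presence/absence).  With ``universe`` given, the unit set is
    fixed and unknown labels are an error; otherwise the unit set is the
    union of observed labels.
    """
    parsed: list[set[str]] = []
    for line in lines:
        labels = [tok for tok in str(line).strip().split(delimiter) if tok.strip()]
        parsed.append({canonical_unit_label(tok) for tok in labels})

    if universe is not None:
        units = tuple(sorted(canonical_unit_label(u) for u in universe))
        known = set(units)
        for i, active in enumerate(parsed):
            unknown = active - known
            if unknown:
                raise ValueError(
                    f"line {i}: unit(s) {sorted(unknown)} outside the supplied universe"
                )
    else:
        units = tuple(sorted(set().union(*parsed) if parsed else set()))

    matrix = np.zeros((len(parsed), len(units)), dtype=np.int8)
    index = {u: j for j, u in enumerate(units)}
    for i, active in enumerate(parsed):
        for u in active:
            matrix[i, index[u]] = 1

    cond = None
    if conditions is not None:
        cond = np.asarray(list(conditions), dtype=object)
    return EventTable(
        units=units,
        matrix=matrix,
        event_id=np.arange(len(parsed), dtype=object),
        condition=cond,
    )


# -- filtering / subsetting -------------------------------------------------


def filter_units(
    table: EventTable,
    min_count: int = 2,
    drop: Iterable[str] = (),
) -> tuple[EventTable, UnitFilterReport]:
    """Remove rare units and explicitly named units.

    Units active in fewer than ``min_count`` events are removed (the default
    of 2 removes units that do not occur more than once); units in ``drop``
    are removed regardless of frequency.  Events are always retained, even
    when left with no active units -- they still count in probability
    denominators.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    drop_set = {canonical_unit_label(u) for u in drop}
    counts = table.unit_counts()
    removed_explicit = tuple(u for u in table.units if u in drop_set)
    removed_rare = tuple(
        (u, counts[u])
        for u in table.units
        if u not in drop_set and counts[u] < min_count
    )
    removed = set(removed_explicit) | {u for u, _ in removed_rare}
    keep = [j for j, u in enumerate(table.units) if u not in removed]
    out = EventTable(
        units=tuple(table.units[j] for j in keep),
        matrix=table.matrix[:, keep],
        event_id=table.event_id,
        condition=table.condition,
        individual_id=table.individual_id,
        strata=table.strata,
    )
    return out, UnitFilterReport(removed_rare=removed_rare, removed_explicit=removed_explicit)


def subset_by_condition(
    table: EventTable, condition: str, complement: bool = False
) -> EventTable:
    """Events of one condition (or, with ``complement``, all other events).

    The unit universe is unchanged, so subset and complement stay directly
    comparable; together they partition the original events exactly.
    """
    if table.condition is None:
        raise ValueError("table has no condition labels")
    labels = np.asarray([str(c) for c in table.condition])
    if str(condition) not in labels:
        raise ValueError(f"unknown condition {condition!r}; available: {table.conditions()}")
    mask = labels == str(condition)
    if complement:
        mask = ~mask
    return table.take(np.flatnonzero(mask))
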