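import numpy as np
import pytest

from aunet import EventTable, generate_dataset, ck_like_spec, parse_combination_strings


@pytest.fixture
def toy_table() -> EventTable:
    """Four events over units A, B, C: {A,B}, {A}, {A,B,C}, {C}.

    Events 1-2 belong to condition X, events 3-4 to condition Y.
    """
    return parse_combination_strings(
        ["A+B", "A", "A+B+C", "C"], universe=["A", "B", "C"], conditions=["X", "X", "Y", "Y"]
    )


@pytest.fixture(scope="session")
def ck_table() -> EventTable:
    """One draw of the packaged seven-condition synthetic dataset."""
    return generate_dataset(ck_like_spec(seed=11))


def random_event_table(rng: np.random.Generator, n_events: int, n_units: int, density: float = 0.4) -> EventTable:
    matrix = (rng.random((n_events, n_units)) < density).astype(np.int8)
    units = tuple(f"AU{i + 1}" for i in range(n_units))
    conditions = np.asarray(
        [["X", "Y"][int(b)] for b in rng.integers(0, 2, n_events)], dtype=object
    )
    return EventTable(
        units=units,
        matrix=matrix,
        event_id=np.arange(n_events, dtype=object),
        condition=conditions,
    )
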