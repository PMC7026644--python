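"""Shared fixtures: small toy tables and one session-scoped benchmark run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import coda
from coda.library import ActivityRecord, ActivityTable, WildType
from coda.scoring import run_coda
from coda.simulate import (
    library_to_activity_table,
    make_default_benchmark,
    simulate_library,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def wt10() -> WildType:
    return WildType(id="toy", sequence="ACGUACGUAC")


@pytest.fixture
def multiplicative_table() -> tuple[ActivityTable, dict]:
    """Noiseless table where every double RA is the product of its singles."""
    rng = np.random.default_rng(42)
    L = 30
    wt = WildType(id="mult", sequence="".join(rng.choice(list("ACGU"), L)))
    singles = {}
    records = []
    for pos in range(1, L + 1):
        for alt in "ACGU":
            if alt != wt.sequence[pos - 1]:
                ra = float(rng.uniform(0.0, 1.2))
                singles[(pos, alt)] = ra
                records.append(ActivityRecord(((pos, alt),), ra))
    keys = list(singles)
    seen = set()
    while len(seen) < 400:
        a, b = rng.choice(len(keys), 2, replace=False)
        sa, sb = keys[a], keys[b]
        if sa[0] == sb[0]:
            continue
        key = tuple(sorted((sa, sb)))
        if key in seen:
            continue
        seen.add(key)
        records.append(ActivityRecord(key, singles[sa] * singles[sb]))
    return ActivityTable.from_records(wt, records), singles


@pytest.fixture(scope="session")
def benchmark_run():
    """One full synthetic benchmark with fitted CODA scores (seed 1).

    Session-scoped: the SVR fit is the expensive step and every consumer
    needs the same default conditions.
    """
    ribozyme = make_default_benchmark(1)
    variants, truth = simulate_library(ribozyme, rng=1)
    table = library_to_activity_table(ribozyme, variants)
    model, mixture, score_map = run_coda(table, seed=1)
    return {
        "ribozyme": ribozyme,
        "variants": variants,
        "truth": truth,
        "table": table,
        "model": model,
        "mixture": mixture,
        "score_map": score_map,
    }
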