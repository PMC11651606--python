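"""Shared fixtures: abstract selection instances and seeded landscapes."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import LineString

from fbnopt import (
    BreakSegment,
    ConstituentSet,
    ContainmentRecord,
    ProblemInstance,
    SynthConfig,
    generate_landscape,
    toy_fixture,
)


def make_break(bid: str, cost: float, row: float = 0.0) -> BreakSegment:
    """Abstract break: a horizontal segment whose length equals its cost."""
    return BreakSegment(id=bid, geom=LineString([(0, row), (cost, row)]), cost=cost)


def make_record(fid: str, break_ids, value: float, *, awb: float | None = None,
                size: float = 1.0, max_flame: float = 0.0) -> ContainmentRecord:
    s = ConstituentSet(frozenset(break_ids))
    return ContainmentRecord(
        fire_id=fid, s=s, s_raw=s, max_flame=max_flame if s else None,
        afb=value, awb=value if awb is None else awb, size=size,
    )


@pytest.fixture
def three_break_instance() -> ProblemInstance:
    """Breaks b1,b2,b3 costs (2,2,3); fires f1(4,{b1,b2}), f2(3,{b2,b3}),
    f3(5,{b1,b3}); budget 5.  Known optimum 5 via {b1,b3}."""
    breaks = [make_break("b1", 2.0), make_break("b2", 2.0, 1), make_break("b3", 3.0, 2)]
    records = [
        make_record("f1", {"b1", "b2"}, 4.0),
        make_record("f2", {"b2", "b3"}, 3.0),
        make_record("f3", {"b1", "b3"}, 5.0),
    ]
    return ProblemInstance(breaks=breaks, records=records, budget=5.0,
                           objective="afb", budget_mode="cost")


def random_instance(rng: np.random.Generator, max_breaks: int = 12,
                    max_fires: int = 40) -> ProblemInstance:
    """Random abstract instance for oracle-equivalence and property tests."""
    nb = int(rng.integers(1, max_breaks + 1))
    nf = int(rng.integers(0, max_fires + 1))
    breaks = [make_break(f"b{i:02d}", float(rng.uniform(0.5, 5.0)), row=i)
              for i in range(nb)]
    ids = [b.id for b in breaks]
    records = []
    for j in range(nf):
        if rng.random() < 0.15:  # some never-containable fires
            records.append(make_record(f"f{j:02d}", set(), 0.0))
            continue
        m = int(rng.integers(1, min(4, nb) + 1))
        chosen = rng.choice(ids, size=m, replace=False)
        records.append(
            make_record(f"f{j:02d}", set(chosen), float(rng.uniform(0.0, 10.0)),
                        awb=float(rng.uniform(0.0, 3.0)),
                        size=float(rng.lognormal(0, 1)))
        )
    total = sum(b.effective_cost for b in breaks)
    budget = float(rng.uniform(0, 1.1)) * total
    return ProblemInstance(breaks=breaks, records=records, budget=budget,
                           objective="afb", budget_mode="cost")


@pytest.fixture(scope="session")
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def small_landscape():
    """Compact seeded landscape reused across geometry/pipeline tests."""
    cfg = SynthConfig(seed=11, extent=(6000.0, 6000.0), spacing=1200.0, n_fires=60)
    return generate_landscape(cfg)
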