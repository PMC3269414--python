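import math

import numpy as np
import pytest

from sporepulse.colony import (CellRecord, Microcolony, SimConfig,
                               simulate_microcolony)


@pytest.fixture(scope="session")
def noisefree_colony() -> Microcolony:
    """Deterministic colony: default saturating feedback, no noise."""
    cfg = SimConfig(seed=11, cycle_cv=0.0, amplitude_cv=0.0, measurement_cv=0.0)
    return simulate_microcolony(cfg)


@pytest.fixture(scope="session")
def wildtype_colony() -> Microcolony:
    """Wild-type-like colony at the default noise levels."""
    return simulate_microcolony(SimConfig(seed=7))


def make_tree(spec: dict[str, tuple[str | None, int, int, str]],
              frames_per_cell: int = 3) -> Microcolony:
    """Hand-built lineage tree for deferral-statistic oracles.

    ``spec`` maps cell_id -> (parent_id, birth_frame, end_frame, fate);
    traces are filled with trivial constant series.
    """
    colony = Microcolony()
    for cid, (parent, b, e, fate) in spec.items():
        n = e - b + 1
        colony.add(CellRecord(
            cell_id=cid, parent_id=parent, birth_frame=b, end_frame=e,
            fate=fate, time_min=10.0 * np.arange(b, e + 1),
            length=np.ones(n), mean_fluor={"yfp": np.ones(n)}))
    return colony


def synchronous_binary_tree(depth: int, cycle_frames: int = 4) -> Microcolony:
    """Full binary tree; every depth-``depth`` leaf sporulates simultaneously."""
    spec = {}

    def add(cid: str, parent: str | None, d: int) -> None:
        b = d * cycle_frames
        e = b + cycle_frames
        if d == depth:
            spec[cid] = (parent, b, e, "sporulated")
        else:
            spec[cid] = (parent, b, e, "divided")
            add(cid + "0", cid, d + 1)
            add(cid + "1", cid, d + 1)

    add("1", None, 0)
    return make_tree(spec)


def constant_hazard_tree(q: float, seed: int, max_depth: int = 12) -> Microcolony:
    """Branching tree where every cell sporulates with probability q per cycle.

    The memoryless (geometric) deferral process whose flat hazard the
    experimental data rule out.
    """
    rng = np.random.default_rng(seed)
    spec = {}

    def add(cid: str, parent: str | None, d: int) -> None:
        b, e = 4 * d, 4 * d + 4
        if d < max_depth and rng.random() >= q:
            spec[cid] = (parent, b, e, "divided")
            add(cid + "0", cid, d + 1)
            add(cid + "1", cid, d + 1)
        elif d < max_depth:
            spec[cid] = (parent, b, e, "sporulated")
        else:
            spec[cid] = (parent, b, e, "censored")

    add("1", None, 0)
    return make_tree(spec)
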