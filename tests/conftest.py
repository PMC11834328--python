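import numpy as np
import pytest

from retscn import (
    CohortTable,
    Eye,
    EyeRecord,
    Group,
    ModularityModel,
    NODES,
    default_config,
    generate_cohort,
)


def make_record(
    value=40.0,
    subject_id="S1",
    eye=Eye.OD,
    group=Group.HC,
    age=45.0,
    overrides=None,
):
    """EyeRecord with constant thickness plus optional per-node overrides."""
    thickness = {node: float(value) for node in NODES}
    if overrides:
        thickness.update(overrides)
    return EyeRecord(subject_id, eye, group, age, thickness)


def make_cohort(n_hc=6, n_dwor=6, rng=None, base=40.0, spread=5.0):
    """Small cohort with independent noisy thicknesses and varying ages."""
    rng = rng or np.random.default_rng(0)
    records = []
    for i in range(n_hc + n_dwor):
        group = Group.HC if i < n_hc else Group.DWOR
        thickness = {
            node: float(base + spread * rng.standard_normal()) for node in NODES
        }
        records.append(
            EyeRecord(
                f"S{i:03d}",
                Eye.OD if i % 2 == 0 else Eye.OS,
                group,
                float(rng.uniform(20, 80)),
                thickness,
            )
        )
    return CohortTable(records)


@pytest.fixture
def small_cohort():
    return make_cohort()


@pytest.fixture
def triangles_model():
    """Two disconnected unit-weight triangles: unique optimum at Q = 0.5."""
    A = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[a, b] = A[b, a] = 1.0
    return ModularityModel(A)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort with its planted truth (seeded)."""
    return generate_cohort(default_config(seed=20240101))


def random_weighted_model(rng, n=7, density=0.5, gamma=1.0):
    W = rng.random((n, n))
    W = (W + W.T) / 2
    mask = rng.random((n, n)) < density
    mask = mask & mask.T
    W = W * mask
    np.fill_diagonal(W, 0.0)
    if W.sum() == 0:
        W[0, 1] = W[1, 0] = 1.0
    return ModularityModel(W, gamma=gamma)
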