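import numpy as np
import pandas as pd
import pytest

from pollnet.construction import VISITATION_COLUMNS, IncidenceMatrix


def make_visit_row(
    pop="pop01",
    plant="p01",
    species="sp01",
    group="large_bee",
    visits=1,
    minutes=25.0,
    flowers=10,
):
    return dict(
        zip(
            VISITATION_COLUMNS,
            (pop, plant, species, group, visits, minutes, flowers),
        )
    )


def visit_table(rows):
    return pd.DataFrame([make_visit_row(**r) for r in rows])


def random_incidence(rng, r, c, fill=0.4, ensure_valid=True):
    """Random binary matrix; optionally with no empty rows/columns."""
    for _ in range(1000):
        m = (rng.random((r, c)) < fill).astype(int)
        if not ensure_valid or (m.sum(1).all() and m.sum(0).all()):
            return m
    raise RuntimeError("could not draw a valid incidence matrix")


def incidence_from_matrix(m):
    m = np.asarray(m)
    return IncidenceMatrix(
        plants=[f"p{i:02d}" for i in range(m.shape[0])],
        pollinators=[f"s{k:02d}" for k in range(m.shape[1])],
        presence=m.astype(int),
        counts=m.astype(int),
    )


@pytest.fixture
def toy_visits():
    """Five plants: p1 ok, p2 exactly 15 min, p3 zero visits, p4 ok, p5 fails both."""
    return visit_table(
        [
            dict(plant="p1", species="sp01", visits=3, minutes=25.0),
            dict(plant="p1", species="sp02", visits=1, minutes=25.0),
            dict(plant="p2", species="sp01", visits=3, minutes=15.0),
            dict(plant="p3", species="sp01", visits=0, minutes=20.0),
            dict(plant="p4", species="sp02", visits=2, minutes=30.0),
            dict(plant="p5", species="sp03", visits=0, minutes=10.0),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
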