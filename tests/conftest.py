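import numpy as np
import pytest
from hypothesis import settings

import formulaviz as fv
from formulaviz.attribute_space import EmbeddingConfig

settings.register_profile("repro", derandomize=True, database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fixture_data():
    """The shipped 7-formula tonic fixture: (group, attributes, anchors)."""
    return fv.load_fixture()


@pytest.fixture(scope="session")
def fixture_group(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def fixture_attrs(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def fixture_anchors(fixture_data):
    return fixture_data[2]


@pytest.fixture(scope="session")
def pca_config():
    return EmbeddingConfig(method="pca")


@pytest.fixture(scope="session")
def fixture_embedding(fixture_attrs, pca_config):
    """Deterministic linear-fallback embedding of the fixture herbs."""
    return fv.embed(fixture_attrs, pca_config)


@pytest.fixture(scope="session")
def fixture_distances(fixture_embedding):
    return fv.pairwise_distance(fixture_embedding)


@pytest.fixture(scope="session")
def fixture_bundle(fixture_data, pca_config):
    group, attrs, anchors = fixture_data
    return fv.build_views(
        group, attrs, anchors, embedding_config=pca_config, layout_seed=42
    )


def small_sim_config(seed: int) -> fv.SimConfig:
    """Quick synthetic groups for property sweeps."""
    return fv.SimConfig(
        n_formulas=8,
        herb_pool_size=30,
        min_herbs=2,
        median_herbs=5.0,
        max_herbs=10,
        seed=seed,
    )


def points_distance_matrix(points: np.ndarray) -> tuple[list[str], fv.DistanceMatrix]:
    """Distance matrix over synthetic 2D points labelled h0, h1, ..."""
    ids = [f"h{i}" for i in range(len(points))]
    emb = fv.Embedding(ids, np.asarray(points, dtype=float))
    return ids, fv.pairwise_distance(emb)


def field_slope_at(field, pts: np.ndarray, eps: float) -> np.ndarray:
    """Numerical directional Lipschitz estimate of a UCS color field.

    Max ΔE per unit embedding distance around each point, sampled over
    eight directions at step ``eps``; used to bound raster-vs-pointwise
    color discrepancies by the cell size.
    """
    dirs = np.array(
        [[1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [-1, -1], [1, -1], [-1, 1]],
        dtype=float,
    )
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    base = field(pts)
    slopes = np.zeros(len(pts))
    for d in dirs:
        shifted = field(pts + eps * d)
        de = np.linalg.norm(shifted - base, axis=-1) / eps
        slopes = np.maximum(slopes, de)
    return slopes


def assert_layout_invariants(layout: fv.IcicleLayout, group: fv.FormulaGroup):
    """Structural invariants of a finished icicle layout.

    Column content bijection, principal cells confined to the padded top
    region, global nonprincipal alignment row, contiguity of equal
    top-level herbs, and row equality for nonprincipal herbs shared by
    adjacent columns.
    """
    pr = layout.principal_rows
    assert pr == max((len(f.principal) for f in group.formulas), default=0)
    assert [c.formula for c in layout.columns] != [] or not group.formulas

    by_name = {f.name: f for f in group.formulas}
    assert sorted(by_name) == sorted(c.formula for c in layout.columns)

    for col in layout.columns:
        f = by_name[col.formula]
        non_pad = [c for c in col.cells if c.herb is not None]
        assert sorted(c.herb for c in non_pad) == sorted(f.herbs)
        rows = [c.row for c in col.cells]
        assert len(rows) == len(set(rows))
        pset = set(f.principal)
        for c in non_pad:
            if c.is_principal:
                assert c.row < pr and c.herb in pset
            else:
                assert c.row >= pr and c.herb not in pset

    # contiguity of top-level groups
    tops = [layout.top_level[c.formula] for c in layout.columns]
    seen = set()
    prev = object()
    for t in tops:
        if t != prev:
            assert t not in seen, f"top-level {t} not contiguous"
            seen.add(t)
        prev = t

    # shared nonprincipal herbs of adjacent columns sit on equal rows
    for left, right in zip(layout.columns, layout.columns[1:]):
        lrows = left.nonprincipal_rows()
        rrows = right.nonprincipal_rows()
        for herb, row in lrows.items():
            if herb in rrows:
                assert rrows[herb] == row, (
                    f"{herb} misaligned between {left.formula} and "
                    f"{right.formula}"
                )
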