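import itertools

import numpy as np
import pytest

import formulaviz as fv
from formulaviz.similarity_layout import (
    assign_top_level,
    build_icicle,
    count_aligned_pairs,
    input_order_layout,
    layout_principal,
    layout_remaining,
    order_by_similarity,
)
from formulaviz.types import NO_PRINCIPAL

from conftest import (
    assert_layout_invariants,
    points_distance_matrix,
    small_sim_config,
)


def greedy_chain_oracle(points: np.ndarray, start: int) -> list[int]:
    """Exhaustive-enumeration oracle for the similarity sequence.

    Enumerates every permutation and keeps the ones satisfying the greedy
    property (each element is the nearest unplaced one to its predecessor,
    first-index tie-break).  Exactly one must survive.
    """

    def dist(i, j):
        return float(np.linalg.norm(points[i] - points[j]))

    n = len(points)
    valid = []
    for perm in itertools.permutations(range(n)):
        if perm[0] != start:
            continue
        ok = True
        for k in range(1, n):
            rest = perm[k:]
            dmin = min(dist(perm[k - 1], r) for r in rest)
            winners = [r for r in sorted(rest) if dist(perm[k - 1], r) <= dmin + 1e-12]
            if perm[k] != winners[0]:
                ok = False
                break
        if ok:
            valid.append(list(perm))
    assert len(valid) == 1
    return valid[0]


class TestOrderBySimilarity:
    def test_single_herb(self):
        ids, d = points_distance_matrix(np.zeros((1, 2)))
        assert order_by_similarity(ids, d, start=0) == ["h0"]

    def test_empty_sequence(self):
        _, d = points_distance_matrix(np.zeros((0, 2)))
        assert order_by_similarity([], d) == []

    def test_collinear_points(self):
        ids, d = points_distance_matrix([[0, 0], [1, 0], [3, 0]])
        assert order_by_similarity(ids, d, start=0) == ["h0", "h1", "h2"]

    @pytest.mark.parametrize("n", range(2, 8))
    def test_matches_exhaustive_enumeration(self, n):
        """Greedy chain equals the unique greedy permutation, all sizes <= 7."""
        rng = np.random.default_rng(100 + n)
        for trial in range(5):
            pts = rng.normal(size=(n, 2))
            ids, d = points_distance_matrix(pts)
            start = int(rng.integers(n))
            got = order_by_similarity(ids, d, start=start)
            expected = [f"h{i}" for i in greedy_chain_oracle(pts, start)]
            assert got == expected

    def test_seeded_start_is_deterministic(self):
        ids, d = points_distance_matrix(np.random.default_rng(1).normal(size=(6, 2)))
        assert order_by_similarity(ids, d, seed=9) == order_by_similarity(
            ids, d, seed=9
        )

    def test_output_is_permutation(self):
        ids, d = points_distance_matrix(np.random.default_rng(2).normal(size=(9, 2)))
        assert sorted(order_by_similarity(ids, d, seed=0)) == sorted(ids)


class TestAssignTopLevel:
    def test_fixture_renshen_is_top_level(self, fixture_group, fixture_distances):
        top, ordered = assign_top_level(fixture_group, fixture_distances, seed=42)
        assert "Renshen" in ordered
        assert top["Shengmaisan"] == "Renshen"
        assert top["Sijunzitang"] == "Renshen"

    def test_multi_principal_reuses_listed_herb(
        self, fixture_group, fixture_distances
    ):
        """Bazhentang's principals Renshen and Shudihuang are both listed
        (each is a sole principal elsewhere); the tie resolves to whichever
        comes first in the similarity-ordered list."""
        top, ordered = assign_top_level(fixture_group, fixture_distances, seed=42)
        assert set(ordered) >= {"Renshen", "Shudihuang"}
        both = [h for h in ordered if h in ("Renshen", "Shudihuang")]
        assert top["Bazhentang"] == both[0]

    def test_every_principal_formula_mapped(self, fixture_group, fixture_distances):
        top, _ = assign_top_level(fixture_group, fixture_distances, seed=0)
        for f in fixture_group.formulas:
            assert top[f.name] in f.principal

    def test_unlisted_principals_random_but_seeded(self):
        pts = np.random.default_rng(0).normal(size=(3, 2))
        ids, d = points_distance_matrix(pts)
        group = fv.FormulaGroup(
            "g", [fv.Formula("F", herbs=ids, principal=ids)]
        )
        runs = [assign_top_level(group, d, seed=5) for _ in range(2)]
        assert runs[0] == runs[1]
        assert runs[0][0]["F"] in ids

    def test_zero_principal_goes_to_sentinel(self, fixture_distances):
        group = fv.FormulaGroup(
            "g", [fv.Formula("F", herbs=["Renshen", "Fuling"])]
        )
        top, ordered = assign_top_level(group, fixture_distances, seed=0)
        assert top["F"] == NO_PRINCIPAL
        assert NO_PRINCIPAL not in ordered


class TestLayoutPrincipal:
    def test_fixture_global_pad_is_max_principal_count(
        self, fixture_group, fixture_distances
    ):
        top, ordered = assign_top_level(fixture_group, fixture_distances, seed=42)
        partial = layout_principal(fixture_group, top, ordered, fixture_distances)
        assert partial.principal_rows == 4  # Dihuangyinzi has 4 principals

    def test_renshen_subgroup_depth_is_three(
        self, fixture_group, fixture_distances
    ):
        """Within the Renshen group the deepest principal stack is 3
        (Shenlingbaizhusan), regardless of the global pad height."""
        top, ordered = assign_top_level(fixture_group, fixture_distances, seed=42)
        partial = layout_principal(fixture_group, top, ordered, fixture_distances)
        depths = [
            max(c.level for c in col.cells if c.herb is not None and c.is_principal)
            + 1
            for col in partial.columns
            if top[col.formula] == "Renshen"
        ]
        assert max(depths) == 3

    def test_renshen_group_sorted_by_ascending_principal_count(
        self, fixture_group, fixture_distances
    ):
        top, ordered = assign_top_level(fixture_group, fixture_distances, seed=42)
        partial = layout_principal(fixture_group, top, ordered, fixture_distances)
        renshen_cols = [
            col.formula for col in partial.columns if top[col.formula] == "Renshen"
        ]
        counts = [len(fixture_group[n].principal) for n in renshen_cols]
        assert counts == sorted(counts)
        assert renshen_cols.index("Bazhentang") > renshen_cols.index("Sijunzitang")
        assert renshen_cols.index("Bazhentang") > renshen_cols.index("Shengmaisan")
        if "Shenlingbaizhusan" in renshen_cols:
            assert renshen_cols[-1] == "Shenlingbaizhusan"

    def test_all_single_principal_means_no_pad(self):
        pts = np.random.default_rng(0).normal(size=(6, 2))
        ids, d = points_distance_matrix(pts)
        group = fv.FormulaGroup(
            "g",
            [
                fv.Formula("A", herbs=ids[:3], principal=[ids[0]]),
                fv.Formula("B", herbs=ids[3:], principal=[ids[3]]),
            ],
        )
        top, ordered = assign_top_level(group, d, seed=0)
        partial = layout_principal(group, top, ordered, d)
        assert partial.principal_rows == 1
        for col in partial.columns:
            assert not any(c.herb is None for c in col.cells)


class TestLayoutRemaining:
    def test_identical_herb_sets_align_perfectly(self):
        pts = np.random.default_rng(4).normal(size=(5, 2))
        ids, d = points_distance_matrix(pts)
        group = fv.FormulaGroup(
            "g",
            [
                fv.Formula("A", herbs=ids, principal=[ids[0]]),
                fv.Formula("B", herbs=ids, principal=[ids[0]]),
            ],
        )
        emb = fv.Embedding(ids, pts)
        layout = build_icicle(group, emb, seed=0)
        a, b = layout.columns
        assert a.herb_rows() == b.herb_rows()

    def test_fixture_baizhu_fuling_align_as_nonprincipals(self, fixture_bundle):
        """Baizhu and Fuling, nonprincipal in both Sijunzitang and
        Bazhentang, occupy equal rows wherever those columns are adjacent."""
        layout = fixture_bundle.layout
        cols = {c.formula: i for i, c in enumerate(layout.columns)}
        i, j = cols["Sijunzitang"], cols["Bazhentang"]
        if abs(i - j) == 1:
            a = layout.columns[i].nonprincipal_rows()
            b = layout.columns[j].nonprincipal_rows()
            for herb in ("Baizhu", "Fuling"):
                assert a[herb] == b[herb]
        else:  # still must satisfy the adjacency invariant chain
            assert_layout_invariants(layout, fixture_bundle.group)

    def test_disjoint_adjacent_column_is_distance_sorted(self):
        # left column h0..h3 (h0 principal), right column h4..h7 disjoint
        pts = np.array(
            [[0, 0], [0, 1], [0, 2], [0, 3], [5, 2.5], [5, 0.2], [5, 1.4], [5, 3.9]]
        )
        ids, d = points_distance_matrix(pts)
        group = fv.FormulaGroup(
            "g",
            [
                fv.Formula("A", herbs=ids[:4], principal=[ids[0]]),
                fv.Formula("B", herbs=ids[4:], principal=[ids[4]]),
            ],
        )
        # pin the column order A, B by assigning top levels explicitly
        top = {"A": ids[0], "B": ids[4]}
        partial = layout_principal(group, top, [ids[0], ids[4]], d)
        layout = layout_remaining(partial, group, d)
        right = next(c for c in layout.columns if c.formula == "B")
        rows = right.nonprincipal_rows()
        placed = sorted(rows, key=rows.get)
        # brute-force key: ascending min distance to the left column's herbs
        def key(h):
            return min(d.d(h, x) for x in group["A"].herbs)

        assert placed == sorted(rows, key=key)

    def test_compact_mode_removes_gaps_keeps_order(self, fixture_data, pca_config):
        group, attrs, _ = fixture_data
        emb = fv.embed(attrs, pca_config)
        full = build_icicle(group, emb, seed=42)
        compact = build_icicle(group, emb, seed=42, compact=True)
        for cf, cc in zip(full.columns, compact.columns):
            fr = cf.nonprincipal_rows()
            cr = cc.nonprincipal_rows()
            assert sorted(fr, key=fr.get) == sorted(cr, key=cr.get)
            if cr:
                rows = sorted(cr.values())
                assert rows == list(
                    range(compact.principal_rows, compact.principal_rows + len(rows))
                )


class TestBuildIcicle:
    def test_fixture_invariants(self, fixture_bundle):
        assert_layout_invariants(fixture_bundle.layout, fixture_bundle.group)

    def test_empty_group_empty_layout(self):
        layout = build_icicle(
            fv.FormulaGroup("g", []), fv.Embedding([], np.zeros((0, 2))), seed=0
        )
        assert layout.columns == [] and layout.principal_rows == 0

    def test_seed_determinism(self, fixture_group, fixture_embedding):
        l1 = build_icicle(fixture_group, fixture_embedding, seed=7)
        l2 = build_icicle(fixture_group, fixture_embedding, seed=7)
        assert l1.to_dict() == l2.to_dict()

    def test_formula_permutation_preserves_invariants(
        self, fixture_group, fixture_embedding
    ):
        reversed_group = fv.FormulaGroup(
            fixture_group.name, list(reversed(fixture_group.formulas))
        )
        layout = build_icicle(reversed_group, fixture_embedding, seed=7)
        assert_layout_invariants(layout, reversed_group)

    def test_synthetic_invariants_sweep(self, pca_config):
        for seed in range(15):
            group, attrs, _ = fv.simulate_group(small_sim_config(seed))
            emb = fv.embed(attrs, pca_config)
            layout = build_icicle(group, emb, seed=seed)
            assert_layout_invariants(layout, group)

    def test_missing_embedding_herb_raises(self, fixture_group, fixture_attrs):
        emb = fv.embed(fixture_attrs[:-1], fv.EmbeddingConfig(method="pca"))
        with pytest.raises(KeyError):
            build_icicle(fixture_group, emb, seed=0)


class TestAlignmentQuality:
    def test_fixture_beats_input_order(self, fixture_bundle):
        sim = count_aligned_pairs(fixture_bundle.layout)
        base = count_aligned_pairs(input_order_layout(fixture_bundle.group))
        assert sim >= base

    def test_synthetic_groups_not_worse_than_input_order(self, pca_config):
        for seed in range(10):
            group, attrs, _ = fv.simulate_group(small_sim_config(seed))
            emb = fv.embed(attrs, pca_config)
            sim = count_aligned_pairs(build_icicle(group, emb, seed=seed))
            base = count_aligned_pairs(input_order_layout(group))
            assert sim >= base, f"seed {seed}: {sim} < {base}"
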