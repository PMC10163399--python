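"""Similarity-based icicle layout of formula groups.

The icicle plot shows a sparse set-element matrix: one column per formula,
stacked cells per herb, with the principal herbs (Junyao) in a padded top
region and the remaining herbs below.  Because a formula is a *set*, cell
order within a column is free; this module fixes it with a greedy,
similarity-driven two-step arrangement so that equal herbs in adjacent
columns line up vertically and similar formulas sit next to each other:

1. *Principal arrangement.*  Every herb that is the sole principal of some
   formula becomes a top-level principal herb; the top-level list is
   ordered by the greedy nearest-neighbour chain (the "similarity
   sequence").  A multi-principal formula reuses a listed herb when it can,
   otherwise one of its principals is drawn at random (seeded) and appended
   to the list.  Columns are grouped contiguously by top-level herb, groups
   follow the top-level sequence, and within a group columns are sorted by
   ascending principal count.  The principal region is padded to the global
   maximum principal count so the tops of all nonprincipal herbs align.

2. *Remaining arrangement.*  The leftmost column's nonprincipal herbs are
   chained by similarity starting from the herb nearest its top-level
   principal.  Each subsequent column first copies the row of every herb it
   shares with the column immediately to its left, then fills the free rows
   top-to-bottom with its remaining herbs sorted by ascending minimum
   distance to the left column's herb set.

All distance look-ups use the 2D-embedding distance matrix; ties break by
input order, and every random draw comes from a caller-provided seed, so
the layout is end-to-end deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attribute_space import DistanceMatrix, Embedding, pairwise_distance
from .types import Formula, FormulaGroup, NO_PRINCIPAL


@dataclass(frozen=True)
class IcicleCell:
    row: int
    herb: str | None  # None marks a PAD cell
    is_principal: bool = False
    level: int = 0  # depth within its region (0-based)

    @property
    def is_pad(self) -> bool:
        return self.herb is None


@dataclass
class IcicleColumn:
    formula: str
    cells: list[IcicleCell]

    def herb_rows(self) -> dict[str, int]:
        return {c.herb: c.row for c in self.cells if c.herb is not None}

    def nonprincipal_rows(self) -> dict[str, int]:
        return {
            c.herb: c.row
            for c in self.cells
            if c.herb is not None and not c.is_principal
        }


@dataclass
class IcicleLayout:
    columns: list[IcicleColumn]
    principal_rows: int
    top_level: dict[str, str] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return max(
            (c.row + 1 for col in self.columns for c in col.cells), default=0
        )

    def to_dict(self) -> dict:
        return {
            "principal_rows": self.principal_rows,
            "columns": [
                {
                    "formula": col.formula,
                    "top_level": self.top_level.get(col.formula),
                    "cells": [
                        {
                            "row": c.row,
                            "herb": c.herb,
                            "principal": c.is_principal,
                            "level": c.level,
                        }
                        for c in col.cells
                    ],
                }
                for col in self.columns
            ],
        }


def order_by_similarity(
    herbs: list[str],
    d: DistanceMatrix,
    start: int | None = None,
    seed: int | None = None,
) -> list[str]:
    """Greedy nearest-neighbour chain (the similarity sequence).

    The first element is ``herbs[start]``; when ``start`` is omitted it is
    drawn uniformly from a generator seeded with ``seed``.  Each following
    element is the unplaced herb closest to the previous one, ties broken
    by input order.
    """
    if not herbs:
        return []
    missing = [h for h in herbs if h not in d]
    if missing:
        raise KeyError(f"herbs missing from distance matrix: {missing}")
    if start is None:
        rng = np.random.default_rng(seed)
        start = int(rng.integers(len(herbs)))
    if not 0 <= start < len(herbs):
        raise IndexError(f"start index {start} out of range for {len(herbs)} herbs")
    remaining = list(herbs)
    seq = [remaining.pop(start)]
    while remaining:
        dists = np.array([d.d(seq[-1], h) for h in remaining])
        seq.append(remaining.pop(int(np.argmin(dists))))
    return seq


def assign_top_level(
    group: FormulaGroup, d: DistanceMatrix, seed: int = 0
) -> tuple[dict[str, str], list[str]]:
    """Assign each formula its top-level principal herb.

    Returns ``(top_level, ordered_tops)`` where ``top_level`` maps every
    formula name to a herb id (or the no-principal sentinel) and
    ``ordered_tops`` is the similarity-ordered top-level herb list, with
    herbs appended for formulas none of whose principals were listed.
    """
    rng = np.random.default_rng(seed)
    sole: list[str] = []
    for f in group.formulas:
        if len(f.principal) == 1 and f.principal[0] not in sole:
            sole.append(f.principal[0])
    if sole:
        start = int(rng.integers(len(sole)))
        ordered = order_by_similarity(sole, d, start=start)
    else:
        ordered = []

    top_level: dict[str, str] = {}
    for f in group.formulas:
        if not f.principal:
            top_level[f.name] = NO_PRINCIPAL
            continue
        listed = [h for h in ordered if h in f.principal]
        if listed:
            top_level[f.name] = listed[0]  # tie broken by list order
        else:
            pick = f.principal[int(rng.integers(len(f.principal)))]
            ordered.append(pick)
            top_level[f.name] = pick
    return top_level, ordered


def _principal_cells(
    f: Formula, top: str, d: DistanceMatrix, principal_rows: int
) -> list[IcicleCell]:
    cells = []
    if top != NO_PRINCIPAL:
        rest = [h for h in f.principal if h != top]
        order = np.argsort([d.d(top, h) for h in rest], kind="stable")
        ordered = [top] + [rest[i] for i in order]
        for lvl, h in enumerate(ordered):
            cells.append(IcicleCell(row=lvl, herb=h, is_principal=True, level=lvl))
    for row in range(len(cells), principal_rows):
        cells.append(IcicleCell(row=row, herb=None, is_principal=False, level=row))
    return cells


def layout_principal(
    group: FormulaGroup,
    top_level: dict[str, str],
    ordered_tops: list[str],
    d: DistanceMatrix,
) -> IcicleLayout:
    """Arrange and pad the principal region; nonprincipal cells come later.

    The pad height is the global maximum principal count so that the top of
    the nonprincipal region is a single row across all columns.
    """
    principal_rows = max((len(f.principal) for f in group.formulas), default=0)
    bucket_order = list(ordered_tops)
    if any(t == NO_PRINCIPAL for t in top_level.values()):
        bucket_order.append(NO_PRINCIPAL)

    columns: list[IcicleColumn] = []
    index = {f.name: i for i, f in enumerate(group.formulas)}
    for top in bucket_order:
        members = [f for f in group.formulas if top_level[f.name] == top]
        members.sort(key=lambda f: (len(f.principal), index[f.name]))
        for f in members:
            columns.append(
                IcicleColumn(f.name, _principal_cells(f, top, d, principal_rows))
            )
    return IcicleLayout(columns, principal_rows, dict(top_level))


def layout_remaining(
    partial: IcicleLayout,
    group: FormulaGroup,
    d: DistanceMatrix,
    compact: bool = False,
) -> IcicleLayout:
    """Fill the nonprincipal region, aligning shared herbs across neighbours.

    With ``compact=True`` the per-column row gaps left by alignment are
    squeezed out, keeping only relative order.
    """
    base = partial.principal_rows
    prev_rows: dict[str, int] = {}
    prev_all: list[str] = []
    for col in partial.columns:
        f = group[col.formula]
        herbs = f.nonprincipal
        placed: dict[str, int] = {}
        if not prev_all:  # leftmost column
            if herbs:
                top = partial.top_level.get(col.formula, NO_PRINCIPAL)
                if top != NO_PRINCIPAL:
                    start = int(np.argmin([d.d(top, h) for h in herbs]))
                else:
                    start = 0
                seq = order_by_similarity(herbs, d, start=start)
                for i, h in enumerate(seq):
                    placed[h] = base + i
        else:
            aligned = {h: prev_rows[h] for h in herbs if h in prev_rows}
            placed.update(aligned)
            rest = [h for h in herbs if h not in aligned]
            order = np.argsort(
                [min(d.d(h, x) for x in prev_all) for h in rest], kind="stable"
            )
            taken = set(aligned.values())
            row = base
            for i in order:
                while row in taken:
                    row += 1
                placed[rest[i]] = row
                taken.add(row)
        if compact and placed:
            for i, h in enumerate(sorted(placed, key=placed.get)):
                placed[h] = base + i

        cells = [c for c in col.cells if c.row < base]
        if placed:
            occupied = {r: h for h, r in placed.items()}
            for row in range(base, max(placed.values()) + 1):
                h = occupied.get(row)
                cells.append(
                    IcicleCell(
                        row=row, herb=h, is_principal=False, level=row - base
                    )
                )
        col.cells = cells
        prev_rows = placed
        prev_all = list(f.herbs)
    return partial


def build_icicle(
    group: FormulaGroup,
    embedding: Embedding,
    seed: int = 0,
    compact: bool = False,
) -> IcicleLayout:
    """Full pipeline: top-level assignment → principal region → remaining."""
    if not group.formulas:
        return IcicleLayout([], 0, {})
    d = pairwise_distance(embedding)
    missing = [h for h in group.herb_universe if h not in d]
    if missing:
        raise KeyError(f"herbs missing from embedding: {missing}")
    top_level, ordered = assign_top_level(group, d, seed=seed)
    partial = layout_principal(group, top_level, ordered, d)
    return layout_remaining(partial, group, d, compact=compact)


def input_order_layout(group: FormulaGroup) -> IcicleLayout:
    """Baseline layout in raw input order (no similarity, no alignment).

    Columns follow the group's formula order; principals then nonprincipals
    keep their file order, with the same global principal-region padding.
    Serves as the comparison point for alignment-quality measurements.
    """
    principal_rows = max((len(f.principal) for f in group.formulas), default=0)
    columns = []
    for f in group.formulas:
        cells = [
            IcicleCell(row=i, herb=h, is_principal=True, level=i)
            for i, h in enumerate(f.principal)
        ]
        for row in range(len(cells), principal_rows):
            cells.append(IcicleCell(row=row, herb=None, level=row))
        for j, h in enumerate(f.nonprincipal):
            cells.append(
                IcicleCell(row=principal_rows + j, herb=h, level=j)
            )
        columns.append(IcicleColumn(f.name, cells))
    return IcicleLayout(columns, principal_rows, {})


def count_aligned_pairs(layout: IcicleLayout) -> int:
    """Number of (adjacent-column, herb) pairs occupying equal rows.

    The quality measure for layout comparison: a herb shared by two
    neighbouring columns counts when it sits on the same row in both.
    """
    total = 0
    for left, right in zip(layout.columns, layout.columns[1:]):
        lrows, rrows = left.herb_rows(), right.herb_rows()
        total += sum(1 for h, r in lrows.items() if rrows.get(h) == r)
    return total
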