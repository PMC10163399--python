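"""Pairwise shared-herb counts between formulas and group summary statistics.

The shared-herb matrix M is the formula-by-formula co-occurrence matrix:
M[i, j] = |herbs(F_i) ∩ herbs(F_j)| under exact string identity.  The
diagonal holds each formula's own size (self-intersection); it is excluded
from pair statistics and from heat-map color normalization so that the
largest off-diagonal overlap dominates the scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import FormulaGroup


@dataclass
class SharedHerbMatrix:
    formula_names: list[str]
    values: np.ndarray  # (n, n) int

    def count(self, a: str, b: str) -> int:
        i = self.formula_names.index(a)
        j = self.formula_names.index(b)
        return int(self.values[i, j])

    def off_diagonal_max(self) -> int:
        if len(self.formula_names) < 2:
            return 0
        masked = self.values.copy()
        np.fill_diagonal(masked, -1)
        return int(masked.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.formula_names, columns=self.formula_names
        )

    def to_csv(self, target: str | Path) -> None:
        self.to_frame().to_csv(Path(target))


@dataclass
class GroupStats:
    """Summary statistics of a formula group.

    Pairwise fields are over unordered formula pairs (n·(n−1)/2 of them),
    with the sample (n−1) standard deviation; both are ``None`` for
    single-formula groups where no pair exists, and the SD is ``None``
    when only one pair exists.
    """

    n_formulas: int
    n_herbs: int
    n_principal: int
    median_herbs_per_formula: float
    min_herbs_per_formula: int
    max_herbs_per_formula: int
    median_principal_per_formula: float
    mean_shared: float | None
    sd_shared: float | None

    def to_json(self, target: str | Path) -> None:
        Path(target).write_text(json.dumps(self.__dict__, indent=1) + "\n")


def compute_matrix(group: FormulaGroup) -> SharedHerbMatrix:
    """All-pairs intersection cardinalities via binary membership algebra."""
    universe = group.herb_universe
    idx = {h: i for i, h in enumerate(universe)}
    B = np.zeros((len(group.formulas), len(universe)), dtype=np.int64)
    for i, f in enumerate(group.formulas):
        for h in f.herbs:
            B[i, idx[h]] = 1
    return SharedHerbMatrix([f.name for f in group.formulas], B @ B.T)


def compute_stats(group: FormulaGroup) -> GroupStats:
    sizes = [len(f) for f in group.formulas]
    n = len(group.formulas)
    M = compute_matrix(group).values
    iu = np.triu_indices(n, k=1)
    shared = M[iu]
    if shared.size == 0:
        mean_shared, sd_shared = None, None
    else:
        mean_shared = float(np.mean(shared))
        sd_shared = float(np.std(shared, ddof=1)) if shared.size > 1 else None
    return GroupStats(
        n_formulas=n,
        n_herbs=len(group.herb_universe),
        n_principal=len(group.principal_universe),
        median_herbs_per_formula=float(np.median(sizes)),
        min_herbs_per_formula=int(min(sizes)),
        max_herbs_per_formula=int(max(sizes)),
        median_principal_per_formula=float(
            np.median([len(f.principal) for f in group.formulas])
        ),
        mean_shared=mean_shared,
        sd_shared=sd_shared,
    )
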