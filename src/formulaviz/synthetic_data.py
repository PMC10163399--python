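"""Seeded random formula groups with the statistical shape of real data.

The generator emulates the scale of a textbook formula category: a few
dozen formulas over a shared herb pool, herb counts per formula following
a discretized log-normal matched to a (min, median, max) triple, a median
of one principal herb per formula, and a preferential-attachment herb
sampler so that popular herbs recur across formulas and pairwise overlaps
are nonzero — the feature the similarity layout and the shared-herb matrix
exist to show.  Attribute flags are independent Bernoulli draws per block
(Siqi/Wuwei/Guijing) with at least one flag forced per block, mimicking
the sparse one-to-few flag patterns of real materia-medica tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    ATTRIBUTE_SCHEMA,
    GUIJING,
    SIQI,
    WUWEI,
    AttributeRecord,
    Formula,
    FormulaGroup,
)

#: Five-element archetypes: (siqi flag, wuwei flag, guijing flag) and the
#: default muted color each element maps to.
ELEMENT_ARCHETYPES = {
    "wood": (("cool", "sour", "liver"), "#7A9E7E"),
    "fire": (("hot", "bitter", "heart"), "#C08081"),
    "earth": (("calm", "sweet", "spleen"), "#C3AE76"),
    "metal": (("pungent", "lung"), "#C2C2BC"),
    "water": (("cold", "salty", "kidney"), "#6E6E78"),
}


@dataclass
class SimConfig:
    """Generator settings; defaults mirror a 20-formula tonic-scale group."""

    n_formulas: int = 20
    herb_pool_size: int = 58
    min_herbs: int = 2
    median_herbs: float = 7.5
    max_herbs: int = 15
    principal_probs: tuple[float, ...] = (0.6, 0.25, 0.1, 0.05)  # P(1..4 principals)
    overlap_weight: float = 1.0  # preferential-attachment strength; 0 = uniform
    flag_prob: dict = field(
        default_factory=lambda: {"siqi": 0.2, "wuwei": 0.2, "guijing": 0.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_herbs < 2:
            raise ValueError("min_herbs must be >= 2")
        if self.herb_pool_size < self.max_herbs:
            raise ValueError("herb_pool_size must be >= max_herbs")
        if not np.isclose(sum(self.principal_probs), 1.0):
            raise ValueError("principal_probs must sum to 1")


def _draw_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Discretized log-normal herb counts truncated to [min, max].

    The log-normal median is the configured median and sigma places the
    configured max near the 99th percentile, reproducing the right-skewed
    size distributions of real formula categories.
    """
    mu = np.log(cfg.median_herbs)
    sigma = max((np.log(cfg.max_herbs) - mu) / 2.33, 0.05)
    sizes = np.rint(rng.lognormal(mu, sigma, size=cfg.n_formulas)).astype(int)
    return np.clip(sizes, cfg.min_herbs, cfg.max_herbs)


def simulate_group(
    cfg: SimConfig | None = None,
) -> tuple[FormulaGroup, list[AttributeRecord], list[dict]]:
    """Generate a (formula group, attribute table, anchor palette) triple.

    Deterministic for a fixed config (including its seed).  Anchors are
    the five herbs (among those used) closest in Hamming distance to the
    per-element attribute archetypes, colored with the default palette.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    pool = [f"Herb{i:03d}" for i in range(cfg.herb_pool_size)]
    usage = np.zeros(cfg.herb_pool_size)

    formulas = []
    sizes = _draw_sizes(cfg, rng)
    for i in range(cfg.n_formulas):
        size = int(sizes[i])
        weights = 1.0 + cfg.overlap_weight * usage
        chosen: list[int] = []
        w = weights.copy()
        for _ in range(size):
            p = w / w.sum()
            j = int(rng.choice(cfg.herb_pool_size, p=p))
            chosen.append(j)
            w[j] = 0.0
        usage[chosen] += 1.0
        herbs = [pool[j] for j in chosen]
        n_prin = min(
            1 + int(rng.choice(len(cfg.principal_probs), p=cfg.principal_probs)),
            size,
        )
        principal = list(rng.choice(herbs, size=n_prin, replace=False))
        formulas.append(
            Formula(name=f"Formula{i:02d}", herbs=herbs, principal=principal)
        )
    group = FormulaGroup(name=f"synthetic-{cfg.seed}", formulas=formulas)

    blocks = {"siqi": SIQI, "wuwei": WUWEI, "guijing": GUIJING}
    records = []
    for h in group.herb_universe:
        flags: list[int] = []
        for bname, names in blocks.items():
            p = cfg.flag_prob[bname]
            f = (rng.random(len(names)) < p).astype(int)
            if f.sum() == 0:
                f[int(rng.integers(len(names)))] = 1
            flags.extend(int(v) for v in f)
        records.append(AttributeRecord(herb_id=h, flags=tuple(flags)))

    anchors = _pick_anchors(records)
    return group, records, anchors


def _pick_anchors(records: list[AttributeRecord]) -> list[dict]:
    """Per-element representative herbs: nearest to each archetype vector."""
    col = {name: i for i, name in enumerate(ATTRIBUTE_SCHEMA)}
    X = np.vstack([r.vector() for r in records])
    taken: set[int] = set()
    anchors = []
    for element, (flag_names, color) in ELEMENT_ARCHETYPES.items():
        proto = np.zeros(len(ATTRIBUTE_SCHEMA))
        for name in flag_names:
            proto[col[name]] = 1.0
        dist = np.abs(X - proto).sum(axis=1)
        order = np.argsort(dist, kind="stable")
        best = next(int(i) for i in order if int(i) not in taken)
        taken.add(best)
        anchors.append(
            {"herb": records[best].herb_id, "element": element, "srgb": color}
        )
    return anchors
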