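"""Core domain types for herbal-formula set systems.

A *formula* is an ordered, duplicate-free list of herb identifiers, a subset
of which are flagged as principal herbs (Junyao) — the herbs playing the
major role against the main syndrome under the Jun-Chen-Zuo-Shi
compatibility principle.  Herb identity is exact Pinyin-string equality: no
normalization is applied, so prepared and raw forms of the same plant (e.g.
``Zhigancao`` vs ``Gancao``) are distinct herbs.

Each herb additionally carries a 23-dimensional binary attribute vector in a
fixed schema order: Siqi (5 thermal-property flags), Wuwei (7 flavor flags)
and Guijing (11 meridian-orientation flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Siqi — thermal property categories (4 plus "calm" for gentle herbs).
SIQI = ("cold", "hot", "warm", "cool", "calm")

#: Wuwei — flavor categories.
WUWEI = ("pungent", "sweet", "sour", "bitter", "salty", "tasteless", "astringent")

#: Guijing — meridian/organ orientations.
GUIJING = (
    "liver",
    "heart",
    "spleen",
    "lung",
    "kidney",
    "bladder",
    "large_intestine",
    "small_intestine",
    "stomach",
    "gallbladder",
    "pericardium",
)

#: Full 23-column attribute schema, in canonical order siqi ‖ wuwei ‖ guijing.
ATTRIBUTE_SCHEMA = SIQI + WUWEI + GUIJING

N_ATTRIBUTES = len(ATTRIBUTE_SCHEMA)  # 23

#: Sentinel top-level bucket for formulas without any principal herb.
NO_PRINCIPAL = "__no_principal__"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class Herb:
    """An herbal medicine, keyed by its Pinyin name."""

    id: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("herb id must be nonempty")
        if not self.display_name:
            object.__setattr__(self, "display_name", self.id)


@dataclass
class Formula:
    """A named combination of herbs with principal-herb flags.

    ``herbs`` preserves input order and is duplicate-free; ``principal`` is
    the subset of ``herbs`` flagged as Junyao, in ``herbs`` order.
    """

    name: str
    herbs: list[str]
    principal: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValidationError(f"formula {self.name!r} has no herbs")
        seen = set()
        for h in self.herbs:
            if h in seen:
                raise ValidationError(
                    f"duplicate herb {h!r} in formula {self.name!r}"
                )
            seen.add(h)
        bad = [h for h in self.principal if h not in seen]
        if bad:
            raise ValidationError(
                f"principal herbs {bad} not members of formula {self.name!r}"
            )
        # principal preserves herbs order regardless of input order
        pset = set(self.principal)
        self.principal = [h for h in self.herbs if h in pset]

    @property
    def nonprincipal(self) -> list[str]:
        pset = set(self.principal)
        return [h for h in self.herbs if h not in pset]

    def __len__(self) -> int:
        return len(self.herbs)


@dataclass
class FormulaGroup:
    """An ordered collection of formulas (e.g. one textbook category)."""

    name: str
    formulas: list[Formula]

    def __post_init__(self) -> None:
        names = [f.name for f in self.formulas]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate formula names: {dupes}")

    @property
    def herb_universe(self) -> list[str]:
        """Union of member herb lists, in first-appearance order."""
        seen: dict[str, None] = {}
        for f in self.formulas:
            for h in f.herbs:
                seen.setdefault(h)
        return list(seen)

    @property
    def principal_universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.formulas:
            for h in f.principal:
                seen.setdefault(h)
        return list(seen)

    def __len__(self) -> int:
        return len(self.formulas)

    def __getitem__(self, name: str) -> Formula:
        for f in self.formulas:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass(frozen=True)
class AttributeRecord:
    """Binary Siqi/Wuwei/Guijing attribute flags for one herb."""

    herb_id: str
    flags: tuple[int, ...]  # length 23, schema order

    def __post_init__(self) -> None:
        if len(self.flags) != N_ATTRIBUTES:
            raise ValidationError(
                f"herb {self.herb_id!r}: expected {N_ATTRIBUTES} flags, "
                f"got {len(self.flags)}"
            )
        if any(v not in (0, 1) for v in self.flags):
            raise ValidationError(f"herb {self.herb_id!r}: flags must be 0/1")

    @property
    def siqi(self) -> tuple[int, ...]:
        return self.flags[: len(SIQI)]

    @property
    def wuwei(self) -> tuple[int, ...]:
        return self.flags[len(SIQI) : len(SIQI) + len(WUWEI)]

    @property
    def guijing(self) -> tuple[int, ...]:
        return self.flags[len(SIQI) + len(WUWEI) :]

    def vector(self) -> np.ndarray:
        return np.asarray(self.flags, dtype=float)
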