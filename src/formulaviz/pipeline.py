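"""End-to-end pipeline: tables in, three rendered views out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import color_encoding as ce
from .attribute_space import Embedding, EmbeddingConfig, embed
from .color_encoding import AnchorColor, ColorField2D, Raster
from .formula_io import validate_group
from .render import Highlights, RenderSpec, render_report
from .shared_matrix import GroupStats, SharedHerbMatrix, compute_matrix, compute_stats
from .similarity_layout import IcicleLayout, build_icicle
from .types import AttributeRecord, FormulaGroup, ValidationError


@dataclass
class ViewBundle:
    """All computed artifacts for one formula group."""

    group: FormulaGroup
    embedding: Embedding
    layout: IcicleLayout
    matrix: SharedHerbMatrix
    stats: GroupStats
    field: ColorField2D
    raster: Raster
    herb_colors: dict[str, np.ndarray]

    def report_html(
        self,
        spec: RenderSpec | None = None,
        highlights: Highlights | None = None,
    ) -> str:
        return render_report(
            self.group,
            self.layout,
            self.matrix,
            self.stats,
            self.embedding,
            self.herb_colors,
            self.raster,
            spec,
            highlights,
        )


def build_views(
    group: FormulaGroup,
    attributes: list[AttributeRecord],
    anchors: list[dict] | list[AnchorColor],
    embedding_config: EmbeddingConfig | None = None,
    layout_seed: int = 0,
    kernel: str = "linear",
    raster_resolution: tuple[int, int] = (64, 64),
    compact: bool = False,
) -> ViewBundle:
    """Run the full method on one formula group.

    Validates inputs, embeds the herbs, builds the similarity icicle
    layout, the shared-herb matrix and statistics, fits the anchor color
    field and assigns herb colors.
    """
    report = validate_group(group, attributes)
    if not report.ok:
        raise ValidationError(
            f"inconsistent inputs: missing attributes for "
            f"{report.missing_attributes}, duplicates "
            f"{report.duplicate_herb_records}"
        )
    universe = set(group.herb_universe)
    used = [r for r in attributes if r.herb_id in universe]
    embedding = embed(used, embedding_config)
    layout = build_icicle(group, embedding, seed=layout_seed, compact=compact)
    matrix = compute_matrix(group)
    stats = compute_stats(group)
    anchor_objs = [
        a if isinstance(a, AnchorColor) else AnchorColor.from_dict(a)
        for a in anchors
    ]
    field = ce.fit_field(anchor_objs, embedding, kernel=kernel)
    raster = ce.rasterize(field, resolution=raster_resolution)
    herb_colors = ce.assign_herb_colors(field, embedding)
    return ViewBundle(
        group, embedding, layout, matrix, stats, field, raster, herb_colors
    )
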