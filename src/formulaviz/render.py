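"""Static SVG/HTML rendering of the three linked views.

Emits the formula icicle plot, the shared-herb matrix heat map and the
herb scatter over the continuous colormap as standalone SVG documents, and
a single-page HTML report combining all three with the group statistics
table.  Interactive brushing is replaced by static highlighting: selected
formulas get a blue solid outline, formulas containing the selected herbs
a red dashed outline.

All output is built from plain strings with fixed float formatting and
stable element order, so renders are byte-identical for identical inputs.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps

from .color_encoding import Raster, srgb_to_hex
from .attribute_space import Embedding
from .shared_matrix import GroupStats, SharedHerbMatrix
from .similarity_layout import IcicleLayout
from .types import FormulaGroup


@dataclass
class RenderSpec:
    """Geometry and styling for the static views."""

    cell_w: int = 96
    cell_h: int = 20
    font_family: str = "Helvetica, Arial, sans-serif"
    font_size: int = 10
    principal_fill: str = "#1F4E9C"  # blue, bold, glow
    formula_name_offset: int = 14  # fixed vertical spacing under the column
    matrix_cmap: str = "YlGnBu"
    matrix_cell: int = 44
    scatter_size: int = 420
    dot_radius: float = 4.0
    highlight_formula_stroke: str = "#1F4E9C"  # blue solid
    highlight_herb_stroke: str = "#C0392B"  # red dashed


@dataclass
class Highlights:
    """Static stand-in for the interactive selections.

    ``formulas`` are outlined blue solid; formulas containing the selected
    ``herbs`` are outlined red dashed.  By default a formula must contain
    *all* selected herbs to match; ``any_mode`` switches to union
    semantics.
    """

    formulas: list[str] = field(default_factory=list)
    herbs: list[str] = field(default_factory=list)
    any_mode: bool = False

    def matched_formulas(self, group: FormulaGroup) -> list[str]:
        if not self.herbs:
            return []
        sel = set(self.herbs)
        out = []
        for f in group.formulas:
            fs = set(f.herbs)
            hit = bool(sel & fs) if self.any_mode else sel <= fs
            if hit:
                out.append(f.name)
        return out

    def validate(self, group: FormulaGroup) -> None:
        names = {f.name for f in group.formulas}
        universe = set(group.herb_universe)
        bad = [x for x in self.formulas if x not in names]
        bad += [h for h in self.herbs if h not in universe]
        if bad:
            raise ValueError(f"highlight names not in group: {bad}")


def _f(v: float) -> str:
    return f"{v:.2f}"


def _esc(s: str) -> str:
    return html.escape(str(s), quote=True)


_GLOW_FILTER = (
    '<filter id="glow" x="-40%" y="-40%" width="180%" height="180%">'
    '<feGaussianBlur stdDeviation="1.6" result="b"/>'
    '<feMerge><feMergeNode in="b"/><feMergeNode in="SourceGraphic"/></feMerge>'
    "</filter>"
)


def _svg(width: float, height: float, body: list[str]) -> str:
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(width)}" '
        f'height="{_f(height)}" viewBox="0 0 {_f(width)} {_f(height)}">\n'
        + "\n".join(body)
        + "\n</svg>\n"
    )


def _text_color(rgb: np.ndarray) -> str:
    # relative luminance decides black vs white labels
    lum = float(0.2126 * rgb[0] + 0.7152 * rgb[1] + 0.0722 * rgb[2])
    return "#000000" if lum > 0.45 else "#FFFFFF"


def render_icicle(
    layout: IcicleLayout,
    herb_colors: dict[str, np.ndarray],
    spec: RenderSpec | None = None,
    highlight_formulas: list[str] | None = None,
    herb_matched_formulas: list[str] | None = None,
) -> str:
    """Icicle plot: one labeled rect per non-PAD cell, columns = formulas."""
    spec = spec or RenderSpec()
    missing = sorted(
        {
            c.herb
            for col in layout.columns
            for c in col.cells
            if c.herb is not None and c.herb not in herb_colors
        }
    )
    if missing:
        raise ValueError(f"missing herb colors: {missing}")

    cw, ch, fs = spec.cell_w, spec.cell_h, spec.font_size
    body = [f"<defs>{_GLOW_FILTER}</defs>"]
    max_row = 0
    for x, col in enumerate(layout.columns):
        col_rows = [c.row for c in col.cells if c.herb is not None]
        for cell in col.cells:
            if cell.herb is None:
                continue
            rgb = herb_colors[cell.herb]
            px, py = x * cw, cell.row * ch
            body.append(
                f'<rect x="{_f(px)}" y="{_f(py)}" width="{_f(cw - 1)}" '
                f'height="{_f(ch - 1)}" fill="{srgb_to_hex(rgb)}" '
                'stroke="#FFFFFF" stroke-width="0.5"/>'
            )
            if cell.is_principal:
                style = (
                    f'fill="{spec.principal_fill}" font-weight="bold" '
                    'filter="url(#glow)"'
                )
            else:
                style = f'fill="{_text_color(rgb)}"'
            body.append(
                f'<text x="{_f(px + cw / 2)}" y="{_f(py + ch / 2 + fs / 3)}" '
                f'font-family="{spec.font_family}" font-size="{fs}" '
                f'text-anchor="middle" {style}>{_esc(cell.herb)}</text>'
            )
        bottom = (max(col_rows) + 1) * ch if col_rows else layout.principal_rows * ch
        body.append(
            f'<text x="{_f(x * cw + cw / 2)}" '
            f'y="{_f(bottom + spec.formula_name_offset)}" '
            f'font-family="{spec.font_family}" font-size="{fs}" '
            f'font-style="italic" text-anchor="middle" '
            f'fill="#000000">{_esc(col.formula)}</text>'
        )
        max_row = max(max_row, (max(col_rows) + 1) if col_rows else 0)

    def _outline(names: list[str], stroke: str, dashed: bool) -> None:
        dash = ' stroke-dasharray="6,3"' if dashed else ""
        for x, col in enumerate(layout.columns):
            if col.formula not in names:
                continue
            col_rows = [c.row for c in col.cells if c.herb is not None]
            h = (max(col_rows) + 1) * ch if col_rows else ch
            body.append(
                f'<rect class="highlight" x="{_f(x * cw - 0.5)}" y="-0.5" '
                f'width="{_f(cw)}" height="{_f(h + 1)}" fill="none" '
                f'stroke="{stroke}" stroke-width="2"{dash}/>'
            )

    if highlight_formulas:
        _outline(highlight_formulas, spec.highlight_formula_stroke, dashed=False)
    if herb_matched_formulas:
        _outline(herb_matched_formulas, spec.highlight_herb_stroke, dashed=True)

    width = max(len(layout.columns) * cw, cw)
    height = max_row * ch + spec.formula_name_offset + fs + 4
    return _svg(width, height, body)


def render_matrix(M: SharedHerbMatrix, spec: RenderSpec | None = None) -> str:
    """Heat map of pairwise shared-herb counts.

    The sequential colormap is normalized to the off-diagonal maximum;
    diagonal cells (formula sizes) are drawn neutral so the strongest
    *overlap* carries the darkest color.
    """
    spec = spec or RenderSpec()
    n = len(M.formula_names)
    cmap = colormaps[spec.matrix_cmap]
    vmax = max(M.off_diagonal_max(), 1)
    cs, fs = spec.matrix_cell, spec.font_size
    label_w = 110
    body = []
    for i, name in enumerate(M.formula_names):
        body.append(
            f'<text x="{_f(label_w - 6)}" '
            f'y="{_f(label_w + i * cs + cs / 2 + fs / 3)}" text-anchor="end" '
            f'font-family="{spec.font_family}" font-size="{fs}" '
            f'fill="#000000">{_esc(name)}</text>'
        )
        body.append(
            f'<text x="{_f(label_w + i * cs + cs / 2)}" y="{_f(label_w - 6)}" '
            f'font-family="{spec.font_family}" font-size="{fs}" '
            f'text-anchor="start" transform="rotate(-60 '
            f'{_f(label_w + i * cs + cs / 2)} {_f(label_w - 6)})" '
            f'fill="#000000">{_esc(name)}</text>'
        )
    for i in range(n):
        for j in range(n):
            v = int(M.values[i, j])
            if i == j:
                fill, tcol = "#EEEEEE", "#666666"
            else:
                rgba = cmap(v / vmax)
                fill = srgb_to_hex(np.array(rgba[:3]))
                tcol = _text_color(np.array(rgba[:3]))
            x, y = label_w + j * cs, label_w + i * cs
            body.append(
                f'<rect x="{_f(x)}" y="{_f(y)}" width="{_f(cs - 1)}" '
                f'height="{_f(cs - 1)}" fill="{fill}" '
                'stroke="#FFFFFF" stroke-width="0.5"/>'
            )
            body.append(
                f'<text x="{_f(x + cs / 2)}" y="{_f(y + cs / 2 + fs / 3)}" '
                f'font-family="{spec.font_family}" font-size="{fs}" '
                f'text-anchor="middle" fill="{tcol}">{v}</text>'
            )
    side = label_w + n * cs + 4
    return _svg(side, side, body)


def render_scatter(
    embedding: Embedding,
    herb_colors: dict[str, np.ndarray],
    raster: Raster | None = None,
    spec: RenderSpec | None = None,
    labels: bool = True,
) -> str:
    """Herb scatter over the continuous colormap background."""
    spec = spec or RenderSpec()
    size = spec.scatter_size
    if raster is not None:
        (x0, y0), (x1, y1) = raster.extent
    else:
        lo = embedding.coords.min(axis=0)
        hi = embedding.coords.max(axis=0)
        span = np.maximum(hi - lo, 1e-9)
        (x0, y0), (x1, y1) = lo - 0.1 * span, hi + 0.1 * span

    def to_px(xy: np.ndarray) -> tuple[float, float]:
        fx = (xy[0] - x0) / max(x1 - x0, 1e-12)
        fy = (xy[1] - y0) / max(y1 - y0, 1e-12)
        return fx * size, (1.0 - fy) * size  # y up in data, down in SVG

    body = []
    if raster is not None:
        H, W = raster.rgb.shape[:2]
        pw, ph = size / W, size / H
        for i in range(H):
            y = (1.0 - (i + 1) / H) * size
            for j in range(W):
                body.append(
                    f'<rect x="{_f(j * pw)}" y="{_f(y)}" '
                    f'width="{_f(pw + 0.5)}" height="{_f(ph + 0.5)}" '
                    f'fill="{srgb_to_hex(raster.rgb[i, j])}"/>'
                )
    for idx, herb in enumerate(embedding.herb_ids):
        px, py = to_px(embedding.coords[idx])
        fill = srgb_to_hex(herb_colors[herb])
        body.append(
            f'<circle class="herb-dot" cx="{_f(px)}" cy="{_f(py)}" '
            f'r="{_f(spec.dot_radius)}" fill="{fill}" '
            'stroke="#333333" stroke-width="0.8"/>'
        )
        if labels:
            body.append(
                f'<text x="{_f(px + spec.dot_radius + 2)}" y="{_f(py + 3)}" '
                f'font-family="{spec.font_family}" '
                f'font-size="{spec.font_size}" fill="#000000">'
                f"{_esc(herb)}</text>"
            )
    return _svg(size, size, body)


_REPORT_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<title>{title}</title>
<style>
body {{ font-family: {font}; margin: 24px; }}
section {{ margin-bottom: 32px; }}
table.stats {{ border-collapse: collapse; }}
table.stats td, table.stats th {{ border: 1px solid #999; padding: 4px 10px; }}
.views svg {{ max-width: 100%; height: auto; }}
</style>
</head>
<body>
<h1>{title}</h1>
<section><h2>Group statistics</h2>{stats_table}</section>
<section class="views"><h2>Formula view</h2>{icicle}</section>
<section class="views"><h2>Shared-herb matrix</h2>{matrix}</section>
<section class="views"><h2>Herb map</h2>{scatter}</section>
</body>
</html>
"""


def _stats_table(stats: GroupStats) -> str:
    rows = []
    for key, val in stats.__dict__.items():
        shown = "n/a" if val is None else (f"{val:g}" if isinstance(val, float) else val)
        rows.append(f"<tr><th>{_esc(key)}</th><td>{shown}</td></tr>")
    return '<table class="stats">\n' + "\n".join(rows) + "\n</table>"


def render_report(
    group: FormulaGroup,
    layout: IcicleLayout,
    M: SharedHerbMatrix,
    stats: GroupStats,
    embedding: Embedding,
    herb_colors: dict[str, np.ndarray],
    raster: Raster | None = None,
    spec: RenderSpec | None = None,
    highlights: Highlights | None = None,
) -> str:
    """Single static HTML page embedding the three views and statistics."""
    spec = spec or RenderSpec()
    highlight_formulas: list[str] = []
    herb_matched: list[str] = []
    if highlights is not None:
        highlights.validate(group)
        highlight_formulas = list(highlights.formulas)
        herb_matched = highlights.matched_formulas(group)
    icicle = render_icicle(
        layout,
        herb_colors,
        spec,
        highlight_formulas=highlight_formulas,
        herb_matched_formulas=herb_matched,
    )
    matrix = render_matrix(M, spec)
    scatter = render_scatter(embedding, herb_colors, raster, spec)
    return _REPORT_TEMPLATE.format(
        title=_esc(f"Formula group: {group.name}"),
        font=_esc(spec.font_family),
        stats_table=_stats_table(stats),
        icicle=icicle,
        matrix=matrix,
        scatter=scatter,
    )
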