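"""Perceptual, data-driven herb coloring.

Pipeline: a small set of *anchor* herbs receives hand-picked sRGB colors
inspired by the five-element (Wuxing) color tradition — wood/green,
fire/red, earth/yellow, metal/white, water/black.  Anchor colors are
transformed to the perceptually uniform CAM02-UCS space (via CIEXYZ), each
UCS channel is interpolated over the 2D herb embedding with a radial basis
function (linear kernel plus a constant term by default, so the field is
exact at anchors, the two-anchor midpoint is the channel-wise average, and
the field stays bounded beyond the anchor hull), and every herb's color is
read off the field at its embedded point.
Rasterizing the field over the embedding bounding box yields the
continuous 2D colormap; out-of-gamut results are clamped per channel and
the clamp fraction is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator

from ._ciecam02 import (
    DEFAULT_VC,
    ViewingConditions,
    delta_e,
    srgb_to_ucs,
    ucs_to_srgb,
)
from .attribute_space import Embedding

# kernel -> (scipy name, polynomial degree).  The lowest legal polynomial
# degree is used for each kernel: it keeps the interpolant exact at anchors
# and (for the default linear kernel) forces the RBF weights to sum to
# zero, so the field stays bounded away from the anchors instead of
# growing linearly and leaving the sRGB gamut across most of the map.
_KERNELS = {
    "linear": ("linear", 0),
    "gaussian": ("gaussian", -1),
    "cubic": ("cubic", 1),
    "thin-plate": ("thin_plate_spline", 1),
}


def hex_to_srgb(code: str) -> np.ndarray:
    code = code.lstrip("#")
    if len(code) != 6:
        raise ValueError(f"expected #RRGGBB, got {code!r}")
    return np.array([int(code[i : i + 2], 16) / 255.0 for i in (0, 2, 4)])


def srgb_to_hex(rgb: np.ndarray) -> str:
    r, g, b = (int(round(float(v) * 255)) for v in np.clip(rgb, 0, 1))
    return f"#{r:02X}{g:02X}{b:02X}"


@dataclass(frozen=True)
class AnchorColor:
    """A representative herb with its hand-picked color."""

    herb_id: str
    srgb: np.ndarray  # in [0,1]^3
    element: str = ""  # wood / fire / earth / metal / water

    def __post_init__(self) -> None:
        rgb = np.asarray(self.srgb, dtype=float)
        if rgb.shape != (3,) or np.any(rgb < 0) or np.any(rgb > 1):
            raise ValueError(f"anchor {self.herb_id!r}: srgb must be in [0,1]^3")
        object.__setattr__(self, "srgb", rgb)

    @classmethod
    def from_dict(cls, d: dict) -> "AnchorColor":
        return cls(
            herb_id=d["herb"],
            srgb=hex_to_srgb(d["srgb"]),
            element=d.get("element", ""),
        )


@dataclass
class ColorField2D:
    """Per-channel RBF interpolant of anchor colors in CAM02-UCS."""

    anchors: list[AnchorColor]
    anchor_points: np.ndarray  # (k, 2)
    anchor_ucs: np.ndarray  # (k, 3)
    kernel: str
    vc: ViewingConditions = field(default_factory=lambda: DEFAULT_VC)
    _interp: RBFInterpolator | None = None
    _bbox: np.ndarray | None = None  # embedding bounding box

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        """Evaluate the UCS color field at (..., 2) coordinates."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self._interp is None:  # single-anchor degenerate field: constant
            return np.broadcast_to(self.anchor_ucs[0], xy.shape[:-1] + (3,)).copy()
        return self._interp(xy.reshape(-1, 2)).reshape(xy.shape[:-1] + (3,))

    def srgb_at(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return ucs_to_srgb(self(xy), self.vc)

    @property
    def bbox(self) -> np.ndarray:
        """Bounding box of the embedding the field was fitted over."""
        if self._bbox is not None:
            return self._bbox
        return np.array(
            [self.anchor_points.min(axis=0), self.anchor_points.max(axis=0)]
        )


def fit_field(
    anchors: list[AnchorColor],
    embedding: Embedding,
    kernel: str = "linear",
    vc: ViewingConditions = DEFAULT_VC,
) -> ColorField2D:
    """Fit the per-channel UCS color field over the embedding plane.

    The interpolant is exact at each anchor's embedded point, and with the
    linear kernel the value midway between two anchors is their UCS
    average.  A minimal polynomial tail (a constant, for the linear
    kernel) keeps the field bounded far from the anchors; without it the
    interpolant grows linearly and pushes most of the rasterized map out
    of the sRGB gamut.  A single anchor yields a constant field.

    Raises
    ------
    ValueError
        If two anchors share one embedded point but disagree in color
        (singular interpolation system), naming the herbs.
    """
    if not anchors:
        raise ValueError("need at least one anchor color")
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(_KERNELS)}")
    pts = np.vstack([embedding.point(a.herb_id) for a in anchors])
    ucs = srgb_to_ucs(np.vstack([a.srgb for a in anchors]), vc)

    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            if np.allclose(pts[i], pts[j]) and not np.allclose(ucs[i], ucs[j]):
                raise ValueError(
                    "coincident anchor points with different colors: "
                    f"{anchors[i].herb_id!r} and {anchors[j].herb_id!r}"
                )

    bbox = np.array(
        [embedding.coords.min(axis=0), embedding.coords.max(axis=0)]
    ) if len(embedding) else None
    if len(anchors) == 1:
        return ColorField2D(anchors, pts, ucs, kernel, vc, None, bbox)
    scipy_kernel, degree = _KERNELS[kernel]
    interp = RBFInterpolator(
        pts, ucs, kernel=scipy_kernel, degree=degree,
        epsilon=1.0 if kernel == "gaussian" else None,
    )
    return ColorField2D(anchors, pts, ucs, kernel, vc, interp, bbox)


@dataclass
class Raster:
    """Rasterized continuous colormap over the field's bounding box."""

    rgb: np.ndarray  # (H, W, 3)
    clamped: np.ndarray  # (H, W) bool
    extent: np.ndarray  # [[xmin, ymin], [xmax, ymax]]

    @property
    def clamp_fraction(self) -> float:
        return float(self.clamped.mean())

    def cell_at(self, xy: np.ndarray) -> np.ndarray:
        """Color of the raster cell containing a point (nearest cell at edges)."""
        (x0, y0), (x1, y1) = self.extent
        H, W = self.rgb.shape[:2]
        fx = (np.asarray(xy, dtype=float)[..., 0] - x0) / max(x1 - x0, 1e-12)
        fy = (np.asarray(xy, dtype=float)[..., 1] - y0) / max(y1 - y0, 1e-12)
        i = np.clip((fy * H).astype(int), 0, H - 1)
        j = np.clip((fx * W).astype(int), 0, W - 1)
        return self.rgb[i, j]


def rasterize(
    field: ColorField2D,
    resolution: tuple[int, int] = (128, 128),
    bbox: np.ndarray | None = None,
    margin: float = 0.1,
) -> Raster:
    """Evaluate the field on an H×W grid (row 0 at the bottom of the bbox).

    ``margin`` expands the bounding box by that fraction of its span on
    every side so anchors do not sit on the raster border.
    """
    H, W = resolution
    box = np.asarray(bbox, dtype=float) if bbox is not None else field.bbox
    span = np.maximum(box[1] - box[0], 1e-9)
    lo = box[0] - margin * span
    hi = box[1] + margin * span
    xs = lo[0] + (np.arange(W) + 0.5) / W * (hi[0] - lo[0])
    ys = lo[1] + (np.arange(H) + 0.5) / H * (hi[1] - lo[1])
    XX, YY = np.meshgrid(xs, ys)
    rgb, clamped = field.srgb_at(np.stack([XX, YY], axis=-1))
    return Raster(rgb=rgb, clamped=clamped, extent=np.array([lo, hi]))


def assign_herb_colors(
    field: ColorField2D, embedding: Embedding
) -> dict[str, np.ndarray]:
    """Evaluate the color field at every herb's embedded point.

    Pointwise evaluation — no raster needed when only the herbs shown in
    the formulas require colors.
    """
    rgb, _ = field.srgb_at(embedding.coords)
    return {h: rgb[i] for i, h in enumerate(embedding.herb_ids)}


@dataclass
class PaletteReport:
    """Perceptual summary of an anchor palette.

    ``lightness_range`` is max−min of UCS J'; ``max_chroma`` is the largest
    UCS chroma M' = √(a'² + b'²).  A good palette keeps luminance variation
    modest and avoids saturated colors; exceeding the configured bounds
    produces warnings, not errors.
    """

    lightness_range: float
    max_chroma: float
    lightness_bound: float
    chroma_bound: float
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.warnings


def check_palette(
    anchors: list[AnchorColor],
    lightness_bound: float = 45.0,
    chroma_bound: float = 30.0,
    vc: ViewingConditions = DEFAULT_VC,
) -> PaletteReport:
    if len(anchors) < 2:
        raise ValueError("palette check needs at least 2 anchors")
    ucs = srgb_to_ucs(np.vstack([a.srgb for a in anchors]), vc)
    jp = ucs[:, 0]
    chroma = np.hypot(ucs[:, 1], ucs[:, 2])
    lrange = float(jp.max() - jp.min())
    cmax = float(chroma.max())
    warnings = []
    if lrange > lightness_bound:
        warnings.append(
            f"lightness range {lrange:.1f} exceeds bound {lightness_bound:.1f}"
        )
    if cmax > chroma_bound:
        worst = anchors[int(np.argmax(chroma))].herb_id
        warnings.append(
            f"max chroma {cmax:.1f} ({worst}) exceeds bound {chroma_bound:.1f}"
        )
    return PaletteReport(lrange, cmax, lightness_bound, chroma_bound, warnings)


def anchor_assignment_error(
    field: ColorField2D, herb_colors: dict[str, np.ndarray]
) -> float:
    """Largest UCS ΔE between an anchor's color and its herb's assigned color."""
    errs = [
        delta_e(srgb_to_ucs(herb_colors[a.herb_id], field.vc), field.anchor_ucs[i])
        for i, a in enumerate(field.anchors)
        if a.herb_id in herb_colors
    ]
    return float(max(errs)) if errs else 0.0
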