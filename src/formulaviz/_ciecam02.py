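"""sRGB ↔ CIEXYZ ↔ CIECAM02 ↔ CAM02-UCS color transforms.

Implements the CIECAM02 color appearance model (CIE 159:2004) and its
uniform color space CAM02-UCS (Luo, Cui & Li 2006), forward and inverse,
vectorized over trailing-axis-3 arrays.  Euclidean distance in CAM02-UCS
(J', a', b') approximates perceived color difference ΔE.

Default viewing conditions model an sRGB display viewed in an average
surround: D65 white (as implied by the sRGB primaries), 20% background
luminance factor, adapting luminance L_A = 64/(5π) ≈ 4.07 cd/m² (the
sRGB reference ambient of 64 lux).  XYZ is on the 0–100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# sRGB (IEC 61966-2-1) linear-RGB ↔ XYZ, D65
_M_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_M_XYZ2RGB = np.linalg.inv(_M_RGB2XYZ)

#: D65 white point on the 0–100 scale, consistent with the sRGB matrix.
WHITE_D65 = 100.0 * _M_RGB2XYZ @ np.ones(3)

_M_CAT02 = np.array(
    [
        [0.7328, 0.4296, -0.1624],
        [-0.7036, 1.6975, 0.0061],
        [0.0030, 0.0136, 0.9834],
    ]
)
_M_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)
_M_CAT02_INV = np.linalg.inv(_M_CAT02)
_M_HPE_INV = np.linalg.inv(_M_HPE)

# CAM02-UCS coefficients (K_L = 1)
_UCS_C1 = 0.007
_UCS_C2 = 0.0228


@dataclass(frozen=True)
class ViewingConditions:
    """CIECAM02 viewing-condition parameter set (surround "average")."""

    white: np.ndarray = field(default_factory=lambda: WHITE_D65.copy())
    L_A: float = 64.0 / (5.0 * np.pi)
    Y_b: float = 20.0
    F: float = 1.0
    c: float = 0.69
    N_c: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.white, dtype=float)
        object.__setattr__(self, "white", w)
        RGB_w = _M_CAT02 @ w
        D = self.F * (1.0 - (1.0 / 3.6) * np.exp((-self.L_A - 42.0) / 92.0))
        D = float(np.clip(D, 0.0, 1.0))
        D_RGB = D * w[1] / RGB_w + 1.0 - D
        k = 1.0 / (5.0 * self.L_A + 1.0)
        F_L = 0.2 * k**4 * 5.0 * self.L_A + 0.1 * (1.0 - k**4) ** 2 * (
            5.0 * self.L_A
        ) ** (1.0 / 3.0)
        n = self.Y_b / w[1]
        z = 1.48 + np.sqrt(n)
        N_bb = 0.725 * (1.0 / n) ** 0.2
        RGBp_w = _M_HPE @ (_M_CAT02_INV @ (D_RGB * RGB_w))
        RGBa_w = _adapt(RGBp_w, F_L)
        A_w = (2.0 * RGBa_w[0] + RGBa_w[1] + RGBa_w[2] / 20.0 - 0.305) * N_bb
        for name, val in [
            ("D_RGB", D_RGB),
            ("F_L", float(F_L)),
            ("n", float(n)),
            ("z", float(z)),
            ("N_bb", float(N_bb)),
            ("N_cb", float(N_bb)),
            ("A_w", float(A_w)),
        ]:
            object.__setattr__(self, name, val)

    def describe(self) -> dict:
        return {
            "white_XYZ": [round(float(v), 4) for v in self.white],
            "L_A": round(self.L_A, 4),
            "Y_b": self.Y_b,
            "surround": {"F": self.F, "c": self.c, "N_c": self.N_c},
        }


def _adapt(rgb: np.ndarray, F_L: float) -> np.ndarray:
    """Post-adaptation nonlinear response compression (sign-symmetric)."""
    x = np.sign(rgb) * (F_L * np.abs(rgb) / 100.0) ** 0.42
    return 400.0 * x / (np.abs(x) + 27.13) + 0.1


def _adapt_inv(rgba: np.ndarray, F_L: float) -> np.ndarray:
    x = rgba - 0.1
    mag = (100.0 / F_L) * (27.13 * np.abs(x) / (400.0 - np.abs(x))) ** (1.0 / 0.42)
    return np.sign(x) * mag


DEFAULT_VC = ViewingConditions()


def srgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Gamma-decoded sRGB in [0,1] → XYZ on the 0–100 scale (D65)."""
    rgb = np.asarray(rgb, dtype=float)
    if not np.all(np.isfinite(rgb)):
        raise ValueError("non-finite sRGB input")
    lin = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    return 100.0 * lin @ _M_RGB2XYZ.T


def xyz_to_srgb(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """XYZ (0–100) → sRGB in [0,1], per-channel clamped.

    Returns ``(rgb, clamped)`` where ``clamped`` flags colors that fell
    outside the sRGB gamut before clamping.
    """
    xyz = np.asarray(xyz, dtype=float)
    lin = (xyz / 100.0) @ _M_XYZ2RGB.T
    clamped = np.any((lin < -1e-9) | (lin > 1.0 + 1e-9), axis=-1)
    lin = np.clip(lin, 0.0, 1.0)
    rgb = np.where(
        lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1.0 / 2.4) - 0.055
    )
    return rgb, clamped


def xyz_to_cam(xyz: np.ndarray, vc: ViewingConditions = DEFAULT_VC) -> dict:
    """CIECAM02 forward model: XYZ → appearance correlates J, C, h, Q, M, s."""
    xyz = np.asarray(xyz, dtype=float)
    RGB = xyz @ _M_CAT02.T
    RGB_c = vc.D_RGB * RGB
    RGBp = (RGB_c @ _M_CAT02_INV.T) @ _M_HPE.T
    RGBa = _adapt(RGBp, vc.F_L)
    Ra, Ga, Ba = RGBa[..., 0], RGBa[..., 1], RGBa[..., 2]
    a = Ra - 12.0 * Ga / 11.0 + Ba / 11.0
    b = (Ra + Ga - 2.0 * Ba) / 9.0
    h = np.degrees(np.arctan2(b, a)) % 360.0
    e_t = (np.cos(np.radians(h) + 2.0) + 3.8) / 4.0
    A = (2.0 * Ra + Ga + Ba / 20.0 - 0.305) * vc.N_bb
    J = 100.0 * np.clip(A / vc.A_w, 0.0, None) ** (vc.c * vc.z)
    t = (
        (50000.0 / 13.0)
        * vc.N_c
        * vc.N_cb
        * e_t
        * np.hypot(a, b)
        / (Ra + Ga + 21.0 * Ba / 20.0)
    )
    C = t**0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**vc.n) ** 0.73
    M = C * vc.F_L**0.25
    Q = (4.0 / vc.c) * np.sqrt(J / 100.0) * (vc.A_w + 4.0) * vc.F_L**0.25
    with np.errstate(divide="ignore", invalid="ignore"):
        s = 100.0 * np.sqrt(np.where(Q > 0, M / np.where(Q > 0, Q, 1.0), 0.0))
    return {"J": J, "C": C, "h": h, "Q": Q, "M": M, "s": s}


def cam_to_xyz(
    J: np.ndarray,
    M: np.ndarray,
    h: np.ndarray,
    vc: ViewingConditions = DEFAULT_VC,
) -> np.ndarray:
    """CIECAM02 inverse model from lightness J, colorfulness M and hue h."""
    J = np.asarray(J, dtype=float)
    M = np.asarray(M, dtype=float)
    h = np.asarray(h, dtype=float)
    C = M / vc.F_L**0.25
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            J > 0,
            (
                C
                / (
                    np.sqrt(np.where(J > 0, J, 1.0) / 100.0)
                    * (1.64 - 0.29**vc.n) ** 0.73
                )
            )
            ** (1.0 / 0.9),
            0.0,
        )
    e_t = (np.cos(np.radians(h) + 2.0) + 3.8) / 4.0
    A = vc.A_w * (J / 100.0) ** (1.0 / (vc.c * vc.z))
    p2 = A / vc.N_bb + 0.305

    hr = np.radians(h)
    sin_h, cos_h = np.sin(hr), np.cos(hr)
    a = np.zeros_like(p2)
    b = np.zeros_like(p2)
    nz = t > 1e-15
    if np.any(nz):
        p1 = (50000.0 / 13.0) * vc.N_c * vc.N_cb * e_t / np.where(nz, t, 1.0)
        num = p2 * (2.0 + 21.0 / 20.0) * (460.0 / 1403.0)
        sin_dom = np.abs(sin_h) >= np.abs(cos_h)
        # hue quadrant split avoids division blow-ups near 0/90 degrees
        with np.errstate(divide="ignore", invalid="ignore"):
            b_s = num / (
                p1 / np.where(sin_h != 0, sin_h, 1.0)
                + (2.0 + 21.0 / 20.0)
                * (220.0 / 1403.0)
                * (cos_h / np.where(sin_h != 0, sin_h, 1.0))
                - 27.0 / 1403.0
                + (21.0 / 20.0) * (6300.0 / 1403.0)
            )
            a_s = b_s * cos_h / np.where(sin_h != 0, sin_h, 1.0)
            a_c = num / (
                p1 / np.where(cos_h != 0, cos_h, 1.0)
                + (2.0 + 21.0 / 20.0) * (220.0 / 1403.0)
                - (
                    27.0 / 1403.0
                    - (21.0 / 20.0) * (6300.0 / 1403.0)
                )
                * (sin_h / np.where(cos_h != 0, cos_h, 1.0))
            )
            b_c = a_c * sin_h / np.where(cos_h != 0, cos_h, 1.0)
        a = np.where(nz, np.where(sin_dom, a_s, a_c), 0.0)
        b = np.where(nz, np.where(sin_dom, b_s, b_c), 0.0)

    Ra = (460.0 * p2 + 451.0 * a + 288.0 * b) / 1403.0
    Ga = (460.0 * p2 - 891.0 * a - 261.0 * b) / 1403.0
    Ba = (460.0 * p2 - 220.0 * a - 6300.0 * b) / 1403.0
    RGBp = _adapt_inv(np.stack([Ra, Ga, Ba], axis=-1), vc.F_L)
    RGB_c = (RGBp @ _M_HPE_INV.T) @ _M_CAT02.T
    RGB = RGB_c / vc.D_RGB
    return RGB @ _M_CAT02_INV.T


def cam_to_ucs(J: np.ndarray, M: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Appearance correlates → CAM02-UCS (J', a', b')."""
    J = np.asarray(J, dtype=float)
    M = np.asarray(M, dtype=float)
    Jp = (1.0 + 100.0 * _UCS_C1) * J / (1.0 + _UCS_C1 * J)
    Mp = np.log1p(_UCS_C2 * M) / _UCS_C2
    hr = np.radians(np.asarray(h, dtype=float))
    return np.stack([Jp, Mp * np.cos(hr), Mp * np.sin(hr)], axis=-1)


def ucs_to_cam(jab: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    jab = np.asarray(jab, dtype=float)
    Jp, ap, bp = jab[..., 0], jab[..., 1], jab[..., 2]
    J = Jp / (1.0 + 100.0 * _UCS_C1 - _UCS_C1 * Jp)
    Mp = np.hypot(ap, bp)
    M = np.expm1(_UCS_C2 * Mp) / _UCS_C2
    h = np.degrees(np.arctan2(bp, ap)) % 360.0
    return J, M, h


def srgb_to_ucs(rgb: np.ndarray, vc: ViewingConditions = DEFAULT_VC) -> np.ndarray:
    """sRGB in [0,1] → CAM02-UCS (J', a', b') via CIEXYZ and CIECAM02."""
    cam = xyz_to_cam(srgb_to_xyz(rgb), vc)
    return cam_to_ucs(cam["J"], cam["M"], cam["h"])


def ucs_to_srgb(
    jab: np.ndarray, vc: ViewingConditions = DEFAULT_VC
) -> tuple[np.ndarray, np.ndarray]:
    """CAM02-UCS → sRGB with per-channel gamut clamping.

    Returns ``(rgb, clamped)``; clamped colors lay outside the sRGB gamut.
    """
    jab = np.asarray(jab, dtype=float)
    if not np.all(np.isfinite(jab)):
        raise ValueError("non-finite UCS input")
    J, M, h = ucs_to_cam(jab)
    return xyz_to_srgb(cam_to_xyz(J, M, h, vc))


def delta_e(jab1: np.ndarray, jab2: np.ndarray) -> np.ndarray:
    """Perceptual color difference: Euclidean distance in CAM02-UCS."""
    d = np.asarray(jab1, dtype=float) - np.asarray(jab2, dtype=float)
    return np.linalg.norm(d, axis=-1)
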