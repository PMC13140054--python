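"""Elliptical section geometry.

A stem cross-section is modelled as an ellipse with semi-axes ``a >= b``.
Concentric zones (epidermis, periphery, inner) are bands of constant normal
thickness, i.e. regions between the boundary and its inward offset curves.
The inward offset of an ellipse is not an ellipse; the closed forms below use
the convex-offset identities, valid while the offset distance stays below the
minimum radius of curvature ``b**2 / a``.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def ellipse_area(a: float, b: float) -> float:
    """Area of an ellipse with semi-axes a, b."""
    return float(np.pi * a * b)


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter via the complete elliptic integral E(m).

    ``scipy.special.ellipe`` uses the parameter m = e**2 = 1 - (b/a)**2.
    """
    if a < b:
        a, b = b, a
    if a == 0:
        return 0.0
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * special.ellipe(m))


def inward_offset_area(a: float, b: float, t: float) -> float:
    """Area enclosed by the inward offset of an ellipse at distance t.

    For any convex curve with area A and perimeter P the inward offset at
    distance t encloses ``A - P*t + pi*t**2`` while t is below the minimum
    radius of curvature (b**2/a for an ellipse).
    """
    if t < 0:
        raise ValueError("offset distance must be non-negative")
    if t == 0:
        return ellipse_area(a, b)
    r_min = min(a, b) ** 2 / max(a, b)
    if t > r_min:
        raise ValueError(
            f"offset {t} exceeds the minimum radius of curvature {r_min:.3f}; "
            "the offset-area identity no longer holds"
        )
    A = ellipse_area(a, b)
    P = ellipse_perimeter(a, b)
    return float(A - P * t + np.pi * t * t)


def band_areas(a: float, b: float, t_outer: float, t_inner: float) -> tuple[float, float, float]:
    """Areas of the three constant-thickness bands of an elliptical section.

    Returns (outer band area, middle band area, core area) for bands
    [0, t_outer], [t_outer, t_outer + t_inner] measured inward from the
    boundary, and the remaining core.
    """
    A = ellipse_area(a, b)
    A1 = inward_offset_area(a, b, t_outer)
    A2 = inward_offset_area(a, b, t_outer + t_inner)
    return A - A1, A1 - A2, A2


def point_in_ellipse(x, y, cx: float, cy: float, a: float, b: float) -> np.ndarray:
    """Vectorised test for points inside an axis-aligned ellipse."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def distance_to_ellipse(x: float, y: float, cx: float, cy: float,
                        a: float, b: float, n: int = 4096) -> float:
    """Unsigned distance from a point to the ellipse boundary.

    Brute-force minimum over a dense boundary polyline; accuracy is set by
    ``n`` (error O((P/n)**2 / radius of curvature), well below 1e-3*b at the
    default). Intended as an independent geometric oracle, not a hot path.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    bx = cx + a * np.cos(theta)
    by = cy + b * np.sin(theta)
    return float(np.min(np.hypot(bx - x, by - y)))
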