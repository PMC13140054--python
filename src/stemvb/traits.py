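"""Microanatomical trait computation for stem cross-sections.

The trait inventory covers 32 section-level descriptors in four families:

* stem size/shape (``SZ_*``): cross-section area, perimeter, long/short axis
  and their ratio;
* zone geometry (``EZ/PZ/IZ``): areas and thicknesses of the epidermis,
  periphery and inner zones;
* vascular-bundle counts/areas/densities (``VB_*``, ``PZ_VB_*``,
  ``IZ_VB_*``);
* engineering-mechanics descriptors treating each bundle as a point mass of
  its area at its centroid: the moment of area about a neutral bending axis
  (MOA = sum A_i * y_i^2), the polar moment of inertia about the section
  centroid (PMOI = sum A_i * r_i^2) and its decomposition about the long and
  short principal axes (MOIAL, MOIAS), plus per-bundle averages (ave*).

Units: areas mm^2, lengths mm, densities mm^-2, moments mm^4, ratios
dimensionless. Internally everything is carried in micrometres and converted
on output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

#: The 32 trait names, in canonical column order.
TRAIT_NAMES: tuple[str, ...] = (
    "SZ_A", "SZ_P", "SZ_LA", "SZ_SA", "SZ_LWR",
    "EZ_A", "EZ_T", "PZ_A", "PZ_T", "IZ_A", "IZ_T",
    "VB_N", "VB_A", "VB_Aave", "VB_D", "VB_AreaRatio",
    "PZ_VB_N", "PZ_VB_A", "PZ_VB_D", "PZ_VB_AreaRatio",
    "IZ_VB_N", "IZ_VB_A", "IZ_VB_D", "IZ_VB_AreaRatio",
    "MOA", "PMOI", "MOIAL", "MOIAS",
    "aveMOA", "avePMOI", "aveMOIAL", "aveMOIAS",
)

TRAIT_UNITS: dict[str, str] = {
    "SZ_A": "mm2", "SZ_P": "mm", "SZ_LA": "mm", "SZ_SA": "mm", "SZ_LWR": "1",
    "EZ_A": "mm2", "EZ_T": "mm", "PZ_A": "mm2", "PZ_T": "mm",
    "IZ_A": "mm2", "IZ_T": "mm",
    "VB_N": "1", "VB_A": "mm2", "VB_Aave": "mm2", "VB_D": "mm-2",
    "VB_AreaRatio": "1",
    "PZ_VB_N": "1", "PZ_VB_A": "mm2", "PZ_VB_D": "mm-2",
    "PZ_VB_AreaRatio": "1",
    "IZ_VB_N": "1", "IZ_VB_A": "mm2", "IZ_VB_D": "mm-2",
    "IZ_VB_AreaRatio": "1",
    "MOA": "mm4", "PMOI": "mm4", "MOIAL": "mm4", "MOIAS": "mm4",
    "aveMOA": "mm4", "avePMOI": "mm4", "aveMOIAL": "mm4", "aveMOIAS": "mm4",
}

#: zone label codes in a ZoneMask raster
BACKGROUND, EZ, PZ, IZ = 0, 1, 2, 3

NEUTRAL_AXIS_CHOICES = ("image_horizontal", "long_axis", "short_axis")

UM2_PER_MM2 = 1e6
UM_PER_MM = 1e3
UM4_PER_MM4 = 1e12


@dataclass(frozen=True)
class AxisConvention:
    """Neutral-axis choice for the bending moment of area.

    ``image_horizontal`` is the default: the horizontal image axis through
    the section centroid, matching a bending rig that loads the section
    vertically. ``long_axis``/``short_axis`` use the principal axes of the
    stem mask's second central moments instead; with ``long_axis`` the MOA
    coincides with MOIAL.
    """

    neutral_axis: str = "image_horizontal"

    def __post_init__(self) -> None:
        if self.neutral_axis not in NEUTRAL_AXIS_CHOICES:
            raise ValueError(
                f"neutral_axis must be one of {NEUTRAL_AXIS_CHOICES}, "
                f"got {self.neutral_axis!r}"
            )


def _axis_direction(axis: AxisConvention, orientation: float) -> tuple[float, float]:
    """Unit direction (x, y) of the neutral axis.

    ``orientation`` is the angle of the section's long principal axis with
    the image x axis, radians, measured in (x=column, y=row) coordinates.
    """
    if axis.neutral_axis == "image_horizontal":
        return 1.0, 0.0
    if axis.neutral_axis == "long_axis":
        return math.cos(orientation), math.sin(orientation)
    return -math.sin(orientation), math.cos(orientation)


def compute_moa(
    bundles: pd.DataFrame,
    axis: AxisConvention = AxisConvention(),
    centroid_um: tuple[float, float] = (0.0, 0.0),
    orientation: float = 0.0,
) -> float:
    """Moment of area MOA = sum(A_i * y_i^2) in mm^4.

    ``y_i`` is the perpendicular distance (mm) from bundle centroid i to the
    neutral axis, a line through ``centroid_um`` with direction given by the
    axis convention. ``bundles`` needs columns ``centroid_x_um``,
    ``centroid_y_um``, ``area_um2``; only rows with ``accepted`` True are
    used if the column is present.
    """
    b = _accepted(bundles)
    if len(b) == 0:
        logger.warning("MOA of empty bundle table is 0")
        return 0.0
    ux, uy = _axis_direction(axis, orientation)
    dx = b["centroid_x_um"].to_numpy(float) - centroid_um[0]
    dy = b["centroid_y_um"].to_numpy(float) - centroid_um[1]
    # perpendicular distance = |cross(u, d)|
    y = np.abs(ux * dy - uy * dx)
    return float(np.sum(b["area_um2"].to_numpy(float) * y**2) / UM4_PER_MM4)


def compute_pmoi_moia(
    bundles: pd.DataFrame,
    centroid_um: tuple[float, float],
    orientation: float = 0.0,
) -> tuple[float, float, float]:
    """Polar moment PMOI = sum(A_i * r_i^2) and its split (PMOI, MOIAL, MOIAS).

    ``r_i`` is the distance from bundle centroid to the section centroid;
    MOIAL/MOIAS are the point-mass moments about the long/short principal
    axes, so PMOI = MOIAL + MOIAS by the perpendicular-axis identity.
    Returns mm^4.
    """
    b = _accepted(bundles)
    if len(b) == 0:
        logger.warning("PMOI of empty bundle table is 0")
        return 0.0, 0.0, 0.0
    dx = b["centroid_x_um"].to_numpy(float) - centroid_um[0]
    dy = b["centroid_y_um"].to_numpy(float) - centroid_um[1]
    a = b["area_um2"].to_numpy(float)
    c, s = math.cos(orientation), math.sin(orientation)
    # coordinates along the long axis (t) and across it (n)
    t = dx * c + dy * s
    n = -dx * s + dy * c
    moial = float(np.sum(a * n**2) / UM4_PER_MM4)  # about the long axis
    moias = float(np.sum(a * t**2) / UM4_PER_MM4)  # about the short axis
    pmoi = float(np.sum(a * (dx**2 + dy**2)) / UM4_PER_MM4)
    return pmoi, moial, moias


def _accepted(bundles: pd.DataFrame) -> pd.DataFrame:
    if "accepted" in bundles.columns:
        return bundles[bundles["accepted"].astype(bool)]
    return bundles


def _mask_moments(mask: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Centroid (x, y) px, orientation of the long axis, and full axis
    lengths (long, short) in px of a binary mask, from second central
    moments with the filled-ellipse normalisation (axis length =
    4*sqrt(eigenvalue/area))."""
    ys, xs = np.nonzero(mask)
    n = xs.size
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    # + 1/12 per axis: variance of the uniform unit pixel footprint
    mxx = float(np.mean(dx * dx)) + 1.0 / 12.0
    myy = float(np.mean(dy * dy)) + 1.0 / 12.0
    mxy = float(np.mean(dx * dy))
    theta = 0.5 * math.atan2(2.0 * mxy, mxx - myy)
    common = math.hypot(2.0 * mxy, mxx - myy)
    lam1 = (mxx + myy) / 2.0 + common / 2.0
    lam2 = (mxx + myy) / 2.0 - common / 2.0
    long_ax = 4.0 * math.sqrt(max(lam1, 0.0))
    short_ax = 4.0 * math.sqrt(max(lam2, 0.0))
    return (cx, cy), theta, long_ax, short_ax


def _interface_depth(dt: np.ndarray, zone_a: np.ndarray, zone_b: np.ndarray) -> float:
    """Mean stem-depth (px) of the interface between two zone masks.

    Averages the distance-transform values of boundary pixels on both sides
    of the interface, which is unbiased to ~half a pixel.
    """
    structure = ndi.generate_binary_structure(2, 1)
    a_side = zone_a & ndi.binary_dilation(zone_b, structure)
    b_side = zone_b & ndi.binary_dilation(zone_a, structure)
    vals = np.concatenate([dt[a_side], dt[b_side]])
    if vals.size == 0:
        raise ValueError("zones share no interface")
    return float(vals.mean())


def compute_section_traits(
    zone_labels: np.ndarray,
    bundles: pd.DataFrame,
    pixel_size: float,
    axis: AxisConvention = AxisConvention(),
) -> pd.Series:
    """Compute the full 32-trait vector of one section.

    Parameters
    ----------
    zone_labels:
        Raster over {0 background, 1 EZ, 2 PZ, 3 IZ}; the stem region is the
        union of the three zones.
    bundles:
        Bundle table (accepted rows are used) with centroids in µm, areas in
        µm² and a ``zone`` column holding "PZ"/"IZ".
    pixel_size:
        µm per pixel.
    """
    for code, name in ((EZ, "EZ"), (PZ, "PZ"), (IZ, "IZ")):
        if not np.any(zone_labels == code):
            raise ValueError(f"zone {name} is missing from the zone raster")
    stem = zone_labels > 0
    px2 = pixel_size**2

    (cx, cy), theta, long_px, short_px = _mask_moments(stem)
    sz_a = stem.sum() * px2 / UM2_PER_MM2
    from skimage.measure import perimeter_crofton

    sz_p = perimeter_crofton(stem, directions=4) * pixel_size / UM_PER_MM
    sz_la = long_px * pixel_size / UM_PER_MM
    sz_sa = short_px * pixel_size / UM_PER_MM

    ez, pz, iz = zone_labels == EZ, zone_labels == PZ, zone_labels == IZ
    ez_a = ez.sum() * px2 / UM2_PER_MM2
    pz_a = pz.sum() * px2 / UM2_PER_MM2
    iz_a = iz.sum() * px2 / UM2_PER_MM2

    dt = ndi.distance_transform_edt(stem)
    d_ez_pz = _interface_depth(dt, ez, pz)
    d_pz_iz = _interface_depth(dt, pz, iz)
    ez_t = d_ez_pz * pixel_size / UM_PER_MM
    pz_t = (d_pz_iz - d_ez_pz) * pixel_size / UM_PER_MM
    # IZ thickness = inradius of the inner zone
    iz_t = float(ndi.distance_transform_edt(iz).max()) * pixel_size / UM_PER_MM

    b = _accepted(bundles)
    centroid_um = (cx * pixel_size, cy * pixel_size)
    in_pz = b["zone"] == "PZ"
    in_iz = b["zone"] == "IZ"
    vb_n = int(len(b))
    vb_a = float(b["area_um2"].sum()) / UM2_PER_MM2
    pz_vb_n = int(in_pz.sum())
    iz_vb_n = int(in_iz.sum())
    pz_vb_a = float(b.loc[in_pz, "area_um2"].sum()) / UM2_PER_MM2
    iz_vb_a = float(b.loc[in_iz, "area_um2"].sum()) / UM2_PER_MM2

    moa = compute_moa(b, axis, centroid_um, theta)
    pmoi, moial, moias = compute_pmoi_moia(b, centroid_um, theta)

    def ave(x: float) -> float:
        return x / vb_n if vb_n > 0 else float("nan")

    values = {
        "SZ_A": sz_a, "SZ_P": sz_p, "SZ_LA": sz_la, "SZ_SA": sz_sa,
        "SZ_LWR": sz_la / sz_sa,
        "EZ_A": ez_a, "EZ_T": ez_t, "PZ_A": pz_a, "PZ_T": pz_t,
        "IZ_A": iz_a, "IZ_T": iz_t,
        "VB_N": vb_n, "VB_A": vb_a, "VB_Aave": ave(vb_a),
        "VB_D": vb_n / sz_a, "VB_AreaRatio": vb_a / sz_a,
        "PZ_VB_N": pz_vb_n, "PZ_VB_A": pz_vb_a,
        "PZ_VB_D": pz_vb_n / pz_a, "PZ_VB_AreaRatio": pz_vb_a / pz_a,
        "IZ_VB_N": iz_vb_n, "IZ_VB_A": iz_vb_a,
        "IZ_VB_D": iz_vb_n / iz_a, "IZ_VB_AreaRatio": iz_vb_a / iz_a,
        "MOA": moa, "PMOI": pmoi, "MOIAL": moial, "MOIAS": moias,
        "aveMOA": ave(moa), "avePMOI": ave(pmoi),
        "aveMOIAL": ave(moial), "aveMOIAS": ave(moias),
    }
    tv = pd.Series(values, index=list(TRAIT_NAMES), dtype=float)
    validate_trait_vector(tv)
    return tv


def validate_trait_vector(tv: pd.Series, rel_tol: float = 1e-9) -> None:
    """Assert the internal-consistency invariants of a trait vector.

    Checks additivity of counts/areas across zones, density and ratio
    definitions, the perpendicular-axis identity PMOI = MOIAL + MOIAS, and
    per-bundle average consistency. Raises ValueError on violation.
    """
    def close(x, y, scale=None):
        scale = max(abs(x), abs(y), 1e-30) if scale is None else scale
        return abs(x - y) <= rel_tol * scale

    checks = {
        "VB_N = PZ_VB_N + IZ_VB_N": close(tv.VB_N, tv.PZ_VB_N + tv.IZ_VB_N),
        "VB_A = PZ_VB_A + IZ_VB_A": close(tv.VB_A, tv.PZ_VB_A + tv.IZ_VB_A),
        "SZ_A = EZ_A + PZ_A + IZ_A": close(tv.SZ_A, tv.EZ_A + tv.PZ_A + tv.IZ_A,
                                           scale=tv.SZ_A),
        "VB_D = VB_N / SZ_A": close(tv.VB_D, tv.VB_N / tv.SZ_A),
        "PMOI = MOIAL + MOIAS": close(tv.PMOI, tv.MOIAL + tv.MOIAS,
                                      scale=max(tv.PMOI, 1e-30)),
        "SZ_LWR >= 1": tv.SZ_LWR >= 1.0 - rel_tol,
    }
    for ratio in ("VB_AreaRatio", "PZ_VB_AreaRatio", "IZ_VB_AreaRatio"):
        checks[f"{ratio} in [0, 1]"] = -rel_tol <= tv[ratio] <= 1.0 + rel_tol
    if tv.VB_N > 0:
        checks["VB_Aave * VB_N = VB_A"] = close(tv.VB_Aave * tv.VB_N, tv.VB_A)
        for x in ("MOA", "PMOI", "MOIAL", "MOIAS"):
            checks[f"ave{x} * VB_N = {x}"] = close(tv[f"ave{x}"] * tv.VB_N, tv[x])
    else:
        for x in ("VB_Aave", "aveMOA", "avePMOI", "aveMOIAL", "aveMOIAS"):
            checks[f"{x} missing when VB_N = 0"] = bool(np.isnan(tv[x]))
    for x in ("MOA", "PMOI", "MOIAL", "MOIAS"):
        checks[f"{x} >= 0"] = tv[x] >= 0
    failed = [name for name, ok in checks.items() if not ok]
    if failed:
        raise ValueError("trait vector invariants violated: " + "; ".join(failed))


def aggregate_slices(slice_traits: pd.DataFrame, statistic: str = "median") -> pd.Series:
    """Aggregate per-slice trait vectors to one sample-level vector.

    ``slice_traits`` has one row per slice and the 32 traits as columns.
    The default statistic is the per-trait median (robust to occasional bad
    slices); the output also carries ``<trait>_mean``, ``<trait>_sd`` and
    ``n_slices``.
    """
    if len(slice_traits) == 0:
        raise ValueError("cannot aggregate zero slices")
    cols = [c for c in TRAIT_NAMES if c in slice_traits.columns]
    if len(cols) != len(TRAIT_NAMES):
        missing = set(TRAIT_NAMES) - set(cols)
        raise ValueError(f"slice table is missing traits: {sorted(missing)}")
    data = slice_traits[list(TRAIT_NAMES)]
    if statistic == "median":
        agg = data.median()
    elif statistic == "mean":
        agg = data.mean()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    out = agg.copy()
    for name in TRAIT_NAMES:
        out[f"{name}_mean"] = data[name].mean()
        out[f"{name}_sd"] = data[name].std(ddof=1) if len(data) > 1 else 0.0
    out["n_slices"] = float(len(data))
    return out
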