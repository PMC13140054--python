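"""Synthetic stem cross-section, phenotype and bending-curve generators.

Everything downstream of image acquisition is testable against exact ground
truth produced here. A section is an axis-aligned ellipse (long axis
horizontal) carrying three concentric zones of constant normal thickness —
a thin dense epidermis (EZ), a bundle-rich periphery (PZ) and an inner zone
(IZ) with fewer, larger bundles — rendered at micro-CT-like scale
(15 µm/px, 8-bit) with Gaussian blur and additive Gaussian noise. Vascular
bundles are non-overlapping bright disks placed by rejection sampling.

Phenotype tables follow the standard multi-environment random-effects model
Y_ikm = mu + g_i + tau_k + (g tau)_ik + delta_(k)m + eps_ikm with
independent normal effects, and bending fixtures are smooth
load–displacement curves with a known peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import geometry
from .traits import TRAIT_NAMES, AxisConvention, EZ, PZ, IZ

__all__ = [
    "SectionSpec", "Bundle", "GroundTruth", "CrossSectionImage",
    "PhenoSimSpec", "simulate_cross_section", "truth_zone_labels",
    "bundle_label_raster", "truth_bundle_table", "truth_traits",
    "simulate_phenotypes", "simulate_bending_curve", "make_trait_benchmark",
]


class PlacementError(RuntimeError):
    """Requested bundle layout could not be placed (unplaceable)."""


@dataclass(frozen=True)
class SectionSpec:
    """Geometry, intensity and noise model of one synthetic cross-section.

    Defaults mirror the acquisition scale of basal-internode stem CT:
    15 µm/px, ~1,200 px field of view, semi-axes of 8.4 x 7.4 mm, a thin
    epidermis ring and a 2 mm periphery. Bundle radii are lognormal
    (median µm, log-sigma); ``min_separation`` is clearance between disk
    *edges* (so centroid spacing always exceeds it too).
    """

    image_shape: tuple[int, int] = (1200, 1200)  # (H, W) px
    pixel_size: float = 15.0                     # µm/px
    stem_center: tuple[float, float] = (600.0, 600.0)  # (x, y) px
    semi_axes: tuple[float, float] = (8400.0, 7400.0)  # (a, b) µm, a >= b
    ez_thickness: float = 240.0                  # µm
    pz_thickness: float = 2000.0                 # µm
    n_pz_bundles: int = 140
    n_iz_bundles: int = 60
    pz_radius_dist: tuple[float, float] = (150.0, 0.12)  # (median µm, sigma)
    iz_radius_dist: tuple[float, float] = (260.0, 0.12)
    min_separation: float = 150.0                # µm edge-to-edge clearance
    zone_margin: float = 50.0                    # µm bundle clearance to zone edges
    intensity_levels: tuple[int, int, int, int] = (20, 100, 235, 200)
    #   (background, ground tissue, epidermis, bundle), 8-bit
    noise_sigma: float = 6.0                     # 8-bit units
    blur_sigma: float = 1.0                      # px
    invert_contrast: bool = False
    max_attempts: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > self.ez_thickness + self.pz_thickness > 0):
            raise ValueError(
                "invalid geometry: need a >= b > ez_thickness + pz_thickness > 0"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_pz_bundles < 0 or self.n_iz_bundles < 0:
            raise ValueError("bundle counts must be non-negative")
        if not all(0 <= v <= 255 for v in self.intensity_levels):
            raise ValueError("intensity levels must lie in [0, 255]")

    @property
    def a_px(self) -> float:
        return self.semi_axes[0] / self.pixel_size

    @property
    def b_px(self) -> float:
        return self.semi_axes[1] / self.pixel_size


@dataclass(frozen=True)
class Bundle:
    id: int
    centroid_um: tuple[float, float]  # (x, y) in the image frame
    radius_um: float
    zone: str  # "PZ" or "IZ"

    @property
    def area_um2(self) -> float:
        return math.pi * self.radius_um**2


@dataclass(frozen=True)
class GroundTruth:
    """Exact geometry behind a rendered section.

    Zone boundaries are the inward offsets of the stem ellipse at the EZ and
    EZ+PZ thicknesses (constant normal distance, not shrunken ellipses).
    """

    center_um: tuple[float, float]
    semi_axes_um: tuple[float, float]
    ez_thickness_um: float
    pz_thickness_um: float
    bundles: tuple[Bundle, ...]
    seed: int


@dataclass
class CrossSectionImage:
    pixels: np.ndarray           # 2-D uint8
    pixel_size: float            # µm/px
    sample_id: str = "synthetic"
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.pixels.dtype != np.uint8:
            raise ValueError("cross-section images are 8-bit")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def _stem_mask(spec: SectionSpec) -> np.ndarray:
    h, w = spec.image_shape
    cx, cy = spec.stem_center
    yy, xx = np.mgrid[0:h, 0:w]
    return geometry.point_in_ellipse(xx, yy, cx, cy, spec.a_px, spec.b_px)


def truth_zone_labels(spec: SectionSpec) -> np.ndarray:
    """Ground-truth zone raster {0, EZ, PZ, IZ} for a spec.

    Zones are constant-thickness bands measured by Euclidean depth from the
    (noise-free) stem boundary.
    """
    mask = _stem_mask(spec)
    dt = ndi.distance_transform_edt(mask)
    t_ez = spec.ez_thickness / spec.pixel_size
    t_pz = spec.pz_thickness / spec.pixel_size
    labels = np.zeros(spec.image_shape, dtype=np.uint8)
    labels[mask] = EZ
    labels[mask & (dt > t_ez)] = PZ
    labels[mask & (dt > t_ez + t_pz)] = IZ
    if not np.any(labels == IZ):
        raise ValueError("invalid geometry: zone thicknesses leave no inner zone")
    return labels


def _place_bundles(spec: SectionSpec, rng: np.random.Generator,
                   dt_um: np.ndarray) -> list[Bundle]:
    """Rejection-sample non-overlapping disks inside their zones.

    A candidate is accepted when the whole disk (plus ``zone_margin``) lies
    at a stem depth inside its zone's band and it clears every accepted disk
    by ``min_separation`` edge-to-edge.
    """
    t_ez, t_pz, m = spec.ez_thickness, spec.pz_thickness, spec.zone_margin
    h, w = spec.image_shape
    placed: list[Bundle] = []
    xs = np.empty(0)
    ys = np.empty(0)
    rs = np.empty(0)

    def zone_band(zone: str, r: float) -> tuple[float, float]:
        if zone == "PZ":
            return t_ez + m + r, t_ez + t_pz - m - r
        return t_ez + t_pz + m + r, np.inf

    next_id = 0
    for zone, count, (med, sig) in (
        ("PZ", spec.n_pz_bundles, spec.pz_radius_dist),
        ("IZ", spec.n_iz_bundles, spec.iz_radius_dist),
    ):
        attempts = 0
        n_done = 0
        while n_done < count:
            if attempts >= spec.max_attempts:
                raise PlacementError(
                    f"unplaceable: {n_done}/{count} {zone} bundles after "
                    f"{attempts} attempts"
                )
            attempts += 1
            r = float(med * math.exp(sig * rng.standard_normal()))
            x = rng.uniform(0, w) * spec.pixel_size
            y = rng.uniform(0, h) * spec.pixel_size
            ix = min(int(x / spec.pixel_size), w - 1)
            iy = min(int(y / spec.pixel_size), h - 1)
            lo, hi = zone_band(zone, r)
            if not lo <= dt_um[iy, ix] <= hi:
                continue
            if xs.size:
                d = np.hypot(xs - x, ys - y)
                if np.any(d < rs + r + spec.min_separation):
                    continue
            placed.append(Bundle(next_id, (x, y), r, zone))
            xs = np.append(xs, x)
            ys = np.append(ys, y)
            rs = np.append(rs, r)
            next_id += 1
            n_done += 1
    return placed


def bundle_label_raster(spec: SectionSpec, truth: GroundTruth) -> np.ndarray:
    """Rasterise truth bundles as an integer label image (id+1, 0=background)."""
    h, w = spec.image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    for b in truth.bundles:
        cx, cy = b.centroid_um[0] / spec.pixel_size, b.centroid_um[1] / spec.pixel_size
        r = b.radius_um / spec.pixel_size
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        labels[y0:y1, x0:x1][disk] = b.id + 1
    return labels


def simulate_cross_section(spec: SectionSpec) -> tuple[CrossSectionImage, GroundTruth]:
    """Render one synthetic cross-section and its exact ground truth.

    Deterministic under ``spec.seed``: the same spec yields byte-identical
    pixels and identical truth.
    """
    rng = np.random.default_rng(spec.seed)
    zones = truth_zone_labels(spec)
    mask = zones > 0
    dt_um = ndi.distance_transform_edt(mask) * spec.pixel_size
    bundles = _place_bundles(spec, rng, dt_um)

    bg, tissue, epi, vb = spec.intensity_levels
    img = np.full(spec.image_shape, float(bg))
    img[mask] = tissue
    img[zones == EZ] = epi
    truth = GroundTruth(
        center_um=(spec.stem_center[0] * spec.pixel_size,
                   spec.stem_center[1] * spec.pixel_size),
        semi_axes_um=spec.semi_axes,
        ez_thickness_um=spec.ez_thickness,
        pz_thickness_um=spec.pz_thickness,
        bundles=tuple(bundles),
        seed=spec.seed,
    )
    vb_labels = bundle_label_raster(spec, truth)
    img[vb_labels > 0] = vb

    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if spec.invert_contrast:
        img = 255 - img
    return CrossSectionImage(img, spec.pixel_size), truth


def truth_bundle_table(truth: GroundTruth) -> pd.DataFrame:
    """Truth bundles in the BundleTable schema (all accepted)."""
    rows = [
        {
            "id": b.id,
            "centroid_x_um": b.centroid_um[0],
            "centroid_y_um": b.centroid_um[1],
            "area_um2": b.area_um2,
            "zone": b.zone,
            "eccentricity": 0.0,
            "solidity": 1.0,
            "mean_intensity": float("nan"),
            "accepted": True,
            "reject_reason": "",
        }
        for b in truth.bundles
    ]
    cols = ["id", "centroid_x_um", "centroid_y_um", "area_um2", "zone",
            "eccentricity", "solidity", "mean_intensity", "accepted",
            "reject_reason"]
    return pd.DataFrame(rows, columns=cols)


def truth_traits(truth: GroundTruth, spec: SectionSpec,
                 axis: AxisConvention = AxisConvention()) -> pd.Series:
    """Analytic 32-trait vector from exact geometry (the oracle).

    Zone areas use the convex inward-offset identities; moments use the
    point-mass sums over exact disk areas and centroids. Units follow the
    trait registry (mm, mm², mm⁴).
    """
    a, b = truth.semi_axes_um
    t_ez, t_pz = truth.ez_thickness_um, truth.pz_thickness_um
    mm2, mm, mm4 = 1e6, 1e3, 1e12

    sz_a = geometry.ellipse_area(a, b) / mm2
    sz_p = geometry.ellipse_perimeter(a, b) / mm
    ez_a, pz_a, iz_a = (v / mm2 for v in geometry.band_areas(a, b, t_ez, t_pz))

    cx, cy = truth.center_um
    ori = 0.0  # long axis rendered horizontal
    areas = np.array([bd.area_um2 for bd in truth.bundles])
    xs = np.array([bd.centroid_um[0] for bd in truth.bundles])
    ys = np.array([bd.centroid_um[1] for bd in truth.bundles])
    zones = np.array([bd.zone for bd in truth.bundles])

    if axis.neutral_axis in ("image_horizontal", "long_axis"):
        ydist = np.abs(ys - cy)
    else:
        ydist = np.abs(xs - cx)
    moa = float(np.sum(areas * ydist**2)) / mm4
    moial = float(np.sum(areas * (ys - cy) ** 2)) / mm4
    moias = float(np.sum(areas * (xs - cx) ** 2)) / mm4
    pmoi = moial + moias

    vb_n = len(truth.bundles)
    in_pz = zones == "PZ"
    vb_a = float(areas.sum()) / mm2 if vb_n else 0.0
    pz_vb_a = float(areas[in_pz].sum()) / mm2 if vb_n else 0.0
    iz_vb_a = vb_a - pz_vb_a
    pz_vb_n = int(in_pz.sum())
    iz_vb_n = vb_n - pz_vb_n

    def ave(x: float) -> float:
        return x / vb_n if vb_n > 0 else float("nan")

    values = {
        "SZ_A": sz_a, "SZ_P": sz_p,
        "SZ_LA": 2 * a / mm, "SZ_SA": 2 * b / mm, "SZ_LWR": a / b,
        "EZ_A": ez_a, "EZ_T": t_ez / mm, "PZ_A": pz_a, "PZ_T": t_pz / mm,
        "IZ_A": iz_a, "IZ_T": (b - t_ez - t_pz) / mm,
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
    return pd.Series(values, index=list(TRAIT_NAMES), dtype=float)


# ---------------------------------------------------------------------------
# multi-environment phenotype simulation


@dataclass(frozen=True)
class PhenoSimSpec:
    """Balanced line x environment x replicate simulation under the
    random-effects model Y_ikm = mu + g_i + tau_k + (g tau)_ik + delta_(k)m
    + eps_ikm, every effect independent N(0, its variance)."""

    n_lines: int = 200
    n_envs: int = 2
    n_reps: int = 3
    mu: float = 0.0
    Vg: float = 1.0
    V_env: float = 0.0
    V_GL: float = 0.0
    V_rep: float = 0.0
    Ve: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("Vg", "V_env", "V_GL", "V_rep", "Ve"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_lines < 1 or self.n_envs < 1 or self.n_reps < 1:
            raise ValueError("counts must be >= 1")


def simulate_phenotypes(spec: PhenoSimSpec, trait: str = "trait",
                        return_effects: bool = False):
    """Draw one balanced long-format phenotype table.

    Columns: ``line, env, rep, trait, value``. With ``return_effects`` the
    true per-line genotype effects are returned alongside (for recovery
    tests).
    """
    rng = np.random.default_rng(spec.seed)
    nl, ne, nr = spec.n_lines, spec.n_envs, spec.n_reps
    g = rng.normal(0, math.sqrt(spec.Vg), nl)
    tau = rng.normal(0, math.sqrt(spec.V_env), ne)
    gl = rng.normal(0, math.sqrt(spec.V_GL), (nl, ne))
    rep = rng.normal(0, math.sqrt(spec.V_rep), (ne, nr))
    eps = rng.normal(0, math.sqrt(spec.Ve), (nl, ne, nr))
    y = (spec.mu + g[:, None, None] + tau[None, :, None]
         + gl[:, :, None] + rep[None, :, :] + eps)
    idx = pd.MultiIndex.from_product(
        [[f"L{i:04d}" for i in range(nl)],
         [f"E{k}" for k in range(ne)],
         [f"R{m}" for m in range(nr)]],
        names=["line", "env", "rep"],
    )
    table = pd.DataFrame({"trait": trait, "value": y.ravel()}, index=idx).reset_index()
    table = table[["line", "env", "rep", "trait", "value"]]
    if return_effects:
        effects = pd.Series(g, index=[f"L{i:04d}" for i in range(nl)], name="g")
        return table, effects
    return table


# ---------------------------------------------------------------------------
# bending-curve simulation


def simulate_bending_curve(f_max: float, d_peak: float, n_points: int = 200,
                           seed: int = 0, d_end: float | None = None,
                           noise_sigma: float = 0.0):
    """Smooth three-point-bending load–displacement fixture.

    Load rises as a quarter sine to exactly ``f_max`` at ``d_peak``
    (a sample is placed exactly on the peak), then decays exponentially to
    ``d_end`` (default 1.5 × d_peak). Returns ``(table, info)`` where info
    flags whether the 10 mm displacement is bracketed and whether it lies
    past the peak.
    """
    if f_max <= 0 or d_peak <= 0:
        raise ValueError("f_max and d_peak must be positive")
    if d_end is None:
        d_end = 1.5 * d_peak
    rng = np.random.default_rng(seed)
    d = np.unique(np.concatenate([
        np.linspace(0.0, d_end, n_points),
        [d_peak],
        [10.0] if d_end >= 10.0 else [],
    ]))
    rise = f_max * np.sin(0.5 * np.pi * np.minimum(d, d_peak) / d_peak)
    tau = 0.35 * d_peak
    decay = f_max * np.exp(-(np.maximum(d - d_peak, 0.0)) / tau)
    load = np.where(d <= d_peak, rise, decay)
    if noise_sigma > 0:
        noisy = load + rng.normal(0, noise_sigma, size=load.shape)
        noisy[d == d_peak] = f_max  # keep the documented peak exact
        load = np.clip(noisy, 0.0, None)
    table = pd.DataFrame({"displacement_mm": d, "load_N": load})
    info = {
        "reaches_10mm": bool(d_end >= 10.0),
        "post_peak_at_10mm": bool(d_peak < 10.0),
    }
    return table, info


# ---------------------------------------------------------------------------
# planted-signal trait benchmark for the prediction protocol


def make_trait_benchmark(n_samples: int = 400, frac_signal: float = 0.70,
                         informative: tuple[str, ...] = (
                             "VB_A", "PZ_VB_A", "PZ_T", "PZ_A", "MOA"),
                         target: str = "BMMax", seed: int = 0) -> pd.DataFrame:
    """Trait table with a planted linear signal in a known subset.

    All 32 traits are drawn i.i.d. standard normal; the target is a linear
    combination of the ``informative`` traits plus Gaussian noise, scaled so
    the signal explains ``frac_signal`` of the target variance in
    expectation. Used to benchmark feature selection and the regression
    protocol with a known noise floor.
    """
    if not 0.0 < frac_signal < 1.0:
        raise ValueError("frac_signal must be in (0, 1)")
    unknown = set(informative) - set(TRAIT_NAMES)
    if unknown:
        raise ValueError(f"unknown informative traits: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, len(TRAIT_NAMES)))
    df = pd.DataFrame(X, columns=list(TRAIT_NAMES))
    beta = np.ones(len(informative)) / math.sqrt(len(informative))
    signal = df[list(informative)].to_numpy() @ beta  # unit variance
    noise_sd = math.sqrt((1.0 - frac_signal) / frac_signal)
    y = signal + rng.normal(0.0, noise_sd, n_samples)
    df.insert(0, "sample_id", [f"S{i:04d}" for i in range(n_samples)])
    df[target] = y
    return df
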