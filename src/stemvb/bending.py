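"""Three-point-bending moments from load–displacement curves.

For a specimen on two supports a span L apart loaded centrally, the bending
moment at load F is F*L/4. Two summary moments are reported: BMMax at the
maximum load over the whole record, and BM10mm at a crosshead displacement
of 10 mm (linearly interpolated between the bracketing samples). Spans may
be given in centimetres or metres; moments are always N·m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DISPLACEMENT_AT_BM10_MM = 10.0


class DisplacementNotReached(ValueError):
    pass


def normalize_span(span: float, unit: str = "m") -> float:
    """Span in metres from a value in 'm' or 'cm'."""
    if unit == "m":
        out = float(span)
    elif unit == "cm":
        out = float(span) / 100.0
    else:
        raise ValueError(f"span unit must be 'm' or 'cm', got {unit!r}")
    if out <= 0:
        raise ValueError("span must be positive")
    return out


def _check_curve(curve: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if len(curve) == 0:
        raise ValueError("empty load-displacement curve")
    d = curve["displacement_mm"].to_numpy(float)
    f = curve["load_N"].to_numpy(float)
    if np.any(f < 0):
        raise ValueError("negative loads in curve")
    order = np.argsort(d, kind="stable")
    return d[order], f[order]


def load_at_displacement(curve: pd.DataFrame, displacement_mm: float) -> float:
    """Load (N) at a displacement, linear interpolation between samples.

    An exact sample at the displacement is used as-is; a displacement
    outside the recorded range raises DisplacementNotReached.
    """
    d, f = _check_curve(curve)
    if displacement_mm < d[0] or displacement_mm > d[-1]:
        raise DisplacementNotReached(
            f"displacement not reached: curve spans [{d[0]:g}, {d[-1]:g}] mm, "
            f"requested {displacement_mm:g} mm"
        )
    return float(np.interp(displacement_mm, d, f))


def compute_bmmax(curve: pd.DataFrame, span: float, span_unit: str = "m") -> float:
    """BMMax = F_max * L / 4 (N·m), F_max the global maximum load."""
    _, f = _check_curve(curve)
    L = normalize_span(span, span_unit)
    return float(f.max()) * L / 4.0


def compute_bm10(curve: pd.DataFrame, span: float, span_unit: str = "m") -> float:
    """BM10mm = F(10 mm) * L / 4 (N·m)."""
    L = normalize_span(span, span_unit)
    return load_at_displacement(curve, DISPLACEMENT_AT_BM10_MM) * L / 4.0


@dataclass(frozen=True)
class BendingRecord:
    """Summary of one three-point-bending test."""

    sample_id: str
    span_m: float
    f_max_N: float
    f_at_10mm_N: float
    BMMax_Nm: float
    BM10mm_Nm: float


def summarize_curve(curve: pd.DataFrame, span: float, span_unit: str = "m",
                    sample_id: str = "sample") -> BendingRecord:
    """Both bending moments of one curve as a BendingRecord."""
    d, f = _check_curve(curve)
    L = normalize_span(span, span_unit)
    f_max = float(f.max())
    f10 = load_at_displacement(curve, DISPLACEMENT_AT_BM10_MM)
    return BendingRecord(sample_id, L, f_max, f10,
                         f_max * L / 4.0, f10 * L / 4.0)


def records_to_frame(records: list[BendingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "f_max_N": r.f_max_N,
                "f_at_10mm_N": r.f_at_10mm_N,
                "BMMax_Nm": r.BMMax_Nm,
                "BM10mm_Nm": r.BM10mm_Nm,
            }
            for r in records
        ]
    )
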