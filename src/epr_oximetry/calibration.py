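"""Linewidth-to-pO2 conversion via an invertible linear calibration.

The oximetric principle: the corrected peak-to-peak linewidth of an
implanted LiPc deposit grows affinely with the local oxygen partial
pressure, ``dBpp = dB0 + k * pO2``, so pO2 follows by inverting the line.
The package ships a literature-magnitude default curve (clearly marked
non-authoritative) and a bench-calibration fit for measured probe batches.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import statsmodels.api as sm
import yaml

from .errors import CalibrationError, ValidationError
from .pipeline import LineMeasurement

__all__ = [
    "CalibrationCurve",
    "DEFAULT_CALIBRATION",
    "PO2Result",
    "linewidth_to_po2",
    "fit_calibration",
    "read_calibration",
    "write_calibration",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Invertible linear map between corrected linewidth and pO2.

    ``anoxic_linewidth`` (G) is the zero-oxygen intercept,
    ``oxygen_sensitivity`` (G/mmHg) the slope. Optional standard errors
    and residual sd are populated by :func:`fit_calibration`.
    """

    anoxic_linewidth: float
    oxygen_sensitivity: float
    valid_range: tuple[float, float] = (0.0, 100.0)
    source: str = ""
    intercept_se: float | None = None
    slope_se: float | None = None
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if self.oxygen_sensitivity <= 0:
            raise CalibrationError("oxygen_sensitivity must be positive")
        if self.anoxic_linewidth <= 0:
            raise CalibrationError("anoxic_linewidth must be positive")
        lo, hi = self.valid_range
        if not (lo < hi):
            raise CalibrationError("valid_range must be an increasing interval")

    def width_from_po2(self, po2: float | np.ndarray) -> float | np.ndarray:
        return self.anoxic_linewidth + self.oxygen_sensitivity * np.asarray(po2, float)

    def po2_from_width(self, width: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(width, float) - self.anoxic_linewidth) / self.oxygen_sensitivity


DEFAULT_CALIBRATION = CalibrationCurve(
    anoxic_linewidth=0.050,
    oxygen_sensitivity=0.006,
    valid_range=(0.0, 100.0),
    source=(
        "package default of literature magnitude for LiPc; synthetic, "
        "NOT a measured batch calibration"
    ),
)


@dataclass
class PO2Result:
    """A pO2 point estimate with propagated standard error."""

    po2: float              # mmHg
    se: float               # mmHg
    flags: list[str] = dc_field(default_factory=list)


def linewidth_to_po2(line: LineMeasurement, cal: CalibrationCurve) -> PO2Result:
    """Convert a corrected line to pO2, ``(width - dB0) / k``.

    The standard error is the line's width uncertainty divided by the
    calibration slope. Negative point estimates are reported as computed
    and flagged ``below-anoxic``, never clamped.
    """
    if line.linewidth_corrected is None:
        raise ValidationError(
            "line has no corrected width; run correct_linewidth (or "
            "analyze_spectrum with correct=True) first"
        )
    po2 = float(cal.po2_from_width(line.linewidth_corrected))
    se = float(line.width_se / cal.oxygen_sensitivity)
    flags = list(line.flags)
    if po2 < 0:
        flags.append("below-anoxic")
    lo, hi = cal.valid_range
    if not (lo <= po2 <= hi):
        flags.append("outside-calibration-range")
    return PO2Result(po2=po2, se=se, flags=flags)


def fit_calibration(
    widths: np.ndarray, po2_levels: np.ndarray, source: str = "bench fit"
) -> CalibrationCurve:
    """Ordinary least-squares calibration of width against pO2.

    Requires at least three distinct pO2 levels. Returns the fitted
    slope/intercept with their standard errors and the residual sd;
    ``valid_range`` spans the supplied levels.
    """
    widths = np.asarray(widths, float)
    po2_levels = np.asarray(po2_levels, float)
    if widths.shape != po2_levels.shape or widths.ndim != 1:
        raise CalibrationError("widths and po2_levels must be equal-length vectors")
    if np.unique(po2_levels).size < 3:
        raise CalibrationError("need >= 3 distinct pO2 levels to fit a calibration")
    result = sm.OLS(widths, sm.add_constant(po2_levels)).fit()
    intercept, slope = result.params
    resid_sd = float(np.sqrt(result.scale)) if result.df_resid > 0 else 0.0
    return CalibrationCurve(
        anoxic_linewidth=float(intercept),
        oxygen_sensitivity=float(slope),
        valid_range=(float(po2_levels.min()), float(po2_levels.max())),
        source=source,
        intercept_se=float(result.bse[0]),
        slope_se=float(result.bse[1]),
        residual_sd=resid_sd,
    )


# ---------------------------------------------------------------------------
# Calibration files (YAML or JSON)
# ---------------------------------------------------------------------------

_KEYS = {
    "anoxic_linewidth_G": "anoxic_linewidth",
    "oxygen_sensitivity_G_per_mmHg": "oxygen_sensitivity",
    "valid_range_mmHg": "valid_range",
    "source": "source",
}


def write_calibration(cal: CalibrationCurve, path: str | os.PathLike) -> None:
    payload = {
        "anoxic_linewidth_G": cal.anoxic_linewidth,
        "oxygen_sensitivity_G_per_mmHg": cal.oxygen_sensitivity,
        "valid_range_mmHg": list(cal.valid_range),
        "source": cal.source,
    }
    text_path = os.fspath(path)
    with open(path, "w") as fh:
        if text_path.endswith(".json"):
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        else:
            yaml.safe_dump(payload, fh, sort_keys=True)


def read_calibration(path: str | os.PathLike) -> CalibrationCurve:
    with open(path) as fh:
        payload = yaml.safe_load(fh)  # YAML is a JSON superset
    if not isinstance(payload, dict):
        raise CalibrationError(f"calibration file {os.fspath(path)} is not a mapping")
    missing = [k for k in _KEYS if k != "source" and k not in payload]
    if missing:
        raise CalibrationError(f"calibration file missing keys: {missing}")
    return CalibrationCurve(
        anoxic_linewidth=float(payload["anoxic_linewidth_G"]),
        oxygen_sensitivity=float(payload["oxygen_sensitivity_G_per_mmHg"]),
        valid_range=tuple(float(v) for v in payload["valid_range_mmHg"]),
        source=str(payload.get("source", "")),
    )
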