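"""Acquisition metadata and the in-memory spectrum container.

A continuous-wave EPR measurement sweeps the static field across a window
``centre_field ± sweep_width/2`` while the lock-in detects the
field-modulated signal, so the recorded trace approximates the first
derivative of the absorption lineshape.  :class:`AcquisitionSettings`
carries every spectrometer parameter the analysis needs; its defaults are
the L-band oximetry protocol this package emulates (3 G sweep about 384 G,
512 points, 10 s sweep, 20.48 ms time constant, 0.1 G modulation, 36 mW,
20 added sweeps, optional 1 G/cm gradient for probe multiplexing).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Any, Mapping

import numpy as np

from .errors import ValidationError

__all__ = ["AcquisitionSettings", "SpectrumTrace"]


@dataclass(frozen=True)
class AcquisitionSettings:
    """Spectrometer parameters of one field-swept CW-EPR acquisition.

    Units: fields in gauss, times in seconds, power in milliwatt,
    gradient in gauss/cm. ``gradient = 0`` means no gradient coil.
    ``microwave_power`` is metadata only (no saturation model is applied
    unless a probe carries an explicit saturation factor).
    """

    centre_field: float = 384.0
    sweep_width: float = 3.0
    n_points: int = 512
    sweep_time: float = 10.0
    time_constant: float = 0.02048
    modulation_amplitude: float = 0.1
    microwave_power: float = 36.0
    n_averages: int = 20
    gradient: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ValidationError(f"n_points must be >= 8, got {self.n_points}")
        if self.sweep_width <= 0:
            raise ValidationError("sweep_width must be positive")
        if self.sweep_time <= 0:
            raise ValidationError("sweep_time must be positive")
        if self.time_constant < 0:
            raise ValidationError("time_constant must be >= 0")
        if self.modulation_amplitude < 0:
            raise ValidationError("modulation_amplitude must be >= 0")
        if self.n_averages < 1:
            raise ValidationError("n_averages must be >= 1")

    @property
    def field_axis(self) -> np.ndarray:
        """Uniform ascending field axis, ``centre ± sweep_width/2`` [G]."""
        half = 0.5 * self.sweep_width
        return np.linspace(
            self.centre_field - half, self.centre_field + half, self.n_points
        )

    @property
    def grid_spacing(self) -> float:
        """Field step between adjacent samples [G]."""
        return self.sweep_width / (self.n_points - 1)

    @property
    def dwell_time(self) -> float:
        """Time between adjacent samples during the sweep [s]."""
        return self.sweep_time / (self.n_points - 1)

    @property
    def sweep_rate(self) -> float:
        """Field sweep rate [G/s]."""
        return self.sweep_width / self.sweep_time

    def replace(self, **changes: Any) -> "AcquisitionSettings":
        return replace(self, **changes)


@dataclass
class SpectrumTrace:
    """A sampled first-derivative EPR sweep plus acquisition metadata.

    ``provenance`` is a flat string-to-string mapping of free-text labels;
    simulated traces record their truth parameters there.
    """

    field: np.ndarray
    intensity: np.ndarray
    settings: AcquisitionSettings
    provenance: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("field and intensity must be 1-D vectors")
        if self.field.shape != self.intensity.shape:
            raise ValidationError(
                f"field ({self.field.size}) and intensity ({self.intensity.size}) "
                "must have the same length"
            )
        if self.field.size < 8:
            raise ValidationError("a spectrum needs at least 8 points")
        if not np.all(np.diff(self.field) > 0):
            raise ValidationError("field axis must be strictly increasing")

    @property
    def grid_spacing(self) -> float:
        return float(self.field[1] - self.field[0])

    def with_intensity(
        self, intensity: np.ndarray, extra_provenance: Mapping[str, str] | None = None
    ) -> "SpectrumTrace":
        """Copy of the trace with a new intensity vector (same axis/metadata)."""
        prov = dict(self.provenance)
        if extra_provenance:
            prov.update({k: str(v) for k, v in extra_provenance.items()})
        return SpectrumTrace(self.field.copy(), np.asarray(intensity, float),
                             self.settings, prov)
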