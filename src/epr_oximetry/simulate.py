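"""Forward simulation of CW-EPR oximetry spectra and whole mouse cohorts.

Physics implemented here, and nowhere else (the analysis module inverts
exactly this chain):

* a pure Lorentzian absorption line per LiPc deposit, whose peak-to-peak
  first-derivative width grows affinely with oxygen pressure,
  ``dBpp = dB0 + k * pO2``;
* optional spatial averaging over the probe's physical extent along the
  gradient axis (a uniform 1-D segment);
* sinusoidal field modulation with first-harmonic (lock-in) detection,
  computed by numerical projection ("pseudo-modulation"), which reduces to
  the analytic first derivative in the small-modulation limit and produces
  the familiar overmodulation broadening when the modulation amplitude is
  comparable to the linewidth;
* causal single-pole RC distortion from the lock-in time constant during
  the sweep;
* additive white Gaussian noise scaled by 1/sqrt(n_averages), plus a
  polynomial baseline standing in for slow drift.

All randomness flows from explicit seeds; there is no global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .acquisition import AcquisitionSettings, SpectrumTrace
from .errors import OutOfSweepWindowError, ValidationError

__all__ = [
    "ProbeModel",
    "GrowthModel",
    "CohortDesign",
    "lorentzian_absorption",
    "lorentzian_derivative",
    "apply_field_modulation",
    "rc_alpha",
    "rc_smooth",
    "apply_rc_filter",
    "simulate_spectrum",
    "simulate_cohort_table",
    "simulate_cohort",
]

_SQRT3 = np.sqrt(3.0)

# Quadrature resolutions of the forward model. The analysis module inverts
# the same discretisation, so round trips are exact by construction.
N_MODULATION_POINTS = 48
N_FOOTPRINT_POINTS = 7


# ---------------------------------------------------------------------------
# Lineshapes
# ---------------------------------------------------------------------------

def _gamma_from_dbpp(delta_bpp: float) -> float:
    """Lorentzian HWHM from the peak-to-peak derivative width.

    The derivative extrema of a Lorentzian of half-width Gamma sit at
    centre +- Gamma/sqrt(3), hence dBpp = 2*Gamma/sqrt(3).
    """
    return 0.5 * _SQRT3 * float(delta_bpp)


def lorentzian_absorption(
    field: np.ndarray, centre: float, delta_bpp: float, amplitude: float = 1.0
) -> np.ndarray:
    """Peak-normalised Lorentzian absorption, parametrised by ``delta_bpp``."""
    if delta_bpp <= 0:
        raise ValidationError("delta_bpp must be positive")
    gamma = _gamma_from_dbpp(delta_bpp)
    x = np.asarray(field, dtype=float) - centre
    return amplitude * gamma * gamma / (gamma * gamma + x * x)


def lorentzian_derivative(
    field: np.ndarray, centre: float, delta_bpp: float, amplitude: float = 1.0
) -> np.ndarray:
    """Analytic first derivative of a Lorentzian absorption.

    Normalised so the positive extremum (at ``centre - delta_bpp/2``)
    equals ``amplitude``; the minimum, at ``centre + delta_bpp/2``,
    equals ``-amplitude``. Odd about the centre.
    """
    if delta_bpp <= 0:
        raise ValidationError("delta_bpp must be positive")
    gamma = _gamma_from_dbpp(delta_bpp)
    x = np.asarray(field, dtype=float) - centre
    raw = -x * gamma * gamma / (gamma * gamma + x * x) ** 2
    # |raw| peaks at 9 / (16*sqrt(3)*gamma)
    return amplitude * raw * (16.0 * _SQRT3 * gamma / 9.0)


# ---------------------------------------------------------------------------
# Field modulation (first-harmonic lock-in detection)
# ---------------------------------------------------------------------------

def apply_field_modulation(
    absorption_profile: Callable[[np.ndarray], np.ndarray],
    modulation_amplitude: float,
    field: np.ndarray,
    n_harmonic_points: int = N_MODULATION_POINTS,
    derivative_profile: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """First-harmonic detected signal under sinusoidal field modulation.

    At each field point the absorption is sampled along one cycle of the
    modulation excursion (peak-to-peak size ``modulation_amplitude``) and
    projected onto the fundamental by midpoint quadrature.  The result is
    scaled by ``2/modulation_amplitude`` so that it converges to the exact
    first derivative of the absorption as the modulation vanishes; with
    ``modulation_amplitude == 0`` the analytic derivative is returned
    directly (``derivative_profile`` if supplied, else a central
    difference of the absorption).
    """
    if modulation_amplitude < 0:
        raise ValidationError("modulation_amplitude must be >= 0")
    field = np.asarray(field, dtype=float)
    if modulation_amplitude == 0.0:
        if derivative_profile is not None:
            return np.asarray(derivative_profile(field), dtype=float)
        h = max(np.ptp(field) / (field.size * 200.0), 1e-9)
        return (
            np.asarray(absorption_profile(field + h), float)
            - np.asarray(absorption_profile(field - h), float)
        ) / (2.0 * h)
    theta = 2.0 * np.pi * (np.arange(n_harmonic_points) + 0.5) / n_harmonic_points
    excursion = 0.5 * modulation_amplitude * np.sin(theta)
    sampled = np.asarray(
        absorption_profile(field[:, None] + excursion[None, :]), dtype=float
    )
    first_harmonic = (2.0 / n_harmonic_points) * sampled @ np.sin(theta)
    return first_harmonic * (2.0 / modulation_amplitude)


# ---------------------------------------------------------------------------
# RC filtering
# ---------------------------------------------------------------------------

def rc_alpha(tau: float, dwell_time: float) -> float:
    """Per-sample smoothing coefficient ``alpha = exp(-dt/tau)``."""
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    if tau == 0.0:
        return 0.0
    return float(np.exp(-dwell_time / tau))


def rc_smooth(
    intensity: np.ndarray, tau: float, dwell_time: float, mode: str = "causal"
) -> np.ndarray:
    """Single-pole exponential smoothing with unit DC gain.

    ``mode='causal'`` (forward pass only) emulates acquisition-time RC
    distortion and drags peaks in the sweep direction; ``'zero_phase'``
    runs forward then backward, preserving peak symmetry.  ``tau = 0``
    returns the input unchanged.
    """
    y = np.asarray(intensity, dtype=float)
    alpha = rc_alpha(tau, dwell_time)
    if alpha == 0.0:
        return y.copy()
    b, a = [1.0 - alpha], [1.0, -alpha]

    def _forward(x: np.ndarray) -> np.ndarray:
        # zi chosen so a constant input passes unchanged from sample 0
        out, _ = sp_signal.lfilter(b, a, x, zi=np.array([alpha * x[0]]))
        return out

    if mode == "causal":
        return _forward(y)
    if mode == "zero_phase":
        return _forward(_forward(y)[::-1])[::-1]
    raise ValidationError(f"unknown RC filter mode: {mode!r}")


def apply_rc_filter(
    intensity: np.ndarray, settings: AcquisitionSettings, mode: str = "causal"
) -> np.ndarray:
    """RC smoothing at the acquisition time constant of ``settings``."""
    return rc_smooth(intensity, settings.time_constant, settings.dwell_time, mode)


# ---------------------------------------------------------------------------
# Probes and single-spectrum simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeModel:
    """One implanted LiPc deposit.

    ``position`` locates the probe along the gradient axis (cm, relative
    to the gradient isocentre); its resonance is shifted by
    ``gradient * position``.  The default anoxic width and oxygen
    sensitivity are package defaults of literature magnitude for LiPc,
    not a measured batch calibration. ``footprint_length`` is the
    physical extent averaged over (the probes emulated here are about
    1.4 mm long). ``saturation`` applies an optional microwave
    saturation broadening factor ``sqrt(1 + s)`` to the true width.
    """

    position: float = 0.0
    pO2_true: float = 0.0
    anoxic_linewidth: float = 0.050
    oxygen_sensitivity: float = 0.006
    amplitude: float = 1.0
    footprint_length: float = 0.14
    saturation: float = 0.0

    def __post_init__(self) -> None:
        if self.anoxic_linewidth <= 0:
            raise ValidationError("anoxic_linewidth must be positive")
        if self.oxygen_sensitivity <= 0:
            raise ValidationError("oxygen_sensitivity must be positive")
        if self.pO2_true < 0:
            raise ValidationError("pO2_true must be >= 0")
        if self.footprint_length < 0:
            raise ValidationError("footprint_length must be >= 0")
        if self.saturation < 0:
            raise ValidationError("saturation must be >= 0")

    @property
    def delta_bpp(self) -> float:
        """True peak-to-peak linewidth, ``(dB0 + k*pO2) * sqrt(1+s)`` [G]."""
        width = self.anoxic_linewidth + self.oxygen_sensitivity * self.pO2_true
        return width * float(np.sqrt(1.0 + self.saturation))


def footprint_offsets(smear: float, n_points: int = N_FOOTPRINT_POINTS) -> np.ndarray:
    """Midpoint-rule field offsets of a uniform smear of total width ``smear`` [G]."""
    if smear == 0.0:
        return np.zeros(1)
    u = (np.arange(n_points) + 0.5) / n_points - 0.5
    return smear * u


def _probe_profiles(
    probes: Sequence[ProbeModel], settings: AcquisitionSettings
) -> tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]:
    """Summed absorption and analytic-derivative callables for a probe set."""
    axis = settings.field_axis
    lo, hi = axis[0], axis[-1]
    components: list[tuple[float, float, float]] = []  # (centre, dbpp, amp)
    for i, p in enumerate(probes):
        centre = settings.centre_field + settings.gradient * p.position
        if not (lo <= centre <= hi):
            raise OutOfSweepWindowError(
                f"probe {i} resonates at {centre:.3f} G, outside the swept "
                f"window [{lo:.3f}, {hi:.3f}] G"
            )
        smear = abs(settings.gradient) * p.footprint_length
        offsets = footprint_offsets(smear)
        w = p.amplitude / offsets.size
        for off in offsets:
            components.append((centre + off, p.delta_bpp, w))

    def absorption(field: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(field, float))
        for centre, dbpp, amp in components:
            out += lorentzian_absorption(field, centre, dbpp, amp)
        return out

    def derivative(field: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(field, float))
        for centre, dbpp, amp in components:
            gamma = _gamma_from_dbpp(dbpp)
            x = np.asarray(field, float) - centre
            out += -amp * x * gamma * gamma / (gamma * gamma + x * x) ** 2
        return out

    return absorption, derivative


def simulate_spectrum(
    probes: Sequence[ProbeModel],
    settings: AcquisitionSettings,
    noise_sd: float = 0.0,
    baseline: Sequence[float] = (0.0,),
    rng: np.random.Generator | None = None,
) -> SpectrumTrace:
    """Simulate one field-swept first-derivative spectrum.

    The clean signal is the first-harmonic detection of the summed probe
    absorption (with spatial footprint averaging when a gradient is on),
    passed through the causal RC filter at the acquisition time constant.
    White Gaussian noise of sd ``noise_sd / sqrt(n_averages)`` and a
    polynomial baseline (coefficients low-to-high order, argument
    ``field - centre_field``) are added on top.  A zero-probe, zero-noise
    simulation is identically the baseline (the empty-resonator case).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    field = settings.field_axis
    if probes:
        absorption, derivative = _probe_profiles(probes, settings)
        clean = apply_field_modulation(
            absorption,
            settings.modulation_amplitude,
            field,
            derivative_profile=derivative,
        )
        clean = apply_rc_filter(clean, settings, mode="causal")
    else:
        clean = np.zeros_like(field)
    intensity = clean + np.polynomial.polynomial.polyval(
        field - settings.centre_field, np.asarray(baseline, float)
    )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(settings.rng_seed)
        intensity = intensity + rng.normal(
            0.0, noise_sd / np.sqrt(settings.n_averages), field.size
        )
    provenance = {
        "simulated": "true",
        "n_probes": str(len(probes)),
        "noise_sd": repr(float(noise_sd)),
        "baseline": json.dumps([float(c) for c in baseline]),
        "rng_seed": str(settings.rng_seed),
    }
    for i, p in enumerate(probes):
        provenance[f"probe{i}_position_cm"] = repr(p.position)
        provenance[f"probe{i}_pO2_true_mmHg"] = repr(p.pO2_true)
        provenance[f"probe{i}_delta_bpp_G"] = repr(p.delta_bpp)
    return SpectrumTrace(field, intensity, settings, provenance)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthModel:
    """Exponential tumour growth with lognormal measurement noise.

    ``volume(day) = initial_volume * exp(rate * (day - day0)) * exp(eps)``
    with ``eps ~ N(0, volume_noise_sd)``; treated animals grow at
    ``rate * treatment_rate_multiplier``.
    """

    initial_volume: float = 40.0
    growth_rate: float = 0.18
    treatment_rate_multiplier: float = 0.5
    volume_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.initial_volume <= 0:
            raise ValidationError("initial_volume must be positive")
        if self.volume_noise_sd < 0:
            raise ValidationError("volume_noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    """A two-group (control vs treated) xenograft oximetry study design.

    Defaults encode the emulated study: two tumours per animal (one per
    flank) whose probes sit 1 cm apart along the gradient axis, treated
    tumours ~50% better oxygenated than controls (15 vs 10 mmHg), volumes
    recorded every 2-3 days, and spectra at effective SNR ~10.
    """

    n_animals_per_group: int = 6
    tumours_per_animal: int = 2
    control_pO2_mean: float = 10.0
    treated_pO2_mean: float = 15.0
    pO2_between_animal_sd: float = 0.75
    pO2_within_animal_sd: float = 0.75
    growth_model: GrowthModel = dc_field(default_factory=GrowthModel)
    measurement_days: tuple[int, ...] = (7, 9, 12, 14, 16, 19, 21)
    target_snr: float | None = 10.0
    probe_anoxic_linewidth: float = 0.050
    probe_oxygen_sensitivity: float = 0.006
    probe_footprint_length: float = 0.14
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1:
            raise ValidationError("n_animals_per_group must be >= 1")
        if self.tumours_per_animal not in (1, 2):
            raise ValidationError("tumours_per_animal must be 1 or 2")
        for name in (
            "control_pO2_mean",
            "treated_pO2_mean",
            "pO2_between_animal_sd",
            "pO2_within_animal_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.measurement_days:
            raise ValidationError("measurement_days must be non-empty")
        if self.target_snr is not None and self.target_snr <= 0:
            raise ValidationError("target_snr must be positive (or None)")

    @property
    def probe_positions(self) -> tuple[float, ...]:
        """Gradient-axis probe positions [cm]; two tumours sit 1 cm apart."""
        return (0.0,) if self.tumours_per_animal == 1 else (-0.5, 0.5)


COHORT_COLUMNS = [
    "animal_id",
    "tumour_id",
    "group",
    "probe_position_cm",
    "pO2_true_mmHg",
    "day",
    "volume_mm3",
]


def simulate_cohort_table(
    design: CohortDesign, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the per-tumour truth table (no spectra).

    One row per tumour per measurement day; ``pO2_true_mmHg`` is the
    tumour's (day-constant) truth, truncated at zero.
    """
    if rng is None:
        rng = np.random.default_rng(design.rng_seed)
    gm = design.growth_model
    day0 = min(design.measurement_days)
    rows = []
    for group, mean, rate in (
        ("control", design.control_pO2_mean, gm.growth_rate),
        ("treated", design.treated_pO2_mean,
         gm.growth_rate * gm.treatment_rate_multiplier),
    ):
        for a in range(design.n_animals_per_group):
            animal_id = f"{group[0].upper()}{a + 1:02d}"
            animal_effect = rng.normal(0.0, design.pO2_between_animal_sd)
            for t, pos in enumerate(design.probe_positions):
                po2 = max(
                    0.0,
                    mean + animal_effect
                    + rng.normal(0.0, design.pO2_within_animal_sd),
                )
                for day in design.measurement_days:
                    vol = gm.initial_volume * np.exp(
                        rate * (day - day0)
                        + rng.normal(0.0, gm.volume_noise_sd)
                    )
                    rows.append(
                        (animal_id, f"{animal_id}-T{t + 1}", group, pos,
                         po2, int(day), float(vol))
                    )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def simulate_cohort(
    design: CohortDesign, settings: AcquisitionSettings
) -> tuple[pd.DataFrame, list[SpectrumTrace]]:
    """Simulate the truth table and one spectrum per animal.

    Each animal's spectrum contains the probes of all its tumours,
    separated along the field axis by ``gradient * position``.  Noise is
    scaled so the effective (post-averaging) peak SNR equals
    ``design.target_snr``; a random linear baseline of that noise scale
    models slow drift.  Fully reproducible from ``design.rng_seed``.
    """
    rng = np.random.default_rng(design.rng_seed)
    table = simulate_cohort_table(design, rng)
    final_day = max(design.measurement_days)
    truth = (
        table[table["day"] == final_day]
        .drop_duplicates("tumour_id")
        .set_index("tumour_id")
    )
    traces: list[SpectrumTrace] = []
    for animal_id in truth["animal_id"].unique():
        sub = truth[truth["animal_id"] == animal_id].sort_values("probe_position_cm")
        probes = [
            ProbeModel(
                position=float(r.probe_position_cm),
                pO2_true=float(r.pO2_true_mmHg),
                anoxic_linewidth=design.probe_anoxic_linewidth,
                oxygen_sensitivity=design.probe_oxygen_sensitivity,
                footprint_length=design.probe_footprint_length,
            )
            for r in sub.itertuples()
        ]
        clean = simulate_spectrum(probes, settings, noise_sd=0.0)
        if design.target_snr is None:
            trace = clean
        else:
            noise_eff = float(np.max(np.abs(clean.intensity))) / design.target_snr
            baseline = (
                rng.normal(0.0, 0.5 * noise_eff),
                rng.normal(0.0, 0.5 * noise_eff) / settings.sweep_width,
            )
            trace = simulate_spectrum(
                probes,
                settings,
                noise_sd=noise_eff * np.sqrt(settings.n_averages),
                baseline=baseline,
                rng=rng,
            )
        trace.provenance["animal_id"] = str(animal_id)
        trace.provenance["group"] = str(sub["group"].iloc[0])
        trace.provenance["day"] = str(final_day)
        for i, r in enumerate(sub.itertuples()):
            trace.provenance[f"probe{i}_tumour_id"] = str(r.Index)
        traces.append(trace)
    return table, traces
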