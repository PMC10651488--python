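"""Load specifications, allometric force scaling and implant stiffness testing.

Tissue-scale loading of the implant is either a static horizontal force
(magnitude from measured resting tensions, supplied by configuration), a
distributed body force, or a vibration characterised by an acceleration
amplitude in multiples of standard gravity and a frequency.  Vibration is
converted to its quasi-static peak: an acceleration of ``a`` g corresponds
to a body force of ``a * 9.8`` N per kg of vibrating mass (g is fixed at
9.8 m/s^2).  At 1.38 g this gives ~13.5 N/kg, the mechanically stimulating
implant (MSI) operating point (1.38 g, 203 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "STANDARD_GRAVITY",
    "LoadSpec",
    "StressStrainCurve",
    "vibration_body_force",
    "peak_quasistatic_load",
    "static_load_from_resting_tension",
    "allometric_force_scale",
    "youngs_modulus_from_curve",
]

#: m/s^2; deliberately 9.8 (not 9.80665) so that 1.38 g = 13.524 N/kg.
STANDARD_GRAVITY = 9.8

_KINDS = ("static_force", "body_force", "vibration")


@dataclass(frozen=True)
class LoadSpec:
    """Horizontal loading of the implant.

    magnitude is N for ``static_force`` and N/kg for ``body_force``;
    vibration loads carry (amplitude_g, frequency_hz) instead.
    """

    kind: str
    magnitude: float = 0.0
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    amplitude_g: Optional[float] = None
    frequency_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"load kind must be one of {_KINDS}, got {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("load magnitude must be >= 0")
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0:
            raise ValueError("load direction must be a nonzero vector")
        object.__setattr__(self, "direction", tuple(d / n))
        is_vib = self.kind == "vibration"
        has_vib = self.amplitude_g is not None and self.frequency_hz is not None
        if is_vib != has_vib:
            raise ValueError(
                "amplitude_g and frequency_hz must be given iff kind='vibration'"
            )
        if is_vib and (self.amplitude_g < 0 or self.frequency_hz < 0):
            raise ValueError("vibration amplitude and frequency must be >= 0")

    def direction_vector(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


def vibration_body_force(amplitude_g: float) -> float:
    """Body-force magnitude (N/kg) of a vibration of ``amplitude_g`` g."""
    if amplitude_g < 0:
        raise ValueError("amplitude must be >= 0")
    return amplitude_g * STANDARD_GRAVITY


def peak_quasistatic_load(vibration: LoadSpec, loaded_mass: float) -> LoadSpec:
    """Static-equivalent peak of a periodic load: m * a_peak along the load axis."""
    if vibration.kind != "vibration":
        raise ValueError("peak_quasistatic_load requires a vibration LoadSpec")
    if loaded_mass <= 0:
        raise ValueError("loaded mass must be > 0")
    force = loaded_mass * vibration_body_force(vibration.amplitude_g)
    return LoadSpec(kind="static_force", magnitude=force, direction=vibration.direction)


def static_load_from_resting_tension(
    tension: float, direction=(1.0, 0.0, 0.0)
) -> LoadSpec:
    """Static LoadSpec from a resting-tension magnitude (N).

    Species default tensions live in the preset configuration files with
    their provenance; this constructor only validates and normalises.
    """
    if tension < 0:
        raise ValueError("resting tension must be >= 0")
    return LoadSpec(kind="static_force", magnitude=tension, direction=direction)


def allometric_force_scale(
    ref_mass: float, ref_force: float, target_mass: float, exponent: float = 2.0 / 3.0
) -> float:
    """Scale a tissue force across body masses: F_ref * (m/m_ref)**exponent.

    The default exponent 2/3 corresponds to force growing with load-bearing
    cross-sectional area; it is a modelling choice and configurable.
    """
    if ref_mass <= 0 or target_mass <= 0:
        raise ValueError("masses must be > 0")
    return ref_force * (target_mass / ref_mass) ** exponent


@dataclass(frozen=True)
class StressStrainCurve:
    """Compression test samples: strain (dimensionless) vs stress (Pa)."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.strain, dtype=float)
        t = np.asarray(self.stress, dtype=float)
        if s.ndim != 1 or s.shape != t.shape or s.size < 2:
            raise ValueError("strain and stress must be equal-length 1-D, length >= 2")
        if np.any(np.diff(s) <= 0):
            raise ValueError("strain samples must be strictly increasing")
        object.__setattr__(self, "strain", s)
        object.__setattr__(self, "stress", t)


def youngs_modulus_from_curve(
    curve: StressStrainCurve, strain_window: tuple[float, float] = (0.0, 0.10)
) -> float:
    """Young's modulus as the least-squares slope over the low-strain window.

    Mirrors the compression protocol: the linear slope of the stress-strain
    curve between 0 and 0.10 compressive strain.
    """
    lo, hi = strain_window
    mask = (curve.strain >= lo) & (curve.strain <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"need >= 2 samples with strain in [{lo}, {hi}], found {int(mask.sum())}"
        )
    slope = np.polynomial.polynomial.polyfit(
        curve.strain[mask], curve.stress[mask], 1
    )[1]
    return float(slope)
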