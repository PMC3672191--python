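"""Analytic forward model for fluorescence correlation spectroscopy (FCS).

The observation volume is a three-dimensional Gaussian with radial 1/e²
radius ``omega0`` and axial 1/e² radius ``z0``.  For a mixture of up to two
freely diffusing species the normalized fluorescence autocorrelation is

    G(τ) = B + (1/N) · Σ_i f_i · (1 + τ/τ_D,i)^(-1) · (1 + τ/(s²·τ_D,i))^(-1/2)

where ``N`` is the mean number of molecules in the observation volume
(occupancy), ``B`` an additive baseline, ``f_i`` amplitude fractions summing
to one, ``s = z0/omega0`` the structure parameter, and ``τ_D,i`` the
diffusion time of species ``i``.  The diffusion time is linked to the
translational diffusion coefficient ``D`` by

    τ_D = ω0² / (4·D)   (one-photon excitation)
    τ_D = ω0² / (8·D)   (two-photon excitation)

— two-photon excitation squares the illumination profile, which shrinks the
effective detection volume and halves the residence time at fixed beam
radius.  Fractions are amplitude fractions under the equal-brightness
assumption (no brightness correction is applied).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

import numpy as np

from .constants import FL_TO_L, N_AVOGADRO
from .errors import DomainError, ModelError

__all__ = [
    "PhotonMode",
    "BeamGeometry",
    "Species",
    "FcsModel",
    "CorrelationCurve",
    "PhysicalConditions",
    "autocorrelation",
    "diffusion_time",
    "diffusion_from_time",
    "calibrate_beam",
    "effective_volume",
    "occupancy_to_concentration",
]


class PhotonMode(str, Enum):
    """Excitation mode; sets the prefactor k in τ_D = ω0²/(k·D)."""

    ONE_PHOTON = "one-photon"
    TWO_PHOTON = "two-photon"

    @property
    def tau_prefactor(self) -> float:
        return 4.0 if self is PhotonMode.ONE_PHOTON else 8.0


def _as_mode(mode: "PhotonMode | str") -> PhotonMode:
    return PhotonMode(mode)


@dataclass(frozen=True)
class BeamGeometry:
    """Gaussian observation-volume geometry.

    Parameters
    ----------
    omega0_um : radial 1/e² beam radius, µm.
    z0_um : axial 1/e² radius, µm.
    photon_mode : excitation mode ("one-photon" or "two-photon").
    """

    omega0_um: float
    z0_um: float
    photon_mode: PhotonMode = PhotonMode.TWO_PHOTON

    def __post_init__(self) -> None:
        object.__setattr__(self, "photon_mode", _as_mode(self.photon_mode))
        if not self.omega0_um > 0:
            raise DomainError(f"omega0 must be positive, got {self.omega0_um}")
        if not self.z0_um > 0:
            raise DomainError(f"z0 must be positive, got {self.z0_um}")
        if self.structure_parameter < 1.0:
            raise DomainError(
                f"structure parameter s = z0/omega0 = {self.structure_parameter:.3g} "
                "must be >= 1 (axial radius cannot be shorter than radial)"
            )

    @property
    def structure_parameter(self) -> float:
        """s = z0/ω0, the axial elongation of the observation volume."""
        return self.z0_um / self.omega0_um


@dataclass(frozen=True)
class Species:
    """One diffusing species: diffusion coefficient (µm²/s) and amplitude fraction."""

    D_um2_s: float
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.D_um2_s > 0:
            raise DomainError(f"diffusion coefficient must be positive, got {self.D_um2_s}")
        if not 0.0 <= self.fraction <= 1.0:
            raise DomainError(f"fraction must lie in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class FcsModel:
    """Mixture model for the autocorrelation amplitude and decay.

    ``occupancy`` is the mean molecule number N in the observation volume,
    related to molar concentration C by N = C·V_eff·N_A.
    """

    species: Tuple[Species, ...]
    occupancy: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if len(self.species) == 0:
            raise ModelError("model requires at least one species")
        if len(self.species) > 2:
            raise ModelError(f"at most two species supported, got {len(self.species)}")
        if not self.occupancy > 0:
            raise ModelError(f"occupancy must be positive, got {self.occupancy}")
        total = sum(sp.fraction for sp in self.species)
        if abs(total - 1.0) > 1e-12:
            raise ModelError(f"species fractions must sum to 1 (got {total!r})")


def _validated_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class CorrelationCurve:
    """A measured or simulated correlation curve: lag times (s), G values,
    and optional per-point standard deviations."""

    lags_s: np.ndarray
    g: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        lags = _validated_array(self.lags_s, "lags")
        g = _validated_array(self.g, "g")
        if len(lags) != len(g):
            raise DomainError("lags and g must have the same length")
        if np.any(lags <= 0):
            raise DomainError("lag times must be strictly positive")
        if np.any(np.diff(lags) <= 0):
            raise DomainError("lag times must be strictly increasing")
        sigma = self.sigma
        if sigma is not None:
            sigma = _validated_array(sigma, "sigma")
            if len(sigma) != len(g):
                raise DomainError("sigma must have the same length as g")
            if np.any(sigma <= 0):
                raise DomainError("sigma values must be strictly positive")
        for name, arr in (("lags_s", lags), ("g", g), ("sigma", sigma)):
            if arr is not None:
                arr = arr.copy()
                arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.lags_s)

    def fingerprint(self) -> str:
        """Stable identity of the data (used to check two fits share a curve)."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.lags_s.tobytes())
        h.update(self.g.tobytes())
        if self.sigma is not None:
            h.update(self.sigma.tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class PhysicalConditions:
    """Solvent conditions: absolute temperature (K) and viscosity (cP).

    Defaults are water at 25 °C (η = 0.89 cP).
    """

    temperature_K: float = 298.15
    viscosity_cP: float = 0.89

    def __post_init__(self) -> None:
        if not self.temperature_K > 0:
            raise DomainError(f"temperature must be positive, got {self.temperature_K}")
        if not self.viscosity_cP > 0:
            raise DomainError(f"viscosity must be positive, got {self.viscosity_cP}")


def diffusion_time(D_um2_s: float, beam: BeamGeometry) -> float:
    """Diffusion time τ_D (s) of a species with diffusion coefficient D (µm²/s).

    τ_D = ω0²/(4D) for one-photon excitation, ω0²/(8D) for two-photon.
    """
    if not D_um2_s > 0:
        raise DomainError(f"D must be positive, got {D_um2_s}")
    k = beam.photon_mode.tau_prefactor
    return beam.omega0_um**2 / (k * D_um2_s)


def diffusion_from_time(tau_d_s: float, beam: BeamGeometry) -> float:
    """Invert :func:`diffusion_time`: D (µm²/s) from τ_D (s)."""
    if not tau_d_s > 0:
        raise DomainError(f"tau_d must be positive, got {tau_d_s}")
    k = beam.photon_mode.tau_prefactor
    return beam.omega0_um**2 / (k * tau_d_s)


def calibrate_beam(
    tau_d_ref_s: float,
    D_ref_um2_s: float = 300.0,
    photon_mode: "PhotonMode | str" = PhotonMode.TWO_PHOTON,
    structure_parameter: float = 5.0,
) -> BeamGeometry:
    """Calibrate the beam radius from a reference fluorophore.

    A dye of known diffusion coefficient (rhodamine 110, D = 300 µm²/s, is
    the conventional standard) is measured; its fitted diffusion time fixes
    ω0 = sqrt(k·D_ref·τ_D) with k = 4 (one-photon) or 8 (two-photon).
    The axial radius is set through the supplied structure parameter.
    """
    if not tau_d_ref_s > 0:
        raise DomainError(f"reference tau_d must be positive, got {tau_d_ref_s}")
    if not D_ref_um2_s > 0:
        raise DomainError(f"reference D must be positive, got {D_ref_um2_s}")
    mode = _as_mode(photon_mode)
    omega0 = float(np.sqrt(mode.tau_prefactor * D_ref_um2_s * tau_d_ref_s))
    return BeamGeometry(omega0_um=omega0, z0_um=structure_parameter * omega0, photon_mode=mode)


def autocorrelation(model: FcsModel, beam: BeamGeometry, lags_s) -> np.ndarray:
    """Evaluate G(τ) of the 3D-Gaussian diffusion model at the given lags (s)."""
    lags = np.asarray(lags_s, dtype=float)
    if np.any(lags <= 0):
        raise DomainError("lags must be strictly positive")
    s2 = beam.structure_parameter**2
    g = np.zeros_like(lags)
    for sp in model.species:
        tau_d = diffusion_time(sp.D_um2_s, beam)
        x = lags / tau_d
        g += sp.fraction / ((1.0 + x) * np.sqrt(1.0 + x / s2))
    return model.baseline + g / model.occupancy


def effective_volume(beam: BeamGeometry) -> float:
    """Effective observation volume V_eff = π^(3/2)·ω0²·z0 in fL.

    This is a reporting convention: only concentration values depend on it,
    never fitted diffusion coefficients.
    """
    return float(np.pi**1.5 * beam.omega0_um**2 * beam.z0_um)


def occupancy_to_concentration(occupancy: float, v_eff_fL: float) -> float:
    """Molar concentration C = N/(N_A·V_eff) from occupancy and volume (fL)."""
    if not occupancy > 0:
        raise DomainError(f"occupancy must be positive, got {occupancy}")
    if not v_eff_fL > 0:
        raise DomainError(f"effective volume must be positive, got {v_eff_fL}")
    return occupancy / (N_AVOGADRO * v_eff_fL * FL_TO_L)
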