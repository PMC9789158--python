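"""Instrument and photophysics configuration.

The optical model is purely geometric: the objective is treated as an ideal
aplanatic lens (Abbe sine condition), perfectly corrected for the design
coverslip, so the only source of aberration is the refractive-index step at
the coverslip/sample interface.  Wavelengths and coverslip thickness are kept
as metadata because they document the instrument, but they do not enter the
ray-tracing equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import yaml

__all__ = [
    "MicroscopeConfig",
    "PhotophysicsParams",
    "paper_instrument",
    "default_photophysics",
]

#: Förster–Hoffman power-law defaults for the 4-daspi style molecular rotor:
#: bulk lifetime 0.12 ns in water (viscosity 1 mPa.s), surface plateau 1.7 ns,
#: and a common lifetime/quantum-yield intersection at 2e4 mPa.s, Phi = 0.15.
TAU_SURFACE_NS = 1.7
PHI_SURFACE = 0.15
ETA_INTERSECT_MPAS = 2.0e4
TAU_WATER_NS = 0.12


@dataclass(frozen=True)
class MicroscopeConfig:
    """Optical geometry and refractive indices of the confocal microscope.

    Parameters
    ----------
    na : float
        Numerical aperture of the (dry) objective.
    magnification : float
        Lateral magnification objective -> image plane.
    pinhole_diameter : float
        Physical pinhole diameter at the image plane, in µm.
    wavelength_ex, wavelength_em : float
        Excitation / emission wavelengths in nm (metadata; geometric optics
        is achromatic here).
    n_immersion : float
        Refractive index between objective and coverslip (1.0 for dry).
    n_coverslip : float
        Coverslip refractive index; the objective is assumed perfectly
        corrected for this glass.
    coverslip_thickness : float
        Coverslip thickness in µm (metadata under the perfect-correction
        assumption).
    n_sample : float
        Refractive index of the solution above the coverslip.
    design_aberration_free : bool
        If True, refraction at the coverslip/sample interface is suppressed
        (the sample is treated as index-matched to the coverslip); this
        defines the "index-matched" reference behaviour.
    """

    na: float = 0.75
    magnification: float = 20.0
    pinhole_diameter: float = 56.6
    wavelength_ex: float = 470.0
    wavelength_em: float = 600.0
    n_immersion: float = 1.0
    n_coverslip: float = 1.523
    coverslip_thickness: float = 170.0
    n_sample: float = 1.333
    design_aberration_free: bool = False

    def __post_init__(self) -> None:
        if not self.na > 0:
            raise ValueError("numerical aperture must be positive")
        if not self.magnification > 1:
            raise ValueError("magnification must exceed 1")
        if not self.pinhole_diameter > 0:
            raise ValueError("pinhole diameter must be positive (a zero pinhole accepts nothing)")
        for name in ("n_immersion", "n_coverslip", "n_sample"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if self.coverslip_thickness <= 0:
            raise ValueError("coverslip thickness must be positive")
        # All aperture rays must refract into the sample without total
        # internal reflection: sin(theta) in any medium is na/n.
        n_min = self.n_coverslip if self.design_aberration_free else min(self.n_coverslip, self.n_sample)
        if self.na >= n_min:
            raise ValueError(
                f"NA = {self.na} >= {n_min}: marginal aperture rays undergo total "
                "internal reflection at the coverslip/sample interface"
            )

    @property
    def n_sample_effective(self) -> float:
        """Sample index actually used by the ray tracer.

        In index-matched (aberration-free) mode the coverslip/sample step is
        suppressed, which is equivalent to filling the sample half-space with
        coverslip glass.
        """
        return self.n_coverslip if self.design_aberration_free else self.n_sample

    @property
    def pinhole_radius_object(self) -> float:
        """Pinhole radius conjugated back to object space, in µm."""
        return self.pinhole_diameter / (2.0 * self.magnification)

    def replace(self, **changes) -> "MicroscopeConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "MicroscopeConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "MicroscopeConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "microscope" in data:
            data = data["microscope"]
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"microscope": self.to_dict()}, fh, sort_keys=False)


def paper_instrument(**overrides) -> MicroscopeConfig:
    """The 20x/NA 0.75 dry configuration with a 56.6 µm pinhole and #1.5H
    coverslip over an aqueous sample."""
    return MicroscopeConfig().replace(**overrides)


@dataclass(frozen=True)
class PhotophysicsParams:
    """Photophysical constants entering the surface/bulk brightness ratio.

    ``eps_ratio`` is the surface/bulk extinction-coefficient ratio
    (assumed 1: extinction reflects the ground-state conformation).
    Quantum yields and amplitude-averaged lifetimes for the bulk (B) and the
    physisorbed surface species (S).
    """

    phi_b: float
    tau_b: float
    phi_s: float = PHI_SURFACE
    tau_s: float = TAU_SURFACE_NS
    eps_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in ("phi_b", "phi_s", "tau_b", "tau_s", "eps_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.phi_b > 1 or self.phi_s > 1:
            raise ValueError("quantum yields cannot exceed 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhotophysicsParams":
        return cls(**dict(d))


def forster_hoffman_alpha(
    tau_low: float = TAU_WATER_NS,
    tau_high: float = TAU_SURFACE_NS,
    eta_low: float = 1.0,
    eta_high: float = ETA_INTERSECT_MPAS,
) -> float:
    """Power-law exponent connecting the water lifetime to the surface plateau."""
    import math

    return math.log(tau_high / tau_low) / math.log(eta_high / eta_low)


def default_photophysics(eta_mpas: float = 1.0) -> PhotophysicsParams:
    """Viscosity-dependent defaults for a 4-daspi style rotor.

    Bulk lifetime and quantum yield follow a common Förster–Hoffman power law
    anchored at tau(1 mPa.s) = 0.12 ns and at the surface-plateau intersection
    (2e4 mPa.s, Phi = 0.15); the surface species is fixed at
    tau_S = 1.7 ns, Phi_S = 0.15.
    """
    if eta_mpas <= 0:
        raise ValueError("viscosity must be positive")
    alpha = forster_hoffman_alpha()
    tau_b = TAU_WATER_NS * eta_mpas**alpha
    phi_b = PHI_SURFACE * (eta_mpas / ETA_INTERSECT_MPAS) ** alpha
    return PhotophysicsParams(phi_b=min(phi_b, 1.0), tau_b=tau_b)
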