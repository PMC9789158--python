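"""Synthetic experiments with known ground truth.

Generates the three data types the analysis consumes — TCSPC decay
histograms, z-scan intensity/lifetime profiles, and glycerol/water solvent
property curves — from a forward model of the surface + bulk signal, so every
pipeline stage can be exercised and round-tripped without measured data.

Conditions emulate the physical study: 10⁻⁷ M dye in glycerol/water mixtures
spanning 0–99 wt% (viscosity ≈ 1–900 mPa·s), imaged through the ray-traced
depth response; surface densities of order 3×10³ µm⁻² on hydrophobic glass
and zero on hydrophilic glass.  Noise is multiplicative lognormal on z-scan
intensities (shot noise plus slow laser/detection drift) and Poisson on decay
histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import MicroscopeConfig, PhotophysicsParams, default_photophysics
from .lifetime import DecayHistogram, decay_component
from .optics import DepthResponse, trace_depth_response
from .zscan import MOLAR_TO_PER_UM3, ZScanProfile

__all__ = [
    "GroundTruth",
    "simulate_decay",
    "simulate_zscan",
    "solvent_properties",
    "generate_study",
    "StudyBundle",
]

#: refractive indices of the two endpoint solvents (visible, room temperature)
N_WATER = 1.333
N_GLYCEROL = 1.473
#: default solution temperature (°C) for the viscosity correlation
DEFAULT_TEMPERATURE_C = 22.5


@dataclass(frozen=True)
class GroundTruth:
    """Known truth for one synthetic z-scan condition."""

    sigma_true: float  # adsorbed surface density, µm⁻²
    rho: float = 1.0e-7  # bulk concentration, M
    photophysics: PhotophysicsParams = field(default_factory=lambda: default_photophysics(1.0))
    wt_glycerol: float = 0.0
    noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_true < 0:
            raise ValueError("sigma_true must be non-negative")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    @property
    def k_true(self) -> float:
        """Surface/bulk brightness ratio implied by the truth, in µm."""
        p = self.photophysics
        rho_um3 = self.rho * MOLAR_TO_PER_UM3
        return self.sigma_true * p.eps_ratio * p.phi_s / (rho_um3 * p.phi_b)


def solvent_properties(
    wt_glycerol: float, temperature_c: float = DEFAULT_TEMPERATURE_C
) -> tuple[float, float]:
    """Viscosity (mPa·s) and refractive index of a glycerol/water mixture.

    Viscosity follows the Cheng (2008) empirical correlation
    (Ind. Eng. Chem. Res. 47, 3285) evaluated at room temperature by
    default; the refractive index interpolates linearly between water
    (1.333) and glycerol (1.473) in mass fraction.
    """
    if not 0.0 <= wt_glycerol <= 100.0:
        raise ValueError("glycerol mass fraction must be between 0 and 100 wt%")
    cm = wt_glycerol / 100.0
    T = temperature_c
    mu_w = 1.790 * math.exp((-1230.0 - T) * T / (36100.0 + 360.0 * T))
    mu_g = 12100.0 * math.exp((-1233.0 + T) * T / (9900.0 + 70.0 * T))
    a = 0.705 - 0.0017 * T
    b = (4.9 + 0.036 * T) * a**2.5
    alpha = 1.0 - cm + a * b * cm * (1.0 - cm) / (a * cm + b * (1.0 - cm))
    eta = mu_w**alpha * mu_g ** (1.0 - alpha)
    n = N_WATER + (N_GLYCEROL - N_WATER) * cm
    return float(eta), float(n)


def simulate_decay(
    components,
    irf_fwhm: float | None = None,
    n_photons: int = 100_000,
    rep_rate: float = 40.0,
    n_bins: int = 1024,
    seed: int = 0,
) -> DecayHistogram:
    """Poisson-sampled TCSPC histogram for a multi-exponential decay.

    ``components`` is a list of (amplitude, lifetime_ns) pairs; amplitudes
    set the relative pre-exponential weights.  The expected profile includes
    wrap-around from previous pulses and, optionally, convolution with a
    Gaussian IRF of the given FWHM.  Total counts are Poisson around
    ``n_photons``.
    """
    comps = [(float(a), float(tau)) for a, tau in components]
    if not comps or any(a < 0 or tau <= 0 for a, tau in comps) or all(a == 0 for a, _ in comps):
        raise ValueError("components must be (amplitude >= 0, lifetime > 0) pairs, not all zero")
    if n_photons < 1:
        raise ValueError("n_photons must be at least 1")
    period = 1.0e3 / rep_rate
    dt = period / n_bins
    t = (np.arange(n_bins) + 0.5) * dt
    sigma = None
    t0 = 0.0
    if irf_fwhm is not None:
        sigma = irf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        t0 = 5.0 * sigma  # keep the rising edge inside the record
    lam = np.zeros_like(t)
    for a, tau in comps:
        lam += a * decay_component(t, tau, period, t0, sigma)
    lam *= n_photons / lam.sum()
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return DecayHistogram(t=t, counts=counts, rep_rate=rep_rate, irf_fwhm=irf_fwhm)


def simulate_zscan(
    depth_response: DepthResponse,
    truth: GroundTruth,
    i0: float = 1.0e5,
    surface_kind: str = "hydrophobic",
) -> ZScanProfile:
    """Forward-model a z-scan from a traced depth response and known truth.

    The noiseless intensity is
    ``I(z_F) ∝ H(z_F) (1 + K phi(0, z_F)) / (1 + K phi(0, 0))`` — the bulk
    rise modulated by the surface sheet seen through the depth response —
    scaled to ``i0`` counts/s at the interface, with multiplicative lognormal
    noise of coefficient of variation ``noise_cv``.  The per-depth
    amplitude-averaged lifetime mixes the surface and bulk species with
    amplitudes proportional to (intensity / lifetime) of each.
    """
    k = truth.k_true
    p = truth.photophysics
    z_f = depth_response.z_f_grid
    phi0z = depth_response.phi_surface  # phi(0, z_F)
    clean = depth_response.h_pred * (1.0 + k * phi0z) / (1.0 + k * depth_response.phi00)
    rng = np.random.default_rng(truth.seed)
    if truth.noise_cv > 0:
        s = math.sqrt(math.log(1.0 + truth.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * s**2, sigma=s, size=z_f.size)
    else:
        noise = np.ones(z_f.size)
    intensity = i0 * clean * noise
    # two-species lifetime mixture: surface intensity fraction K phi(0,z_F)
    w_s = k * phi0z / p.tau_s
    w_b = 1.0 / p.tau_b
    tau = (k * phi0z + 1.0) / (w_s + w_b)
    return ZScanProfile(
        z_f=z_f.copy(),
        intensity=intensity,
        lifetime=tau,
        surface_kind=surface_kind,
        wt_glycerol=truth.wt_glycerol,
        dye_concentration=truth.rho,
    )


@dataclass
class StudyBundle:
    """A full synthetic study: per-solvent z-scans over both surfaces, decay
    histograms, and the ground truths used to generate them."""

    wt_list: list
    profiles: dict  # (surface_kind, wt) -> ZScanProfile
    decays: dict  # ("bulk"|"surface", wt) -> DecayHistogram
    truths: dict  # wt -> GroundTruth (hydrophobic surface)
    depth_responses: dict  # wt -> DepthResponse
    seed: int


def generate_study(
    config: MicroscopeConfig,
    wt_list,
    sigma_curve,
    seed: int = 0,
    rho: float = 1.0e-7,
    noise_cv: float = 0.01,
    z_f_grid=None,
    n_rays: int = 50_000,
    n_photons_decay: int = 200_000,
) -> StudyBundle:
    """Generate a synthetic adsorption-versus-solvent study.

    For each glycerol mass fraction: solvent viscosity and refractive index
    are computed, the depth response is ray-traced with the solvent's index,
    bulk photophysics follow the Förster–Hoffman defaults at that viscosity
    (constant surface lifetime), and one hydrophobic (sigma from
    ``sigma_curve``) plus one hydrophilic (sigma = 0) profile are simulated,
    along with bulk and near-surface decay histograms.  Deterministic for a
    given seed.
    """
    wt_list = [float(w) for w in wt_list]
    if callable(sigma_curve):
        sigmas = {w: float(sigma_curve(w)) for w in wt_list}
    else:
        sigmas = {float(w): float(s) for w, s in dict(sigma_curve).items()}
        missing = [w for w in wt_list if w not in sigmas]
        if missing:
            raise ValueError(f"sigma_curve lacks values for wt% {missing}")
    if z_f_grid is None:
        z_f_grid = np.concatenate([[0.0, 1.0, 2.0, 3.0], np.arange(4.0, 41.0, 2.0), [5.0, 7.0]])
        z_f_grid = np.unique(z_f_grid)
    root = np.random.SeedSequence(seed)
    profiles: dict = {}
    decays: dict = {}
    truths: dict = {}
    drs: dict = {}
    for i, wt in enumerate(wt_list):
        eta, n_sol = solvent_properties(wt)
        p = default_photophysics(eta)
        cfg = replace(config, n_sample=n_sol)
        sub = np.random.SeedSequence((seed, i)).generate_state(4)
        dr = trace_depth_response(cfg, z_f_grid=z_f_grid, n_rays=n_rays, seed=int(sub[0] % 2**31))
        drs[wt] = dr
        for kind, sigma in (("hydrophobic", sigmas[wt]), ("hydrophilic", 0.0)):
            gt = GroundTruth(
                sigma_true=sigma,
                rho=rho,
                photophysics=p,
                wt_glycerol=wt,
                noise_cv=noise_cv,
                seed=int((sub[1] if kind == "hydrophobic" else sub[2]) % 2**31),
            )
            profiles[(kind, wt)] = simulate_zscan(dr, gt, surface_kind=kind)
            if kind == "hydrophobic":
                truths[wt] = gt
        decays[("bulk", wt)] = simulate_decay(
            [(1.0, p.tau_b)], n_photons=n_photons_decay, seed=int(sub[3] % 2**31)
        )
        k0 = truths[wt].k_true * dr.phi00
        a_s = k0 / p.tau_s
        a_b = 1.0 / p.tau_b
        decays[("surface", wt)] = simulate_decay(
            [(a_s, p.tau_s), (a_b, p.tau_b)],
            n_photons=n_photons_decay,
            seed=int((sub[3] + 1) % 2**31),
        )
    return StudyBundle(
        wt_list=wt_list,
        profiles=profiles,
        decays=decays,
        truths=truths,
        depth_responses=drs,
        seed=seed,
    )
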