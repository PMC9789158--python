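"""Surface + bulk z-scan signal model and surface-density extraction.

A z-scan of a dye solution over glass detects, at each nominal focus depth
z_F, a mixture of light from a physisorbed surface sheet (surface density
sigma) and from the homogeneous bulk (number density rho).  Normalising the
scan to its value at the interface (I_N), dividing by the equivalent
normalised homogeneous reference (H), and comparing to the ray-traced
interface-contribution curve R_th isolates the surface/bulk brightness ratio

    K = sigma * eps_S * Phi_S / (rho * eps_B * Phi_B)     [units of length]

via  U(z_F) = I_N/H = (phi00^-1 + K R_th(z_F)) / (phi00^-1 + K),
with the asymptote U_inf = 1/(1 + phi00 K).  Known photophysics then converts
K to the adsorbed surface density sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PhotophysicsParams
from .optics import DepthResponse

__all__ = [
    "ZScanProfile",
    "SurfaceAdsorptionModel",
    "AdsorptionResults",
    "normalize_profile",
    "compute_U",
    "estimate_K",
    "sigma_from_K",
    "collapse_Rtau",
    "mono_ratio",
    "tube_partition_ratio",
    "coverage_fraction",
    "AVOGADRO",
    "MOLAR_TO_PER_UM3",
]

#: Avogadro constant (exact, SI 2019)
AVOGADRO = 6.02214076e23
#: molecules per µm³ in a 1 M solution: N_A / (1e15 µm³ per litre)
MOLAR_TO_PER_UM3 = AVOGADRO / 1.0e15

DEFAULT_DEPTHS = (5.0, 7.0, 10.0, 20.0, 30.0)


@dataclass
class ZScanProfile:
    """Detected intensity (and optional amplitude-averaged lifetime) versus
    nominal focus depth for one surface/solvent condition.

    Depths in µm (0 at the interface, increasing into the solution, 0 must be
    present), intensity in counts/s, lifetimes in ns.
    """

    z_f: np.ndarray
    intensity: np.ndarray
    lifetime: np.ndarray | None = None
    surface_kind: str = "hydrophobic"
    wt_glycerol: float = 0.0
    dye_concentration: float = 1.0e-7

    def __post_init__(self) -> None:
        self.z_f = np.asarray(self.z_f, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.z_f.ndim != 1 or self.z_f.shape != self.intensity.shape:
            raise ValueError("z_f and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.z_f) <= 0):
            raise ValueError("z_f must be strictly increasing")
        if not np.any(np.isclose(self.z_f, 0.0, atol=1e-9)):
            raise ValueError("profile must include the interface anchor z_f = 0")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.lifetime is not None:
            self.lifetime = np.asarray(self.lifetime, dtype=float)
            if self.lifetime.shape != self.z_f.shape:
                raise ValueError("lifetime must match the z_f grid")
            if np.any(self.lifetime <= 0):
                raise ValueError("lifetimes must be positive")
        if self.surface_kind not in ("hydrophobic", "hydrophilic", "bulk"):
            raise ValueError("surface_kind must be hydrophobic, hydrophilic or bulk")

    @property
    def intensity_series(self) -> pd.Series:
        return pd.Series(self.intensity, index=self.z_f, name="intensity")

    @property
    def lifetime_series(self) -> pd.Series | None:
        if self.lifetime is None:
            return None
        return pd.Series(self.lifetime, index=self.z_f, name="tau_ns")


def _anchor_index(z: np.ndarray) -> int:
    return int(np.flatnonzero(np.isclose(z, 0.0, atol=1e-9))[0])


def normalize_profile(profile: ZScanProfile, mode: str = "sample") -> pd.Series:
    """Normalise a z-scan to its interface value.

    ``mode="homogeneous"`` yields H(z_F) = I_H(z_F)/I_H(0);
    ``mode="sample"`` yields I_N(z_F) = I(z_F)/I(0).  The arithmetic is the
    same; the mode names the physical quantity.
    """
    if mode not in ("homogeneous", "sample"):
        raise ValueError("mode must be 'homogeneous' or 'sample'")
    i0 = profile.intensity[_anchor_index(profile.z_f)]
    if i0 <= 0:
        raise ValueError("anchor intensity at z_F = 0 must be strictly positive")
    name = "H" if mode == "homogeneous" else "I_N"
    return pd.Series(profile.intensity / i0, index=profile.z_f, name=name)


def compute_U(i_n: pd.Series, h: pd.Series, smooth: bool = False) -> pd.Series:
    """U(z_F) = I_N(z_F)/H(z_F), the surface-excess ratio (<= 1 noiselessly).

    Both curves must live on the same z_F grid and be anchored to 1 at 0.
    Noisy values above 1 are flagged with a warning but never clipped.
    ``smooth`` applies a centred moving average of width 3 to both curves
    before dividing (off by default).
    """
    if len(i_n) != len(h) or not np.allclose(i_n.index.values, h.index.values, atol=1e-9):
        raise ValueError("I_N and H must be sampled on the same z_F grid")
    for name, c in (("I_N", i_n), ("H", h)):
        i0 = c.values[_anchor_index(c.index.values)]
        if not np.isclose(i0, 1.0, atol=1e-6):
            raise ValueError(f"{name} must be normalised to 1 at z_F = 0")
    if smooth:
        i_n = i_n.rolling(3, center=True, min_periods=1).mean()
        h = h.rolling(3, center=True, min_periods=1).mean()
    u = pd.Series(i_n.values / h.values, index=i_n.index, name="U")
    n_above = int(np.sum(u.values > 1.0 + 1e-12))
    # the anchor itself is exactly 1; only flag interior points
    if n_above > 1 or (n_above == 1 and u.values[_anchor_index(u.index.values)] <= 1.0 + 1e-12):
        warnings.warn(
            f"{n_above} U value(s) exceed 1 (noise); retained unclipped", stacklevel=2
        )
    return u


def _k_sensitivity(u: np.ndarray, r: np.ndarray) -> np.ndarray:
    """First-order |d ln K / d ln U| for the per-depth estimator."""
    with np.errstate(divide="ignore", invalid="ignore"):
        s = u * (1.0 - r) / ((1.0 - u) * (u - r))
    return np.abs(s)


def per_depth_K(
    u: pd.Series,
    phi00: float,
    depths=DEFAULT_DEPTHS,
    r_th: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-depth brightness-ratio estimates K_i.

    With ``r_th=None`` this is the asymptotic estimator
    K_i = (1 - U_i)/(phi00 U_i), which treats U at the chosen depths as the
    asymptote U_inf.  Supplying the ray-traced interface curve R_th at the
    same depths switches to the exact inversion of the signal model,
    K_i = (1 - U_i)/(phi00 (U_i - R_th_i)), which removes the finite-depth
    bias of the asymptotic form.
    """
    if phi00 <= 0:
        raise ValueError("phi00 must be positive")
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth list")
    zi = []
    for d in depths:
        hits = np.flatnonzero(np.isclose(u.index.values, d, atol=1e-6))
        if hits.size == 0:
            raise ValueError(f"depth {d} µm not present in the U grid")
        zi.append(int(hits[0]))
    uv = u.values[zi]
    if np.any(uv <= 0):
        raise ValueError("U must be positive at the chosen depths")
    if r_th is None:
        rv = np.zeros_like(uv)
    else:
        rv = np.asarray(r_th, dtype=float)
        if rv.shape != uv.shape:
            raise ValueError("r_th must supply one value per chosen depth")
    above = uv > 1.0
    if np.any(above):
        warnings.warn(
            "U > 1 at some depths (noise); the corresponding K_i are set to 0",
            stacklevel=2,
        )
    denom = uv - rv
    with np.errstate(divide="ignore"):
        k_i = np.where(above, 0.0, (1.0 - uv) / (phi00 * denom))
    valid = above | (denom > 0)
    if not np.any(valid):
        raise ValueError("U below R_th at every depth — signal model inconsistent")
    if not np.all(valid):
        warnings.warn(
            "U < R_th at some depths (noise); those depths are excluded", stacklevel=2
        )
    return pd.DataFrame(
        {"U": uv, "r_th": rv, "K_i": k_i, "valid": valid}, index=pd.Index(depths, name="z_f")
    )


def estimate_K(
    u: pd.Series,
    phi00: float,
    depths=DEFAULT_DEPTHS,
    r_th: np.ndarray | None = None,
    weighted: bool = False,
) -> tuple[float, float]:
    """Estimate the surface/bulk brightness ratio K (µm) from a U curve.

    Returns ``(K, sd)`` where sd is the (unweighted) standard deviation of
    the per-depth estimates.  ``weighted=True`` averages the per-depth K_i
    with inverse-variance weights from first-order error propagation
    (multiplicative noise on U), using a median pilot estimate; recommended
    together with ``r_th`` when K is large, where shallow depths carry almost
    no information.
    """
    table = per_depth_K(u, phi00, depths, r_th=r_th)
    k_i = table.loc[table["valid"], "K_i"].values
    uv = table.loc[table["valid"], "U"].values
    rv = table.loc[table["valid"], "r_th"].values
    if k_i.size == 0:
        raise ValueError("no valid depths for K estimation")
    if weighted and k_i.size > 1:
        k_pilot = float(np.median(k_i))
        u_model = (1.0 + phi00 * k_pilot * rv) / (1.0 + phi00 * k_pilot)
        sens = _k_sensitivity(u_model, rv)
        sens = np.where(np.isfinite(sens) & (sens > 0), sens, np.inf)
        w = 1.0 / sens**2
        if not np.any(w > 0):
            w = np.ones_like(k_i)
        k = float(np.sum(w * k_i) / np.sum(w))
    else:
        k = float(np.mean(k_i))
    sd = float(np.std(k_i, ddof=1)) if k_i.size > 1 else 0.0
    return k, sd


def sigma_from_K(
    k: float,
    rho_molar: float,
    p: PhotophysicsParams,
    k_sd: float = 0.0,
) -> tuple[float, float]:
    """Adsorbed surface density sigma (µm⁻²) from the brightness ratio K (µm).

    Inverts K = sigma eps_S Phi_S / (rho eps_B Phi_B) with rho converted from
    molarity to molecules/µm³ (1 M = 6.02214e8 µm⁻³).  The uncertainty on K is
    propagated linearly.
    """
    if k < 0:
        raise ValueError("K must be non-negative")
    if rho_molar <= 0:
        raise ValueError("bulk concentration must be positive")
    if k_sd < 0:
        raise ValueError("k_sd must be non-negative")
    rho = rho_molar * MOLAR_TO_PER_UM3
    factor = rho * p.phi_b / (p.phi_s * p.eps_ratio)
    return k * factor, k_sd * factor


def collapse_Rtau(lifetime_profile: pd.Series, tau_b: float) -> pd.Series:
    """Empirical lifetime collapse R_tau(z_F) = (<tau>(z_F) - tau_B)/(<tau>(0) - tau_B).

    Maps the amplitude-averaged lifetime profile onto [0, 1]: 1 at the
    interface, 0 deep in the bulk.  Raises if the interface lifetime does not
    differ from the bulk (no detectable surface species — the hydrophilic
    case).
    """
    if tau_b <= 0:
        raise ValueError("tau_b must be positive")
    z = lifetime_profile.index.values
    tau0 = lifetime_profile.values[_anchor_index(z)]
    denom = tau0 - tau_b
    scale = max(abs(tau0), abs(tau_b))
    if abs(denom) < 1e-6 * scale:
        raise ValueError(
            "interface lifetime equals the bulk lifetime: no detectable surface species"
        )
    return pd.Series(
        (lifetime_profile.values - tau_b) / denom, index=z, name="R_tau"
    )


def mono_ratio(
    r_tau: pd.Series, k: float, phi00: float, p: PhotophysicsParams
) -> pd.Series:
    """Predicted ratio R_th/R_tau for monoexponential surface and bulk decays.

    R_th/R_tau = phi00^-1 / (phi00^-1 + (tau_B/tau_S) K (1 - R_tau)).
    Equals 1 when K = 0 or at the interface (R_tau = 1); multiplying a
    measured R_tau by this ratio recovers R_th under the two-monoexponential
    assumption.
    """
    if phi00 <= 0:
        raise ValueError("phi00 must be positive")
    if k < 0:
        raise ValueError("K must be non-negative")
    rt = r_tau.values
    ratio = (1.0 / phi00) / (1.0 / phi00 + (p.tau_b / p.tau_s) * k * (1.0 - rt))
    return pd.Series(ratio, index=r_tau.index, name="Rth_over_Rtau")


def tube_partition_ratio(sigma: float, rho_molar: float, radius: float) -> float:
    """Adsorbed-to-bulk molecule ratio 2 sigma/(r rho) in a tube of radius r.

    sigma in µm⁻², rho in molarity, radius in µm.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if rho_molar <= 0 or radius <= 0:
        raise ValueError("concentration and radius must be positive")
    rho = rho_molar * MOLAR_TO_PER_UM3
    return 2.0 * sigma / (radius * rho)


def coverage_fraction(sigma: float, s_mol_nm2: float = 1.0) -> float:
    """Monolayer coverage fraction sigma * s_mol (sigma in µm⁻², s_mol in nm²)."""
    if sigma < 0 or s_mol_nm2 < 0:
        raise ValueError("inputs must be non-negative")
    return sigma * s_mol_nm2 * 1.0e-6


class SurfaceAdsorptionModel:
    """Surface-adsorption model for a measured (or simulated) z-scan.

    Parameters
    ----------
    sample : ZScanProfile
        Scan over the surface of interest (surface + bulk signal).
    reference : ZScanProfile, optional
        Homogeneous reference scan (e.g. over the hydrophilic surface).  If
        omitted, the ray-traced prediction H from ``depth_response`` is used.
    depth_response : DepthResponse, optional
        Ray-traced depth response; supplies phi00, R_th and (if needed) the
        predicted H.
    phi00 : float, optional
        Override for phi(0,0) in µm⁻¹ (otherwise taken from depth_response).
    photophysics : PhotophysicsParams
    rho_molar : float, optional
        Bulk dye concentration (M); defaults to the sample profile metadata.
    depths : sequence of float
        z_F values (µm) at which K is estimated.
    """

    def __init__(
        self,
        sample: ZScanProfile,
        reference: ZScanProfile | None = None,
        depth_response: DepthResponse | None = None,
        phi00: float | None = None,
        photophysics: PhotophysicsParams | None = None,
        rho_molar: float | None = None,
        depths=DEFAULT_DEPTHS,
        smooth: bool = False,
    ) -> None:
        if reference is None and depth_response is None:
            raise ValueError(
                "provide a homogeneous reference scan or a ray-traced depth "
                "response to predict H"
            )
        if phi00 is None:
            if depth_response is None:
                raise ValueError("phi00 must be given when no depth response is supplied")
            phi00 = depth_response.phi00
        if photophysics is None:
            raise ValueError("photophysics parameters are required to convert K to sigma")
        self.sample = sample
        self.reference = reference
        self.depth_response = depth_response
        self.phi00 = float(phi00)
        self.photophysics = photophysics
        self.rho_molar = float(rho_molar if rho_molar is not None else sample.dye_concentration)
        self.depths = tuple(float(d) for d in depths)
        self.smooth = bool(smooth)

    def _reference_curve(self) -> tuple[pd.Series, str]:
        if self.reference is not None:
            return normalize_profile(self.reference, mode="homogeneous"), "measured"
        dr = self.depth_response
        h = np.interp(self.sample.z_f, dr.z_f_grid, dr.h_pred)
        return pd.Series(h, index=self.sample.z_f, name="H"), "ray-traced"

    def fit(self, method: str = "corrected", weighted: bool = True) -> "AdsorptionResults":
        """Estimate K and sigma.

        ``method="corrected"`` inverts the full signal model using the
        ray-traced R_th at each depth (requires ``depth_response``);
        ``method="asymptotic"`` uses the deep-focus limit U -> U_inf.
        """
        if method not in ("corrected", "asymptotic"):
            raise ValueError("method must be 'corrected' or 'asymptotic'")
        i_n = normalize_profile(self.sample, mode="sample")
        h, h_source = self._reference_curve()
        u = compute_U(i_n, h, smooth=self.smooth)
        if method == "corrected":
            if self.depth_response is None:
                raise ValueError("corrected estimation requires a depth response")
            r_th = self.depth_response.r_th_at(self.depths)
        else:
            r_th = None
        table = per_depth_K(u, self.phi00, self.depths, r_th=r_th)
        k, k_sd = estimate_K(u, self.phi00, self.depths, r_th=r_th, weighted=weighted)
        sigma, sigma_sd = sigma_from_K(k, self.rho_molar, self.photophysics, k_sd=k_sd)
        return AdsorptionResults(
            model=self,
            k_value=k,
            k_sd=k_sd,
            u_inf=1.0 / (1.0 + self.phi00 * k),
            sigma=sigma,
            sigma_sd=sigma_sd,
            depths_used=list(self.depths),
            phi00_used=self.phi00,
            rho=self.rho_molar * MOLAR_TO_PER_UM3,
            per_depth=table,
            u_curve=u,
            h_source=h_source,
            method=method,
        )


@dataclass
class AdsorptionResults:
    """Fitted surface-adsorption quantities with first-order uncertainties."""

    model: SurfaceAdsorptionModel
    k_value: float
    k_sd: float
    u_inf: float
    sigma: float
    sigma_sd: float
    depths_used: list
    phi00_used: float
    rho: float  # molecules per µm³
    per_depth: pd.DataFrame = field(repr=False)
    u_curve: pd.Series = field(repr=False)
    h_source: str = "measured"
    method: str = "corrected"

    def coverage(self, s_mol_nm2: float = 1.0) -> float:
        """Monolayer coverage fraction of the fitted sigma."""
        return coverage_fraction(self.sigma, s_mol_nm2)

    def to_dict(self) -> dict:
        return {
            "k_value_um": self.k_value,
            "k_sd_um": self.k_sd,
            "u_inf": self.u_inf,
            "sigma_per_um2": self.sigma,
            "sigma_sd_per_um2": self.sigma_sd,
            "depths_used_um": list(self.depths_used),
            "phi00_used_per_um": self.phi00_used,
            "rho_per_um3": self.rho,
            "h_source": self.h_source,
            "method": self.method,
        }

    def summary(self) -> str:
        lines = [
            "Surface adsorption from confocal z-scan",
            "=" * 47,
            f"estimator              {self.method} (H {self.h_source})",
            f"depths used (µm)       {', '.join(f'{d:g}' for d in self.depths_used)}",
            f"phi(0,0) used (µm⁻¹)   {self.phi00_used:.4f}",
            f"bulk density (µm⁻³)    {self.rho:.4g}",
            f"K  (µm)                {self.k_value:.4g} ± {self.k_sd:.2g}",
            f"U∞                     {self.u_inf:.4g}",
            f"sigma (µm⁻²)           {self.sigma:.4g} ± {self.sigma_sd:.2g}",
            f"monolayer coverage     {self.coverage():.3%} (s_mol = 1 nm²)",
            "",
            "per-depth estimates:",
            self.per_depth.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot U(z_F) with the fitted model curve and asymptote."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.u_curve.index, self.u_curve.values, "o", ms=3, label="U = I_N/H")
        if self.model.depth_response is not None:
            dr = self.model.depth_response
            u_fit = (1.0 + self.phi00_used * self.k_value * dr.r_th) / (
                1.0 + self.phi00_used * self.k_value
            )
            ax.plot(dr.z_f_grid, u_fit, "-", label="model")
        ax.axhline(self.u_inf, ls=":", color="grey", label="U∞")
        ax.set_xlabel("nominal focus depth z_F (µm)")
        ax.set_ylabel("U")
        ax.legend()
        return ax
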