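"""TCSPC decay analysis and Förster–Hoffman viscosity calibration.

Decay histograms are fitted by Poisson maximum likelihood with a
biexponential model (plus constant background), including wrap-around of
slow components under pulsed excitation and optional Gaussian-IRF
reconvolution.  The headline statistic is the amplitude-averaged lifetime

    <tau> = (A1 tau1 + A2 tau2) / (A1 + A2).

Bulk lifetimes versus solvent viscosity follow the empirical molecular-rotor
power law tau = C eta^alpha (Förster–Hoffman), fitted in log–log space; its
inversion locates the viscosity at which the bulk lifetime would reach the
surface-species plateau, yielding the quantum yield assigned to the adsorbed
layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.special import erfcx

__all__ = [
    "DecayHistogram",
    "BiexpFit",
    "FHFit",
    "BiexponentialDecayModel",
    "ForsterHoffmanModel",
    "fit_biexponential",
    "amplitude_avg_lifetime",
    "fit_forster_hoffman",
    "intersect_viscosity",
    "power_law_quantum_yield",
]

_MIN_COUNTS = 1000


@dataclass
class DecayHistogram:
    """A TCSPC histogram: uniformly spaced time-bin centres (ns), photon
    counts per bin, and the laser repetition rate (MHz).

    ``irf_fwhm`` (ns), when given, switches the fit to Gaussian-IRF
    reconvolution over the whole record instead of tail fitting.
    """

    t: np.ndarray
    counts: np.ndarray
    rep_rate: float = 40.0
    irf_fwhm: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.counts.shape or self.t.size < 4:
            raise ValueError("t and counts must be equal-length 1-D arrays (>= 4 bins)")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time bins must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time bins must be uniformly spaced")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.rep_rate <= 0:
            raise ValueError("repetition rate must be positive")
        if (self.t[-1] - self.t[0]) + dt[0] > self.period * (1.0 + 1e-6):
            raise ValueError("histogram span exceeds the laser period")
        if self.irf_fwhm is not None and self.irf_fwhm <= 0:
            raise ValueError("irf_fwhm must be positive")

    @property
    def period(self) -> float:
        """Laser period in ns."""
        return 1.0e3 / self.rep_rate

    @property
    def bin_width(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


def amplitude_avg_lifetime(a1: float, tau1: float, a2: float, tau2: float) -> float:
    """Amplitude-averaged lifetime (A1 tau1 + A2 tau2)/(A1 + A2) in ns."""
    if a1 < 0 or a2 < 0:
        raise ValueError("amplitudes must be non-negative")
    if a1 + a2 <= 0:
        raise ValueError("amplitudes must not both be zero")
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    return (a1 * tau1 + a2 * tau2) / (a1 + a2)


def decay_component(
    t: np.ndarray,
    tau: float,
    period: float,
    t0: float = 0.0,
    irf_sigma: float | None = None,
) -> np.ndarray:
    """Unit-amplitude decay shape under periodic excitation.

    Without an IRF this is the tail model exp(-(t-t0)/tau) summed over all
    previous pulses (geometric series); with a Gaussian IRF of width
    ``irf_sigma`` centred at t0 the shape is the analytic
    exponential-Gaussian convolution, with a few previous pulses added
    explicitly.
    """
    if tau <= 0:
        raise ValueError("lifetime must be positive")
    if irf_sigma is None:
        x = t - t0
        out = np.where(x >= 0, np.exp(-np.clip(x, 0, None) / tau), 0.0)
        return out / (1.0 - math.exp(-period / tau))
    n_wrap = max(1, min(8, int(math.ceil(10.0 * tau / period))))
    out = np.zeros_like(t, dtype=float)
    for k in range(n_wrap + 1):
        out += _exp_gauss(t + k * period, tau, t0, irf_sigma)
    return out


def _exp_gauss(t: np.ndarray, tau: float, mu: float, sigma: float) -> np.ndarray:
    """Exponential decay convolved with a Gaussian.

    Two numerically stable branches of 0.5 exp(a) erfc(b) with
    a = sigma²/(2 tau²) - x/tau, b = sigma/(√2 tau) - x/(√2 sigma):
    for b >= 0 use 0.5 erfcx(b) exp(a - b²); for b < 0 (far past the IRF)
    expand erfc(b) = 2 - erfc(-b) to avoid the overflowing erfcx tail.
    """
    x = np.asarray(t, dtype=float) - mu
    a = sigma**2 / (2.0 * tau**2) - x / tau
    b = sigma / (math.sqrt(2.0) * tau) - x / (math.sqrt(2.0) * sigma)
    gauss = np.exp(-(x**2) / (2.0 * sigma**2))  # == exp(a - b²)
    out = np.empty_like(x)
    pos = b >= 0
    out[pos] = 0.5 * erfcx(b[pos]) * gauss[pos]
    out[~pos] = np.exp(a[~pos]) - 0.5 * erfcx(-b[~pos]) * gauss[~pos]
    return out


@dataclass
class BiexpFit:
    """Two-component decay fit.  Components are ordered tau1 <= tau2;
    ``tau_avg`` is the amplitude-averaged lifetime; ``goodness`` the reduced
    Pearson chi-square over the fit window."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    tau_avg: float
    background: float
    fit_window: tuple
    goodness: float

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("lifetimes must be positive")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be non-negative")
        lo, hi = sorted((self.tau1, self.tau2))
        if not (lo - 1e-9 <= self.tau_avg <= hi + 1e-9):
            raise ValueError("tau_avg must lie between the component lifetimes")


class BiexponentialDecayModel:
    """Poisson-MLE biexponential model for a TCSPC histogram.

    Tail fitting (from the bin after the histogram maximum) is the default;
    when the histogram carries an ``irf_fwhm``, Gaussian-IRF reconvolution
    over the full record is used instead.  A nested single-exponential fit is
    evaluated alongside and preferred when the second component is not
    supported by the likelihood, so that monoexponential data report a zero
    second amplitude.
    """

    def __init__(self, hist: DecayHistogram, fit_window: tuple | None = None) -> None:
        if hist.total_counts < _MIN_COUNTS:
            raise ValueError(
                f"histogram holds {hist.total_counts:.0f} counts; "
                f"at least {_MIN_COUNTS} are required for a stable fit"
            )
        self.hist = hist
        peak = int(np.argmax(hist.counts))
        if hist.irf_fwhm is not None:
            lo = 0
            self.irf_sigma = hist.irf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            self.t0 = float(hist.t[peak])
        else:
            lo = peak + 1
            self.irf_sigma = None
            self.t0 = float(hist.t[min(lo, hist.t.size - 1)])
        hi = hist.t.size
        if fit_window is not None:
            lo = max(lo, int(np.searchsorted(hist.t, fit_window[0])))
            hi = min(hi, int(np.searchsorted(hist.t, fit_window[1], side="right")))
        if hi - lo < 6:
            raise ValueError("fit window too short")
        self._sl = slice(lo, hi)
        self.t_fit = hist.t[self._sl]
        self.c_fit = hist.counts[self._sl]

    # -- model & likelihood ---------------------------------------------------
    #
    # Packed parameter vector x: logarithms of the positive parameters
    # (A1, tau1[, A2, tau2], background), followed, in reconvolution mode,
    # by the IRF centre t0 in ns (linear).

    @property
    def _fits_t0(self) -> bool:
        return self.irf_sigma is not None

    def _unpack(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        if self._fits_t0:
            return np.exp(x[:-1]), float(x[-1])
        return np.exp(x), self.t0

    def _mu_theta(self, theta: np.ndarray, t0: float) -> np.ndarray:
        """Expected counts per bin for natural parameters
        (A1, tau1[, A2, tau2], background) and decay origin t0."""
        if theta.size == 5:
            amps, taus = (theta[0], theta[2]), (theta[1], theta[3])
        else:
            amps, taus = (theta[0],), (theta[1],)
        mu = np.full_like(self.t_fit, theta[-1])
        for ai, tau in zip(amps, taus):
            mu = mu + ai * decay_component(
                self.t_fit, tau, self.hist.period, t0, self.irf_sigma
            )
        return np.clip(mu, 1e-12, None)

    def _nll(self, x: np.ndarray) -> float:
        lo, hi = self._bounds(x.size)
        clipped = np.clip(x, lo, hi)
        penalty = 1.0e4 * float(np.sum((x - clipped) ** 2))
        theta, t0 = self._unpack(clipped)
        mu = self._mu_theta(theta, t0)
        return float(np.sum(mu - self.c_fit * np.log(mu))) + penalty

    def _bounds(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.full(n, -30.0)
        hi = np.full(n, 40.0)
        n_log = n - 1 if self._fits_t0 else n
        tau_idx = [1, 3] if n_log == 5 else [1]
        lo[tau_idx] = math.log(self.hist.bin_width / 10.0)
        hi[tau_idx] = math.log(20.0 * self.hist.period)
        if self._fits_t0:
            lo[-1] = float(self.t_fit[0]) - 2.0
            hi[-1] = float(self.t_fit[-1])
        return lo, hi

    # -- initialisation -------------------------------------------------------

    def _log_slope_tau(self, frac_lo: float, frac_hi: float) -> float:
        n = self.t_fit.size
        i0, i1 = int(frac_lo * n), max(int(frac_lo * n) + 2, int(frac_hi * n))
        t, c = self.t_fit[i0:i1], np.clip(self.c_fit[i0:i1], 0.5, None)
        slope = np.polyfit(t, np.log(c), 1)[0]
        return float(np.clip(-1.0 / slope if slope < 0 else self.hist.period, 1e-3, self.hist.period * 10))

    def _starts(self) -> list[np.ndarray]:
        c0 = max(self.c_fit.max(), 1.0)
        bg = max(np.median(self.c_fit[-max(4, self.t_fit.size // 10):]), 1e-3)
        tau_fast = self._log_slope_tau(0.1, 0.3)
        tau_slow = self._log_slope_tau(0.5, 1.0)
        if tau_slow <= tau_fast:
            tau_slow = 3.0 * tau_fast
        starts = []
        for f in (0.8, 0.5, 0.95):
            x0 = np.log([f * c0, tau_fast, (1 - f) * c0, tau_slow, bg])
            if self._fits_t0:
                x0 = np.append(x0, self.t0)
            starts.append(x0)
        return starts

    # -- fitting --------------------------------------------------------------

    def _minimize(self, x0: np.ndarray):
        res = minimize(self._nll, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        res = minimize(self._nll, res.x, method="BFGS",
                       options={"maxiter": 2000, "gtol": 1e-8})
        return res

    def fit(self) -> "BiexpFitResults":
        best = None
        for x0 in self._starts():
            res = self._minimize(x0)
            if np.all(np.isfinite(res.x)) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError("biexponential fit failed to converge after restarts")
        theta_b, t0_b = self._unpack(best.x)
        # nested monoexponential fit for model selection
        tau_init = amplitude_avg_lifetime(theta_b[0], theta_b[1], theta_b[2], theta_b[3])
        x0m = np.log([max(self.c_fit.max(), 1.0), tau_init, theta_b[4]])
        if self._fits_t0:
            x0m = np.append(x0m, t0_b)
        resm = self._minimize(x0m)
        use_mono = 2.0 * (resm.fun - best.fun) < 5.99  # LRT, chi2(2) at 95%
        if use_mono:
            theta_m, t0 = self._unpack(resm.x)
            a, tau, bg = theta_m
            theta = np.array([a, tau, 0.0, tau, bg])
            x_active = resm.x
            nll = float(resm.fun)
        else:
            t0 = t0_b
            theta = theta_b.copy()
            x_active = best.x.copy()
            nll = float(best.fun)
            if theta[1] > theta[3]:  # order tau1 <= tau2
                theta = theta[[2, 3, 0, 1, 4]]
                perm = [2, 3, 0, 1, 4] + ([5] if self._fits_t0 else [])
                x_active = x_active[perm]
        mu = self._mu_theta(theta, t0)
        dof = max(self.t_fit.size - x_active.size, 1)
        chi2 = float(np.sum((self.c_fit - mu) ** 2 / np.clip(mu, 1e-9, None)) / dof)
        cov = self._covariance(x_active)
        fit = BiexpFit(
            a1=float(theta[0]),
            tau1=float(theta[1]),
            a2=float(theta[2]),
            tau2=float(theta[3]),
            tau_avg=amplitude_avg_lifetime(theta[0], theta[1], max(theta[2], 0.0), theta[3])
            if theta[0] + theta[2] > 0
            else float(theta[1]),
            background=float(theta[4]),
            fit_window=(float(self.t_fit[0]), float(self.t_fit[-1])),
            goodness=chi2,
        )
        return BiexpFitResults(
            fit=fit,
            model=self,
            nll=nll,
            params=x_active,
            cov=cov,
            t0=float(t0),
            monoexponential=use_mono,
        )

    def _covariance(self, log_theta: np.ndarray) -> np.ndarray:
        """Covariance of the packed parameters from a central-difference
        Hessian of the negative log-likelihood."""
        n = log_theta.size
        h = 1e-4
        hess = np.empty((n, n))
        f0 = self._nll(log_theta)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h
                ej = np.zeros(n); ej[j] = h
                if i == j:
                    fpp = self._nll(log_theta + ei)
                    fmm = self._nll(log_theta - ei)
                    hess[i, i] = (fpp - 2 * f0 + fmm) / h**2
                else:
                    fpp = self._nll(log_theta + ei + ej)
                    fpm = self._nll(log_theta + ei - ej)
                    fmp = self._nll(log_theta - ei + ej)
                    fmm = self._nll(log_theta - ei - ej)
                    hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
        try:
            return np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return np.full((n, n), np.nan)


@dataclass
class BiexpFitResults:
    """Fit results: the :class:`BiexpFit` parameters plus likelihood,
    parameter covariance and convenience accessors.

    ``params`` is the packed MLE vector (logs of the positive parameters,
    plus the IRF centre t0 in reconvolution mode) and ``cov`` its covariance
    from the observed information.
    """

    fit: BiexpFit
    model: BiexponentialDecayModel
    nll: float
    params: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    t0: float = 0.0
    monoexponential: bool = False

    @property
    def tau_avg(self) -> float:
        return self.fit.tau_avg

    def param_names(self) -> list[str]:
        names = (
            ["a1", "tau1", "background"]
            if self.monoexponential
            else ["a1", "tau1", "a2", "tau2", "background"]
        )
        if self.model._fits_t0:
            names.append("t0")
        return names

    def se(self) -> dict:
        """Approximate standard errors of the natural parameters (delta
        method from the log-parameter covariance; t0 is already linear)."""
        names = self.param_names()
        n_log = len(names) - 1 if self.model._fits_t0 else len(names)
        scale = np.concatenate([np.exp(self.params[:n_log]), np.ones(len(names) - n_log)])
        diag = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        return {n: float(s * d) for n, s, d in zip(names, scale, diag)}

    def expected_counts(self) -> np.ndarray:
        theta = np.array(
            [self.fit.a1, self.fit.tau1, self.fit.a2, self.fit.tau2, self.fit.background]
        )
        return self.model._mu_theta(theta, self.t0)

    def summary(self) -> str:
        f = self.fit
        kind = "monoexponential" if self.monoexponential else "biexponential"
        se = self.se()
        lines = [
            f"TCSPC decay fit ({kind}, Poisson MLE)",
            "=" * 44,
            f"fit window (ns)      {f.fit_window[0]:.3f} – {f.fit_window[1]:.3f}",
            f"A1                   {f.a1:.4g} ± {se.get('a1', float('nan')):.2g}",
            f"tau1 (ns)            {f.tau1:.4g} ± {se.get('tau1', float('nan')):.2g}",
            f"A2                   {f.a2:.4g}",
            f"tau2 (ns)            {f.tau2:.4g}",
            f"background           {f.background:.4g}",
            f"<tau> (ns)           {f.tau_avg:.4g}",
            f"reduced chi-square   {f.goodness:.3f}",
        ]
        return "\n".join(lines)


def fit_biexponential(hist: DecayHistogram, fit_window: tuple | None = None) -> BiexpFit:
    """Fit a (bi)exponential decay to a TCSPC histogram; returns the
    :class:`BiexpFit` parameter set.  See :class:`BiexponentialDecayModel`
    for the full results object."""
    return BiexponentialDecayModel(hist, fit_window=fit_window).fit().fit


# ---------------------------------------------------------------------------
# Förster–Hoffman calibration
# ---------------------------------------------------------------------------


@dataclass
class FHFit:
    """Förster–Hoffman power law tau = prefactor * eta^alpha.

    ``covariance`` is the 2x2 covariance of (ln prefactor, alpha) from the
    log–log least-squares fit; ``eta_range`` records the fitted viscosity
    span for extrapolation checks."""

    prefactor: float
    alpha: float
    covariance: np.ndarray = field(repr=False)
    eta_range: tuple = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")
        if not (0.0 < self.alpha < 1.5):
            raise ValueError(f"Förster–Hoffman exponent {self.alpha:.3g} outside (0, 1.5)")

    def predict(self, eta) -> np.ndarray:
        return self.prefactor * np.asarray(eta, dtype=float) ** self.alpha


class ForsterHoffmanModel:
    """Power-law model tau = C eta^alpha for bulk molecular-rotor lifetimes."""

    def __init__(self, tau, eta) -> None:
        tau = np.asarray(tau, dtype=float)
        eta = np.asarray(eta, dtype=float)
        if tau.shape != eta.shape or tau.ndim != 1:
            raise ValueError("tau and eta must be 1-D arrays of equal length")
        if tau.size < 3:
            raise ValueError("at least 3 (tau, eta) points are required")
        if np.any(tau <= 0) or np.any(eta <= 0):
            raise ValueError("lifetimes and viscosities must be positive")
        self.tau = tau
        self.eta = eta

    def fit(self) -> "FHFitResults":
        x = np.log(self.eta)
        y = np.log(self.tau)
        X = np.column_stack([np.ones_like(x), x])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        dof = max(x.size - 2, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        fh = FHFit(
            prefactor=float(np.exp(beta[0])),
            alpha=float(beta[1]),
            covariance=cov,
            eta_range=(float(self.eta.min()), float(self.eta.max())),
        )
        return FHFitResults(fit=fh, model=self, residual_sd=math.sqrt(s2))


@dataclass
class FHFitResults:
    fit: FHFit
    model: ForsterHoffmanModel
    residual_sd: float

    @property
    def alpha(self) -> float:
        return self.fit.alpha

    @property
    def prefactor(self) -> float:
        return self.fit.prefactor

    def alpha_se(self) -> float:
        return float(np.sqrt(self.fit.covariance[1, 1]))

    def intersect(self, tau_surface_plateau: float, phi_of_eta=None) -> tuple:
        return intersect_viscosity(self.fit, tau_surface_plateau, phi_of_eta)

    def summary(self) -> str:
        f = self.fit
        return "\n".join(
            [
                "Förster–Hoffman fit  tau = C eta^alpha",
                "=" * 40,
                f"C (ns·(mPa·s)^-alpha)  {f.prefactor:.4g}",
                f"alpha                  {f.alpha:.4g} ± {self.alpha_se():.2g}",
                f"eta range (mPa·s)      {f.eta_range[0]:.3g} – {f.eta_range[1]:.3g}",
                f"log-residual sd        {self.residual_sd:.3g}",
            ]
        )


def fit_forster_hoffman(tau, eta) -> FHFit:
    """Least-squares fit of log tau = log C + alpha log eta; returns the
    :class:`FHFit` parameter set."""
    return ForsterHoffmanModel(tau, eta).fit().fit


def power_law_quantum_yield(
    alpha: float, phi_anchor: float = 0.15, eta_anchor: float = 2.0e4
) -> Callable[[float], float]:
    """Quantum-yield relation Phi(eta) = phi_anchor (eta/eta_anchor)^alpha.

    A single documented anchor — the common surface/bulk intersection at
    2e4 mPa·s with Phi = 0.15 — pins the curve; the exponent is shared with
    the lifetime power law (non-radiative TICT relaxation dominating both).
    """
    if phi_anchor <= 0 or eta_anchor <= 0:
        raise ValueError("anchor values must be positive")

    def phi(eta: float) -> float:
        return float(min(phi_anchor * (eta / eta_anchor) ** alpha, 1.0))

    return phi


def intersect_viscosity(
    fh_bulk: FHFit,
    tau_surface_plateau: float,
    phi_of_eta=None,
) -> tuple[float, float]:
    """Viscosity at which the bulk lifetime power law reaches the surface
    plateau, and the quantum yield there.

    eta_I = (tau_plateau / C)^(1/alpha); Phi_I = phi_of_eta(eta_I).
    ``phi_of_eta`` may be a callable or a 2-column (eta, Phi) table
    (log-log interpolated); by default the anchored power law with the
    fitted exponent is used.
    """
    if tau_surface_plateau <= 0:
        raise ValueError("surface plateau lifetime must be positive")
    if tau_surface_plateau < fh_bulk.predict(fh_bulk.eta_range[1]) - 1e-12:
        raise ValueError(
            "surface plateau lies below the fitted bulk lifetimes: no intersection"
        )
    eta_i = (tau_surface_plateau / fh_bulk.prefactor) ** (1.0 / fh_bulk.alpha)
    if phi_of_eta is None:
        phi_of_eta = power_law_quantum_yield(fh_bulk.alpha)
    if callable(phi_of_eta):
        phi_i = float(phi_of_eta(eta_i))
    else:
        table = np.asarray(phi_of_eta, dtype=float)
        if table.ndim != 2 or table.shape[1] != 2:
            raise ValueError("phi_of_eta table must have two columns (eta, Phi)")
        phi_i = float(
            np.exp(np.interp(np.log(eta_i), np.log(table[:, 0]), np.log(table[:, 1])))
        )
    return float(eta_i), phi_i
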