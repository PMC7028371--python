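"""Confocal FCS autocorrelation model, diffusion fits, and Langmuir K_D.

The autocorrelation of fluorescence fluctuations in a 3-D Gaussian confocal
volume, for a mixture of freely diffusing species of equal brightness, is

    G(tau) = [pi^{3/2} omega_o^3 S <C>]^-1
             * sum_i f_i (1 + 4 D_i tau / omega_o^2)^-1
                       (1 + 4 D_i tau / (S^2 omega_o^2))^-1/2

with lateral beam radius ``omega_o`` (um), aspect ratio ``S = z_o/omega_o``,
time-averaged concentration ``<C>`` (molecules/um^3), fractions ``f_i`` and
diffusion coefficients ``D_i`` (um^2/s).  Fits include an additive baseline
offset (standard practice; measured curves need not decay exactly to zero).

The binding analysis titrates a fixed concentration ``C`` of labeled ligand
with its binding partner at total concentration ``R_T``; two-component fits
yield the bound fraction ``f_bound`` which is converted to
``R_bound = C f_bound``, ``R_free = R_T - R_bound`` and fitted,
1/SE^2-weighted, to the Langmuir isotherm
``f_bound = R_free / (R_free + K_D)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy.optimize import curve_fit

__all__ = [
    "NM_TO_UM3",
    "FCSCurve",
    "FCSModelParams",
    "TitrationSeries",
    "LangmuirFit",
    "fcs_model",
    "calibrate_beam",
    "fit_free_species",
    "fit_bound_fraction",
    "langmuir_kd",
    "exact_bound_fraction",
]

#: molecules/um^3 per nM (Avogadro * 1e-9 mol/L * 1e-15 L/um^3)
NM_TO_UM3 = 0.6022


@dataclass
class FCSCurve:
    """Lag-domain autocorrelation data.

    ``lags`` in seconds (strictly increasing, > 0), ``g`` dimensionless,
    ``sigma`` optional per-point standard errors.
    """

    lags: np.ndarray
    g: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.lags.ndim != 1 or self.g.shape != self.lags.shape:
            raise ValueError("lags and g must be 1-D arrays of equal length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("non-finite autocorrelation values")


@dataclass
class FCSModelParams:
    """Parameters of the multi-component diffusion model."""

    omega_o: float  # um
    s_ratio: float  # z_o / omega_o
    c_avg: float  # molecules / um^3
    components: list[dict] = field(default_factory=list)  # {"f":, "d":}
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_o <= 0:
            raise ValueError("omega_o must be > 0")
        if self.s_ratio <= 1:
            raise ValueError("aspect ratio S must be > 1")
        if self.c_avg <= 0:
            raise ValueError("c_avg must be > 0")
        fsum = sum(c["f"] for c in self.components)
        if abs(fsum - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1 (got {fsum})")
        for c in self.components:
            if not 0.0 <= c["f"] <= 1.0 or c["d"] <= 0:
                raise ValueError("need f in [0,1] and d > 0 for every component")

    @property
    def c_avg_nM(self) -> float:
        return self.c_avg / NM_TO_UM3


def fcs_model(lags, params: FCSModelParams) -> np.ndarray:
    """Evaluate G(tau) for the given parameters (plus additive offset)."""
    tau = np.asarray(lags, dtype=float)
    amp = 1.0 / (math.pi**1.5 * params.omega_o**3 * params.s_ratio * params.c_avg)
    g = np.zeros_like(tau)
    w2 = params.omega_o**2
    for comp in params.components:
        x = 4.0 * comp["d"] * tau / w2
        g += comp["f"] / ((1.0 + x) * np.sqrt(1.0 + x / params.s_ratio**2))
    return amp * g + params.offset


def _two_component_g(tau, omega_o, s_ratio, c_avg, f1, d1, d2, offset):
    """Raw two-component model for the fitting backend (f2 = 1 - f1)."""
    w2 = omega_o**2
    amp = 1.0 / (math.pi**1.5 * omega_o**3 * s_ratio * c_avg)
    x1 = 4.0 * d1 * tau / w2
    x2 = 4.0 * d2 * tau / w2
    s2 = s_ratio**2
    g = f1 / ((1.0 + x1) * np.sqrt(1.0 + x1 / s2)) + (1.0 - f1) / (
        (1.0 + x2) * np.sqrt(1.0 + x2 / s2)
    )
    return amp * g + offset


class FitDivergenceError(RuntimeError):
    """Raised when no fit start converges to a finite optimum."""


def _multistart_fit(curve: FCSCurve, make_params, starts) -> lmfit.minimizer.MinimizerResult:
    """Run a weighted least-squares fit from several starts; keep the best.

    ``make_params(start) -> lmfit.Parameters``; ``starts`` is an iterable of
    start descriptors.  Ties broken by lowest residual sum of squares.
    """
    weights = None if curve.sigma is None else 1.0 / curve.sigma

    def residual(p):
        g = _two_component_g(
            curve.lags,
            p["omega_o"].value,
            p["s_ratio"].value,
            p["c_avg"].value,
            p["f1"].value,
            p["d1"].value,
            p["d2"].value,
            p["offset"].value,
        )
        r = curve.g - g
        return r if weights is None else r * weights

    best = None
    for start in starts:
        try:
            res = lmfit.minimize(residual, make_params(start), method="leastsq")
        except Exception:
            continue
        if not np.isfinite(res.chisqr):
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitDivergenceError("all fit starts diverged")
    return best


def calibrate_beam(curve: FCSCurve, d_ref: float = 280.0) -> tuple[float, float]:
    """Calibrate beam geometry from a reference-dye curve of known D.

    Fits the single-component model with the diffusion coefficient fixed at
    ``d_ref`` (um^2/s; rhodamine-6G is the conventional standard) and returns
    ``(omega_o, S)``, which are then held fixed in all sample fits.  Note the
    model constrains omega_o only through D/omega_o^2, so the calibrated
    omega_o scales as sqrt(d_ref).
    """
    g0 = float(np.max(curve.g))
    # half-decay lag gives a diffusion-time scale for the omega_o starts
    tau_half = float(curve.lags[np.argmin(np.abs(curve.g - g0 / 2.0))])
    w_guess = math.sqrt(max(4.0 * d_ref * tau_half, 1e-6))

    def make_params(w0):
        p = lmfit.Parameters()
        p.add("omega_o", value=w0, min=1e-3, max=100.0)
        p.add("s_ratio", value=5.0, min=1.001, max=100.0)
        p.add("c_avg", value=1.0, min=1e-9)
        p.add("f1", value=1.0, vary=False)
        p.add("d1", value=d_ref, vary=False)
        p.add("d2", value=d_ref, vary=False)
        p.add("offset", value=0.0, min=-0.5, max=0.5)
        # seed amplitude consistently with the omega_o start
        p["c_avg"].value = max(
            1.0 / (math.pi**1.5 * w0**3 * 5.0 * max(g0, 1e-12)), 1e-9
        )
        return p

    starts = w_guess * np.logspace(-1, 1, 5)
    res = _multistart_fit(curve, make_params, starts)
    return res.params["omega_o"].value, res.params["s_ratio"].value


def fit_free_species(
    curve: FCSCurve, omega_o: float, s_ratio: float
) -> tuple[float, float]:
    """Single-component fit with fixed beam geometry: returns (c_avg, D)."""

    def make_params(d0):
        p = lmfit.Parameters()
        p.add("omega_o", value=omega_o, vary=False)
        p.add("s_ratio", value=s_ratio, vary=False)
        g0 = max(float(np.max(curve.g)), 1e-12)
        p.add(
            "c_avg",
            value=1.0 / (math.pi**1.5 * omega_o**3 * s_ratio * g0),
            min=1e-9,
        )
        p.add("f1", value=1.0, vary=False)
        p.add("d1", value=d0, min=1e-3, max=1e4)
        p.add("d2", value=d0, vary=False)
        p.add("offset", value=0.0, min=-0.5, max=0.5)
        return p

    res = _multistart_fit(curve, make_params, np.logspace(0, 3, 5))
    return res.params["c_avg"].value, res.params["d1"].value


def fit_bound_fraction(
    curve: FCSCurve,
    omega_o: float,
    s_ratio: float,
    d_free: float,
    d_bound_bounds: tuple[float, float] = (1.0, 100.0),
) -> dict:
    """Two-component fit with the free-species D fixed.

    Returns a dict with ``c_avg``, ``f_bound`` (fraction of label diffusing
    as the slow, complexed species), ``d_bound`` and a ``pinned`` warning
    flag set when f_bound converges onto a boundary (0 or 1), in which case
    a single-component model is statistically adequate.
    """
    lo, hi = d_bound_bounds

    def make_params(start):
        f0, d0 = start
        p = lmfit.Parameters()
        p.add("omega_o", value=omega_o, vary=False)
        p.add("s_ratio", value=s_ratio, vary=False)
        g0 = max(float(np.max(curve.g)), 1e-12)
        p.add(
            "c_avg",
            value=1.0 / (math.pi**1.5 * omega_o**3 * s_ratio * g0),
            min=1e-9,
        )
        # component 1 = free species (D fixed), f1 = 1 - f_bound
        p.add("f1", value=1.0 - f0, min=0.0, max=1.0)
        p.add("d1", value=d_free, vary=False)
        p.add("d2", value=d0, min=lo, max=hi)
        p.add("offset", value=0.0, min=-0.5, max=0.5)
        return p

    d_starts = np.logspace(math.log10(lo * 1.2), math.log10(hi / 1.2), 5)
    starts = [(f0, d0) for f0, d0 in zip((0.1, 0.3, 0.5, 0.7, 0.9), d_starts)]
    res = _multistart_fit(curve, make_params, starts)
    f_bound = 1.0 - res.params["f1"].value
    pinned = f_bound < 1e-4 or f_bound > 1.0 - 1e-4
    return {
        "c_avg": res.params["c_avg"].value,
        "f_bound": f_bound,
        "d_bound": res.params["d2"].value,
        "offset": res.params["offset"].value,
        "pinned": pinned,
        "chisqr": float(res.chisqr),
        "aic": float(res.aic),
    }


@dataclass
class TitrationSeries:
    """(R_T, f_bound +/- SE) titration points at fixed label concentration C."""

    r_total: np.ndarray  # molar
    f_bound: np.ndarray
    se: np.ndarray
    label_conc: float  # molar

    def __post_init__(self) -> None:
        self.r_total = np.asarray(self.r_total, dtype=float)
        self.f_bound = np.asarray(self.f_bound, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(self.r_total < 0):
            raise ValueError("total concentrations must be >= 0")
        if np.any((self.f_bound < 0) | (self.f_bound > 1)):
            raise ValueError("bound fractions must lie in [0, 1]")


@dataclass
class LangmuirFit:
    kd: float  # molar
    se: float
    r_free: np.ndarray = field(default=None, repr=False)


def langmuir_kd(titration: TitrationSeries) -> LangmuirFit:
    """SE-weighted Langmuir fit of a bound-fraction titration.

    Computes ``R_bound = C f_bound`` and ``R_free = R_T - R_bound`` per
    point, then fits ``f_bound = R_free / (R_free + K_D)`` by 1/SE^2-weighted
    least squares.
    """
    r_bound = titration.label_conc * titration.f_bound
    r_free = titration.r_total - r_bound
    if np.any(r_free < 0):
        raise ValueError(
            "negative free concentration: bound exceeds total (inconsistent inputs)"
        )

    def isotherm(rf, kd):
        return rf / (rf + kd)

    sigma = np.where(titration.se > 0, titration.se, np.nan)
    if np.all(np.isnan(sigma)):
        sigma = None
    elif np.any(np.isnan(sigma)):
        sigma = np.where(np.isnan(sigma), np.nanmin(sigma), sigma)

    # midpoint-interpolation start
    kd0 = float(np.interp(0.5, np.sort(titration.f_bound), np.sort(r_free)))
    kd0 = max(kd0, float(np.max(r_free)) * 1e-3, 1e-12)
    popt, pcov = curve_fit(
        isotherm,
        r_free,
        titration.f_bound,
        p0=[kd0],
        sigma=sigma,
        absolute_sigma=sigma is not None,
        maxfev=10000,
    )
    kd = float(popt[0])
    if kd <= 0:
        raise ValueError("Langmuir fit produced non-positive K_D")
    return LangmuirFit(kd=kd, se=float(np.sqrt(pcov[0, 0])), r_free=r_free)


def exact_bound_fraction(label_conc: float, r_total: float, kd: float) -> float:
    """Exact 1:1 binding with depletion.

    Solves ``b^2 - b (C + R_T + K_D) + C R_T = 0`` for the complex
    concentration ``b`` and returns ``f_bound = b / C``.  This is the
    ground-truth generator counterpart of the (depletion-free) Langmuir
    fitting path.
    """
    if label_conc <= 0 or r_total < 0 or kd <= 0:
        raise ValueError("concentrations must be positive (r_total >= 0)")
    s = label_conc + r_total + kd
    b = 0.5 * (s - math.sqrt(s * s - 4.0 * label_conc * r_total))
    return b / label_conc
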