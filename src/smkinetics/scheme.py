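"""Two-closed-complex promoter kinetic scheme.

RNA polymerase holoenzyme binds promoter DNA (second-order rate constant
``k1``) and forms an initial closed complex RP1, which can either dissociate
back to the unbound state (``k_m1``) or isomerize reversibly to a second
closed complex RP2 (forward ``k2``, reverse ``k_m2``).  Dissociation occurs
only from RP1.  The dwell of a polymerase on the promoter -- the time from
entry into RP1 until return to the unbound state -- is then a two-phase
(biexponential) random variable whose amplitudes and time constants are
elementary functions of the three first-order rates.

This module provides the forward map (rates -> observable dwell spectrum),
its exact inverse (dwell spectrum -> rates), and the assembly of a full rate
set from fitted first-binding and dwell-time parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SchemeRates",
    "DwellSpectrum",
    "scheme_dwell_params",
    "invert_dwell_params",
    "assemble_scheme",
]


@dataclass(frozen=True)
class SchemeRates:
    """Rate constants of the two-closed-complex scheme.

    Parameters
    ----------
    k1 : float
        Second-order promoter association rate constant (M^-1 s^-1).
    k_m1 : float
        RP1 -> unbound dissociation rate (s^-1).  The only exit channel.
    k2 : float
        RP1 -> RP2 forward isomerization rate (s^-1).
    k_m2 : float
        RP2 -> RP1 reverse isomerization rate (s^-1).
    primed : bool
        True for the rate set of SCF-bound polymerase (the primed symbols
        k1', k-1', k2', k-2').
    """

    k1: float = 0.0
    k_m1: float = 0.0
    k2: float = 0.0
    k_m2: float = 0.0
    primed: bool = False
    se: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("k1", "k_m1", "k2", "k_m2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DwellSpectrum:
    """Biexponential dwell spectrum: survival S(t) = a e^{-t/tau1} + (1-a) e^{-t/tau2}."""

    a: float
    tau1_s: float
    tau2_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("amplitude a must lie in [0, 1]")
        if not 0.0 < self.tau1_s <= self.tau2_s:
            raise ValueError("need 0 < tau1 <= tau2")

    @property
    def lambda1(self) -> float:
        """Fast eigenvalue 1/tau1 (s^-1)."""
        return 1.0 / self.tau1_s

    @property
    def lambda2(self) -> float:
        """Slow eigenvalue 1/tau2 (s^-1)."""
        return 1.0 / self.tau2_s

    @property
    def mean_s(self) -> float:
        """Mean dwell a*tau1 + (1-a)*tau2 (s)."""
        return self.a * self.tau1_s + (1.0 - self.a) * self.tau2_s

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        return self.a * np.exp(-t / self.tau1_s) + (1.0 - self.a) * np.exp(
            -t / self.tau2_s
        )


def scheme_dwell_params(rates: SchemeRates) -> DwellSpectrum:
    """Eigendecomposition of the scheme: rates -> (a, tau1, tau2).

    With entry into RP1 and exit only via RP1, the dwell-time survival is
    ``S(t) = a exp(-lam1 t) + (1-a) exp(-lam2 t)`` where the eigenvalues
    satisfy ``lam1 + lam2 = k_m1 + k2 + k_m2`` and ``lam1 lam2 = k_m1 k_m2``,
    and ``a = k_m1 (lam1 - k_m2) / (lam1 (lam1 - lam2))``.

    Degenerate eigenvalues (k2 = 0 with k_m1 = k_m2, or k2 = 0 generally
    unreachable RP2) collapse to a single exponential with a = 1.
    """
    if rates.k_m1 <= 0:
        raise ValueError("k_m1 must be > 0 (otherwise dwells are infinite)")
    s = rates.k_m1 + rates.k2 + rates.k_m2
    p = rates.k_m1 * rates.k_m2
    disc = s * s - 4.0 * p
    if rates.k2 == 0.0:
        # RP2 unreachable: pure exponential exit from RP1.
        return DwellSpectrum(a=1.0, tau1_s=1.0 / rates.k_m1, tau2_s=1.0 / rates.k_m1)
    if p == 0.0:
        # k_m2 = 0: the slow phase is absorption into RP2 (infinite dwell).
        raise ValueError("k_m2 = 0 with k2 > 0 gives an infinite-mean dwell")
    root = math.sqrt(max(disc, 0.0))
    lam1 = 0.5 * (s + root)
    lam2 = 0.5 * (s - root)
    if root / s < 1e-12:
        return DwellSpectrum(a=1.0, tau1_s=1.0 / lam1, tau2_s=1.0 / lam1)
    a = rates.k_m1 * (lam1 - rates.k_m2) / (lam1 * (lam1 - lam2))
    a = min(max(a, 0.0), 1.0)
    return DwellSpectrum(a=a, tau1_s=1.0 / lam1, tau2_s=1.0 / lam2)


def invert_dwell_params(spec: DwellSpectrum) -> tuple[float, float, float]:
    """Exact inverse of :func:`scheme_dwell_params`.

    Solves the three spectral relations for (k_m1, k2, k_m2).  The solution
    is closed form:

        k_m1 = a*lam1 + (1-a)*lam2
        k_m2 = lam1*lam2 / k_m1
        k2   = lam1 + lam2 - k_m1 - k_m2

    Raises ``ValueError`` if the spectrum admits no non-negative rate set
    (k2 < 0), which happens when ``a`` is too small for the given time
    constants.
    """
    if not (0.0 < spec.a < 1.0):
        raise ValueError("inversion requires a strictly inside (0, 1)")
    if not spec.tau1_s < spec.tau2_s:
        raise ValueError("inversion requires tau1 < tau2")
    lam1, lam2 = spec.lambda1, spec.lambda2
    k_m1 = spec.a * lam1 + (1.0 - spec.a) * lam2
    k_m2 = lam1 * lam2 / k_m1
    k2 = lam1 + lam2 - k_m1 - k_m2
    if k2 < -1e-12 * (lam1 + lam2):
        raise ValueError(
            "no non-negative rate solution: amplitude a=%.4g too small for "
            "tau1=%.4g s, tau2=%.4g s (requires k2 = %.4g >= 0)"
            % (spec.a, spec.tau1_s, spec.tau2_s, k2)
        )
    return k_m1, max(k2, 0.0), k_m2


def assemble_scheme(
    first_binding,
    dwell,
    *,
    primed: bool = False,
    n_boot: int = 1000,
    seed: int | None = None,
) -> SchemeRates:
    """Assemble a full SchemeRates from fitted parameters.

    ``k1`` is taken directly from the first-binding fit's association rate
    constant; the three first-order rates come from inverting the fitted
    dwell spectrum.  Standard errors are propagated by parametric bootstrap
    through the inversion (Gaussian resampling of (a, tau1, tau2) at their
    fitted SEs, discarding draws outside the feasible region).

    Parameters
    ----------
    first_binding : FirstBindingFit
        Fit with attributes ``k_a`` and ``se_k_a``.
    dwell : BiexpFit
        Fit with attributes ``a``, ``tau1_s``, ``tau2_s`` and their SEs.
    """
    k_m1, k2, k_m2 = invert_dwell_params(
        DwellSpectrum(a=dwell.a, tau1_s=dwell.tau1_s, tau2_s=dwell.tau2_s)
    )
    se: dict = {"k1": getattr(first_binding, "se_k_a", 0.0) or 0.0}
    ses = (
        getattr(dwell, "se_a", 0.0) or 0.0,
        getattr(dwell, "se_tau1", 0.0) or 0.0,
        getattr(dwell, "se_tau2", 0.0) or 0.0,
    )
    if n_boot > 0 and any(s > 0 for s in ses):
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            a = rng.normal(dwell.a, ses[0])
            t1 = rng.normal(dwell.tau1_s, ses[1])
            t2 = rng.normal(dwell.tau2_s, ses[2])
            if not (0.0 < a < 1.0 and 0.0 < t1 < t2):
                continue
            try:
                draws.append(invert_dwell_params(DwellSpectrum(a, t1, t2)))
            except ValueError:
                continue
        if len(draws) >= 10:
            arr = np.array(draws)
            se["k_m1"], se["k2"], se["k_m2"] = arr.std(axis=0, ddof=1)
    return SchemeRates(
        k1=first_binding.k_a, k_m1=k_m1, k2=k2, k_m2=k_m2, primed=primed, se=se
    )
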