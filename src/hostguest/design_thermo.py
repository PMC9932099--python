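"""Titration design rules, K <-> free-energy conversion, and the
affinity-versus-simulation-energy comparison.

Design rules for an accurate 1:1 binding-constant determination:

- dilute-host regime: keep ``[H]_T * K < 1`` where feasible (violating it
  inflates the uncertainty of the fitted constant);
- titrant range: span total guest from ``(0.2 [H]_T + 0.25) / K`` to
  ``(0.8 [H]_T + 4) / K``, which walks the bound fraction through the
  informative part of the isotherm.

Free-energy conversion uses Delta G = -R T ln K with
R = 1.9872e-3 kcal mol^-1 K^-1 (RT = 0.602 kcal mol^-1 at 303 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "R_KCAL",
    "DesignSpec",
    "RegimeCheck",
    "AffinityEnergyRecord",
    "AffinityEnergyFit",
    "check_dilute_regime",
    "titrant_range",
    "make_schedule",
    "K_to_deltaG",
    "deltaG_to_K",
    "rt_kcal",
    "correlate_affinity_energy",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3


@dataclass(frozen=True)
class DesignSpec:
    """Inputs for planning a titration: host level, a-priori K, schedule size."""

    host_total: float  # M
    K_guess: float  # M^-1
    n_points: int = 12
    temperature: float = 303.15  # K

    def __post_init__(self) -> None:
        if self.host_total <= 0 or self.K_guess <= 0 or self.temperature <= 0:
            raise ValueError("host_total, K_guess and temperature must be positive")
        if self.n_points < 6:
            raise ValueError("a titration needs at least 6 points for fitting")


@dataclass(frozen=True)
class RegimeCheck:
    """Outcome of the dilute-host check [H]_T * K < 1."""

    product: float
    passed: bool
    message: str


def check_dilute_regime(host_total: float, K_guess: float) -> RegimeCheck:
    """Evaluate the dilute-host design inequality ``[H]_T * K < 1``."""
    if host_total <= 0 or K_guess <= 0:
        raise ValueError("host_total and K_guess must be positive")
    product = host_total * K_guess
    passed = product < 1.0
    if passed:
        msg = f"[H]_T*K = {product:.3g} < 1: dilute regime satisfied"
    else:
        msg = (f"[H]_T*K = {product:.3g} >= 1: outside the dilute regime; "
               "expect a larger uncertainty in the derived binding constant")
    return RegimeCheck(product=product, passed=passed, message=msg)


def titrant_range(host_total: float, K_guess: float) -> tuple[float, float]:
    """Recommended total-guest range for accurate K extraction.

    Returns ``((0.2 [H]_T + 0.25) / K, (0.8 [H]_T + 4) / K)``; the lower
    bound is always below the upper one.
    """
    if host_total < 0 or K_guess <= 0:
        raise ValueError("host_total must be non-negative and K_guess positive")
    g_min = (0.2 * host_total + 0.25) / K_guess
    g_max = (0.8 * host_total + 4.0) / K_guess
    return g_min, g_max


def make_schedule(spec: DesignSpec, spacing: str = "log") -> np.ndarray:
    """Total-guest schedule: a guest-free reference point followed by
    ``n_points - 1`` values spanning the recommended titrant range
    (log-spaced by default, linear on request)."""
    g_min, g_max = titrant_range(spec.host_total, spec.K_guess)
    if spacing == "log":
        body = np.geomspace(g_min, g_max, spec.n_points - 1)
    elif spacing == "linear":
        body = np.linspace(g_min, g_max, spec.n_points - 1)
    else:
        raise ValueError("spacing must be 'log' or 'linear'")
    return np.concatenate([[0.0], body])


def rt_kcal(temperature: float) -> float:
    """R*T in kcal mol^-1."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature


def K_to_deltaG(K: float, temperature: float) -> float:
    """Standard binding free energy Delta G = -R T ln K (kcal mol^-1).

    K in M^-1 (standard state 1 M); strictly decreasing in K.
    """
    if K <= 0:
        raise ValueError("K must be strictly positive")
    return -rt_kcal(temperature) * math.log(K)


def deltaG_to_K(deltaG: float, temperature: float) -> float:
    """Inverse of :func:`K_to_deltaG`."""
    return math.exp(-deltaG / rt_kcal(temperature))


# ---------------------------------------------------------------------------
# affinity vs simulation energy

@dataclass(frozen=True)
class AffinityEnergyRecord:
    """One host: fitted constant (mM^-1, as tabulated) paired with the
    MD-derived mean interaction energy <U+W> (kcal mol^-1).

    <U+W> is an enthalpic proxy (conformational entropy is not included),
    so the comparison with ln K is a trend check, not a free-energy
    identity.  ``charged`` mirrors the plotting convention: only charged
    (filled) hosts enter the fit; neutral hosts are plotted but excluded.
    """

    host: str
    K_mM: float
    K_err_mM: float
    energy_kcal: float
    energy_err_kcal: float
    charged: bool = True

    def __post_init__(self) -> None:
        if self.K_mM <= 0:
            raise ValueError("K must be positive")
        if self.K_err_mM < 0 or self.energy_err_kcal < 0:
            raise ValueError("uncertainties must be non-negative")


@dataclass(frozen=True)
class AffinityEnergyFit:
    """Weighted linear fit of ln K (K in M^-1) versus <U+W>."""

    slope: float  # per kcal mol^-1
    intercept: float
    slope_se: float
    intercept_se: float
    reference_slope: float  # -1/RT: the slope if ln K tracked -<U+W>/RT exactly
    temperature: float
    n_used: int
    excluded_hosts: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "slope_per_kcal": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "reference_slope_per_kcal": self.reference_slope,
            "temperature_K": self.temperature,
            "n_used": self.n_used,
            "excluded_hosts": list(self.excluded_hosts),
        }


def correlate_affinity_energy(records: Sequence[AffinityEnergyRecord],
                              temperature: float = 303.0) -> AffinityEnergyFit:
    """Weighted straight-line fit of ln K against <U+W>.

    Only charged-flagged records enter the fit.  Uncertainties on both
    axes are honoured with the effective-variance scheme: y-variance
    (sigma_lnK = K_err / K) plus slope^2 times x-variance, iterated to
    self-consistency.  With all uncertainties equal (or zero) the fit
    reduces to ordinary least squares.  Also reports the reference slope
    -1/RT for comparison (the slope ln K would have if it tracked the
    energy one-for-one as a free energy).
    """
    used = [r for r in records if r.charged]
    excluded = tuple(r.host for r in records if not r.charged)
    if len(used) < 3:
        raise ValueError("at least 3 charged records with uncertainties are required")

    x = np.array([r.energy_kcal for r in used])
    y = np.array([math.log(r.K_mM * 1e3) for r in used])  # ln K in M^-1
    sy = np.array([r.K_err_mM / r.K_mM for r in used])
    sx = np.array([r.energy_err_kcal for r in used])
    if np.all(sy == 0):
        sy = np.ones_like(sy)
        sx = np.zeros_like(sx)

    slope = 0.0
    for _ in range(20):
        var = sy ** 2 + slope ** 2 * sx ** 2
        var = np.where(var > 0, var, 1.0)
        w = 1.0 / var
        W = w.sum()
        xbar = (w * x).sum() / W
        ybar = (w * y).sum() / W
        sxx = (w * (x - xbar) ** 2).sum()
        new_slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
        conv = abs(new_slope - slope) <= 1e-12 * max(abs(new_slope), 1.0)
        slope = new_slope
        if conv:
            break
    intercept = ybar - slope * xbar
    slope_se = math.sqrt(1.0 / sxx)
    intercept_se = math.sqrt(1.0 / W + xbar ** 2 / sxx)

    return AffinityEnergyFit(
        slope=float(slope), intercept=float(intercept),
        slope_se=float(slope_se), intercept_se=float(intercept_se),
        reference_slope=-1.0 / rt_kcal(temperature),
        temperature=temperature,
        n_used=len(used), excluded_hosts=excluded,
    )
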