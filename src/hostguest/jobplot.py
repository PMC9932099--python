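"""Continuous-variation (Job-plot) simulation and stoichiometry diagnostics.

In a Job experiment the total concentration ``C_T = [H]_T + [G]_T`` is
held fixed while the host mole fraction ``r = [H]_T / C_T`` is varied.
For a pure 1:1 complex the Job ordinate peaks at r = 0.5; species of
other stoichiometry shift the maximum, which makes the plot a sensitive
diagnostic for deviations from 1:1 behaviour.

Convention adopted here (and used consistently): **r is the HOST mole
fraction**.  The experimental ordinate is ddelta * [H]_T (ppm * M); ideal
simulated data use complex concentrations directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .shift_fitting import ShiftSensitivities, predict_shifts
from .speciation import BindingModelSpec, solve_speciation

__all__ = [
    "JobDataset",
    "JobMaximum",
    "simulate_job",
    "locate_job_maximum",
    "job_deviation_report",
]

#: Points on each side of the grid argmax used for the local quadratic.
QUAD_WINDOW = 5


@dataclass(frozen=True)
class JobDataset:
    """Continuous-variation data on a host-mole-fraction grid.

    ``ordinate`` columns are reporter protons (ddelta * [H]_T, ppm*M) or a
    single ``"complex"`` column (bound concentration, M) for ideal data.
    """

    total_conc: float
    host_fraction: np.ndarray
    ordinate: pd.DataFrame
    noise_sd: float | None = None  # sd of the ordinate, same units as ordinate
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.host_fraction, dtype=float)
        object.__setattr__(self, "host_fraction", r)
        if np.any((r < 0) | (r > 1)):
            raise ValueError("host fractions must lie in [0, 1]")
        if np.any(np.diff(r) <= 0):
            raise ValueError("host fractions must be strictly increasing")
        if len(self.ordinate) != r.size:
            raise ValueError("ordinate and host_fraction lengths differ")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.ordinate.columns)


@dataclass(frozen=True)
class JobMaximum:
    """Located Job maximum with uncertainty and quality flags."""

    r_star: float
    uncertainty: float
    ordinate_max: float
    column: str
    flags: tuple[str, ...] = ()


def simulate_job(model: BindingModelSpec, sens: ShiftSensitivities | None,
                 total_conc: float, grid: Sequence[float]) -> JobDataset:
    """Simulate a noise-free continuous-variation experiment.

    At each host fraction r the speciation is solved at
    ``[H]_T = r * C_T``, ``[G]_T = (1 - r) * C_T``.  With ``sens`` given
    the ordinate is ddelta * [H]_T per proton; with ``sens=None`` it is
    the total complexed-guest-containing concentration (ideal data).  The
    ordinate is exactly zero at r = 0 and r = 1.
    """
    if not (total_conc > 0):
        raise ValueError("total_conc must be positive")
    r = np.asarray(grid, dtype=float)
    H = r * total_conc
    G = (1.0 - r) * total_conc
    interior = (r > 0) & (r < 1)

    if sens is None:
        y = np.zeros(r.size)
        for j in np.nonzero(interior)[0]:
            st = solve_speciation(model, H[j], G[j])
            y[j] = sum(c for lab, c in st.complex_conc.items()
                       if model[lab].guest_stoich > 0)
        ordinate = pd.DataFrame({"complex": y})
    else:
        cols = {p: np.zeros(r.size) for p in sens.proton_labels}
        idx = np.nonzero(interior)[0]
        if idx.size:
            dd = predict_shifts(model, sens, H[idx], G[idx])
            for p in sens.proton_labels:
                cols[p][idx] = dd[p].to_numpy() * H[idx]
        ordinate = pd.DataFrame(cols)

    return JobDataset(total_conc=float(total_conc), host_fraction=r,
                      ordinate=ordinate,
                      meta={"model": model.to_dict()})


def _quadratic_vertex(x: np.ndarray, y: np.ndarray,
                      noise_sd: float | None) -> tuple[float, float, float]:
    """Vertex of a local quadratic fit; returns (r*, se(r*), y(r*))."""
    coeffs, cov = np.polyfit(x, y, 2, cov=True)
    a, b, c = coeffs
    r_star = -b / (2.0 * a)
    y_star = np.polyval(coeffs, r_star)
    if noise_sd is not None and noise_sd > 0:
        # delta method: grad r* wrt (a, b) = (b / 2a^2, -1 / 2a)
        grad = np.array([b / (2.0 * a * a), -1.0 / (2.0 * a), 0.0])
        # rescale polyfit covariance to the known noise level
        dof = max(len(x) - 3, 1)
        resid = y - np.polyval(coeffs, x)
        s2 = np.sum(resid ** 2) / dof
        scale = (noise_sd ** 2) / s2 if s2 > 0 else 1.0
        var = float(grad @ (cov * scale) @ grad)
        se = math.sqrt(max(var, 0.0))
    else:
        se = 0.0
    return float(r_star), se, float(y_star)


def locate_job_maximum(data: JobDataset, column: str | None = None) -> JobMaximum:
    """Locate the Job maximum by a local quadratic around the grid argmax.

    The curve (|ordinate| of the chosen column; largest-amplitude column
    by default) is interpolated with a quadratic over
    :data:`QUAD_WINDOW` points centred on the grid argmax, so r* is not
    restricted to grid points.  A maximum at the grid boundary is flagged
    and returned without extrapolation; a flat-topped plateau is flagged
    and resolved to the plateau midpoint with the plateau half-width as
    its uncertainty.
    """
    r = data.host_fraction
    if r.size < 7:
        raise ValueError("at least 7 grid points are required to locate a maximum")
    if column is None:
        column = max(data.columns, key=lambda c: float(np.max(np.abs(data.ordinate[c]))))
    y = np.abs(data.ordinate[column].to_numpy(dtype=float))
    spacing = float(np.median(np.diff(r)))
    j = int(np.argmax(y))
    half = QUAD_WINDOW // 2

    if j < half or j > r.size - 1 - half:
        return JobMaximum(r_star=float(r[j]), uncertainty=spacing,
                          ordinate_max=float(y[j]), column=column,
                          flags=("boundary_maximum",))

    noise = data.noise_sd
    tol = noise if noise and noise > 0 else max(1e-12 * max(y.max(), 1e-300), 0.0)
    plateau = np.nonzero(y >= y[j] - tol)[0]
    # contiguous run containing the argmax
    lo = j
    while lo - 1 in plateau:
        lo -= 1
    hi = j
    while hi + 1 in plateau:
        hi += 1
    if hi - lo + 1 >= QUAD_WINDOW:
        mid = 0.5 * (r[lo] + r[hi])
        return JobMaximum(r_star=float(mid),
                          uncertainty=float(0.5 * (r[hi] - r[lo])),
                          ordinate_max=float(y[j]), column=column,
                          flags=("plateau",))

    sl = slice(j - half, j + half + 1)
    r_star, se, y_star = _quadratic_vertex(r[sl], y[sl], noise)
    unc = max(se, 0.0)
    flags: tuple[str, ...] = ()
    if not (r[sl][0] <= r_star <= r[sl][-1]):  # quadratic vertex escaped the window
        r_star = float(r[j])
        unc = spacing
        flags = ("vertex_outside_window",)
    return JobMaximum(r_star=r_star, uncertainty=unc,
                      ordinate_max=y_star, column=column, flags=flags)


@dataclass(frozen=True)
class JobVerdict:
    """Deviation verdict for a located Job maximum against the 1:1 null."""

    verdict: str  # "consistent" | "deviant" | "inconclusive"
    r_star: float
    deviation: float
    tolerance: float
    maximum: JobMaximum
    note: str

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "r_star": self.r_star,
            "deviation_from_half": self.deviation,
            "tolerance": self.tolerance,
            "flags": list(self.maximum.flags),
            "note": self.note,
        }


def job_deviation_report(data: JobDataset, column: str | None = None, *,
                         max_useful_uncertainty: float = 0.05) -> JobVerdict:
    """Compare the located maximum against the 1:1 expectation r = 0.5.

    Verdicts: "consistent" when |r* - 0.5| is within the combined grid and
    noise tolerance, "deviant" when it clearly exceeds it, and
    "inconclusive" when the location uncertainty is too large to decide
    (noisy or degenerate data).  Continuous-variation data are far more
    sensitive to non-1:1 species than titration curves because they scan
    a much wider [H]_0/[G]_0 ratio range.
    """
    mx = locate_job_maximum(data, column)
    spacing = float(np.median(np.diff(data.host_fraction)))
    dev = abs(mx.r_star - 0.5)
    tol = max(2.0 * mx.uncertainty, spacing)
    weak_signal = (data.noise_sd is not None and data.noise_sd > 0
                   and mx.ordinate_max < 5.0 * data.noise_sd)
    if weak_signal or mx.uncertainty > max_useful_uncertainty \
            or "boundary_maximum" in mx.flags:
        verdict = "inconclusive"
        note = ("binding signal below noise" if weak_signal
                else "maximum location too uncertain to assess stoichiometry")
    elif dev <= tol:
        verdict = "consistent"
        note = "maximum consistent with the 1:1 expectation r = 0.5"
    else:
        verdict = "deviant"
        note = ("maximum displaced from r = 0.5: deviation from a pure 1:1 "
                "binding model (non-1:1 species present)")
    return JobVerdict(verdict=verdict, r_star=mx.r_star, deviation=dev,
                      tolerance=tol, maximum=mx, note=note)
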