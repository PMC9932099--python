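"""Equilibrium speciation for host-guest binding models.

A binding model is a set of complex species ``H_m G_n`` with overall
formation constants ``beta = [HmGn] / ([H]^m [G]^n)``.  Given total
(analytical) host and guest concentrations, the free concentrations are
the root of the two coupled mass balances

    [H]_T = [H] + sum_s m_s beta_s [H]^m_s [G]^n_s
    [G]_T = [G] + sum_s n_s beta_s [H]^m_s [G]^n_s

All concentrations are molar; an association constant of a 1:1 species is
therefore in M^-1 (the reporting layer converts to mM^-1 where a table
convention calls for it).

The 1:1 case has the familiar closed-form quadratic solution
(:func:`solve_one_to_one`); the general solver (:func:`solve_speciation`)
uses a damped Newton iteration on log-concentrations with a bracketed
bisection fallback, so the two routes are independent and can be checked
against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ComplexSpecies",
    "BindingModelSpec",
    "SpeciationState",
    "SpeciationError",
    "solve_one_to_one",
    "solve_speciation",
    "speciate_schedule",
    "effective_one_to_one_constant",
    "one_to_one_model",
    "multi_orientation_model",
    "self_competitive_model",
    "host_guest2_model",
    "host2_guest_model",
]

#: Relative mass-balance tolerance demanded of a converged state.  Far
#: below chemical-shift noise; chosen so oracle comparisons are limited
#: by float arithmetic, not by the solver.
BALANCE_RTOL = 1e-12

_MAX_ITER = 200


class SpeciationError(RuntimeError):
    """Raised when the mass-balance solver fails to converge.

    Carries the scaled residuals of the best iterate for diagnosis.
    """

    def __init__(self, message: str, residuals: tuple[float, float] | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class ComplexSpecies:
    """One complex species ``H_m G_n`` with overall formation constant beta.

    ``beta`` has units M^-(m+n-1).  ``guest_stoich`` may be 0 for a
    guest-free host state (a self-included conformer when ``host_stoich``
    is 1, beta then dimensionless; a mutually self-included host pair when
    ``host_stoich`` is 2, beta in M^-1).
    """

    host_stoich: int
    guest_stoich: int
    beta: float
    label: str

    def __post_init__(self) -> None:
        if int(self.host_stoich) != self.host_stoich or self.host_stoich < 1:
            raise ValueError("host_stoich must be a positive integer")
        if int(self.guest_stoich) != self.guest_stoich or self.guest_stoich < 0:
            raise ValueError("guest_stoich must be a non-negative integer")
        if not (self.beta > 0) or not math.isfinite(self.beta):
            raise ValueError(f"beta must be positive and finite, got {self.beta!r}")
        if not self.label:
            raise ValueError("species label must be non-empty")

    @property
    def order(self) -> int:
        return self.host_stoich + self.guest_stoich

    def to_dict(self) -> dict:
        return {
            "host_stoich": self.host_stoich,
            "guest_stoich": self.guest_stoich,
            "beta": self.beta,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ComplexSpecies":
        return cls(
            host_stoich=int(d["host_stoich"]),
            guest_stoich=int(d["guest_stoich"]),
            beta=float(d["beta"]),
            label=str(d["label"]),
        )


@dataclass(frozen=True)
class BindingModelSpec:
    """A declarative equilibrium model: an ordered set of complex species.

    Every model must contain at least one 1:1 host:guest species (the
    primary inclusion complex); labels must be unique.
    """

    species: tuple[ComplexSpecies, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not self.species:
            raise ValueError("binding model must contain at least one species")
        labels = [s.label for s in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError(f"species labels must be unique, got {labels}")
        if not any(s.host_stoich == 1 and s.guest_stoich == 1 for s in self.species):
            raise ValueError("binding model must contain a 1:1 host:guest species")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.species)

    def __getitem__(self, label: str) -> ComplexSpecies:
        for s in self.species:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def constants(self) -> dict[str, float]:
        """Formation constants keyed by species label."""
        return {s.label: s.beta for s in self.species}

    def is_purely_one_to_one(self) -> bool:
        """True when every guest-containing species is 1:1 and no
        guest-free species is present."""
        return all(s.host_stoich == 1 and s.guest_stoich == 1 for s in self.species)

    def with_constants(self, constants: Mapping[str, float]) -> "BindingModelSpec":
        """Return a copy with the given species' betas replaced."""
        new = []
        for s in self.species:
            if s.label in constants:
                new.append(
                    ComplexSpecies(s.host_stoich, s.guest_stoich, float(constants[s.label]), s.label)
                )
            else:
                new.append(s)
        unknown = set(constants) - {s.label for s in self.species}
        if unknown:
            raise KeyError(f"unknown species labels: {sorted(unknown)}")
        return BindingModelSpec(tuple(new), self.name)

    def to_dict(self) -> dict:
        return {"name": self.name, "species": [s.to_dict() for s in self.species]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "BindingModelSpec":
        return cls(
            species=tuple(ComplexSpecies.from_dict(s) for s in d["species"]),
            name=str(d.get("name", "")),
        )


@dataclass(frozen=True)
class SpeciationState:
    """Free and complexed concentrations (M) at one composition."""

    free_host: float
    free_guest: float
    complex_conc: Mapping[str, float]
    total_host: float
    total_guest: float
    model: BindingModelSpec | None = field(default=None, compare=False)

    @property
    def bound_host(self) -> float:
        if self.model is None:
            return self.total_host - self.free_host
        return sum(self.model[lab].host_stoich * c for lab, c in self.complex_conc.items())

    @property
    def bound_guest(self) -> float:
        if self.model is None:
            return self.total_guest - self.free_guest
        return sum(self.model[lab].guest_stoich * c for lab, c in self.complex_conc.items())

    def host_balance_residual(self) -> float:
        """Relative host mass-balance defect."""
        scale = self.total_host if self.total_host > 0 else 1.0
        return (self.free_host + self.bound_host - self.total_host) / scale

    def guest_balance_residual(self) -> float:
        scale = self.total_guest if self.total_guest > 0 else 1.0
        return (self.free_guest + self.bound_guest - self.total_guest) / scale


# ---------------------------------------------------------------------------
# model factories

def one_to_one_model(K: float, name: str = "simple 1:1", label: str = "HG") -> BindingModelSpec:
    """Single 1:1 inclusion complex with association constant ``K`` (M^-1)."""
    return BindingModelSpec((ComplexSpecies(1, 1, K, label),), name)


def multi_orientation_model(constants: Sequence[float], name: str = "multi-orientation 1:1",
                            labels: Sequence[str] | None = None) -> BindingModelSpec:
    """Several distinct 1:1 bound states (e.g. guest-up / guest-down).

    In fast exchange this model is observationally degenerate with a
    single 1:1 model of constant ``sum(constants)``; it exists to make
    that degeneracy testable and to document why titration data alone
    cannot split orientation constants.
    """
    if labels is None:
        labels = [f"HG-{i + 1}" for i in range(len(constants))]
    sp = tuple(ComplexSpecies(1, 1, K, lab) for K, lab in zip(constants, labels, strict=True))
    return BindingModelSpec(sp, name)


def self_competitive_model(K_bind: float, K_self: float,
                           name: str = "self-competitive") -> BindingModelSpec:
    """Guest binding in competition with host self-inclusion.

    ``HG`` (constant ``K_bind``, M^-1) is the inclusion complex; ``H2``
    (constant ``K_self``, M^-1) is a host pair in which one host's pendant
    arm occupies the partner's cavity, so the host competes with the guest
    for its own binding site.  Because [H2] scales as [H]^2 while [HG]
    scales as [H][G], the two constants are separately identifiable from
    titration data, unlike a pair of 1:1 orientations.
    """
    return BindingModelSpec(
        (ComplexSpecies(1, 1, K_bind, "HG"), ComplexSpecies(2, 0, K_self, "H2")), name
    )


def host_guest2_model(K1: float, K2: float, name: str = "1:1 + 1:2") -> BindingModelSpec:
    """HG plus HG2 with stepwise constants K1, K2 (both M^-1)."""
    return BindingModelSpec(
        (ComplexSpecies(1, 1, K1, "HG"), ComplexSpecies(1, 2, K1 * K2, "HG2")), name
    )


def host2_guest_model(K1: float, K2: float, name: str = "1:1 + 2:1") -> BindingModelSpec:
    """HG plus H2G with stepwise constants K1, K2 (both M^-1)."""
    return BindingModelSpec(
        (ComplexSpecies(1, 1, K1, "HG"), ComplexSpecies(2, 1, K1 * K2, "H2G")), name
    )


# ---------------------------------------------------------------------------
# closed-form 1:1

def solve_one_to_one(total_host: float, total_guest: float, K: float) -> SpeciationState:
    """Closed-form 1:1 speciation.

    The complex concentration x = [HG] is the root of

        K x^2 - (K([H]_T + [G]_T) + 1) x + K [H]_T [G]_T = 0

    lying in [0, min([H]_T, [G]_T)].  Evaluated with the numerically
    stable quadratic formula (no subtractive cancellation).
    """
    if total_host < 0 or total_guest < 0:
        raise ValueError("total concentrations must be non-negative")
    if not (K > 0):
        raise ValueError("K must be strictly positive (use a no-binding model for K=0)")
    H, G = float(total_host), float(total_guest)
    if H == 0.0 or G == 0.0:
        x = 0.0
    else:
        b = K * (H + G) + 1.0
        disc = b * b - 4.0 * K * K * H * G
        # b > 0 always; the smaller root is the physical one
        x = 2.0 * K * H * G / (b + math.sqrt(disc))
        x = min(x, H, G)
    model = one_to_one_model(K)
    return SpeciationState(
        free_host=H - x,
        free_guest=G - x,
        complex_conc={"HG": x},
        total_host=H,
        total_guest=G,
        model=model,
    )


# ---------------------------------------------------------------------------
# general solver

def _complex_concs(ms, ns, betas, h: float, g: float) -> list[float]:
    return [b * h ** m * (g ** n if n else 1.0) for m, n, b in zip(ms, ns, betas)]


def _host_only_free(ms, betas_h, H: float) -> float:
    """Free host when no guest is present; only guest-free species bind host."""
    if not ms:
        return H

    def f(h: float) -> float:
        return h + sum(m * b * h ** m for m, b in zip(ms, betas_h)) - H

    if f(H) <= 0:
        return H
    lo = H * 1e-14
    while f(lo) > 0:
        lo *= 1e-4
        if lo < 1e-300:
            raise SpeciationError("host-only balance has no bracket")
    return brentq(f, lo, H, xtol=1e-300, rtol=8.9e-16, maxiter=300)


def _guest_given_host(ms, ns, betas, h: float, G: float) -> float:
    """Solve the guest balance for fixed free host (monotone in g)."""

    def f(g: float) -> float:
        return g + sum(n * b * h ** m * g ** n for m, n, b in zip(ms, ns, betas) if n) - G

    if f(G) <= 0:
        return G
    lo = G * 1e-14
    while f(lo) > 0:
        lo *= 1e-4
        if lo < 1e-300:
            raise SpeciationError("guest balance has no bracket")
    return brentq(f, lo, G, xtol=1e-300, rtol=8.9e-16, maxiter=300)


def _nested_bisection(ms, ns, betas, H: float, G: float) -> tuple[float, float]:
    """Robust fallback: outer bracketed root in free host, inner in free guest.

    Total bound host is increasing in free host at fixed totals, so the
    outer residual is monotone and brentq is guaranteed to converge.
    """

    def host_res(h: float) -> float:
        g = _guest_given_host(ms, ns, betas, h, G)
        return h + sum(m * b * h ** m * g ** n for m, n, b in zip(ms, ns, betas)) - H

    if host_res(H) <= 0:
        return H, _guest_given_host(ms, ns, betas, H, G)
    lo = H * 1e-14
    while host_res(lo) > 0:
        lo *= 1e-4
        if lo < 1e-300:
            raise SpeciationError("host balance has no bracket")
    h = brentq(host_res, lo, H, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    return h, _guest_given_host(ms, ns, betas, h, G)


def _newton_free(ms, ns, betas, H: float, G: float,
                 h0: float | None = None, g0: float | None = None) -> tuple[float, float]:
    """Damped Newton on (ln[H], ln[G]); falls back to nested bisection."""
    u = math.log(h0 if h0 and h0 > 0 else H * 0.5)
    v = math.log(g0 if g0 and g0 > 0 else G * 0.5)

    def residuals(u: float, v: float):
        h, g = math.exp(u), math.exp(v)
        F1 = h - H
        F2 = g - G
        J11 = h
        J12 = 0.0
        J22 = g
        for m, n, b in zip(ms, ns, betas):
            c = b * h ** m * (g ** n if n else 1.0)
            F1 += m * c
            F2 += n * c
            J11 += m * m * c
            J12 += m * n * c
            J22 += n * n * c
        return F1, F2, J11, J12, J22

    for _ in range(_MAX_ITER):
        F1, F2, J11, J12, J22 = residuals(u, v)
        r1 = F1 / H
        r2 = F2 / G
        if abs(r1) <= BALANCE_RTOL and abs(r2) <= BALANCE_RTOL:
            return math.exp(u), math.exp(v)
        det = J11 * J22 - J12 * J12
        if det <= 0 or not math.isfinite(det):
            break
        du = -(J22 * F1 - J12 * F2) / det
        dv = -(J11 * F2 - J12 * F1) / det
        # clamp the log-step to keep the iterate in a sane region
        step = max(abs(du), abs(dv))
        if step > 4.0:
            du *= 4.0 / step
            dv *= 4.0 / step
        # backtracking line search on the scaled residual norm
        lam = 1.0
        norm0 = math.hypot(r1, r2)
        for _bt in range(12):
            F1n, F2n, *_ = residuals(u + lam * du, v + lam * dv)
            if math.hypot(F1n / H, F2n / G) < norm0:
                break
            lam *= 0.5
        u += lam * du
        v += lam * dv
    return _nested_bisection(ms, ns, betas, H, G)


def _solve_free(model: BindingModelSpec, H: float, G: float,
                warm: tuple[float, float] | None = None) -> tuple[float, float]:
    ms = [s.host_stoich for s in model.species]
    ns = [s.guest_stoich for s in model.species]
    betas = [s.beta for s in model.species]
    if H == 0.0 and G == 0.0:
        return 0.0, 0.0
    if H == 0.0:
        # species all require host
        return 0.0, G
    if G == 0.0:
        ms0 = [m for m, n in zip(ms, ns) if n == 0]
        b0 = [b for b, n in zip(betas, ns) if n == 0]
        return _host_only_free(ms0, b0, H), 0.0
    h0, g0 = warm if warm is not None else (None, None)
    return _newton_free(ms, ns, betas, H, G, h0, g0)


def _state_from_free(model: BindingModelSpec, h: float, g: float,
                     H: float, G: float) -> SpeciationState:
    conc = {
        s.label: s.beta * h ** s.host_stoich * (g ** s.guest_stoich if s.guest_stoich else 1.0)
        for s in model.species
    }
    state = SpeciationState(h, g, conc, H, G, model=model)
    rh, rg = state.host_balance_residual(), state.guest_balance_residual()
    if abs(rh) > 1e-10 or abs(rg) > 1e-10:
        raise SpeciationError(
            f"speciation did not satisfy mass balance (residuals {rh:.2e}, {rg:.2e})",
            residuals=(rh, rg),
        )
    return state


def solve_speciation(model: BindingModelSpec, total_host: float, total_guest: float) -> SpeciationState:
    """Solve the coupled mass balances for an arbitrary binding model.

    Degenerate totals (0, 0) return the all-zero state.  Raises
    :class:`SpeciationError` (with residuals) on non-convergence.
    """
    if total_host < 0 or total_guest < 0:
        raise ValueError("total concentrations must be non-negative")
    H, G = float(total_host), float(total_guest)
    h, g = _solve_free(model, H, G)
    return _state_from_free(model, h, g, H, G)


def speciate_schedule(model: BindingModelSpec, total_host: Sequence[float],
                      total_guest: Sequence[float]) -> dict[str, np.ndarray]:
    """Species concentrations along a titration schedule.

    Returns arrays keyed by species label plus ``"free_host"`` and
    ``"free_guest"``.  Consecutive points warm-start the Newton iteration,
    which makes curve evaluation inside a fitter cheap.
    """
    H = np.asarray(total_host, dtype=float)
    G = np.asarray(total_guest, dtype=float)
    if H.shape != G.shape:
        raise ValueError("total_host and total_guest must have the same length")
    npts = H.size
    out = {s.label: np.empty(npts) for s in model.species}
    fh = np.empty(npts)
    fg = np.empty(npts)
    warm: tuple[float, float] | None = None
    for j in range(npts):
        h, g = _solve_free(model, H[j], G[j], warm=warm)
        warm = (h, g) if h > 0 and g > 0 else None
        fh[j] = h
        fg[j] = g
        for s in model.species:
            out[s.label][j] = s.beta * h ** s.host_stoich * (g ** s.guest_stoich if s.guest_stoich else 1.0)
    out["free_host"] = fh
    out["free_guest"] = fg
    return out


def effective_one_to_one_constant(model: BindingModelSpec) -> float | None:
    """Effective 1:1 constant of a speciation-degenerate model, if any.

    A model whose guest-containing species are all 1:1 is observationally
    a single 1:1 system.  Without guest-free species the effective
    constant is the sum of the 1:1 constants; with monomeric guest-free
    conformers (beta dimensionless) the open-host fraction dilutes it:

        K_eff = sum(K_s) / (1 + sum(beta_conformer))

    Returns ``None`` when the model is not reducible (any species with
    host_stoich > 1 or guest_stoich > 1).
    """
    ksum = 0.0
    conf = 0.0
    for s in model.species:
        if s.guest_stoich == 0:
            if s.host_stoich != 1:
                return None
            conf += s.beta
        elif s.host_stoich == 1 and s.guest_stoich == 1:
            ksum += s.beta
        else:
            return None
    return ksum / (1.0 + conf)
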