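"""Fast-exchange chemical-shift prediction and global binding-constant fitting.

Under fast exchange each reporter proton shows a single population-weighted
resonance, so the referenced shift change of proton *i* at a titration
point is

    ddelta_i = sum_s ddelta_c,s,i * (c_s - c_s0) / [H]_T

where ``c_s`` is the concentration of complex species *s*, ``c_s0`` its
concentration in the guest-free sample at the same total host (non-zero
only for guest-free host states), and ``ddelta_c,s,i`` the limiting shift
change of proton *i* in state *s*.  Referencing against the guest-free
first titration point is built into the prediction, matching the
experimental convention of subtracting the host-only spectrum.

Fitting is global: a single set of binding constants is shared across all
reporter protons, each proton contributing its own sensitivity per bound
state.  Constants are fitted in log space (positivity by construction)
with trust-region least squares; standard errors come from the
Gauss-Newton covariance at the optimum and the full parameter correlation
matrix is reported, because multi-state isotherm fits are notoriously
ill-conditioned and the correlation structure is part of the result.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from .speciation import (
    BindingModelSpec,
    SpeciationError,
    speciate_schedule,
)

__all__ = [
    "TitrationDataset",
    "ShiftSensitivities",
    "GlobalFitResult",
    "ReplicateSummary",
    "AdequacyReport",
    "FitError",
    "reference_shifts",
    "predict_shifts",
    "fit_global",
    "fit_two_state",
    "aggregate_replicates",
    "model_adequacy",
    "TWO_STATE_VARIANTS",
]

#: Soft bounds for a bimolecular association constant (M^-1); an overall
#: beta of order (m+n-1) gets these bounds raised to that power.
K_BOUNDS = (1e-2, 1e9)

#: Bound on |ddelta_c| (ppm): complexation-induced shifts of CD reporter
#: protons are at most a few tenths of a ppm.
DD_BOUND = 1.0

_FIRST_POINT_ATOL = 1e-12


class FitError(RuntimeError):
    """Raised when a fit cannot be run or did not converge.

    ``best_result`` (when present) carries the best-so-far parameters and
    diagnostics.
    """

    def __init__(self, message: str, best_result=None):
        super().__init__(message)
        self.best_result = best_result


@dataclass(frozen=True)
class TitrationDataset:
    """One titration: a ([H]_T, [G]_T) schedule with referenced shift
    changes for each reporter proton.

    The first point is the guest-free reference ([G]_T = 0, all shift
    changes exactly 0); total guest is strictly increasing.
    """

    total_host: np.ndarray
    total_guest: np.ndarray
    shifts: pd.DataFrame  # rows = points, columns = proton labels, ppm
    temperature: float = 303.15
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        th = np.asarray(self.total_host, dtype=float)
        tg = np.asarray(self.total_guest, dtype=float)
        object.__setattr__(self, "total_host", th)
        object.__setattr__(self, "total_guest", tg)
        n = len(tg)
        if th.shape != (n,) or len(self.shifts) != n:
            raise ValueError("total_host, total_guest and shifts must have equal length")
        if n < 2:
            raise ValueError("a titration needs at least a reference point and one addition")
        if tg[0] != 0.0:
            raise ValueError("first titration point must be guest-free ([G]_T = 0)")
        if np.any(np.diff(tg) <= 0):
            raise ValueError("total_guest must be strictly increasing")
        if np.any(th <= 0):
            raise ValueError("total_host must be positive at every point")
        if np.any(np.abs(self.shifts.iloc[0].to_numpy(dtype=float)) > _FIRST_POINT_ATOL):
            raise ValueError("shift changes at the guest-free first point must be zero")

    @property
    def proton_labels(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.shifts.columns)

    @property
    def n_points(self) -> int:
        return len(self.total_guest)


@dataclass(frozen=True)
class ShiftSensitivities:
    """Limiting shift changes ddelta_c (ppm): proton -> species -> value.

    Signs are unconstrained (upfield and downfield changes both occur).
    """

    values: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        frozen = {p: dict(sp) for p, sp in self.values.items()}
        for p, sp in frozen.items():
            for s, v in sp.items():
                if not math.isfinite(float(v)):
                    raise ValueError(f"sensitivity for proton {p!r}, species {s!r} is not finite")
        object.__setattr__(self, "values", frozen)

    @property
    def proton_labels(self) -> tuple[str, ...]:
        return tuple(self.values)

    def get(self, proton: str, species: str) -> float:
        return float(self.values.get(proton, {}).get(species, 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values).T  # rows = protons, cols = species

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ShiftSensitivities":
        return cls({str(p): {str(s): float(frame.loc[p, s]) for s in frame.columns}
                    for p in frame.index})


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-constant mean and sample standard deviation across replicates."""

    constants: pd.DataFrame  # rows = species labels, columns = mean, sd
    n_replicates: int
    model_name: str = ""


# ---------------------------------------------------------------------------
# referencing

def reference_shifts(raw_shifts: pd.DataFrame,
                     reference_observed: Sequence[float] | None = None,
                     reference_ppm: float = 2.014) -> pd.DataFrame:
    """Convert raw shifts to referenced shift changes.

    Each point is first corrected against the internal reference compound
    (observed position ``reference_observed``, true position
    ``reference_ppm``, conventionally acetonitrile at 2.014 ppm); the
    corrected first-point (host-only) shift is then subtracted, so the
    first row is exactly zero by construction.
    """
    raw = raw_shifts.astype(float)
    if len(raw) == 0 or raw.iloc[0].isna().any():
        raise ValueError("first (host-only) point must be present for every proton")
    if reference_observed is not None:
        corr = np.asarray(reference_observed, dtype=float) - reference_ppm
        if corr.shape != (len(raw),):
            raise ValueError("reference_observed must have one value per titration point")
        raw = raw.sub(corr, axis=0)
    out = raw - raw.iloc[0]
    out.iloc[0] = 0.0
    return out


# ---------------------------------------------------------------------------
# prediction

def _conc_matrix(model: BindingModelSpec, total_host: np.ndarray,
                 total_guest: np.ndarray) -> dict[str, np.ndarray]:
    """Referenced species concentrations c_s - c_s0 along a schedule."""
    conc = speciate_schedule(model, total_host, total_guest)
    needs_baseline = any(s.guest_stoich == 0 for s in model.species)
    out: dict[str, np.ndarray] = {}
    if needs_baseline:
        base = speciate_schedule(model, total_host, np.zeros_like(total_host))
        for s in model.species:
            out[s.label] = conc[s.label] - base[s.label]
    else:
        for s in model.species:
            out[s.label] = conc[s.label]
    return out


def predict_shifts(model: BindingModelSpec, sens: ShiftSensitivities,
                   total_host: Sequence[float], total_guest: Sequence[float]) -> pd.DataFrame:
    """Fast-exchange shift changes (ppm) for each proton along a schedule.

    Zero at guest-free points by construction; for a single 1:1 species
    the large-guest limit is the per-proton sensitivity itself.
    """
    H = np.asarray(total_host, dtype=float)
    G = np.asarray(total_guest, dtype=float)
    if np.any(H <= 0):
        raise ValueError("total_host must be positive at every point (host is the observed species)")
    dconc = _conc_matrix(model, H, G)
    protons = sens.proton_labels
    pred = np.zeros((H.size, len(protons)))
    for k, s in enumerate(model.species):
        col = dconc[s.label] / H
        for i, p in enumerate(protons):
            d = sens.get(p, s.label)
            if d != 0.0:
                pred[:, i] += d * col
    return pd.DataFrame(pred, columns=list(protons))


# ---------------------------------------------------------------------------
# global fitting

def _pname(label: str) -> str:
    return re.sub(r"\W", "_", label)


@dataclass
class GlobalFitResult:
    """Result of a global multi-proton fit.

    ``std_errors`` are Gauss-Newton standard errors keyed by readable
    parameter names (``K_<species>`` on the constant's own scale,
    ``dd_<proton>_<species>`` in ppm); ``correlation`` is the full
    parameter correlation matrix on the internal (log-constant) scale.
    """

    model: BindingModelSpec
    sensitivities: ShiftSensitivities
    std_errors: dict[str, float]
    correlation: pd.DataFrame
    rss: float
    converged: bool
    rank_deficient: bool
    flags: list[str]
    fitted_curves: pd.DataFrame
    data: TitrationDataset
    nvarys: int
    ndata: int
    redchi: float

    @property
    def constants(self) -> dict[str, float]:
        return self.model.constants

    @property
    def constant_errors(self) -> dict[str, float]:
        return {lab: self.std_errors.get(f"K_{_pname(lab)}", float("nan"))
                for lab in self.model.labels}

    @property
    def max_correlation(self) -> float:
        c = self.correlation.to_numpy(dtype=float)
        if c.size <= 1 or np.isnan(c).all():
            return float("nan")
        off = c[~np.eye(len(c), dtype=bool)]
        return float(np.nanmax(np.abs(off))) if off.size else float("nan")

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "constants_M": self.constants,
            "constants_mM": {k: v / 1e3 for k, v in self.constants.items()},
            "constant_std_errors_M": self.constant_errors,
            "sensitivities_ppm": {p: dict(sp) for p, sp in self.sensitivities.values.items()},
            "std_errors": self.std_errors,
            "correlation": self.correlation.to_dict(),
            "max_abs_correlation": None if math.isnan(self.max_correlation) else self.max_correlation,
            "rss": self.rss,
            "redchi": self.redchi,
            "converged": self.converged,
            "rank_deficient": self.rank_deficient,
            "flags": list(self.flags),
            "nvarys": self.nvarys,
            "ndata": self.ndata,
        }


def _initial_guesses(data: TitrationDataset, model: BindingModelSpec) -> tuple[dict, dict]:
    """Heuristic starting values.

    The primary constant is taken from the half-saturation point of the
    largest-amplitude proton (K ~ 1/[G]_T at half-maximal shift change);
    secondary constants start a factor 20 lower.  Sensitivities of the
    primary species start at the last-point value corrected by the
    estimated bound fraction there.
    """
    shifts = data.shifts.to_numpy(dtype=float)
    amps = np.max(np.abs(shifts), axis=0)
    ip = int(np.argmax(amps))
    amp = amps[ip]
    G = data.total_guest
    if amp > 0:
        half = np.nonzero(np.abs(shifts[:, ip]) >= 0.5 * amp)[0]
        g_half = G[half[0]] if half.size and G[half[0]] > 0 else G[-1]
    else:
        g_half = G[-1]
    K0 = float(np.clip(1.0 / g_half, *K_BOUNDS))
    bf = K0 * G[-1] / (1.0 + K0 * G[-1])

    primary = next(s for s in model.species if s.host_stoich == 1 and s.guest_stoich == 1)
    constants: dict[str, float] = {}
    sens: dict[str, dict[str, float]] = {p: {} for p in data.proton_labels}
    for s in model.species:
        order = s.order - 1
        if s.label == primary.label:
            constants[s.label] = K0
        else:
            constants[s.label] = (K0 / 20.0) ** max(order, 1)
        for i, p in enumerate(data.proton_labels):
            if s.label == primary.label:
                sens[p][s.label] = float(shifts[-1, i] / max(bf, 1e-3))
            else:
                sens[p][s.label] = 0.01
    return constants, sens


def _make_params(model: BindingModelSpec, constants: Mapping[str, float],
                 sens: Mapping[str, Mapping[str, float]],
                 protons: Sequence[str]) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for s in model.species:
        order = s.order - 1
        lo, hi = (K_BOUNDS[0] ** order, K_BOUNDS[1] ** order) if order >= 1 else K_BOUNDS
        val = float(np.clip(constants[s.label], lo * 1.0001, hi * 0.9999))
        params.add(f"lnb_{_pname(s.label)}", value=math.log(val),
                   min=math.log(lo), max=math.log(hi))
    for p in protons:
        for s in model.species:
            # |ddelta_c| beyond ~1 ppm is unphysical for CD ring protons;
            # the bound blocks the K->0, sensitivity->infinity collapse mode
            val = float(np.clip(sens[p][s.label], -DD_BOUND + 1e-6, DD_BOUND - 1e-6))
            params.add(f"dd_{_pname(p)}__{_pname(s.label)}",
                       value=val, min=-DD_BOUND, max=DD_BOUND)
    return params


def _unpack(params: Mapping, model: BindingModelSpec, protons: Sequence[str]):
    constants = {s.label: math.exp(float(params[f"lnb_{_pname(s.label)}"])) for s in model.species}
    sens = {p: {s.label: float(params[f"dd_{_pname(p)}__{_pname(s.label)}"]) for s in model.species}
            for p in protons}
    return constants, sens


def _numeric_jacobian(fun, x: np.ndarray, rel: float = 1e-6) -> np.ndarray:
    f0 = fun(x)
    J = np.empty((f0.size, x.size))
    for k in range(x.size):
        h = rel * max(abs(x[k]), 1.0)
        xp = x.copy(); xp[k] += h
        xm = x.copy(); xm[k] -= h
        J[:, k] = (fun(xp) - fun(xm)) / (2 * h)
    return J


def fit_global(data: TitrationDataset, model: BindingModelSpec,
               init: Mapping | None = None, *,
               proton_sigmas: Mapping[str, float] | None = None,
               corr_flag_threshold: float = 0.95) -> GlobalFitResult:
    """Global nonlinear least squares across all reporter protons.

    A single set of binding constants is shared by every proton; each
    proton carries one sensitivity per complex species.  Points are
    weighted equally unless per-proton sigmas are given.  The guest-free
    reference point carries no information (its residual is identically
    zero) and is excluded from the residual vector.

    ``init`` may supply ``{"constants": {label: K}, "sensitivities":
    {proton: {label: ppm}}}``; missing entries fall back to the built-in
    heuristics.  Raises :class:`FitError` on non-convergence with the
    best-so-far result attached.
    """
    protons = data.proton_labels
    nvarys = len(model.species) * (1 + len(protons))
    nobs = (data.n_points - 1) * len(protons)
    if nobs < nvarys + 2:
        raise FitError(f"too few observations ({nobs}) for {nvarys} free parameters")

    c0, s0 = _initial_guesses(data, model)
    if init:
        for lab, v in (init.get("constants") or {}).items():
            c0[lab] = float(v)
        for p, sp in (init.get("sensitivities") or {}).items():
            for lab, v in sp.items():
                s0[p][lab] = float(v)
    params = _make_params(model, c0, s0, protons)

    obs = data.shifts.to_numpy(dtype=float)[1:, :]
    H, G = data.total_host, data.total_guest
    if proton_sigmas is None:
        w = np.ones(len(protons))
    else:
        w = np.array([1.0 / float(proton_sigmas[p]) for p in protons])

    def residual(pars) -> np.ndarray:
        constants, sens = _unpack(pars, model, protons)
        try:
            pred = predict_shifts(model.with_constants(constants),
                                  ShiftSensitivities(sens), H, G).to_numpy()
        except SpeciationError as exc:  # pragma: no cover - defensive
            raise FitError(f"speciation failed during fitting: {exc}") from exc
        return ((pred[1:, :] - obs) * w).ravel()

    mini = lmfit.Minimizer(residual, params)
    result = mini.minimize(method="least_squares",
                           ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=20000)

    constants, sens = _unpack(result.params, model, protons)
    fitted_model = model.with_constants(constants)
    fitted_sens = ShiftSensitivities(sens)

    # diagnostics: Jacobian at the optimum on the internal parameter scale
    varnames = list(result.params.keys())
    xopt = np.array([result.params[n].value for n in varnames])

    def res_of_x(x: np.ndarray) -> np.ndarray:
        pars = {n: v for n, v in zip(varnames, x)}
        return residual(pars)

    J = _numeric_jacobian(res_of_x, xopt)
    sv = np.linalg.svd(J, compute_uv=False)
    rank_deficient = bool(sv[0] == 0 or sv[-1] / sv[0] < 1e-8)

    flags: list[str] = []
    if rank_deficient:
        flags.append("rank_deficient: parameters are not all identifiable from these data "
                     "(degenerate model or insufficient curvature); standard errors are "
                     "computed on the identifiable subspace and meaningless for the "
                     "null directions")

    # Gauss-Newton covariance at the optimum.  Directions below the rank
    # cutoff carry no information: their variance is infinite (never the
    # zero a plain pseudo-inverse would imply).
    r0 = res_of_x(xopt)
    rss_now = float(np.sum(r0 ** 2))
    dof = max(r0.size - xopt.size, 1)
    s2 = rss_now / dof
    U, S, Vt = np.linalg.svd(J, full_matrices=False)
    keep = S > 1e-8 * S[0] if S[0] > 0 else np.zeros_like(S, dtype=bool)
    V = Vt.T
    var = s2 * (V[:, keep] ** 2 / S[keep] ** 2).sum(axis=1)
    null_weight = (V[:, ~keep] ** 2).sum(axis=1)
    var = np.where(null_weight > 1e-12, np.inf, var)
    cov = s2 * (V[:, keep] / S[keep] ** 2) @ V[:, keep].T
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        cmat = cov / np.outer(sd, sd)
    np.fill_diagonal(cmat, 1.0)
    corr = pd.DataFrame(cmat, index=varnames, columns=varnames)
    std_errors: dict[str, float] = {}
    for n, s_ in zip(varnames, sd):
        if n.startswith("lnb_"):
            lab = n[len("lnb_"):]
            val = math.exp(result.params[n].value)
            std_errors[f"K_{lab}"] = val * s_
        else:
            std_errors[n.replace("__", "_")] = s_
    off = cmat[~np.eye(len(cmat), dtype=bool)]
    maxc = float(np.nanmax(np.abs(off))) if off.size else 0.0
    if maxc > corr_flag_threshold:
        flags.append(f"high_parameter_correlation: max |corr| = {maxc:.3f} > "
                     f"{corr_flag_threshold}; fitted constants are less robust")

    fitted_curves = predict_shifts(fitted_model, fitted_sens, H, G)
    fitted_curves.columns = list(protons)

    out = GlobalFitResult(
        model=fitted_model,
        sensitivities=fitted_sens,
        std_errors=std_errors,
        correlation=corr,
        rss=float(np.sum(residual(result.params) ** 2)),
        converged=bool(result.success),
        rank_deficient=rank_deficient,
        flags=flags,
        fitted_curves=fitted_curves,
        data=data,
        nvarys=result.nvarys,
        ndata=result.ndata,
        redchi=float(result.redchi),
    )
    if not result.success:
        raise FitError(f"global fit did not converge: {result.message}", best_result=out)
    return out


# ---------------------------------------------------------------------------
# two-state ("self-competitive") fitting

from .speciation import (  # noqa: E402  (grouped with their consumer)
    host2_guest_model,
    host_guest2_model,
    self_competitive_model,
)

#: Shipped non-degenerate two-state variants.  Each maps (K1, K2) ->
#: BindingModelSpec; K1 is always the primary 1:1 inclusion constant.
TWO_STATE_VARIANTS = {
    "self-competitive": self_competitive_model,
    "HG2": host_guest2_model,
    "H2G": host2_guest_model,
}

_SECONDARY_LABEL = {"self-competitive": "H2", "HG2": "HG2", "H2G": "H2G"}


def _stepwise_constants(variant: str, fitted: Mapping[str, float]) -> tuple[float, float]:
    K1 = fitted["HG"]
    lab = _SECONDARY_LABEL[variant]
    if variant == "self-competitive":
        K2 = fitted[lab]
    else:  # overall beta = K1 * K2
        K2 = fitted[lab] / K1
    return K1, K2


def fit_two_state(data: TitrationDataset, variant: str = "self-competitive",
                  init: Mapping | None = None, *,
                  population_threshold: float = 0.05,
                  proton_sigmas: Mapping[str, float] | None = None) -> GlobalFitResult:
    """Fit a two-constant extension of the 1:1 model.

    Variants (all identifiable, unlike a pair of 1:1 orientations):

    - ``"self-competitive"``: HG inclusion (K1) in competition with a
      mutually self-included host pair H2 (K2) -- the host's own pendant
      arms compete with the guest for the cavity.
    - ``"HG2"``: 1:1 plus 1:2 host:guest, stepwise K1, K2.
    - ``"H2G"``: 1:1 plus 2:1 host:guest, stepwise K1, K2.

    Both constants are reported in M^-1.  Note that which microscopic
    state (e.g. guest orientation) each constant belongs to cannot be
    decided from titration data alone; external evidence (ROESY contacts,
    simulation) is required for physical assignment.  A flag is raised
    when the secondary state's population never exceeds
    ``population_threshold`` (default 5%), in which case its constant is
    weakly determined.
    """
    if variant not in TWO_STATE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(TWO_STATE_VARIANTS)}")
    init = dict(init or {})
    c0 = init.pop("constants", None)
    if c0 is None:
        base_c, _ = _initial_guesses(data, TWO_STATE_VARIANTS[variant](1.0, 1.0))
        K1_0 = base_c["HG"]
        model0 = TWO_STATE_VARIANTS[variant](K1_0, K1_0 / 20.0)
    else:
        model0 = TWO_STATE_VARIANTS[variant](float(c0["K1"]), float(c0["K2"]))

    res = fit_global(data, model0, init or None, proton_sigmas=proton_sigmas)

    K1, K2 = _stepwise_constants(variant, res.constants)
    sec = _SECONDARY_LABEL[variant]
    conc = speciate_schedule(res.model, data.total_host, data.total_guest)
    m_sec = res.model[sec].host_stoich
    pop = np.max(m_sec * conc[sec] / data.total_host)
    if pop < population_threshold:
        res.flags.append(
            f"low_secondary_population: state {sec!r} never exceeds "
            f"{population_threshold:.0%} of total host (max {pop:.2%}); "
            f"its constant is weakly determined")
    res.flags.append("orientation_assignment_external: mapping of K1/K2 to physical "
                     "bound states requires ROESY or simulation evidence")
    res.data.meta.setdefault("two_state", {})
    res.data.meta["two_state"] = {
        "variant": variant,
        "K1_M": max(K1, K2) if variant != "self-competitive" else K1,
        "K2_M": min(K1, K2) if variant != "self-competitive" else K2,
        "secondary_max_population": float(pop),
    }
    return res


def two_state_constants(result: GlobalFitResult) -> tuple[float, float]:
    """(K1, K2) in M^-1 from a :func:`fit_two_state` result."""
    ts = result.data.meta.get("two_state")
    if not ts:
        raise ValueError("result does not come from fit_two_state")
    return ts["K1_M"], ts["K2_M"]


# ---------------------------------------------------------------------------
# replicate aggregation

def _model_signature(model: BindingModelSpec):
    return tuple((s.host_stoich, s.guest_stoich, s.label) for s in model.species)


def aggregate_replicates(results: Sequence[GlobalFitResult]) -> ReplicateSummary:
    """Mean and sample standard deviation (n-1) of each fitted constant
    across replicate titrations, the study's headline uncertainty."""
    if len(results) < 2:
        raise ValueError("at least 2 replicate fits are required for a standard deviation")
    sig = _model_signature(results[0].model)
    for r in results[1:]:
        if _model_signature(r.model) != sig:
            raise ValueError("replicates were fitted with different models")
    rows = {}
    for lab in results[0].model.labels:
        vals = np.array([r.constants[lab] for r in results])
        rows[lab] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1))}
    return ReplicateSummary(
        constants=pd.DataFrame(rows).T[["mean", "sd"]],
        n_replicates=len(results),
        model_name=results[0].model.name,
    )


# ---------------------------------------------------------------------------
# model adequacy

@dataclass(frozen=True)
class AdequacyReport:
    """Verdict on whether the simple 1:1 model describes a titration."""

    verdict: str  # "simple_adequate" | "two_state_preferred" | "no_binding"
    per_proton: pd.DataFrame  # columns: amplitude, noise_sd, non_monotonic
    rss_simple: float
    rss_two_state: float | None
    rss_ratio: float | None
    messages: list[str]

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "per_proton": self.per_proton.to_dict(),
            "rss_simple": self.rss_simple,
            "rss_two_state": self.rss_two_state,
            "rss_ratio": self.rss_ratio,
            "messages": list(self.messages),
        }


#: A simple 1:1 fit is declared inadequate when its residual sum of
#: squares exceeds the two-state model's by this factor.
RSS_PREFERENCE_FACTOR = 2.0


def _diff_noise_sd(d: np.ndarray) -> float:
    """Noise of successive differences via the median absolute deviation."""
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad)


def model_adequacy(data: TitrationDataset, fit_simple: GlobalFitResult,
                   fit_two: GlobalFitResult | None = None, *,
                   z_threshold: float = 3.0) -> AdequacyReport:
    """Diagnose whether the simple 1:1 model holds.

    A proton is flagged non-monotonic when its successive shift-change
    differences include moves beyond ``z_threshold`` noise sd in *both*
    directions (noise sd estimated from the first-difference MAD).  The
    simple model is declared inadequate when any proton is non-monotonic
    or its residuals exceed the two-state model's by
    :data:`RSS_PREFERENCE_FACTOR`.  When the simple fit explains no more
    variance than the zero model (F-test, alpha = 0.01), neither model is
    supported ("no_binding": K consistent with 0).
    """
    from scipy.stats import f as f_dist

    msgs: list[str] = []
    # noise floor of the successive differences: per-proton MAD estimates,
    # pooled by taking the minimum -- spectrometer noise is common to all
    # peaks of a spectrum while binding signal only inflates the estimate
    per_sd = {p: _diff_noise_sd(np.diff(data.shifts[p].to_numpy(dtype=float)))
              for p in data.proton_labels}
    positive = [s for s in per_sd.values() if s > 0]
    sd_d = min(positive) if positive else 0.0

    rows = {}
    any_nonmono = False
    for p in data.proton_labels:
        y = data.shifts[p].to_numpy(dtype=float)
        d = np.diff(y)
        amp = float(np.max(np.abs(y)))
        eff = sd_d if sd_d > 0 else max(amp * 1e-12, 1e-15)
        up = np.any(d > z_threshold * eff)
        down = np.any(d < -z_threshold * eff)
        nonmono = bool(up and down)
        any_nonmono |= nonmono
        rows[p] = {"amplitude_ppm": amp,
                   "noise_sd_ppm": sd_d / math.sqrt(2.0),
                   "non_monotonic": nonmono}
    per_proton = pd.DataFrame(rows).T

    rss_two = fit_two.rss if fit_two is not None else None
    ratio = (fit_simple.rss / rss_two) if rss_two not in (None, 0.0) else None

    # does the fitted binding model beat "no binding at all"?
    y_all = data.shifts.to_numpy(dtype=float)[1:, :].ravel()
    rss0 = float(np.sum(y_all ** 2))
    p_fit = fit_simple.nvarys
    dof = max(y_all.size - p_fit, 1)
    if fit_simple.rss <= 0:
        p_value = 0.0
    elif rss0 <= fit_simple.rss:
        p_value = 1.0
    else:
        F = ((rss0 - fit_simple.rss) / p_fit) / (fit_simple.rss / dof)
        p_value = float(f_dist.sf(F, p_fit, dof))
    any_signal = p_value < 0.01

    if not any_signal:
        verdict = "no_binding"
        msgs.append("no proton moves beyond noise; binding constant consistent with 0")
    elif any_nonmono or (ratio is not None and ratio > RSS_PREFERENCE_FACTOR):
        verdict = "two_state_preferred"
        if any_nonmono:
            msgs.append("non-monotonic reporter-proton behaviour: the simple 1:1 model "
                        "does not hold")
        if ratio is not None and ratio > RSS_PREFERENCE_FACTOR:
            msgs.append(f"simple-model residuals exceed the two-state model's by "
                        f"x{ratio:.1f} (threshold x{RSS_PREFERENCE_FACTOR})")
    else:
        verdict = "simple_adequate"
        msgs.append("all reporter protons monotonic within noise; simple 1:1 model adequate")

    return AdequacyReport(
        verdict=verdict,
        per_proton=per_proton,
        rss_simple=fit_simple.rss,
        rss_two_state=rss_two,
        rss_ratio=ratio,
        messages=msgs,
    )
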