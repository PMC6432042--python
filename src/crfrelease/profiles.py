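"""Time-domain outputs: release curves, release times, concentration fields.

All time-domain quantities are obtained by Zakian inversion of the
Laplace-domain solution at each requested dimensionless time tau > 0;
values at tau = 0 come from the initial conditions (theta_m = 1,
theta_f = theta_e = 0), never from the inversion formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .laplace import LaplaceSolution
from .params import DEFAULT_MODE, DimensionlessParams, check_mode
from .zakian import invert

__all__ = [
    "NoConvergenceError",
    "ReleaseProfile",
    "ConcentrationField",
    "Scenario",
    "theta_e_inf",
    "theta_e_at",
    "cumulative_release",
    "release_time",
    "film_concentration",
    "core_concentration",
    "reaction_limit",
    "t_max",
    "reference_scenarios",
]


class NoConvergenceError(RuntimeError):
    """A release-time search did not reach its target within the ceiling."""


def theta_e_inf(params: DimensionlessParams, variant: str = "literal") -> float:
    """Equilibrium (reaction-free) bath concentration theta_e(infinity).

    variant="literal" (default) uses

        1 / (Ka*Kb + (l**3 - 1)/Kb + Vr*l**3)

    the form in which the equilibrium is usually quoted for this model.
    variant="conservation" replaces the Ka*Kb term by Ka/Kb, the form a
    direct mass balance over core, film and bath yields; the two coincide
    whenever Ka = Kb = 1 (as in all bundled scenarios).  The hydrolysis
    source is excluded: at long times the autocatalytic reaction no longer
    contributes to the releasable inventory, so cumulative release is
    normalized by the reaction-free equilibrium regardless of kappa.
    """
    Ka, Kb, l, Vr = params.Ka, params.Kb, params.l, params.Vr
    if variant == "literal":
        lead = Ka * Kb
    elif variant == "conservation":
        lead = Ka / Kb
    else:
        raise ValueError(f"unknown theta_e_inf variant {variant!r}")
    return 1.0 / (lead + (l ** 3 - 1.0) / Kb + Vr * l ** 3)


def theta_e_at(tau: float, params: DimensionlessParams,
               mode: str = DEFAULT_MODE) -> float:
    """Bath concentration theta_e(tau) by Zakian inversion (tau > 0)."""
    sol = LaplaceSolution(params, mode)
    return invert(sol.theta_e, tau)


@dataclass
class ReleaseProfile:
    """Cumulative-release curve on an ascending tau grid.

    ``g = theta_e / theta_e(infinity)`` is the released fraction Mt/Minf;
    it runs from 0 to 1 up to small inversion noise (clipped on export
    only, never in the stored values).
    """

    tau: np.ndarray
    theta_e: np.ndarray
    g: np.ndarray
    params: DimensionlessParams
    mode: str

    def g_clipped(self) -> np.ndarray:
        return np.clip(self.g, 0.0, 1.0)


@dataclass
class ConcentrationField:
    """Dimensionless concentration on an eta x tau grid for one region."""

    eta: np.ndarray
    tau: np.ndarray
    values: np.ndarray          # shape (len(eta), len(tau))
    region: str                 # "core" | "film"
    params: DimensionlessParams
    mode: str


def _check_tau_grid(tau_grid) -> np.ndarray:
    tau = np.asarray(tau_grid, dtype=float)
    if tau.ndim != 1 or tau.size == 0:
        raise ValueError("tau grid must be a non-empty 1-D array")
    if np.any(tau <= 0):
        raise ValueError("tau grid entries must be > 0 "
                         "(tau = 0 belongs to the initial conditions)")
    if np.any(np.diff(tau) <= 0):
        raise ValueError("tau grid must be strictly ascending")
    return tau


def cumulative_release(tau_grid, params: DimensionlessParams,
                       mode: str = DEFAULT_MODE) -> ReleaseProfile:
    """Invert theta_e_bar on a tau grid and normalize by theta_e(infinity)."""
    check_mode(mode)
    tau = _check_tau_grid(tau_grid)
    sol = LaplaceSolution(params, mode)
    te_inf = theta_e_inf(params)
    theta_e = np.empty_like(tau)
    for i, t in enumerate(tau):
        try:
            theta_e[i] = invert(sol.theta_e, t)
        except Exception as exc:
            raise RuntimeError(f"Laplace inversion failed at tau={t}") from exc
        if not math.isfinite(theta_e[i]):
            raise RuntimeError(f"Laplace inversion returned non-finite "
                               f"value at tau={t}")
    return ReleaseProfile(tau=tau, theta_e=theta_e, g=theta_e / te_inf,
                          params=params, mode=mode)


def release_time(x: float, params: DimensionlessParams,
                 mode: str = DEFAULT_MODE, tau_max: float = 1e6,
                 rtol: float = 1e-4) -> float:
    """Smallest tau with g(tau) >= x, by doubling bracket plus bisection.

    The release curve is monotone up to inversion noise well below the
    bracketing scale, so plain bisection on fresh inversions is robust.
    Raises :class:`NoConvergenceError` if the target fraction is not
    reached below ``tau_max``.
    """
    if not 0.0 < x < 1.0:
        raise ValueError(f"release fraction x must lie in (0, 1), got {x}")
    check_mode(mode)
    sol = LaplaceSolution(params, mode)
    te_inf = theta_e_inf(params)

    def g(t: float) -> float:
        return invert(sol.theta_e, t) / te_inf

    lo, hi = 0.0, 0.25
    while g(hi) < x:
        lo = hi
        hi *= 2.0
        if hi > tau_max:
            raise NoConvergenceError(
                f"g(tau) did not reach {x} below the search ceiling "
                f"tau_max={tau_max}")
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if g(mid) < x:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def film_concentration(eta_grid, tau_grid, params: DimensionlessParams,
                       mode: str = DEFAULT_MODE) -> ConcentrationField:
    """Invert theta_f_bar pointwise on an eta x tau grid (requires l > 1)."""
    check_mode(mode)
    if params.l <= 1.0:
        raise ValueError("film_concentration requires a film of nonzero "
                         "extent (l > 1)")
    eta = np.asarray(eta_grid, dtype=float)
    if np.any(eta < 1.0) or np.any(eta > params.l):
        raise ValueError(f"film eta grid must lie in [1, {params.l}]")
    tau = _check_tau_grid(tau_grid)
    sol = LaplaceSolution(params, mode)
    values = np.empty((eta.size, tau.size))
    for j, t in enumerate(tau):
        # one constants solve per Zakian node, vectorized over eta
        values[:, j] = _invert_field(lambda s: sol.theta_f(eta, s), t)
    if not np.all(np.isfinite(values)):
        raise RuntimeError("film-concentration inversion produced "
                           "non-finite values")
    return ConcentrationField(eta=eta, tau=tau, values=values, region="film",
                              params=params, mode=mode)


def core_concentration(eta_grid, tau_grid, params: DimensionlessParams,
                       mode: str = DEFAULT_MODE) -> ConcentrationField:
    """Invert theta_m_bar pointwise on an eta x tau grid (eta in [0, 1])."""
    check_mode(mode)
    eta = np.asarray(eta_grid, dtype=float)
    if np.any(eta < 0.0) or np.any(eta > 1.0):
        raise ValueError("core eta grid must lie in [0, 1]")
    tau = _check_tau_grid(tau_grid)
    sol = LaplaceSolution(params, mode)
    values = np.empty((eta.size, tau.size))
    for j, t in enumerate(tau):
        values[:, j] = _invert_field(lambda s: sol.theta_m(eta, s), t)
    if not np.all(np.isfinite(values)):
        raise RuntimeError("core-concentration inversion produced "
                           "non-finite values")
    return ConcentrationField(eta=eta, tau=tau, values=values, region="core",
                              params=params, mode=mode)


def _invert_field(F_vec, t: float) -> np.ndarray:
    """Zakian inversion of a vector-valued transform at one time."""
    from .zakian import ZAKIAN_NODES, ZAKIAN_WEIGHTS

    acc = None
    for alpha, weight in zip(ZAKIAN_NODES, ZAKIAN_WEIGHTS):
        term = (weight * np.asarray(F_vec(alpha / t))).real
        acc = term if acc is None else acc + term
    return 2.0 * acc / t


def reaction_limit(t, k: float, theta_r0: float):
    """Reaction-dominant limit: concentration with diffusion switched off.

    With a pure autocatalytic pseudo-first-order source the monomer
    concentration grows as theta_r0 * exp(k*t); ``k`` and ``t`` must share
    units (conventionally 1/day and day).
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if theta_r0 < 0:
        raise ValueError(f"theta_r0 must be >= 0, got {theta_r0}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = theta_r0 * np.exp(k * t)
    return out if out.ndim else float(out)


def t_max(k: float, Mn0: float, M1: float) -> float:
    """Upper bound on the hydrolysis time: (1/k) * ln(Mn0/M1) in days.

    ``Mn0`` is the initial number-average molecular weight of the polymer
    and ``M1`` the monomer average weight; full ester-bond conversion at
    rate ``k`` (1/day) takes at most this long.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    if M1 <= 0 or Mn0 < M1:
        raise ValueError(f"need Mn0 >= M1 > 0, got Mn0={Mn0}, M1={M1}")
    return math.log(Mn0 / M1) / k


@dataclass(frozen=True)
class Scenario:
    """A named simulation condition bundled with the package."""

    name: str
    family: str
    params: DimensionlessParams
    k_per_day: float
    note: str = ""


# Rates quoted in 1/day and applied with a core diffusion time a**2/Dm of
# one day, so kappa is numerically the day-rate (sorted set; the source
# enumeration is unordered).
RATE_SET_PER_DAY = (0.0, 0.015, 0.02, 0.03, 0.04, 0.06, 0.08)

# The release-profile studies quote a unit dimensionless coating thickness.
# Read as film thickness p = a, i.e. radius ratio l = b/a = 2: at l = 1 the
# film has zero extent and the solution is exactly independent of Dr and
# kappa, so a unit *radius ratio* could not show the diffusivity and
# reaction-rate effects these scenarios exist to exhibit.
RELEASE_RADIUS_RATIO = 2.0


def reference_scenarios() -> list[Scenario]:
    """The bundled simulation-condition grid.

    Four families:

    - ``diffusion-sweep``: multi-diffusion only (kappa = 0),
      Dr in {0.01, 0.1, 1, 10}, Vr = 10, Ka = Kb = 1.
    - ``reaction-sweep-a``: Dr = 1, Vr = 10, rate set
      k in {0, 0.015, 0.02, 0.03, 0.04, 0.06, 0.08} / day.
    - ``reaction-sweep-b``: Dr = 0.1, Vr = 1, same rate set.  (The source
      material labels the two reaction sweeps' bath volumes inconsistently
      between text and figure captions; both assignments are provided and
      the note records the ambiguity.)
    - ``film-field``: concentration field in the coating, Dr = 0.1,
      Vr = 3, l = 2, k = 0.05 / day.
    """
    l = RELEASE_RADIUS_RATIO
    scen: list[Scenario] = []
    for Dr in (0.01, 0.1, 1.0, 10.0):
        scen.append(Scenario(
            name=f"diffusion-Dr{Dr:g}", family="diffusion-sweep",
            params=DimensionlessParams(Dr=Dr, Vr=10.0, l=l, Ka=1.0, Kb=1.0,
                                       kappa=0.0),
            k_per_day=0.0))
    vr_note = ("bath-volume label ambiguous in the source enumeration "
               "(text swaps Vr=1/Vr=10 against the figure captions)")
    for k in RATE_SET_PER_DAY:
        scen.append(Scenario(
            name=f"reaction-a-k{k:g}", family="reaction-sweep-a",
            params=DimensionlessParams.from_rate_per_day(
                Dr=1.0, Vr=10.0, l=l, Ka=1.0, Kb=1.0, k_per_day=k),
            k_per_day=k, note=vr_note))
        scen.append(Scenario(
            name=f"reaction-b-k{k:g}", family="reaction-sweep-b",
            params=DimensionlessParams.from_rate_per_day(
                Dr=0.1, Vr=1.0, l=l, Ka=1.0, Kb=1.0, k_per_day=k),
            k_per_day=k, note=vr_note))
    scen.append(Scenario(
        name="film-field", family="film-field",
        params=DimensionlessParams.from_rate_per_day(
            Dr=0.1, Vr=3.0, l=2.0, Ka=1.0, Kb=1.0, k_per_day=0.05),
        k_per_day=0.05))
    return scen


def scenario_by_name(name: str) -> Scenario:
    for s in reference_scenarios():
        if s.name == name:
            return s
    raise KeyError(f"unknown scenario {name!r}; see reference_scenarios()")
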