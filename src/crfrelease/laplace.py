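"""Laplace-domain solution of the reaction-multi-diffusion model.

In the Laplace variable ``s`` the transformed core and film equations are
linear two-point boundary-value problems for ``u = eta * theta_bar``:

    core  (0 <= eta <= 1):  u_m'' = s*u_m - eta
    film  (1 <= eta <= l):  u_f'' = q**2 * u_f

where the film wavenumber ``q`` depends on the reaction-transform mode
(:func:`q_film`).  Regularity at eta = 0 removes one core constant, leaving
three complex unknowns fixed by the transformed interface and bath
conditions

    Ka * theta_f(1, s) = theta_m(1, s)                      (partition)
    d theta_m/d eta|_1 = Dr * d theta_f/d eta|_1            (flux continuity)
    Kb * theta_f(l, s) = theta_e(s)                         (bath partition)
    d theta_f/d eta|_l = -(Vr*l/(3*Dr)) * s * theta_e(s)    (bath balance)

The 3x3 system is assembled and solved in a *scaled* basis —

    core:  u_m = eta/s + Am * sinh(sqrt(s)*eta) / sinh(sqrt(s))
    film:  u_f = P * exp(q*(eta - l)) + Q * exp(q*(1 - eta)),  Re q >= 0

— whose matrix entries stay O(1) however fast the exponentials decay.  The
textbook constants A1, A2, B2 of the unscaled form
``theta_m = 1/s + A1*sinh(sqrt(s)*eta)/eta`` and
``theta_f = (A2*sinh(q*eta) + B2*cosh(q*eta))/eta`` are recovered from
(Am, P, Q) on demand; they overflow for strongly decaying ``s`` where the
scaled representation remains exact, so all evaluation goes through the
scaled form.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass, field

import numpy as np

from .params import DEFAULT_MODE, DimensionlessParams, check_mode

__all__ = [
    "SingularPointError",
    "DegenerateParameterError",
    "SolutionConstants",
    "LaplaceSolution",
    "q_film",
    "solve_constants",
    "theta_m_bar",
    "theta_f_bar",
    "theta_e_bar",
]


class SingularPointError(ValueError):
    """The transform is evaluated at a singular point (s = 0)."""


class DegenerateParameterError(ValueError):
    """The boundary-condition system is singular at the given s."""


def q_film(s: complex, params: DimensionlessParams,
           mode: str = DEFAULT_MODE) -> complex:
    """Film wavenumber q(s), canonicalized to Re q >= 0.

    mode="integral"    : q = sqrt((s**2 - kappa) / (s * Dr))
    mode="first_order" : q = sqrt((s - kappa) / Dr)

    Both reduce to sqrt(s/Dr) at kappa = 0.  The solution is invariant
    under q -> -q (the film basis spans both exponentials), so the sign is
    fixed once for numerical definiteness.
    """
    check_mode(mode)
    if s == 0:
        raise SingularPointError("q_film is singular at s = 0")
    if mode == "integral":
        q = cmath.sqrt((s * s - params.kappa) / (s * params.Dr))
    else:
        q = cmath.sqrt((s - params.kappa) / params.Dr)
    if q.real < 0 or (q.real == 0 and q.imag < 0):
        q = -q
    return q


@dataclass
class SolutionConstants:
    """Integration constants of the transformed solution at one s.

    ``Am, P, Q`` are the scaled-basis constants actually used for
    evaluation; ``A1, A2, B2`` are the equivalent constants of the
    unscaled sinh/cosh form (B1 = 0 by regularity at the origin).  A2 and
    B2 involve exp(+|q|)-type factors and may overflow to inf for strongly
    decaying s; the scaled constants never do.  ``bc_residual`` is the
    maximum relative residual of the four transformed boundary conditions
    after back-substitution.
    """

    s: complex
    q: complex
    Am: complex
    P: complex
    Q: complex
    bc_residual: float
    A1: complex = field(default=0j)
    A2: complex = field(default=0j)
    B2: complex = field(default=0j)


def _assemble(s: complex, p: DimensionlessParams, mode: str):
    q = q_film(s, p, mode)
    rs = cmath.sqrt(s)
    l = p.l
    E = cmath.exp(-q * (l - 1.0))            # film decay factor, |E| <= 1
    em = cmath.exp(-2.0 * rs)
    coth = (1.0 + em) / (1.0 - em)
    beta = p.Vr * l * l * s * p.Kb / (3.0 * p.Dr)
    # rows: partition at eta=1; flux continuity at eta=1; bath balance at
    # eta=l (with theta_e eliminated through the bath partition).
    M = np.array([
        [-1.0, p.Ka * E, p.Ka],
        [rs * coth - 1.0, -p.Dr * (q - 1.0) * E, p.Dr * (q + 1.0)],
        [0.0, l * q - 1.0 + beta, E * (-l * q - 1.0 + beta)],
    ], dtype=complex)
    rhs = np.array([1.0 / s, 0.0, 0.0], dtype=complex)
    return M, rhs, q, rs, E, coth, beta


def solve_constants(s: complex, params: DimensionlessParams,
                    mode: str = DEFAULT_MODE) -> SolutionConstants:
    """Solve the transformed boundary-condition system at one complex s."""
    if s == 0:
        raise SingularPointError("the transformed solution is singular at s = 0")
    M, rhs, q, rs, E, coth, beta = _assemble(s, params, mode)
    scale = np.abs(M).max(axis=1)
    if not np.all(np.isfinite(scale)) or np.any(scale == 0):
        raise DegenerateParameterError(
            f"boundary-condition system degenerate at s = {s}")
    try:
        Am, P, Q = np.linalg.solve(M / scale[:, None], rhs / scale)
    except np.linalg.LinAlgError as exc:
        raise DegenerateParameterError(
            f"boundary-condition system singular at s = {s}") from exc

    p = params
    # relative residuals of the three independent conditions (the bath
    # partition Kb*theta_f(l) = theta_e holds identically by construction)
    r1_terms = (p.Ka * (P * E + Q), 1.0 / s + Am)
    r1 = abs(r1_terms[0] - r1_terms[1]) / max(map(abs, r1_terms))
    lhs2 = Am * (rs * coth - 1.0)
    rhs2 = p.Dr * ((q - 1.0) * E * P - (q + 1.0) * Q)
    den2 = max(abs(lhs2), abs(rhs2), 1e-300)
    r2 = abs(lhs2 - rhs2) / den2
    lhs3 = P * (p.l * q - 1.0) + Q * E * (-p.l * q - 1.0)
    rhs3 = -beta * (P + Q * E)
    den3 = max(abs(lhs3), abs(rhs3), 1e-300)
    r3 = abs(lhs3 - rhs3) / den3

    con = SolutionConstants(s=s, q=q, Am=Am, P=P, Q=Q,
                            bc_residual=max(r1, r2, r3))
    # unscaled textbook constants (may overflow; evaluation never uses them)
    with np.errstate(over="ignore", invalid="ignore"):
        sinh_rs = np.sinh(complex(rs))
        con.A1 = Am / sinh_rs if sinh_rs != 0 else complex("inf")
        half = np.exp(complex(-q * p.l)) * P
        other = np.exp(complex(q)) * Q
        con.A2 = half - other
        con.B2 = half + other
    return con


class LaplaceSolution:
    """Evaluator of the transformed concentrations for fixed parameters.

    Evaluation is vectorized over eta at fixed s; the constants are solved
    once per s and cached for the most recent s.
    """

    def __init__(self, params: DimensionlessParams, mode: str = DEFAULT_MODE):
        self.params = params
        self.mode = check_mode(mode)
        self._cache_s: complex | None = None
        self._cache_con: SolutionConstants | None = None

    def constants(self, s: complex) -> SolutionConstants:
        if s != self._cache_s:
            self._cache_con = solve_constants(s, self.params, self.mode)
            self._cache_s = s
        return self._cache_con

    def theta_m(self, eta, s: complex):
        """Transformed core concentration theta_m_bar(eta, s), 0 <= eta <= 1.

        Equals 1/s + A1*sinh(sqrt(s)*eta)/eta with the eta -> 0 limit
        1/s + A1*sqrt(s) taken analytically.
        """
        eta = np.asarray(eta, dtype=float)
        if np.any(eta < 0) or np.any(eta > 1):
            raise ValueError("core coordinate eta must lie in [0, 1]")
        con = self.constants(s)
        rs = cmath.sqrt(s)
        norm = 1.0 - cmath.exp(-2.0 * rs)      # sinh(rs) = norm * e^{rs}/2
        with np.errstate(invalid="ignore"):
            phi = np.exp(rs * (eta - 1.0)) * (1.0 - np.exp(-2.0 * rs * eta)) / norm
            out = np.where(eta > 0,
                           1.0 / s + con.Am * phi / np.where(eta > 0, eta, 1.0),
                           1.0 / s + con.Am * 2.0 * rs * cmath.exp(-rs) / norm)
        return out if out.ndim else complex(out)

    def theta_f(self, eta, s: complex):
        """Transformed film concentration theta_f_bar(eta, s), 1 <= eta <= l."""
        eta = np.asarray(eta, dtype=float)
        if np.any(eta < 1 - 1e-12) or np.any(eta > self.params.l + 1e-12):
            raise ValueError(f"film coordinate eta must lie in [1, {self.params.l}]")
        con = self.constants(s)
        q, l = con.q, self.params.l
        out = (con.P * np.exp(q * (eta - l)) + con.Q * np.exp(q * (1.0 - eta))) / eta
        return out if out.ndim else complex(out)

    def theta_e(self, s: complex) -> complex:
        """Transformed bath concentration theta_e_bar(s) = Kb*theta_f_bar(l, s)."""
        con = self.constants(s)
        q, l = con.q, self.params.l
        E = cmath.exp(-q * (l - 1.0))
        return self.params.Kb * (con.P + con.Q * E) / l


def theta_m_bar(eta, s: complex, params: DimensionlessParams,
                mode: str = DEFAULT_MODE):
    return LaplaceSolution(params, mode).theta_m(eta, s)


def theta_f_bar(eta, s: complex, params: DimensionlessParams,
                mode: str = DEFAULT_MODE):
    return LaplaceSolution(params, mode).theta_f(eta, s)


def theta_e_bar(s: complex, params: DimensionlessParams,
                mode: str = DEFAULT_MODE) -> complex:
    return LaplaceSolution(params, mode).theta_e(s)
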