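"""Cross-validation of the analytic-numerical route against the oracle.

Runs the comparison suite behind the ``crfrelease validate`` command and
the acceptance checks: the Zakian transform-pair battery, the no-reaction
oracle-agreement grid, mass conservation, both reaction-mode comparisons,
and a grid-refinement self-consistency check.  Thresholds are the package's
validation contract; a report entry fails when its measure exceeds them.
"""

from __future__ import annotations

import numpy as np

from .laplace import LaplaceSolution
from .oracle import OracleGrid, solve_ibvp
from .params import DimensionlessParams
from .profiles import theta_e_inf
from .zakian import invert

__all__ = ["zakian_battery", "compare_with_oracle", "run_validation"]

# empirical applicability domain of the five-term rule: decay rate times
# time below ~15 keeps the truncation error under 1e-5 (it grows to ~4e-3
# by a*t = 50, a property of the formula, not of this implementation)
BATTERY_AT_MAX = 15.0
BATTERY_TOL = 1e-5


def zakian_battery(t_grid=None, decay_rates=(0.1, 0.5, 1.0, 2.0, 5.0),
                   at_max: float | None = BATTERY_AT_MAX,
                   normalize_large: bool = True) -> dict:
    """Inversion error on transforms with known originals.

    Battery: 1/s (step), 1/(s+a) (exponential decay), 1/s**2 (ramp),
    1/(s*(s+1)) (saturating).  With ``at_max`` set, exponential members are
    only scored where a*t <= at_max (the formula's applicability domain);
    ``at_max=None`` scores everything.  With ``normalize_large`` the error
    is divided by max(1, |f(t)|), i.e. absolute for order-unity originals
    and relative for larger ones (the ramp grows to 10, and the rule's
    relative ramp defect is ~1.3e-6); without it the error is strictly
    absolute.  Returns the worst error and its location.
    """
    if t_grid is None:
        t_grid = np.linspace(0.1, 10.0, 34)
    worst = (0.0, None)
    for t in t_grid:
        cases = [("1/s", lambda s: 1.0 / s, 1.0),
                 ("1/s^2", lambda s: 1.0 / s ** 2, t),
                 ("1/(s(s+1))", lambda s: 1.0 / (s * (s + 1.0)),
                  1.0 - np.exp(-t))]
        for a in decay_rates:
            if at_max is None or a * t <= at_max:
                cases.append((f"1/(s+{a:g})",
                              lambda s, a=a: 1.0 / (s + a), np.exp(-a * t)))
        for name, F, exact in cases:
            err = abs(invert(F, t) - exact)
            if normalize_large:
                err /= max(1.0, abs(exact))
            if err > worst[0]:
                worst = (err, f"{name} at t={t:.3g}")
    return {"max_abs_error": worst[0], "worst_case": worst[1]}


def compare_with_oracle(params: DimensionlessParams, mode: str,
                        reaction_mode: str, tau_end: float = 3.0,
                        grid: OracleGrid | None = None,
                        tau_lo: float = 0.05, n_compare: int = 60) -> dict:
    """Sup-norm gap between Zakian-inverted theta_e and the oracle's.

    The gap is reported relative to the reaction-free equilibrium
    theta_e(infinity); also returns the oracle's conservation drift.
    """
    res = solve_ibvp(params, grid=grid, tau_end=tau_end,
                     reaction_mode=reaction_mode)
    tt = np.linspace(tau_lo, tau_end, n_compare)
    sol = LaplaceSolution(params, mode)
    za = np.array([invert(sol.theta_e, t) for t in tt])
    orc = np.interp(tt, res.tau, res.theta_e)
    te_inf = theta_e_inf(params)
    return {
        "params": {"Dr": params.Dr, "Vr": params.Vr, "l": params.l,
                   "Ka": params.Ka, "Kb": params.Kb, "kappa": params.kappa},
        "mode": mode,
        "reaction_mode": reaction_mode,
        "sup_error_rel": float(np.max(np.abs(za - orc)) / te_inf),
        "mass_drift": float(np.max(np.abs(res.mass - 1.0))),
        "theta_e_end_oracle": float(res.theta_e[-1]),
        "theta_e_inf": te_inf,
    }


def run_validation(fast: bool = False) -> dict:
    """Full cross-validation suite; returns a machine-readable report.

    ``fast`` shrinks the oracle grids (used by smoke tests); the default
    resolutions are the validation contract.
    """
    grid = OracleGrid(n_core=32, n_film=32, dt=1e-3) if fast else OracleGrid()
    report: dict = {"checks": [], "passed": True}

    def add(name: str, measure: float, threshold: float, **extra) -> None:
        ok = bool(measure <= threshold)
        report["checks"].append(
            {"name": name, "measure": float(measure),
             "threshold": threshold, "passed": ok, **extra})
        report["passed"] = report["passed"] and ok

    bat = zakian_battery()
    add("zakian-battery", bat["max_abs_error"], BATTERY_TOL,
        worst_case=bat["worst_case"])
    bat_full = zakian_battery(at_max=None)
    report["zakian_battery_unrestricted"] = bat_full

    # no-reaction agreement grid
    drifts = []
    for Dr in (0.1, 1.0, 10.0):
        for Vr in (1.0, 10.0):
            p = DimensionlessParams(Dr=Dr, Vr=Vr, l=1.2, Ka=1.0, Kb=1.0)
            cmpres = compare_with_oracle(p, "integral", "first_order",
                                         grid=grid)
            add(f"oracle-agreement-Dr{Dr:g}-Vr{Vr:g}",
                cmpres["sup_error_rel"], 1e-2, **cmpres)
            drifts.append(cmpres["mass_drift"])
    add("mass-conservation", max(drifts), 1e-3)

    # long-time equilibrium against the closed form
    p_eq = DimensionlessParams(Dr=1.0, Vr=1.0, l=1.2, Ka=1.0, Kb=1.0)
    res = solve_ibvp(p_eq, grid=grid, tau_end=6.0)
    te = theta_e_inf(p_eq)
    add("equilibrium-long-time", abs(res.theta_e[-1] - te) / te, 5e-3,
        theta_e_inf=te, theta_e_oracle=float(res.theta_e[-1]))

    # reaction-mode consistency at kappa = 0.03
    p_k = DimensionlessParams(Dr=1.0, Vr=10.0, l=1.2, Ka=1.0, Kb=1.0,
                              kappa=0.03)
    for mode, rmode in (("integral", "integral"),
                        ("first_order", "first_order")):
        cmpres = compare_with_oracle(p_k, mode, rmode, grid=grid)
        add(f"reaction-mode-{mode}", cmpres["sup_error_rel"], 2e-2, **cmpres)

    # refinement self-consistency at tau = 1
    p_c = DimensionlessParams(Dr=1.0, Vr=10.0, l=1.2, Ka=1.0, Kb=1.0)
    coarse = solve_ibvp(p_c, grid=OracleGrid(n_core=grid.n_core,
                                             n_film=grid.n_film,
                                             dt=grid.dt), tau_end=1.0)
    fine = solve_ibvp(p_c, grid=OracleGrid(n_core=2 * grid.n_core,
                                           n_film=2 * grid.n_film,
                                           dt=grid.dt / 2), tau_end=1.0)
    rel_change = abs(fine.theta_e[-1] - coarse.theta_e[-1]) / fine.theta_e[-1]
    add("refinement-self-consistency", rel_change, 1e-3,
        coarse=float(coarse.theta_e[-1]), fine=float(fine.theta_e[-1]))

    return report
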