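"""Parameter types and the dimensional/dimensionless mappings.

A controlled-release-fertilizer granule is modelled as a nutrient core of
radius ``a`` surrounded by a polymer film of outer radius ``b``, immersed in
a finite well-stirred extraction medium of volume ``Ve``.  The solver works
in dimensionless variables

    tau = t * Dm / a**2       (time)
    eta = r / a               (radius)

with the dimensionless groups

    Dr = Df / Dm              (film-to-core diffusivity ratio)
    Vr = Ve / (4*pi*b**3/3)   (bath-to-coated-granule volume ratio)
    l  = b / a                (radius ratio; film thickness is l - 1)

plus the interfacial partition constants ``Ka`` (core/film) and ``Kb``
(medium/film) and the dimensionless hydrolysis rate ``kappa``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

SECONDS_PER_DAY = 86400.0

MODES = ("integral", "first_order")
#: Default treatment of the hydrolysis source in the film equation.  The
#: "integral" mode corresponds to a source kappa * Int_0^tau (eta*theta_f) dtau'
#: (film wavenumber sqrt((s**2 - kappa)/(s*Dr)) in the Laplace domain); the
#: "first_order" mode to the instantaneous pseudo-first-order source
#: kappa * eta * theta_f (wavenumber sqrt((s - kappa)/Dr)).
DEFAULT_MODE = "integral"


class ValidationError(ValueError):
    """A parameter violates its invariant; the message names the field."""


class DegenerateFilmWarning(UserWarning):
    """Radius ratio l == 1: the coating film has zero spatial extent.

    The release formulas remain evaluable, but the solution is then
    independent of the film diffusivity ratio ``Dr`` and of the reaction
    rate ``kappa`` (the film has no volume for either to act in).
    """


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    return mode


@dataclass(frozen=True)
class DimensionalParams:
    """Physical granule/coating/bath parameters (SI units except k_rate).

    Attributes
    ----------
    a, b : float
        Core radius and coated-granule radius in metres; ``b >= a``.
    Dm, Df : float
        Core and film diffusivities in m**2/s.
    C0, Cs : float
        Initial core nutrient concentration and its saturation value in
        mol/m**3; the model assumes a fully dissolved core, ``C0 < Cs``.
    Ve : float
        Extraction-medium (bath) volume in m**3.
    Ka, Kb : float
        Core/film and medium/film partition constants (dimensionless).
    k_rate : float
        Pseudo-first-order hydrolysis rate constant in 1/day.
    """

    a: float
    b: float
    Dm: float
    Df: float
    C0: float
    Cs: float
    Ve: float
    Ka: float
    Kb: float
    k_rate: float = 0.0

    def __post_init__(self) -> None:
        _require(self.a > 0, f"a must be > 0, got {self.a}")
        _require(self.b >= self.a, f"b must be >= a, got b={self.b} < a={self.a}")
        _require(self.Dm > 0, f"Dm must be > 0, got {self.Dm}")
        _require(self.Df > 0, f"Df must be > 0, got {self.Df}")
        _require(self.Ve > 0, f"Ve must be > 0, got {self.Ve}")
        _require(self.Ka > 0, f"Ka must be > 0, got {self.Ka}")
        _require(self.Kb > 0, f"Kb must be > 0, got {self.Kb}")
        _require(self.k_rate >= 0, f"k_rate must be >= 0, got {self.k_rate}")
        _require(self.C0 < self.Cs,
                 f"C0 must be below saturation Cs, got C0={self.C0} >= Cs={self.Cs}")

    @property
    def coating_thickness(self) -> float:
        """Film thickness p = b - a in metres."""
        return self.b - self.a


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless parameter set consumed by the solvers."""

    Dr: float
    Vr: float
    l: float
    Ka: float
    Kb: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        _require(self.Dr > 0, f"Dr must be > 0, got {self.Dr}")
        _require(self.Vr > 0, f"Vr must be > 0, got {self.Vr}")
        _require(self.l >= 1, f"l must be >= 1, got {self.l}")
        _require(self.Ka > 0, f"Ka must be > 0, got {self.Ka}")
        _require(self.Kb > 0, f"Kb must be > 0, got {self.Kb}")
        _require(self.kappa >= 0, f"kappa must be >= 0, got {self.kappa}")
        if self.l == 1.0:
            warnings.warn(
                "l = 1: zero-thickness film; release is independent of Dr "
                "and kappa in this limit", DegenerateFilmWarning, stacklevel=2)

    @classmethod
    def from_rate_per_day(cls, Dr: float, Vr: float, l: float, Ka: float,
                          Kb: float, k_per_day: float,
                          diffusion_time_days: float = 1.0) -> "DimensionlessParams":
        """Build a parameter set from a hydrolysis rate quoted in 1/day.

        ``kappa = k_per_day * diffusion_time_days`` where
        ``diffusion_time_days`` is the core diffusion time a**2/Dm expressed
        in days.  The default of one day makes ``kappa`` numerically equal
        to the day-rate, the convention under which literature rate
        constants are fed directly into the dimensionless film equation.
        """
        return cls(Dr=Dr, Vr=Vr, l=l, Ka=Ka, Kb=Kb,
                   kappa=k_per_day * diffusion_time_days)

    def with_kappa(self, kappa: float) -> "DimensionlessParams":
        return replace(self, kappa=kappa)


def nondimensionalize(p: DimensionalParams) -> DimensionlessParams:
    """Map physical parameters onto the dimensionless groups.

    ``kappa = k_rate * a**2 / Dm`` with ``k_rate`` converted from 1/day to
    1/s, so that kappa is a rate per unit dimensionless time tau.
    """
    return DimensionlessParams(
        Dr=p.Df / p.Dm,
        Vr=p.Ve / (4.0 * math.pi * p.b ** 3 / 3.0),
        l=p.b / p.a,
        Ka=p.Ka,
        Kb=p.Kb,
        kappa=(p.k_rate / SECONDS_PER_DAY) * p.a ** 2 / p.Dm,
    )


def tau_to_time(tau: float, a: float, Dm: float) -> float:
    """Dimensionless time tau -> physical time in seconds (t = tau*a**2/Dm)."""
    _require(tau >= 0, f"tau must be >= 0, got {tau}")
    _require(a > 0, f"a must be > 0, got {a}")
    _require(Dm > 0, f"Dm must be > 0, got {Dm}")
    return tau * a ** 2 / Dm


def time_to_tau(t: float, a: float, Dm: float) -> float:
    """Physical time in seconds -> dimensionless tau (inverse of tau_to_time)."""
    _require(t >= 0, f"t must be >= 0, got {t}")
    _require(a > 0, f"a must be > 0, got {a}")
    _require(Dm > 0, f"Dm must be > 0, got {Dm}")
    return t * Dm / a ** 2


_DIMENSIONAL_FIELDS = ("a", "b", "Dm", "Df", "C0", "Cs", "Ve", "Ka", "Kb", "k_rate")
_DIMENSIONLESS_FIELDS = ("Dr", "Vr", "l", "Ka", "Kb", "kappa")


def params_from_mapping(cfg: dict) -> DimensionlessParams:
    """Build dimensionless parameters from a parsed config mapping.

    Exactly one of the blocks ``dimensional:`` (ten physical fields) or
    ``dimensionless:`` (Dr, Vr, l, Ka, Kb, kappa) must be present; a
    dimensional block is nondimensionalized on load.
    """
    has_dim = "dimensional" in cfg
    has_nd = "dimensionless" in cfg
    if has_dim == has_nd:
        raise ValidationError(
            "config must contain exactly one of the blocks "
            "'dimensional' or 'dimensionless'")
    if has_dim:
        block = dict(cfg["dimensional"])
        unknown = set(block) - set(_DIMENSIONAL_FIELDS)
        if unknown:
            raise ValidationError(f"unknown dimensional fields: {sorted(unknown)}")
        return nondimensionalize(DimensionalParams(**block))
    block = dict(cfg["dimensionless"])
    unknown = set(block) - set(_DIMENSIONLESS_FIELDS)
    if unknown:
        raise ValidationError(f"unknown dimensionless fields: {sorted(unknown)}")
    return DimensionlessParams(**block)


def load_config(path: str | Path) -> DimensionlessParams:
    """Load a parameter set from a YAML or TOML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        cfg = tomllib.loads(text)
    else:
        import yaml

        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config file {path} did not parse to a mapping")
    return params_from_mapping(cfg)
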