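"""Deterministic CSV/JSON export of release profiles and fields.

Floats are written with 9 significant digits and columns in a fixed order
so that identical configurations produce byte-identical files.  Each data
file gets a JSON sidecar carrying the complete effective parameter set,
mode, tool version and scenario name, sufficient to re-run the computation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from . import __version__
from .profiles import ConcentrationField, ReleaseProfile

__all__ = ["write_release_csv", "write_field_csv", "write_sidecar"]

_FMT = "{:.9g}"


def _fmt(x: float) -> str:
    return _FMT.format(float(x))


def write_release_csv(profile: ReleaseProfile, path: str | Path) -> Path:
    """Write columns (tau, theta_e, g) with g clipped to [0, 1]."""
    path = Path(path)
    g = profile.g_clipped()
    lines = ["tau,theta_e,g"]
    for t, te, gv in zip(profile.tau, profile.theta_e, g):
        lines.append(f"{_fmt(t)},{_fmt(te)},{_fmt(gv)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_field_csv(field: ConcentrationField, path: str | Path) -> Path:
    """Write a long-format field: columns (region, eta, tau, value)."""
    path = Path(path)
    lines = ["region,eta,tau,value"]
    for i, eta in enumerate(field.eta):
        for j, tau in enumerate(field.tau):
            lines.append(f"{field.region},{_fmt(eta)},{_fmt(tau)},"
                         f"{_fmt(field.values[i, j])}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_sidecar(data_path: str | Path, params, mode: str,
                  scenario: str | None = None, extra: dict | None = None) -> Path:
    """Write ``<data_path>.json`` describing how the data were produced."""
    data_path = Path(data_path)
    side = data_path.with_suffix(data_path.suffix + ".json")
    payload = {
        "tool": "crfrelease",
        "version": __version__,
        "data_file": data_path.name,
        "mode": mode,
        "scenario": scenario,
        "params": dataclasses.asdict(params),
    }
    if extra:
        payload.update(extra)
    side.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return side
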