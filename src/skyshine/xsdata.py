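"""Photon interaction coefficients for air, concrete and ground.

Tables are bundled as plain-text CSVs (``data/<name>.csv``) with mass
coefficients in cm^2/g for the three interaction channels used by the
transport model — photoelectric absorption, incoherent (Compton) scattering,
and pair production — plus the mass energy-absorption coefficient
``mu_en/rho``.  Coherent (Rayleigh) scattering is deliberately excluded from
both the totals and the channel list: it deposits no energy and its omission
matches the free-electron Compton model used for scatter sampling.

Interpolation between grid points is log-log, appropriate to the power-law
behaviour of the cross sections.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AIR_DENSITY_SEA_LEVEL, CONCRETE_DENSITY

PAIR_THRESHOLD_MEV = 1.022
E_MIN_MEV = 0.01

__all__ = [
    "Material",
    "MaterialTable",
    "load_material",
    "coefficients_at",
    "channel_probabilities",
]


@dataclass(frozen=True)
class Material:
    """A homogeneous material: name, bulk density and element mass fractions."""

    name: str
    density: float                      # g/cm^3
    composition: dict = field(default_factory=dict)  # element -> mass fraction

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.composition:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"mass fractions of {self.name!r} sum to {total}, not 1")


@dataclass(frozen=True)
class MaterialTable:
    """Energy-gridded partial interaction coefficients for one material.

    All coefficient columns are mass coefficients (cm^2/g) on a strictly
    increasing energy grid spanning at least 0.01-20 MeV.
    """

    material: Material
    energy_grid: np.ndarray
    mu_photoelectric: np.ndarray
    mu_incoherent: np.ndarray
    mu_pair: np.ndarray
    muen_over_rho: np.ndarray

    def __post_init__(self):
        e = self.energy_grid
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if e[0] > E_MIN_MEV or e[-1] < 20.0:
            raise ValueError("energy grid must span at least 0.01-20 MeV")
        for arr in (self.mu_photoelectric, self.mu_incoherent, self.mu_pair,
                    self.muen_over_rho):
            if np.any(arr < 0):
                raise ValueError("coefficients must be non-negative")
        if np.any(self.mu_pair[e < PAIR_THRESHOLD_MEV] > 0):
            raise ValueError("pair coefficient must vanish below 1.022 MeV")
        total = self.mu_photoelectric + self.mu_incoherent + self.mu_pair
        if np.any(self.muen_over_rho > total * (1 + 1e-9)):
            raise ValueError("muen/rho exceeds total mu/rho on the grid")

    @property
    def mu_total(self) -> np.ndarray:
        return self.mu_photoelectric + self.mu_incoherent + self.mu_pair

    def with_density(self, density: float) -> "MaterialTable":
        """Same coefficients, different bulk density (e.g. air at altitude)."""
        mat = Material(self.material.name, density, dict(self.material.composition))
        return MaterialTable(mat, self.energy_grid, self.mu_photoelectric,
                             self.mu_incoherent, self.mu_pair, self.muen_over_rho)


_DEFAULT_DENSITIES = {"air": AIR_DENSITY_SEA_LEVEL, "concrete": CONCRETE_DENSITY}
_COMPOSITIONS = {
    # NIST dry air and ordinary concrete, mass fractions
    "air": {"N": 0.755267, "O": 0.231781, "Ar": 0.012827, "C": 0.000124},
    "concrete": {"O": 0.529107, "Si": 0.337021, "Ca": 0.044, "Al": 0.033872,
                 "Na": 0.016, "Fe": 0.014, "K": 0.013, "H": 0.01,
                 "Mg": 0.002, "C": 0.001},
}


def load_material(name: str, density: float | None = None,
                  path: str | Path | None = None) -> MaterialTable:
    """Load a bundled (or user-supplied CSV) coefficient table by name.

    Parameters
    ----------
    name:
        Registry name (``"air"`` or ``"concrete"``; ``"ground"`` is an alias
        for concrete).
    density:
        Bulk density override in g/cm^3 (defaults to sea-level air /
        2.3 g/cm^3 concrete).
    path:
        Optional explicit CSV path instead of the bundled data file.
    """
    key = "concrete" if name == "ground" else name
    if path is None:
        ref = resources.files("skyshine").joinpath(f"data/{key}.csv")
        with resources.as_file(ref) as p:
            raw = pd.read_csv(p, comment="#")
    else:
        raw = pd.read_csv(path, comment="#")
    rho = _DEFAULT_DENSITIES.get(key, 1.0) if density is None else density
    mat = Material(name, rho, _COMPOSITIONS.get(key, {}))
    return MaterialTable(
        mat,
        np.ascontiguousarray(raw["energy_MeV"].to_numpy()),
        np.ascontiguousarray(raw["mu_pe"].to_numpy()),
        np.ascontiguousarray(raw["mu_incoh"].to_numpy()),
        np.ascontiguousarray(raw["mu_pair"].to_numpy()),
        np.ascontiguousarray(raw["muen"].to_numpy()),
    )


def _loglog_interp(table: MaterialTable, column: np.ndarray, energy: float) -> float:
    e = table.energy_grid
    le = np.log(energy)
    lg = np.log(e)
    i = int(np.searchsorted(lg, le))
    i = min(max(i, 1), len(e) - 1)
    y0, y1 = column[i - 1], column[i]
    if y0 <= 0.0 or y1 <= 0.0:
        # linear ramp through zero-valued nodes (pair threshold region)
        f = (energy - e[i - 1]) / (e[i] - e[i - 1])
        return float(y0 + f * (y1 - y0))
    f = (le - lg[i - 1]) / (lg[i] - lg[i - 1])
    return float(np.exp(np.log(y0) + f * (np.log(y1) - np.log(y0))))


def coefficients_at(table: MaterialTable, energy: float) -> dict:
    """Linear interaction coefficients (1/cm) at ``energy`` (MeV).

    Returns the photoelectric, incoherent and pair channels, their total, and
    the linear energy-absorption coefficient, all scaled by the material's
    bulk density.  Interpolation is log-log; a query at a grid node returns
    the tabulated value exactly.
    """
    if not (E_MIN_MEV <= energy <= table.energy_grid[-1]):
        raise ValueError(
            f"energy {energy} MeV outside the tabulated range "
            f"[{E_MIN_MEV}, {table.energy_grid[-1]}] MeV")
    rho = table.material.density
    pe = _loglog_interp(table, table.mu_photoelectric, energy) * rho
    inc = _loglog_interp(table, table.mu_incoherent, energy) * rho
    if energy <= PAIR_THRESHOLD_MEV:
        pp = 0.0
    else:
        pp = _loglog_interp(table, table.mu_pair, energy) * rho
    muen = _loglog_interp(table, table.muen_over_rho, energy) * rho
    return {
        "photoelectric": pe,
        "incoherent": inc,
        "pair": pp,
        "total": pe + inc + pp,
        "muen": muen,
    }


def channel_probabilities(table: MaterialTable, energy: float) -> dict:
    """Per-channel interaction probabilities at ``energy`` (sum to one)."""
    c = coefficients_at(table, energy)
    if c["total"] <= 0.0:
        raise ValueError(f"total interaction coefficient vanishes at {energy} MeV")
    return {k: c[k] / c["total"] for k in ("photoelectric", "incoherent", "pair")}
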