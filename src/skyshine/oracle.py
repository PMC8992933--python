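"""Semi-analytic single-scatter skyshine integral (validation oracle).

For monoenergetic photons projected straight up the cylinder axis of a
roofless vault, the air kerma at a ground-level observation point P from
*singly* scattered photons is a one-dimensional integral over the scatter
height z on the axis:

    K(P) = D0^-1 * integral dz  exp(-mu(E0) (z - z_src))     (primary survival)
                  * n_e                                      (electrons per m^3)
                  * dsigma/dOmega(E0, theta)                 (Klein-Nishina)
                  * exp(-tau_scattered)                      (slant-path survival)
                  * E' (mu_en/rho)(E') / R^2

where theta is the axis-to-P scattering angle at height z, E' the Compton
energy at that angle, R the slant distance, and tau the optical depth of the
scattered leg through air plus the chord of the concrete side wall it
crosses (wall attenuation rather than outright exclusion; the opaque-wall
"shadow" picture is the thick-wall limit).  Ground reflection is excluded:
this models the direct path of photons that scattered exactly once, which is
what the Monte Carlo engine reproduces with ``scatter_limit=1`` and the
ground-kill toggle.

Evaluated by adaptive quadrature; used for equivalence tests against the
transport kernel.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .constants import (AVOGADRO, CLASSICAL_ELECTRON_RADIUS_CM,
                        JOULE_PER_MEV, MEC2_MEV)
from .geometry import CylinderShieldGeometry
from .source import BeamSpectrum
from .tally import isocenter_kerma_per_photon
from .xsdata import MaterialTable, _loglog_interp, load_material

Z_OVER_A_AIR = 0.49919

__all__ = ["SingleScatterProblem", "single_scatter_kerma"]


@dataclass(frozen=True)
class SingleScatterProblem:
    """Monoenergetic axial source, roofless vault, single scattering only."""

    e0: float                      # source energy, MeV
    geometry: CylinderShieldGeometry
    source_z: float = 0.3          # m above grade (1 m below the isocenter)
    observation_z: float = 1.3     # m above grade (isocenter height)
    air_density: float = 1.225e-3  # g/cm^3
    z_max: float = 2000.0          # upper integration limit, m

    def __post_init__(self):
        if self.e0 <= 0.01:
            raise ValueError("source energy must exceed the 10 keV cutoff")
        if self.geometry.t_r != 0.0:
            raise ValueError("the single-scatter oracle models a roofless vault")


def _mu_per_m(table: MaterialTable, energy: float) -> float:
    """Total linear attenuation (1/m), channels as modelled (no coherent)."""
    mass = (_loglog_interp(table, table.mu_photoelectric, energy)
            + _loglog_interp(table, table.mu_incoherent, energy)
            + (_loglog_interp(table, table.mu_pair, energy)
               if energy > 1.022 else 0.0))
    return mass * table.material.density * 100.0


def _kn_dsigma_domega_m2(e0: float, cos_t: float) -> tuple[float, float]:
    """(differential KN cross section in m^2/sr, scattered energy in MeV)."""
    alpha = e0 / MEC2_MEV
    e_prime = e0 / (1.0 + alpha * (1.0 - cos_t))
    ratio = e_prime / e0
    sin2 = 1.0 - cos_t * cos_t
    dsig_cm2 = 0.5 * CLASSICAL_ELECTRON_RADIUS_CM ** 2 * ratio * ratio * (
        ratio + 1.0 / ratio - sin2)
    return dsig_cm2 * 1e-4, e_prime


def _wall_chord_fraction(geom: CylinderShieldGeometry, z: float,
                         d_s: float, z_obs: float) -> float:
    """Fraction of the scattered leg (axis point at height z -> P) that lies
    inside the side-wall annulus."""
    r_in = geom.d_w - geom.wall_thickness
    if d_s <= r_in:
        return 0.0
    t_lo = r_in / d_s
    t_hi = min(geom.d_w / d_s, 1.0)
    # z(t) is linear from z to z_obs; wall occupies wall_base <= z <= wall_top
    dz = z_obs - z
    if dz == 0.0:
        inside = geom.wall_base <= z <= geom.wall_top
        return (t_hi - t_lo) if inside else 0.0
    t_at = lambda zp: (zp - z) / dz
    ta, tb = sorted((t_at(geom.wall_base), t_at(geom.wall_top)))
    lo = max(t_lo, ta, 0.0)
    hi = min(t_hi, tb, 1.0)
    return max(hi - lo, 0.0)


def single_scatter_kerma(problem: SingleScatterProblem, d_s,
                         air_table: MaterialTable | None = None,
                         concrete_table: MaterialTable | None = None,
                         rel_tol: float = 1e-4) -> np.ndarray:
    """Scaled single-scatter air kerma K/D0 at radial distance(s) ``d_s``.

    ``d_s`` may be a scalar or array of horizontal distances (m).  The
    result carries the same normalization as the Monte Carlo ``scaled_AKR``
    mode: air kerma per source photon divided by the per-photon isocenter
    kerma of a 10 x 10 cm^2 field at the source energy.
    """
    if air_table is None:
        air_table = load_material("air", density=problem.air_density)
    if concrete_table is None:
        concrete_table = load_material("concrete")
    geom = problem.geometry
    mu0 = _mu_per_m(air_table, problem.e0)        # 1/m at the source energy
    n_e = (air_table.material.density * Z_OVER_A_AIR * AVOGADRO) * 1e6  # 1/m^3
    d0 = isocenter_kerma_per_photon(BeamSpectrum.monoenergetic(problem.e0),
                                    air_table)
    z_obs = problem.observation_z
    z_src = problem.source_z

    def integrand(z, ds):
        r = math.hypot(ds, z - z_obs)
        cos_t = (z_obs - z) / r
        dsig, e_p = _kn_dsigma_domega_m2(problem.e0, cos_t)
        if e_p < 0.01:
            return 0.0
        frac_wall = _wall_chord_fraction(geom, z, ds, z_obs)
        mu_air = _mu_per_m(air_table, e_p)
        mu_wall = _mu_per_m(concrete_table, e_p)
        tau = mu_air * r * (1.0 - frac_wall) + mu_wall * r * frac_wall
        muen = _loglog_interp(air_table, air_table.muen_over_rho, e_p) * 0.1
        return (math.exp(-mu0 * (z - z_src)) * n_e * dsig
                * math.exp(-tau) * e_p * JOULE_PER_MEV * muen / (r * r))

    def graze_heights(ds):
        """Scatter heights whose ray to P grazes a wall-top corner (integrand
        kinks; passed to the quadrature as break points)."""
        pts = []
        for radius in (geom.d_w - geom.wall_thickness, geom.d_w):
            t = radius / ds
            if 0.0 < t < 1.0:
                zp = (geom.wall_top - z_obs * t) / (1.0 - t)
                if z_src < zp < problem.z_max:
                    pts.append(zp)
        return pts

    out = []
    for ds in np.atleast_1d(np.asarray(d_s, float)):
        if ds <= geom.d_w:
            raise ValueError("observation point lies inside the wall radius")
        val, err = quad(integrand, z_src, problem.z_max, args=(ds,),
                        points=sorted(graze_heights(ds)), limit=400,
                        epsrel=rel_tol, epsabs=0.0)
        if val > 0 and err / val > 50 * rel_tol:
            raise RuntimeError(f"quadrature failed to converge at d_s={ds}")
        out.append(val / d0)
    res = np.array(out)
    return float(res[0]) if np.isscalar(d_s) or np.ndim(d_s) == 0 else res
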