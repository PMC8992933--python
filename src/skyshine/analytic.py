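"""Algebraic skyshine estimation methodology.

For a cylindrically symmetric vault (outer wall radius ``d_w``, isocenter to
rooftop ``h``) the instantaneous skyshine air-kerma rate at horizontal
distance ``d_s`` from the isocenter, 1.3 m above level ground, is

    Kdot_a [nSv/s] = k (F0/400) B_xs (Ddot0/400) (1/d_s) g(x),
    g(x) = 2 (1 + x^2)^{3/2} - x (2 x^2 + 3),   x = h / (d_s - d_w),

with ``k`` an energy-dependent fitting parameter (conservative fits to Monte
Carlo ring tallies; 150 at 4 MV down to 85 at 18 MV), ``F0`` the field area
at isocenter in cm^2, ``B_xs`` the broad-beam roof transmission, and
``Ddot0`` the isocenter dose rate in cGy/min.  The profile peaks near

    d_max ~ 1.5 d_w + 1.1 h        (valid for 0.3 < h/d_w < 1.2),

and the weekly equivalent dose follows by replacing the instantaneous dose
rate with the workload:

    H_s [uSv/wk] = 1.5e-2 k (W_p U T) (F0/400) B_xs (1/d_s) g(x).

Roof transmission is computed from the first/equilibrium tenth-value layers:
``B_xs = 10^(-t_r/TVL1)`` within the first layer, then one decade per TVLe.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import K_TABLE, TVL_CONCRETE_CM

__all__ = [
    "SkyshineScenario", "geometry_factor", "akr_estimate", "d_max",
    "weekly_dose", "max_weekly_dose", "bxs_from_tvl", "rooftop_doses",
    "bxs_for_weekly_rooftop_limit", "bxs_for_high_radiation_area",
    "bxs_for_background_akr", "classify_roof", "k_for_mv", "tvl_for_mv",
]


def k_for_mv(nominal_mv: float) -> float:
    """Fitting parameter ``k``, linearly interpolated between the five
    tabulated accelerating potentials (150 at 4 MV ... 85 at 18 MV)."""
    mvs = np.array(sorted(K_TABLE))
    ks = np.array([K_TABLE[m] for m in mvs])
    if not (mvs[0] <= nominal_mv <= mvs[-1]):
        raise ValueError(f"nominal MV {nominal_mv} outside {mvs[0]}-{mvs[-1]}")
    return float(np.interp(nominal_mv, mvs, ks))


def tvl_for_mv(nominal_mv: int) -> tuple[float, float]:
    """(TVL1, TVLe) in cm of ordinary concrete for a supported MV."""
    try:
        row = TVL_CONCRETE_CM[nominal_mv]
    except KeyError:
        raise ValueError(f"no bundled TVLs for {nominal_mv} MV") from None
    return row["TVL1"], row["TVLe"]


@dataclass(frozen=True)
class SkyshineScenario:
    """Parameter bundle for the analytic model.

    Geometry in metres; ``F0`` in cm^2 at the 100 cm reference distance;
    ``d0_rate`` in cGy/min; workloads in Gy; occupancies dimensionless.
    """

    k: float
    d_w: float
    h: float
    f0: float = 1600.0
    b_xs: float = 1.0
    d0_rate: float = 600.0        # cGy/min at isocenter
    w_p: float = 500.0            # weekly primary workload, Gy/wk
    use_factor: float = 0.25      # roof use factor U
    occupancy: float = 1.0        # T at the point of interest
    roof_occupancy: float = 1 / 20  # T_r on the rooftop
    t_r_cm: float = 0.0           # roof thickness, cm
    tvl1_cm: float = 35.0
    tvle_cm: float = 30.0

    def __post_init__(self):
        if min(self.k, self.d_w, self.h, self.f0, self.d0_rate) <= 0:
            raise ValueError("k, d_w, h, F0 and D0 rate must be positive")
        if not (0.0 < self.b_xs <= 1.0):
            raise ValueError("need 0 < B_xs <= 1")

    @property
    def w_h(self) -> float:
        """Hourly workload, Gy/h (W_h = W_p / 40)."""
        return self.w_p / 40.0

    @classmethod
    def for_mv(cls, nominal_mv: int, d_w: float = 5.0, h: float = 3.0,
               t_r_cm: float = 0.0, **kw) -> "SkyshineScenario":
        """Scenario with the bundled ``k`` and concrete TVLs for one MV."""
        tvl1, tvle = tvl_for_mv(nominal_mv)
        b_xs = bxs_from_tvl(t_r_cm, tvl1, tvle)
        return cls(k=k_for_mv(nominal_mv), d_w=d_w, h=h, t_r_cm=t_r_cm,
                   tvl1_cm=tvl1, tvle_cm=tvle, b_xs=kw.pop("b_xs", b_xs), **kw)

    def with_(self, **kw) -> "SkyshineScenario":
        return replace(self, **kw)


def geometry_factor(x: float) -> float:
    """g(x) = 2(1+x^2)^(3/2) - x(2x^2+3): 2 at x=0, monotone to 0."""
    if x < 0:
        raise ValueError("x must be >= 0")
    return 2.0 * (1.0 + x * x) ** 1.5 - x * (2.0 * x * x + 3.0)


def d_max(d_w: float, h: float) -> float:
    """Distance of the skyshine maximum, ``1.5 d_w + 1.1 h`` (metres).

    Warns outside the fitted validity range ``0.3 < h/d_w < 1.2``.
    """
    if d_w <= 0 or h <= 0:
        raise ValueError("d_w and h must be positive")
    ratio = h / d_w
    if not (0.3 < ratio < 1.2):
        warnings.warn(
            f"h/d_w = {ratio:.2f} outside the fitted range (0.3, 1.2); "
            "the linear d_max formula is extrapolating", stacklevel=2)
    return 1.5 * d_w + 1.1 * h


def _profile(scn: SkyshineScenario, d_s: float) -> float:
    """(1/d_s) g(h/(d_s-d_w)) — the shared radial shape of Eqs for AKR/H_s."""
    if d_s <= scn.d_w:
        raise ValueError("d_s must exceed d_w (the formula is undefined in "
                         "the wall shadow)")
    x = scn.h / (d_s - scn.d_w)
    return geometry_factor(x) / d_s


def akr_estimate(scn: SkyshineScenario, d_s: float) -> float:
    """Instantaneous skyshine air-kerma rate at ``d_s`` (nSv/s)."""
    return (scn.k * (scn.f0 / 400.0) * scn.b_xs * (scn.d0_rate / 400.0)
            * _profile(scn, d_s))


def weekly_dose(scn: SkyshineScenario, d_s: float) -> float:
    """Weekly skyshine equivalent dose at ``d_s`` (uSv/wk)."""
    return (1.5e-2 * scn.k * (scn.w_p * scn.use_factor * scn.occupancy)
            * (scn.f0 / 400.0) * scn.b_xs * _profile(scn, d_s))


def _max_profile(scn: SkyshineScenario) -> tuple[float, float]:
    """(d_s at the maximum, max of the radial profile), golden-section."""
    lo = scn.d_w + 1e-3
    hi = scn.d_w + 100.0 * scn.h
    res = minimize_scalar(lambda d: -_profile(scn, d), bounds=(lo, hi),
                          method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x), float(-res.fun)


def max_weekly_dose(scn: SkyshineScenario) -> tuple[float, float]:
    """(d_s of the maximum, maximum weekly dose in uSv/wk)."""
    ds, prof = _max_profile(scn)
    return ds, (1.5e-2 * scn.k * (scn.w_p * scn.use_factor * scn.occupancy)
                * (scn.f0 / 400.0) * scn.b_xs * prof)


def max_akr(scn: SkyshineScenario) -> tuple[float, float]:
    """(d_s of the maximum, maximum instantaneous AKR in nSv/s)."""
    ds, prof = _max_profile(scn)
    return ds, (scn.k * (scn.f0 / 400.0) * scn.b_xs * (scn.d0_rate / 400.0)
                * prof)


def bxs_from_tvl(t_r_cm: float, tvl1_cm: float, tvle_cm: float) -> float:
    """Broad-beam transmission of ``t_r`` cm of shield from its TVLs."""
    if t_r_cm < 0:
        raise ValueError("thickness must be >= 0")
    if tvl1_cm <= 0 or tvle_cm <= 0:
        raise ValueError("TVLs must be positive")
    if t_r_cm <= tvl1_cm:
        return 10.0 ** (-t_r_cm / tvl1_cm)
    return 10.0 ** (-1.0 - (t_r_cm - tvl1_cm) / tvle_cm)


def rooftop_doses(scn: SkyshineScenario) -> dict:
    """Weekly and hourly equivalent dose 1 m above the rooftop (Sv).

    ``H_w,r = B_xs W_p U T_r / (h+2)^2`` and ``H_h,r = W_h U B_xs / (h+2)^2``
    with ``h`` in metres (the +2 m accounts for the isocenter-to-roof datum
    and the 1 m survey height).
    """
    if scn.h <= -2.0:
        raise ValueError("h must exceed -2 m")
    denom = (scn.h + 2.0) ** 2
    return {
        "weekly_Sv": scn.b_xs * scn.w_p * scn.use_factor * scn.roof_occupancy
        / denom,
        "hourly_Sv": scn.w_h * scn.use_factor * scn.b_xs / denom,
    }


def bxs_for_weekly_rooftop_limit(scn: SkyshineScenario,
                                 limit_sv: float = 2.0e-5) -> float:
    """B_xs that meets a weekly rooftop occupancy limit (default 20 uSv/wk),
    i.e. solves ``(W_p U T_r) B_xs = limit (h+2)^2``."""
    return limit_sv * (scn.h + 2.0) ** 2 / (
        scn.w_p * scn.use_factor * scn.roof_occupancy)


def bxs_for_high_radiation_area(scn: SkyshineScenario,
                                limit_sv: float = 1.0e-3) -> float:
    """B_xs that keeps the rooftop below the high-radiation-area threshold
    (1 mSv in any one hour): ``W_p U B_xs = 40 * limit * (h+2)^2``."""
    return limit_sv * (scn.h + 2.0) ** 2 / (scn.w_h * scn.use_factor)


def bxs_for_background_akr(scn: SkyshineScenario,
                           background_usv_per_hr: float = 0.1) -> float:
    """Roof transmission at which the *maximum* skyshine AKR equals an
    ambient background level (default 0.1 uSv/hr)."""
    _, prof = _max_profile(scn)
    akr_unit_bxs = (scn.k * (scn.f0 / 400.0) * (scn.d0_rate / 400.0) * prof)
    background_nsv_s = background_usv_per_hr * 1000.0 / 3600.0
    return background_nsv_s / akr_unit_bxs


def classify_roof(t_r_cm: float, tvl1_cm: float) -> dict:
    """Thick/thin roof classification via ``mu_bar t_r`` with
    ``mu_bar = ln10 / TVL1``, plus the energy-dominance advisory.

    Below ~30 cm of concrete the lowest MV dominates the skyshine; 30-50 cm
    is roughly energy independent; above ~50 cm the highest MV dominates.
    """
    if tvl1_cm <= 0 or t_r_cm < 0:
        raise ValueError("need TVL1 > 0 and t_r >= 0")
    mu_bar = math.log(10.0) / tvl1_cm
    mt = mu_bar * t_r_cm
    if t_r_cm < 30.0:
        advisory = "lowest MV dominates the skyshine"
    elif t_r_cm <= 50.0:
        advisory = "skyshine roughly independent of MV"
    else:
        advisory = "highest MV dominates the skyshine"
    return {"mu_bar_per_cm": mu_bar, "mu_bar_t_r": mt,
            "label": "thin" if mt < 3.0 else "thick", "advisory": advisory}
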