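"""Ring-crossing fluence/kerma tallies and result normalization.

Cylindrical symmetry is exploited by scoring flat coaxial rings in a
horizontal plane.  A photon crossing the plane inside ring ``n`` (inner
radius ``r_n``, width ``dr``) contributes one over the projected ring area
to the fluence,

    dPhi = 1 / (2 pi r_n (1 + dr/(2 r_n)) |w| dr) = 1 / (pi (r_{n+1}^2 - r_n^2) |w|),

and ``E_gamma * dPhi * (mu_en/rho)_air`` to the air kerma.  Near-horizontal
crossings have |w| floored (default 0.02) to bound the estimator variance;
the floor's bias is checked against a track-length estimator in the tests.

Results can be normalized two ways: ``scaled_akr`` divides the per-history
ring kerma by the per-photon isocenter air kerma of a 10 x 10 cm^2 field
(the dimensionless ratio the vault studies report), and ``exposure_per_ci``
converts to uR/h per Ci of Co-60 for the silo benchmark.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (AIR_KERMA_PER_ROENTGEN_GY, JOULE_PER_MEV,
                        PHOTONS_PER_CI_PER_S_CO60)
from .source import BeamSpectrum
from .xsdata import MaterialTable, _loglog_interp

A_10X10_M2 = 0.01   # 10 x 10 cm^2 reference field at isocenter

__all__ = ["RingTallySet", "RingTallyResult", "NormalizationRecord",
           "score_crossing", "isocenter_kerma_per_photon", "finalize"]


@dataclass
class RingTallySet:
    """Contiguous coaxial rings at height ``z`` with bin width ``dr``."""

    z: float = 1.3                 # tally plane height above outside grade, m
    dr: float = 0.5
    n_rings: int = 120
    w_floor: float = 0.02
    kerma: np.ndarray = field(init=False)     # Gy per batch-sum, per ring
    phi: np.ndarray = field(init=False)       # fluence, 1/m^2
    e_phi: np.ndarray = field(init=False)     # MeV/m^2 (spectrum-weighted)
    e_sum: np.ndarray = field(init=False)     # MeV (per crossing)
    count: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.dr <= 0 or self.n_rings < 1:
            raise ValueError("need dr > 0 and at least one ring")
        for name in ("kerma", "phi", "e_phi", "e_sum", "count"):
            setattr(self, name, np.zeros(self.n_rings))

    @property
    def r_inner(self) -> np.ndarray:
        return np.arange(self.n_rings) * self.dr

    @property
    def r_centers(self) -> np.ndarray:
        return self.r_inner + 0.5 * self.dr

    @property
    def ring_areas(self) -> np.ndarray:
        r = self.r_inner
        return math.pi * ((r + self.dr) ** 2 - r ** 2)


def score_crossing(photon, rings: RingTallySet, muen_air_cm2_g: float) -> float:
    """Score one tally-plane crossing; returns the kerma increment (Gy).

    ``photon`` carries position (m), direction cosines and energy (MeV); the
    crossing radius is taken from the photon's position, which the caller has
    advanced to the tally plane.  Reference implementation used by the
    transport kernel's compiled twin and by the unit tests.
    """
    x, y = float(photon.position[0]), float(photon.position[1])
    w = float(photon.direction[2])
    r_c = math.hypot(x, y)
    ir = int(r_c / rings.dr)
    if ir >= rings.n_rings:
        return 0.0
    aw = max(abs(w), rings.w_floor)
    dphi = 1.0 / (rings.ring_areas[ir] * aw)
    dk = photon.energy * JOULE_PER_MEV * dphi * (muen_air_cm2_g * 0.1)
    rings.kerma[ir] += dk
    rings.phi[ir] += dphi
    rings.e_phi[ir] += dphi * photon.energy
    rings.e_sum[ir] += photon.energy
    rings.count[ir] += 1
    return dk


def isocenter_kerma_per_photon(spectrum: BeamSpectrum,
                               air_table: MaterialTable) -> float:
    """Air kerma at isocenter per source photon for a 10 x 10 cm^2 field (Gy).

    ``D0 = sum_i p_i E_i (mu_en/rho)_air / A_10`` with the 1 m of air between
    target and isocenter left unattenuated (a < 0.01% effect).
    """
    if spectrum.mode == "histogram":
        energies = 0.5 * (spectrum.energies[1:] + spectrum.energies[:-1])
    else:
        energies = spectrum.energies
    p = spectrum.weights / spectrum.weights.sum()
    muen = np.array([_loglog_interp(air_table, air_table.muen_over_rho, e)
                     for e in energies])          # cm^2/g
    return float(np.sum(p * energies * JOULE_PER_MEV * (muen * 0.1)) / A_10X10_M2)


@dataclass(frozen=True)
class NormalizationRecord:
    """Normalization constants attached to a finished run."""

    d0_per_photon: float                 # Gy per source photon at isocenter
    exposure_scale: float = (PHOTONS_PER_CI_PER_S_CO60 * 3600.0
                             / AIR_KERMA_PER_ROENTGEN_GY * 1e6)
    # Gy/photon -> uR/h per Ci (2 photons/decay, 3.7e10 decay/s/Ci)

    def __post_init__(self):
        if self.d0_per_photon <= 0:
            raise ValueError("D0 must be positive")


@dataclass
class RingTallyResult:
    """Per-ring kerma per history with batch standard errors."""

    r_centers: np.ndarray
    kerma_per_photon: np.ndarray         # Gy / source photon
    stderr: np.ndarray                   # same units, from batch means
    mean_energy: np.ndarray              # fluence-weighted MeV
    counts: np.ndarray
    n_histories: int
    n_batches: int
    kill_counts: dict
    tally_height: float
    ring_width: float

    def scaled_akr(self, norm: NormalizationRecord,
                   field_area_f0: float | None = None):
        """Dimensionless K_a / D0 profile (value, stderr).

        By default the denominator is the per-photon isocenter kerma of the
        10 x 10 cm^2 reference field.  Passing ``field_area_f0`` (cm^2)
        instead scales to the isocenter dose rate of the *actual* field —
        the basis on which broad-field profiles are compared with the
        algebraic air-kerma-rate formula (at fixed machine dose rate the
        photon emission rate, and hence the skyshine, grows with field area
        while the central-axis dose rate does not).
        """
        d0 = norm.d0_per_photon
        if field_area_f0 is not None:
            if field_area_f0 <= 0:
                raise ValueError("field area must be positive")
            d0 = d0 * (100.0 / field_area_f0)
        return self.kerma_per_photon / d0, self.stderr / d0

    def exposure_per_ci(self, norm: NormalizationRecord):
        """Exposure rate in uR/h per Ci of Co-60 (value, stderr)."""
        return (self.kerma_per_photon * norm.exposure_scale,
                self.stderr * norm.exposure_scale)

    def ring_index(self, d_s: float) -> int:
        i = int(np.argmin(np.abs(self.r_centers - d_s)))
        return i

    def to_dataframe(self, norm: NormalizationRecord | None = None,
                     mode: str = "scaled_AKR") -> pd.DataFrame:
        df = pd.DataFrame({
            "r_center_m": self.r_centers,
            "kerma_per_photon_Gy": self.kerma_per_photon,
            "stderr_Gy": self.stderr,
            "mean_E_MeV": self.mean_energy,
            "n_crossings": self.counts.astype(int),
        })
        if norm is not None:
            val, err = finalize(self, norm, mode)
            col = "scaled_akr" if mode == "scaled_AKR" else "uR_per_h_per_Ci"
            df[col] = val
            df[col + "_stderr"] = err
        return df


def finalize(result: RingTallyResult, norm: NormalizationRecord,
             mode: str = "scaled_AKR"):
    """Normalize a finished run: ``scaled_AKR`` or ``exposure_per_Ci``."""
    if result.n_histories <= 0:
        raise ValueError("no histories were run")
    if mode == "scaled_AKR":
        return result.scaled_akr(norm)
    if mode == "exposure_per_Ci":
        return result.exposure_per_ci(norm)
    raise ValueError(f"unknown normalization mode {mode!r}")
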