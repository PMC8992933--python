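"""Beam definition and initial photon sampling.

A linac beam is modelled as a point source on the cylinder axis, 1.0 m below
the isocenter (100 cm target-to-isocenter distance), emitting photons with a
fluence that is isotropic over a cone.  The cone half-angle follows from the
equivalent-circle field area at isocenter: ``pi r^2 = F0`` at 100 cm, so a
40 x 40 cm^2 (1600 cm^2) field corresponds to a half-angle of about 12.7
degrees.  The benchmark silo instead uses a bare isotropic point source.

Exact published linac spectra can be supplied as two-column text files; a
parametric bremsstrahlung-shaped stand-in is bundled for the five standard
accelerating potentials.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .constants import PARAMETRIC_MEAN_ENERGY_MEV, SUPPORTED_MV

E_CUTOFF_MEV = 0.01
SAD_M = 1.0  # source-to-isocenter distance

__all__ = ["BeamSpectrum", "BeamSource", "parametric_mv_spectrum", "sample_photon"]


@dataclass(frozen=True)
class BeamSpectrum:
    """Photon energy spectrum: histogram bins, discrete lines, or one line.

    For ``mode="histogram"`` `energies` holds the bin edges (n+1 values) and
    `weights` the relative fluence *per bin* (n values).  For ``"lines"`` and
    ``"monoenergetic"`` both arrays have equal length.
    """

    mode: str
    energies: np.ndarray
    weights: np.ndarray
    nominal_mv: str = ""

    def __post_init__(self):
        e = np.asarray(self.energies, float)
        w = np.asarray(self.weights, float)
        if self.mode not in ("histogram", "lines", "monoenergetic"):
            raise ValueError(f"unknown spectrum mode {self.mode!r}")
        n_expected = len(e) - 1 if self.mode == "histogram" else len(e)
        if len(w) != n_expected or n_expected < 1:
            raise ValueError("energy/weight arrays have inconsistent lengths")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 with at least one positive")
        if np.any(e <= 0):
            raise ValueError("energies must be positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    @classmethod
    def monoenergetic(cls, energy: float) -> "BeamSpectrum":
        return cls("monoenergetic", np.array([energy]), np.array([1.0]))

    @classmethod
    def lines(cls, energies, weights, label: str = "") -> "BeamSpectrum":
        return cls("lines", np.asarray(energies, float),
                   np.asarray(weights, float), label)

    @classmethod
    def co60(cls) -> "BeamSpectrum":
        """The two Co-60 gamma lines, equal intensity."""
        return cls.lines([1.17, 1.33], [0.5, 0.5], "Co-60")

    @classmethod
    def from_file(cls, path: str | Path, label: str = "") -> "BeamSpectrum":
        """Read a histogram spectrum: ``energy_upper_MeV  relative_fluence``.

        Whitespace- or comma-separated text; ``#`` starts a comment.  Bin
        lower edges are the preceding upper edges (first bin starts at the
        transport cutoff).
        """
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip().replace(",", " ")
            if line:
                upper, weight = line.split()[:2]
                rows.append((float(upper), float(weight)))
        if not rows:
            raise ValueError(f"no spectrum rows in {path}")
        uppers = np.array([r[0] for r in rows])
        weights = np.array([r[1] for r in rows])
        edges = np.concatenate([[min(E_CUTOFF_MEV, uppers[0] * 0.5)], uppers])
        return cls("histogram", edges, weights, label or str(path))

    def mean_energy(self) -> float:
        w = self.weights / self.weights.sum()
        if self.mode == "histogram":
            centers = 0.5 * (self.energies[1:] + self.energies[:-1])
            return float(np.sum(w * centers))
        return float(np.sum(w * self.energies))

    def sampling_arrays(self) -> tuple[int, np.ndarray, np.ndarray]:
        """(mode code, energy array, cumulative weights) for the kernel."""
        cdf = np.cumsum(self.weights / self.weights.sum())
        code = {"monoenergetic": 0, "lines": 1, "histogram": 2}[self.mode]
        return code, np.ascontiguousarray(self.energies, float), cdf


def parametric_mv_spectrum(nominal_mv: int, n_bins: int = 100) -> BeamSpectrum:
    """Bremsstrahlung-shaped histogram spectrum for a nominal MV.

    Thin-target kernel ``(E_max - E)/E`` hardened by an ``exp(-b/E)`` factor;
    the single hardening parameter ``b`` is solved per MV so the mean photon
    energy matches the bundled anchor (2.0 MeV for 6 MV, 3.2 MeV for 10 MV,
    6.0 MeV for 18 MV, interpolated anchors otherwise).  A stand-in for
    published linac spectra, which can be dropped in via
    :meth:`BeamSpectrum.from_file`.
    """
    if nominal_mv not in SUPPORTED_MV:
        raise ValueError(f"unsupported nominal MV {nominal_mv}; "
                         f"supported: {SUPPORTED_MV}")
    e_max = float(nominal_mv)
    target = PARAMETRIC_MEAN_ENERGY_MEV[nominal_mv]
    edges = np.linspace(E_CUTOFF_MEV, e_max, n_bins + 1)
    centers = 0.5 * (edges[1:] + edges[:-1])

    def mean_for(b):
        w = (e_max - centers) / centers * np.exp(-b / centers)
        return float(np.sum(w * centers) / np.sum(w))

    b = brentq(lambda b: mean_for(b) - target, 1e-6, 50.0, xtol=1e-10)
    weights = (e_max - centers) / centers * np.exp(-b / centers)
    return BeamSpectrum("histogram", edges, weights, f"{nominal_mv} MV (parametric)")


@dataclass(frozen=True)
class BeamSource:
    """Point photon source on the cylinder axis.

    ``field_area_f0`` (cm^2 at the 100 cm reference distance) selects conical
    emission along +z; ``isotropic=True`` selects a bare isotropic point
    source (silo benchmark).  ``position_z`` is metres above outside grade.
    """

    spectrum: BeamSpectrum
    position_z: float
    field_area_f0: float = 0.0
    isotropic: bool = False

    def __post_init__(self):
        if not self.isotropic and self.field_area_f0 < 0:
            raise ValueError("field area must be >= 0")

    @property
    def cone_cos_min(self) -> float:
        """cos of the cone half-angle; 1.0 for the degenerate 0 x 0 beam."""
        if self.isotropic:
            return -1.0
        if self.field_area_f0 == 0.0:
            return 1.0
        r_iso_m = math.sqrt(self.field_area_f0 / math.pi) / 100.0
        return math.cos(math.atan2(r_iso_m, SAD_M))

    @property
    def cone_half_angle_deg(self) -> float:
        return math.degrees(math.acos(max(self.cone_cos_min, -1.0)))


def sample_photon(source: BeamSource, rng: np.random.Generator):
    """Draw one initial photon state ``(position, direction, energy)``.

    Energy follows the spectrum weights (uniform within a histogram bin,
    resampling anything below the 10 keV cutoff); the direction is uniform
    per solid angle within the cone (or over 4 pi for an isotropic source).
    """
    spec = source.spectrum
    mode, e_arr, cdf = spec.sampling_arrays()
    while True:
        if mode == 0:
            energy = e_arr[0]
        elif mode == 1:
            energy = e_arr[np.searchsorted(cdf, rng.random())]
        else:
            j = int(np.searchsorted(cdf, rng.random()))
            energy = e_arr[j] + rng.random() * (e_arr[j + 1] - e_arr[j])
        if energy >= E_CUTOFF_MEV:
            break
    cos_min = source.cone_cos_min
    w = cos_min + rng.random() * (1.0 - cos_min)
    phi = 2.0 * math.pi * rng.random()
    s = math.sqrt(max(0.0, 1.0 - w * w))
    direction = np.array([s * math.cos(phi), s * math.sin(phi), w])
    position = np.array([0.0, 0.0, source.position_z])
    return position, direction, float(energy)
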