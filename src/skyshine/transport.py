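"""Monte Carlo driver: analog photon transport with ring tallies.

The physics lives in the compiled kernel (:mod:`skyshine._kernel`); this
module provides the run configuration, the per-history and full-run entry
points, and reproducible batch statistics.  No variance reduction is used:
every history is an analog random walk from the source to absorption,
cutoff, pair production or escape from the (2 km) world.

Reproducibility contract: results depend only on ``(seed, n_histories,
n_batches)``.  Each batch owns an independent RNG stream spawned from the
run seed, so the same configuration gives bit-identical tallies.
"""
from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .geometry import CylinderShieldGeometry
from .source import BeamSource
from .tally import RingTallySet, RingTallyResult
from .xsdata import MaterialTable, load_material

logger = logging.getLogger("skyshine")

KILL_LABELS = ("escaped", "photoelectric", "pair", "cutoff",
               "scatter_limit", "ground_kill")

__all__ = ["PhotonState", "RunConfig", "compton_scatter", "step_history", "run"]


@dataclass
class PhotonState:
    """One photon in flight: position (m), direction cosines, energy (MeV)."""

    position: np.ndarray
    direction: np.ndarray
    energy: float
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        self.direction = np.asarray(self.direction, float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction cosines not normalized (|d|={norm})")
        if self.alive and self.energy < 0.01:
            raise ValueError("a live photon must carry at least 10 keV")


@dataclass(frozen=True)
class RunConfig:
    """Transport run parameters."""

    n_histories: int = 1_000_000
    seed: int = 1
    n_batches: int = 20
    air_density: float = 1.225e-3        # g/cm^3
    cutoff: float = 0.01                 # MeV
    scatter_limit: int = 0               # 0: unlimited
    ground_kill: bool = False
    tally_height: float = 1.3            # m above outside grade
    ring_width: float = 0.5              # m
    n_rings: int = 120
    w_floor: float = 0.02

    def __post_init__(self):
        if not (self.n_histories >= self.n_batches >= 2):
            raise ValueError("need n_histories >= n_batches >= 2")


def _batch_seeds(seed: int, n_batches: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n_batches, dtype=np.uint64) % (2**31 - 1)
            ).astype(np.int64) + 1


class _XsPack:
    """Cross-section tables packed as log-log arrays for the kernel.

    Material index 0 is air, 1 is concrete (walls, roof and ground share it
    unless a different table is supplied).
    """

    def __init__(self, air: MaterialTable, concrete: MaterialTable):
        if not np.array_equal(air.energy_grid, concrete.energy_grid):
            raise ValueError("material tables must share one energy grid")
        self.air = air
        self.concrete = concrete
        self.lg_e = np.log(air.energy_grid)

        def pack(*cols):
            out = np.empty((len(cols), len(self.lg_e)))
            for i, c in enumerate(cols):
                out[i] = np.log(np.maximum(c, 1e-300))
            return out

        self.lg_pe = pack(air.mu_photoelectric, concrete.mu_photoelectric)
        self.lg_inc = pack(air.mu_incoherent, concrete.mu_incoherent)
        self.lg_pair = pack(air.mu_pair, concrete.mu_pair)
        self.lg_muen_air = np.log(np.maximum(air.muen_over_rho, 1e-300))
        self.densities = np.array([air.material.density,
                                   concrete.material.density])


def default_tables(air_density: float = 1.225e-3) -> _XsPack:
    return _XsPack(load_material("air", density=air_density),
                   load_material("concrete"))


_REGION_MAT = np.array([0, 1, 1, 1], dtype=np.int64)  # air, wall, roof, ground


def compton_scatter(energy: float, rng) -> tuple[float, float, float]:
    """Sample one Klein-Nishina Compton scatter of a photon of ``energy``.

    Returns ``(scattered energy MeV, polar angle rad, azimuth rad)``.
    ``rng`` may be a ``numpy.random.Generator`` or an integer seed.
    """
    if energy < 0.01:
        raise ValueError("energy below the 10 keV cutoff")
    seed = int(rng) if isinstance(rng, (int, np.integer)) else \
        int(rng.integers(1, 2**31 - 1))
    _kernel.seed_rng(seed)
    e_new, cost = _kernel.sample_compton(energy)
    phi = 2.0 * math.pi * np.random.default_rng(seed).random()
    return e_new, math.acos(cost), phi


def step_history(photon: PhotonState, geom: CylinderShieldGeometry,
                 tables: _XsPack, tallies: RingTallySet, rng,
                 scatter_limit: int = 0, ground_kill: bool = False,
                 cutoff: float = 0.01) -> tuple[PhotonState, str]:
    """Transport one photon to termination, scoring ``tallies`` in place.

    Returns the (dead) photon and the termination reason.  Thin wrapper over
    the compiled kernel used for single-history tests and demonstrations.
    """
    if not photon.alive:
        raise ValueError("photon is not alive")
    if not np.all(np.isfinite(photon.position)):
        raise ValueError(f"non-finite photon state: {photon.position}")
    seed = int(rng) if isinstance(rng, (int, np.integer)) else \
        int(rng.integers(1, 2**31 - 1))
    _kernel.seed_rng(seed)
    code = _kernel.transport_one(
        float(photon.position[0]), float(photon.position[1]),
        float(photon.position[2]),
        float(photon.direction[0]), float(photon.direction[1]),
        float(photon.direction[2]), float(photon.energy),
        geom.to_params(), _REGION_MAT, tables.densities,
        tables.lg_e, tables.lg_pe, tables.lg_inc, tables.lg_pair,
        tables.lg_muen_air,
        tallies.z, tallies.dr, tallies.w_floor,
        ground_kill, scatter_limit, cutoff,
        tallies.kerma, tallies.phi, tallies.e_phi, tallies.e_sum,
        tallies.count)
    photon.alive = False
    return photon, KILL_LABELS[code]


def run(config: RunConfig, geom: CylinderShieldGeometry, source: BeamSource,
        tallies: RingTallySet | None = None,
        tables: _XsPack | None = None) -> RingTallyResult:
    """Run ``config.n_histories`` analog histories and return ring tallies.

    Histories are split into ``config.n_batches`` independent batches; the
    reported standard error is the standard deviation of the batch means.
    """
    if tallies is None:
        tallies = RingTallySet(z=config.tally_height, dr=config.ring_width,
                               n_rings=config.n_rings, w_floor=config.w_floor)
    if tables is None:
        tables = default_tables(air_density=config.air_density)

    e_mode, e_arr, e_cdf = source.spectrum.sampling_arrays()
    gp = geom.to_params()
    seeds = _batch_seeds(config.seed, config.n_batches)
    per_batch = np.full(config.n_batches, config.n_histories // config.n_batches)
    per_batch[: config.n_histories % config.n_batches] += 1

    n_rings = tallies.n_rings
    batch_kerma = np.zeros((config.n_batches, n_rings))
    kills = np.zeros(_kernel.N_KILL_CODES, dtype=np.int64)
    t0 = time.time()
    for b in range(config.n_batches):
        kerma = np.zeros(n_rings)
        phi = np.zeros(n_rings)
        e_phi = np.zeros(n_rings)
        e_sum = np.zeros(n_rings)
        count = np.zeros(n_rings)
        bk = np.zeros(_kernel.N_KILL_CODES, dtype=np.int64)
        _kernel.run_batch(
            int(seeds[b]), int(per_batch[b]),
            source.position_z, source.cone_cos_min, e_mode, e_arr, e_cdf,
            gp, _REGION_MAT, tables.densities,
            tables.lg_e, tables.lg_pe, tables.lg_inc, tables.lg_pair,
            tables.lg_muen_air,
            tallies.z, tallies.dr, tallies.w_floor,
            config.ground_kill, config.scatter_limit, config.cutoff,
            kerma, phi, e_phi, e_sum, count, bk)
        batch_kerma[b] = kerma / per_batch[b]
        tallies.kerma += kerma
        tallies.phi += phi
        tallies.e_phi += e_phi
        tallies.e_sum += e_sum
        tallies.count += count
        kills += bk
        logger.info("batch %d/%d done (%.0f hist/s)", b + 1, config.n_batches,
                    per_batch[: b + 1].sum() / max(time.time() - t0, 1e-9))

    elapsed = time.time() - t0
    logger.info("run complete: %d histories in %.1f s; terminations: %s",
                config.n_histories, elapsed,
                dict(zip(KILL_LABELS, kills.tolist())))
    kerma_mean = batch_kerma.mean(axis=0)
    stderr = batch_kerma.std(axis=0, ddof=1) / math.sqrt(config.n_batches)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_e = np.where(tallies.phi > 0, tallies.e_phi / tallies.phi, 0.0)
    return RingTallyResult(
        r_centers=tallies.r_centers,
        kerma_per_photon=kerma_mean,
        stderr=stderr,
        mean_energy=mean_e,
        counts=tallies.count.copy(),
        n_histories=config.n_histories,
        n_batches=config.n_batches,
        kill_counts=dict(zip(KILL_LABELS, kills.tolist())),
        tally_height=tallies.z,
        ring_width=tallies.dr,
    )
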