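"""Canned experiment recipes, TOML configuration and result files.

Two families of presets reproduce the benchmark runs:

* the Kansas State University skyshine silo — a hollow concrete cylinder
  (outer radius 2.16 m, wall 0.91 m, 2.3 m tall) with an isotropic Co-60
  point source on the axis at 2.0 m height, tallied at 1.0 m height in
  0.5 m rings and reported as uR/h per Ci (open, or with a 43 cm lid);
* the nominal linac vault — (d_w, h) = (5, 3) m and variants, a conical
  megavoltage beam fired straight up, tallied at 1.3 m height and reported
  as the dimensionless scaled AKR.

Every recipe is fully self-contained (bundled data only, no network) and a
result echoes its configuration so any run can be reproduced bit-exactly.
"""
from __future__ import annotations

import io
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .geometry import CylinderShieldGeometry
from .source import BeamSource, BeamSpectrum, parametric_mv_spectrum
from .tally import NormalizationRecord, RingTallyResult, finalize, \
    isocenter_kerma_per_photon
from .transport import RunConfig, default_tables, run

__all__ = ["ExperimentRecipe", "build_ksu_benchmark", "build_vault_recipe",
           "run_recipe", "recipe_to_toml", "recipe_from_toml",
           "write_result_csv"]

EXIT_CONFIG_ERROR = 2
EXIT_PHYSICS_ERROR = 3


@dataclass(frozen=True)
class ExperimentRecipe:
    """A reproducible run: geometry + source + run parameters + output mode."""

    name: str
    geometry: CylinderShieldGeometry
    source: BeamSource
    config: RunConfig
    mode: str = "scaled_AKR"             # or "exposure_per_Ci"

    def with_(self, **kw) -> "ExperimentRecipe":
        cfg = self.config
        cfg_kw = {k: kw.pop(k) for k in list(kw)
                  if k in RunConfig.__dataclass_fields__}
        if cfg_kw:
            cfg = RunConfig(**{**asdict(cfg), **cfg_kw})
        return ExperimentRecipe(name=kw.pop("name", self.name),
                                geometry=kw.pop("geometry", self.geometry),
                                source=kw.pop("source", self.source),
                                config=cfg, mode=kw.pop("mode", self.mode))


def build_ksu_benchmark(lid: str = "open", n_histories: int = 10_000_000,
                        seed: int = 1) -> ExperimentRecipe:
    """The benchmark silo: empty concrete cylinder, isotropic Co-60 source.

    ``lid`` is ``"open"`` (air density 1.12e-3 g/cm^3, as for the roofless
    measurements) or ``"43cm"`` (a 43 cm concrete lid, density 1.21e-3).
    """
    if lid not in ("open", "43cm"):
        raise ValueError("lid must be 'open' or '43cm'")
    lid_t = 0.0 if lid == "open" else 0.43
    density = 1.12e-3 if lid == "open" else 1.21e-3
    geom = CylinderShieldGeometry.silo(lid_thickness=lid_t)
    source = BeamSource(spectrum=BeamSpectrum.co60(), position_z=2.0,
                        isotropic=True)
    config = RunConfig(n_histories=n_histories, seed=seed,
                       air_density=density, tally_height=1.0,
                       ring_width=0.5, n_rings=120)
    return ExperimentRecipe(f"ksu-silo-{lid}", geom, source, config,
                            mode="exposure_per_Ci")


def build_vault_recipe(nominal_mv: int, f0_cm2: float = 1600.0,
                       d_w: float = 5.0, h: float = 3.0, t_r: float = 0.0,
                       n_histories: int = 10_000_000, seed: int = 1,
                       spectrum: BeamSpectrum | None = None,
                       **config_kw) -> ExperimentRecipe:
    """A vault skyshine run: conical beam straight up, scaled-AKR output.

    ``t_r`` is the roof thickness in metres.  ``spectrum`` overrides the
    parametric stand-in (e.g. a published spectrum from a file).
    """
    spec = spectrum if spectrum is not None else parametric_mv_spectrum(nominal_mv)
    geom = CylinderShieldGeometry.vault(d_w=d_w, h=h, t_r=t_r)
    source = BeamSource(spectrum=spec, field_area_f0=f0_cm2,
                        position_z=geom.isocenter_height - 1.0)
    config = RunConfig(n_histories=n_histories, seed=seed, tally_height=1.3,
                       ring_width=0.5, n_rings=80, **config_kw)
    name = f"vault-{nominal_mv}MV-F{f0_cm2:.0f}-dw{d_w:g}-h{h:g}-tr{t_r:g}"
    return ExperimentRecipe(name, geom, source, config, mode="scaled_AKR")


def run_recipe(recipe: ExperimentRecipe):
    """Execute a recipe; returns ``(RingTallyResult, NormalizationRecord)``."""
    tables = default_tables(air_density=recipe.config.air_density)
    result = run(recipe.config, recipe.geometry, recipe.source, tables=tables)
    d0 = isocenter_kerma_per_photon(recipe.source.spectrum, tables.air)
    return result, NormalizationRecord(d0_per_photon=d0)


# ---------------------------------------------------------------------------
# configuration files

def recipe_to_toml(recipe: ExperimentRecipe) -> str:
    g, s, c = recipe.geometry, recipe.source, recipe.config
    spec = s.spectrum
    lines = [
        f'name = "{recipe.name}"',
        f'mode = "{recipe.mode}"',
        "",
        "[geometry]",
        f"d_w_m = {g.d_w}",
        f"wall_thickness_m = {g.wall_thickness}",
        f"h_m = {g.h}",
        f"t_r_m = {g.t_r}",
        f"isocenter_height_m = {g.isocenter_height}",
        f"roof_on_top = {str(g.roof_on_top).lower()}",
        f"world_radius_m = {g.world_radius}",
        "",
        "[source]",
        f'spectrum_mode = "{spec.mode}"',
        f"energies_MeV = {np.asarray(spec.energies).tolist()}",
        f"weights = {np.asarray(spec.weights).tolist()}",
        f'nominal_mv = "{spec.nominal_mv}"',
        f"position_z_m = {s.position_z}",
        f"field_area_F0_cm2 = {s.field_area_f0}",
        f"isotropic = {str(s.isotropic).lower()}",
        "",
        "[run]",
        f"n_histories = {c.n_histories}",
        f"seed = {c.seed}",
        f"n_batches = {c.n_batches}",
        f"air_density_g_cm3 = {c.air_density}",
        f"cutoff_MeV = {c.cutoff}",
        f"scatter_limit = {c.scatter_limit}",
        f"ground_kill = {str(c.ground_kill).lower()}",
        f"tally_height_m = {c.tally_height}",
        f"ring_width_m = {c.ring_width}",
        f"n_rings = {c.n_rings}",
    ]
    return "\n".join(lines) + "\n"


def recipe_from_toml(text_or_path) -> ExperimentRecipe:
    raw = str(text_or_path)
    if "\n" in raw:          # inline TOML text rather than a file path
        text = raw
    else:
        text = Path(raw).read_text()
    data = tomllib.loads(text)
    g = data["geometry"]
    geom = CylinderShieldGeometry(
        d_w=g["d_w_m"], wall_thickness=g["wall_thickness_m"], h=g["h_m"],
        t_r=g["t_r_m"], isocenter_height=g["isocenter_height_m"],
        roof_on_top=g.get("roof_on_top", False),
        world_radius=g.get("world_radius_m", 2000.0))
    s = data["source"]
    spec = BeamSpectrum(s["spectrum_mode"], np.array(s["energies_MeV"]),
                        np.array(s["weights"]), s.get("nominal_mv", ""))
    source = BeamSource(spectrum=spec, position_z=s["position_z_m"],
                        field_area_f0=s.get("field_area_F0_cm2", 0.0),
                        isotropic=s.get("isotropic", False))
    c = data["run"]
    config = RunConfig(
        n_histories=c["n_histories"], seed=c["seed"],
        n_batches=c.get("n_batches", 20),
        air_density=c.get("air_density_g_cm3", 1.225e-3),
        cutoff=c.get("cutoff_MeV", 0.01),
        scatter_limit=c.get("scatter_limit", 0),
        ground_kill=c.get("ground_kill", False),
        tally_height=c.get("tally_height_m", 1.3),
        ring_width=c.get("ring_width_m", 0.5),
        n_rings=c.get("n_rings", 120))
    return ExperimentRecipe(data.get("name", "run"), geom, source, config,
                            data.get("mode", "scaled_AKR"))


def write_result_csv(path, recipe: ExperimentRecipe, result: RingTallyResult,
                     norm: NormalizationRecord) -> None:
    """Result CSV with a commented metadata header echoing the full config."""
    val, err = finalize(result, norm, recipe.mode)
    buf = io.StringIO()
    for line in recipe_to_toml(recipe).splitlines():
        buf.write(f"# {line}\n")
    col = "scaled_akr" if recipe.mode == "scaled_AKR" else "uR_per_h_per_Ci"
    buf.write(f"r_center_m,{col},stderr,mean_E_MeV,n_crossings\n")
    for i in range(len(result.r_centers)):
        buf.write(f"{result.r_centers[i]:.3f},{val[i]:.6e},{err[i]:.6e},"
                  f"{result.mean_energy[i]:.4f},{int(result.counts[i])}\n")
    Path(path).write_text(buf.getvalue())
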