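"""Validate the transport engine against the single-scatter integral.

2 MeV photons are projected straight up the axis of a roofless (5 m, 3 m)
vault; transport is truncated after one Compton scatter and ground scatter
is disabled, which makes the ring kerma an exactly computable quadrature.
Prints both answers side by side.
"""
import numpy as np

from skyshine import (BeamSource, BeamSpectrum, CylinderShieldGeometry,
                      RunConfig, SingleScatterProblem,
                      isocenter_kerma_per_photon, run, single_scatter_kerma)
from skyshine.xsdata import load_material

geom = CylinderShieldGeometry.vault(d_w=5.0, h=3.0)
source = BeamSource(BeamSpectrum.monoenergetic(2.0), position_z=0.3,
                    field_area_f0=0.0)
config = RunConfig(n_histories=1_000_000, seed=1, scatter_limit=1,
                   ground_kill=True, tally_height=1.3, n_rings=70)
result = run(config, geom, source)
d0 = isocenter_kerma_per_photon(BeamSpectrum.monoenergetic(2.0),
                                load_material("air"))

problem = SingleScatterProblem(e0=2.0, geometry=geom)
print("d_s (m)   MC (K/D0)        quadrature       z")
for ds in (6.25, 8.25, 10.25, 12.25, 16.25, 20.25, 25.25):
    i = result.ring_index(ds)
    mc, err = result.kerma_per_photon[i] / d0, result.stderr[i] / d0
    oracle = float(np.mean(single_scatter_kerma(
        problem, np.array([ds - 0.15, ds, ds + 0.15]))))
    print(f"{ds:6.2f}   {mc:.3e}       {oracle:.3e}    "
          f"{(mc - oracle) / err:+.1f}")
# Agreement within ~2 sigma at every ring checks the Klein-Nishina sampler,
# the heterogeneous free-path sampling, the wall shadowing and the ring
# fluence estimator in one shot.
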