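"""Full image formation: initial pressure -> planar detection -> time reversal.

Simulates the 4-wavelength image set for one phantom (with 1% sensor noise)
and quantifies the limited-view reconstruction fidelity inside the vessels.
"""

import numpy as np

from paovox import phantom
from paovox.acoustics import AcousticSpec, simulate_image_set
from paovox.fluence import initial_pressure, simulate_fluence

rng = np.random.default_rng(3)
grid = phantom.GridSpec(16, 24, 24, 0.1)
params = phantom.VesselTreeParams(n_seeds=3, radius_range_mm=(0.2, 0.3))
model = phantom.random_tissue_model(grid, rng, params=params)

p0 = {}
for lam in model.wavelengths:
    fl = simulate_fluence(model, lam, n_photons=10**5, seed=int(lam))
    p0[lam] = initial_pressure(model, fl, lam)

image = simulate_image_set(
    model, p0, spec=AcousticSpec(pml_width=6), noise_coeff=0.01, noise_seed=5
)
print(f"image set shape {image.data.shape} (channels = {image.wavelengths})")

sel = model.body_id > 0
depths = (np.nonzero(sel)[0] + 0.5) * grid.dx_mm
for i, lam in enumerate(image.wavelengths):
    r = np.corrcoef(image.data[i][sel], p0[lam][sel])[0, 1]
    print(f"  {lam:.0f} nm: correlation(reconstruction, true p0) in vessels = {r:.3f}")
print("correlations below 1 reflect limited-view artifacts and sensor noise")
shallow = depths < np.median(depths)
for name, group in (("shallow", shallow), ("deep", ~shallow)):
    rs = [
        np.corrcoef(image.data[i][sel][group], p0[lam][sel][group])[0, 1]
        for i, lam in enumerate(image.wavelengths)
    ]
    print(f"  {name:>7} vessel voxels: mean correlation {np.mean(rs):.3f}")
print("fidelity is lower for the deeper voxels; over an ensemble of")
print("phantoms this depth trend is systematic (see the acoustics tests) —")
print("the limited-view effect the learned estimator must compensate")
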