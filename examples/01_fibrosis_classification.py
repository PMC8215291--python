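"""Classify fibrotic wall from an LGE-like intensity volume.

Builds a synthetic atrial chamber with seeded fibrotic patches, voxelizes
it into an intensity volume, then runs the imaging side of the pipeline:
project intensities through the wall along inward normals, form the image
intensity ratio (IIR) against the blood-pool mean, and threshold at 1.22.
"""

import numpy as np

from atriaflow import (classify_fibrosis, compute_iir, fibrotic_burden_percent,
                       make_chamber_mesh, project_image_to_surface,
                       seed_fibrotic_patches, synth_intensity_volume,
                       vertex_normals)

mesh = make_chamber_mesh(n_vertices=3000, semi_axes=(45, 35, 25), seed=1)
mask, target_burden = seed_fibrotic_patches(mesh, target_burden=17.8,
                                            n_patches=3, seed=2)
volume = synth_intensity_volume(mesh, mask, blood_pool_mean=100.0,
                                contrast=1.5, noise_sd=2.0, seed=3)

normals = vertex_normals(mesh, orientation="inward")
intensity = project_image_to_surface(volume, mesh, normals, depth=2.5)
iir = compute_iir(intensity, blood_pool_mean=100.0)
recovered = classify_fibrosis(iir, threshold=1.22)

agreement = np.mean(recovered.fibrotic == mask.fibrotic)
print(f"seeded fibrotic burden:    {target_burden:.2f} % of wall area")
print(f"recovered fibrotic burden: {fibrotic_burden_percent(mesh, recovered):.2f} %")
print(f"vertexwise agreement:      {100 * agreement:.1f} %")
# The recovered burden tracks the seeded one up to voxelization error at
# patch boundaries; agreement is the fraction of wall points whose
# fibrotic/non-fibrotic label survives the image round trip.
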