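"""Run the full 3D axon/release-site pipeline on a synthetic volume.

Renders a two-channel volume (axon marker + cluster marker) with clusters
planted preferentially inside the axons and smaller than the extra-axonal
ones, then runs the whole per-ROI analysis: Otsu segmentation, size filters,
skeleton length density, >40%-overlap classification, and a local-shuffle
null. Shuffling should lower the in-axon cluster density and raise the mean
in-axon cluster volume — the signature of genuine intra-axonal clustering.
"""

import numpy as np

from dopaquant._rng import substream
from dopaquant.sim3d import Sim3dConfig, analyze_roi
from dopaquant.synth import VolumeSpec, render_scene

spec = VolumeSpec(
    shape_voxels=(28, 140, 140), voxel_size_um=(0.125, 0.08, 0.08),
    n_axons=2, axon_radius_um=0.25,
    cluster_rate_inside=1.5, cluster_rate_outside=0.6,
    cluster_volume_range_um3=(0.004, 0.012),          # inside: small clusters
    cluster_volume_range_outside_um3=(0.015, 0.035),  # outside: larger ones
    seed=3,
)
lines = [
    np.array([[1.75, 2.0, 0.5], [1.75, 9.0, 10.5]]),
    np.array([[1.4, 9.0, 1.0], [1.4, 2.0, 10.0]]),
]
volume, truth = render_scene(lines, spec, substream(spec.seed, "synth.volume"))

config = Sim3dConfig(shuffle_rounds=300, seed=11)
metrics = analyze_roi(volume, config=config)

print(f"true axon length      : {truth.true_axon_length_um:.2f} µm")
print(f"TH volume fraction    : {metrics.th_volume_fraction:.4f} "
      f"(truth {truth.true_th_volume_fraction:.4f})")
print(f"axon length density   : {metrics.axon_length_density_um_per_um3:.4f} µm/µm³")
print(f"in-axon cluster density: {metrics.in_axon_cluster_density_per_um3:.4f} /µm³ "
      f"| shuffled {metrics.shuffled_density_per_um3:.4f} /µm³")
print(f"in-axon mean volume    : {metrics.in_axon_mean_cluster_volume_um3:.4f} µm³ "
      f"| shuffled {metrics.shuffled_volume_um3:.4f} µm³")
print("shuffle control: density drops and volume rises when clusters genuinely "
      "sit inside axons")
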