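#!/usr/bin/env python
"""Multi-state map averaging: alignment, mean/variance maps, FSC.

Simulates seven conformational states in which a sub-structure rotates,
aligns and averages the maps, and quantifies (a) the signal-to-noise gain
of averaging and (b) the variance signature of the mobile region — the
map-space evidence that a sub-structure moves between states.
"""

import os

import numpy as np

from helixtrace import synthetic_data as sd
from helixtrace.map_ops import average_maps, fsc, write_fsc, write_map
from helixtrace.synthetic_data import MapSpec

SEED = 11
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "states")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    bundle = sd.make_bundle(4, [20] * 4, spacing=12.0, rng_seed=SEED)
    centre = bundle.model.ca.mean(axis=0)
    angles = [0, 6, 12, 18, 24, 30, 36]
    maps, models = sd.make_state_ensemble(
        bundle, {4}, angles, centre, [0, 0, 1],
        MapSpec(noise_sigma=0.1), rng_seed=SEED)
    print(f"seven states; helix 4 rotated by {angles} degrees")

    mean_map, var_map = average_maps(maps)
    write_map(mean_map, os.path.join(OUT, "mean.mrc"))
    write_map(var_map, os.path.join(OUT, "variance.mrc"))

    corner = (slice(0, 8), slice(0, 8), slice(0, 8))
    single = float(np.mean([m.grid[corner].std() for m in maps]))
    gain = single / float(mean_map.grid[corner].std())
    print(f"background noise reduced by x{gain:.2f} "
          f"(sqrt(7) = {np.sqrt(7):.2f} expected for 7 maps)")

    from scipy.spatial.distance import cdist

    world = var_map.index_to_world(np.indices(var_map.shape).reshape(3, -1).T)
    mobile_ca = np.concatenate([m.ca[-20:] for m in models])
    static_ca = models[0].ca[:60]
    near_mobile = cdist(world, mobile_ca).min(axis=1) < 3.0
    near_static = (cdist(world, static_ca).min(axis=1) < 3.0) & ~near_mobile
    v = var_map.grid.reshape(-1)
    print(f"median voxel variance: mobile region "
          f"{np.median(v[near_mobile]):.4f} vs static "
          f"{np.median(v[near_static]):.4f} (blurring where states differ)")

    half_a = sd.render_map(bundle.model, MapSpec(box_edge=48, noise_sigma=0.05), 1)
    half_b = sd.render_map(bundle.model, MapSpec(box_edge=48, noise_sigma=0.05), 2)
    curve = fsc(half_a, half_b)
    write_fsc(curve, os.path.join(OUT, "fsc.tsv"))
    print(f"FSC at 1/10 A^-1: {curve.value_at(0.1):.3f} "
          f"(0.143 crossing at {curve.crossing():.3f} A^-1)")
    print(f"wrote mean.mrc, variance.mrc, fsc.tsv -> {OUT}")


if __name__ == "__main__":
    main()
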