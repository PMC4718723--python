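# helixtrace

Tracing a membrane subunit's α-helical fold through a medium-resolution
cryo-EM density map with evolutionary-covariance constraints — and
quantifying conformational heterogeneity between rotational states by map
averaging and rigid-rotation analysis.

## The problem

At 6–8 Å resolution a trans-membrane α-helix appears in a cryo-EM map as a
featureless tubular rod: the map shows *where* helices are, but not *which*
sequence segment occupies which rod, nor in which direction. Co-evolving
residue pairs inferred from deep sequence alignments provide the missing
information: strongly coupled residues are spatially close, so the correct
placement of helix segments onto density rods puts the coupled Cα pairs
together. This package makes that reasoning explicit, exhaustive, and
testable, in the setting of the membrane-embedded a-subunit of a rotary
ATP synthase packed against its c₈-ring rotor:

- **helix_geometry** — ideal α-helix backbones built from internal
  coordinates at φ = −57°, ψ = −47° (rise ≈ 1.5 Å/residue, 3.6
  residues/turn, Cα radius ≈ 2.3 Å), total-least-squares helix axes, rigid
  placement of a helix onto a rod with chosen direction, axial register and
  roll.
- **ec_constraints** — coupling lists (read/write, top-N selection), and
  the validation statistic: the fraction of pairs whose Cα–Cα distance in a
  model is within a threshold (default 15 Å over the top 90 intra-chain
  pairs and the top 6 pairs to the partner ring), plus the mean pair
  distance.
- **rod_assignment** — rod detection (connected components for separated
  helices; Hessian ridge centerlines for helices in contact), exhaustive
  enumeration of the K!·2^K injective (rod, direction) assignments, exact
  register/roll optimisation per assignment, and a deterministic ranked
  search with admissible-bound pruning.
- **map_ops** — MRC map I/O, segmentation, real-space rigid alignment by
  normalized cross-correlation, multi-map averaging with voxelwise variance
  (the heterogeneity signal), and Fourier shell correlation.
- **state_compare** — least-squares superposition, rotation angle / screw
  axis decomposition of inter-state motions, symmetry-aware rotational
  offsets of an 8-fold ring (reported modulo 45°), and linear interpolation
  between states for visualization.
- **synthetic_data** — seeded generators for all of the above: helical
  bundles emulating the subunit's architecture, coupling lists with a
  controlled false-positive fraction, Gaussian-kernel density maps at
  1.64 Å/voxel and ~7 Å resolution, and multi-state map ensembles.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
ground truths. `python analysis/02_trace_fold.py` regenerates the six-helix
study case (seed 0), detects rods in its 7 Å map and searches all 46,080
assignments:

```
detected 6 rods (lengths [46.1, 23.0, 41.1, 36.4, 49.9, 45.4] A)
searched 46080 assignments (18 scored exactly, pruning skipped the rest)
pairs          96
satisfied      91  (94.8% at 15 A)
mean distance  9.29 A
violations     5
recovered the generating fold: True
```

91 of 96 coupling pairs (the top 90 intra-chain plus 6 to the ring) are
within 15 Å of each other in the best-ranked model — the 5 violations are
exactly the generated false-positive couplings — and the winning assignment
places every helix on its true rod in the true direction.
`analysis/03_average_states.py` and `analysis/04_state_rotations.py` run
the map-averaging and state-rotation analyses:

```
background noise reduced by x2.68 (sqrt(7) = 2.65 expected for 7 maps)
median voxel variance: mobile region 0.0456 vs static 0.0090
  generated  12.0 -> recovered 11.91 deg (correlation 0.997)
  rotation  47.0 -> offset +2.00 deg
```

Averaging seven aligned maps raises the signal-to-noise ratio by √7 where
the states agree and concentrates voxel variance where a sub-structure
moves; rigid rotations between states are recovered exactly from models and
to within 0.1° from the maps; a 47° ring rotation reads as a +2° offset
modulo the 45° step of the 8-fold ring.

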