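"""Synthetic ground truths: helical bundles, contact lists, density maps, states.

The generator emulates the study conditions of a membrane-embedded helical
bundle imaged at medium resolution: a six-helix subunit packed at ~10 Å
inter-axis spacing, maps with ~1.64 Å voxels at 6.4–7.4 Å resolution with
additive Gaussian noise, coupling lists of the top 90 pairs carrying a 6%
false-positive fraction, and multi-state ensembles in which a sub-structure
(e.g. a c₈-ring stand-in) is rigidly rotated between states.  Every
generator is seed-deterministic: same inputs and seed give bit-identical
output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .ec_constraints import ContactPair, write_contacts
from .helix_geometry import (
    BackboneModel,
    HelixBuildParams,
    RodAxis,
    _axis_rotation,
    build_ideal_helix,
    fit_axis,
    place_helix,
    segment_distance,
    write_pdb,
)
from .map_ops import DensityMap, write_map
from .rod_assignment import Assignment, AssignmentEntry

__all__ = [
    "MapSpec",
    "BundleTruth",
    "make_bundle",
    "make_ring",
    "make_contacts",
    "make_interchain_contacts",
    "render_map",
    "make_state_ensemble",
    "save_truth",
]

DEFAULT_TRUE_THRESHOLD = 8.0    # Å: Cα–Cα definition of a genuine contact
DEFAULT_FALSE_FLOOR = 20.0      # Å: generated false positives exceed this
DEFAULT_SEGMENT_GAP = 5         # unmodelled residues between helix segments
MIN_AXIS_CLEARANCE = 4.0        # Å: closer axes are rejected as unphysical


@dataclass(frozen=True)
class MapSpec:
    """Rendering parameters for simulated maps.

    ``voxel_size`` 1.64 Å and ``resolution`` ~7 Å match the imaging regime
    emulated here; ``box_edge`` (voxels) fixes the cubic grid, otherwise the
    box is sized to the model plus ``margin`` Å on every side.
    """

    voxel_size: float = 1.64
    resolution: float = 7.0
    box_edge: int | None = None
    noise_sigma: float = 0.0
    margin: float = 8.0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.resolution < 2 * self.voxel_size:
            raise ValueError("resolution must be >= 2 * voxel_size (Nyquist)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def kernel_sigma(self) -> float:
        """Gaussian kernel width: σ = resolution / (π·√2)."""
        return self.resolution / (math.pi * math.sqrt(2.0))


@dataclass
class BundleTruth:
    """A generated helical bundle with its ground-truth assignment."""

    model: BackboneModel
    segments: list[tuple[int, int, int]]
    true_assignment: Assignment
    rng_seed: int
    helices: dict[int, BackboneModel] = field(default_factory=dict)
    rods: list[RodAxis] = field(default_factory=list)


_segment_distance = segment_distance  # shared geometry helper


def make_bundle(n_helices: int,
                lengths: list[int],
                spacing: float = 10.0,
                rng_seed: int = 0,
                max_tilt_deg: float = 5.0,
                lateral_jitter: float = 1.5,
                axial_jitter: float = 2.0,
                min_axis_distance: float | None = None,
                layout: str = "grid",
                gap: int = DEFAULT_SEGMENT_GAP,
                params: HelixBuildParams | None = None) -> BundleTruth:
    """Generate a bundle of ideal helices on near-parallel, tilted axes.

    Helix axes sit on a square lattice with the given inter-axis ``spacing``
    (Å), perturbed laterally by up to ``lateral_jitter`` Å (real bundles are
    irregular, not crystalline — without the jitter a perfectly symmetric
    lattice admits mirror-equivalent assignments that no real fold has),
    tilted by a random angle up to ``max_tilt_deg`` with random azimuth,
    with small axial jitter and random roll, and alternating N→C direction
    (antiparallel packing).  Sequence segments are separated by ``gap``
    unbuilt residues.  The generating placement is recorded as the true
    assignment against the canonicalized fitted axes.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    if len(lengths) != n_helices:
        raise ValueError("lengths must list one length per helix")
    if any(L < 6 for L in lengths):
        raise ValueError("each helix needs at least 6 residues")
    params = params or HelixBuildParams()
    rng = np.random.default_rng(rng_seed)

    if layout == "grid":
        cols = max(1, math.ceil(math.sqrt(n_helices)))
    elif layout == "row":
        # elongated single-file arrangement: extent grows linearly with n,
        # emulating a subunit strung out along a membrane interface
        cols = n_helices
    elif layout == "subunit":
        # the traced subunit's architecture: membrane-inserted helices in a
        # jittered row, with helix 2 running horizontally along the membrane
        # surface above the first helices — the surface helix anchors the
        # direction and register of the whole arrangement
        if n_helices < 3:
            raise ValueError("subunit layout needs at least 3 helices")
        cols = n_helices - 1
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if min_axis_distance is None:
        # the surface helix passes ~7 Å over the membrane-inserted ones
        min_axis_distance = 6.5 if layout == "subunit" else 0.8 * spacing + 0.5
    min_clearance = max(MIN_AXIS_CLEARANCE, min_axis_distance)

    surface_id = 2 if layout == "subunit" else None

    # draw tilt/jitter realizations until every axis pair keeps clearance;
    # the rng stream continues across attempts, so output is seed-deterministic
    for _attempt in range(200):
        placement_axes: list[tuple[np.ndarray, np.ndarray]] = []
        draws = []
        slot = 0
        vertical_tops: list[float] = []
        pair_tilt = rng.uniform(12.0, 20.0)
        pair_azimuth = rng.uniform(0.0, 360.0)
        for k in range(n_helices):
            length = lengths[k]
            if surface_id is not None and k + 1 == surface_id:
                draws.append(None)  # placed after the verticals are known
                continue
            centre = np.array([(slot % cols) * spacing, (slot // cols) * spacing,
                               rng.uniform(-axial_jitter, axial_jitter)])
            centre[:2] += rng.uniform(-lateral_jitter, lateral_jitter, size=2)
            if layout == "subunit" and k >= n_helices - 2:
                # the final helix pair is long and highly tilted (the hairpin
                # that packs against the rotor ring); its members share a
                # tilt direction, running alongside each other
                tilt = pair_tilt + rng.uniform(-3.0, 3.0)
                azimuth = pair_azimuth + rng.uniform(-12.0, 12.0)
            else:
                tilt = rng.uniform(0.0, max_tilt_deg)
                azimuth = rng.uniform(0.0, 360.0)
            base_dir = np.array([math.sin(math.radians(tilt)), 0.0,
                                 math.cos(math.radians(tilt))])
            direction = _axis_rotation(np.array([0.0, 0.0, 1.0]), azimuth) @ base_dir
            if slot % 2 == 1:
                direction = -direction
            roll = rng.uniform(0.0, 360.0)
            half = (length - 1) * 1.5 / 2.0
            placement_axes.append((centre - half * direction, centre + half * direction))
            draws.append((centre, direction, roll))
            vertical_tops.append(centre[2] + half * abs(direction[2]))
            slot += 1
        if surface_id is not None:
            # horizontal surface helix above the start of the row
            k = surface_id - 1
            length = lengths[k]
            half = (length - 1) * 1.5 / 2.0
            z_top = max(vertical_tops[: max(2, n_helices // 2)]) + 7.0
            centre = np.array([half + rng.uniform(-lateral_jitter, lateral_jitter),
                               rng.uniform(-lateral_jitter, lateral_jitter),
                               z_top + rng.uniform(0.0, 1.5)])
            yaw = rng.uniform(-max_tilt_deg, max_tilt_deg)
            direction = _axis_rotation(np.array([0.0, 0.0, 1.0]), yaw) @ np.array([1.0, 0.0, 0.0])
            roll = rng.uniform(0.0, 360.0)
            placement_axes.insert(k, (centre - half * direction, centre + half * direction))
            draws[k] = (centre, direction, roll)
        min_d = math.inf
        for i in range(n_helices):
            for j in range(i + 1, n_helices):
                min_d = min(min_d, _segment_distance(*placement_axes[i],
                                                     *placement_axes[j]))
        if n_helices == 1:
            break
        if min_d >= min_clearance and _packing_physical(draws, lengths, params):
            break
    else:
        raise ValueError(
            f"helix axes approach {min_d:.2f} Å (< {min_clearance:.1f} Å) in "
            "every attempted packing: spacing unphysically small")
    if n_helices > 1 and min_d < MIN_AXIS_CLEARANCE:
        raise ValueError(
            f"helix axes approach {min_d:.2f} Å (< {MIN_AXIS_CLEARANCE} Å): "
            "spacing unphysically small")

    helices: dict[int, BackboneModel] = {}
    segments: list[tuple[int, int, int]] = []
    rods: list[RodAxis] = []
    entries = []
    first = 1
    for k, (centre, direction, roll) in enumerate(draws):
        length = lengths[k]
        half = (length - 1) * 1.5 / 2.0
        gen_rod = RodAxis(centre - half * direction, centre + half * direction)
        helix = place_helix(length, gen_rod, "forward", 0, roll, params,
                            first_residue=first)
        helices[k + 1] = helix
        segments.append((k + 1, first, first + length - 1))
        first += length + gap

        rod = fit_axis(helix).canonical()
        rods.append(rod)
        fwd = float(rod.direction @ (helix.ca[-1] - helix.ca[0])) > 0
        entries.append((k + 1, AssignmentEntry(k, "forward" if fwd else "reverse",
                                               0, roll)))

    model = BackboneModel.concatenate(list(helices.values()))
    return BundleTruth(model=model, segments=segments,
                       true_assignment=Assignment(tuple(entries)),
                       rng_seed=rng_seed, helices=helices, rods=rods)


MIN_INTERHELIX_CA = 3.8  # Å: tighter Cα approach than this is a steric clash


def _packing_physical(draws, lengths, params) -> bool:
    """Reject draws whose rolls bring Cα of different helices under 3.8 Å."""
    from scipy.spatial.distance import cdist

    cas = []
    for (centre, direction, roll), length in zip(draws, lengths):
        half = (length - 1) * 1.5 / 2.0
        rod = RodAxis(centre - half * direction, centre + half * direction)
        cas.append(place_helix(length, rod, "forward", 0, roll, params).ca)
    for i in range(len(cas)):
        for j in range(i + 1, len(cas)):
            if cdist(cas[i], cas[j]).min() < MIN_INTERHELIX_CA:
                return False
    return True


def make_ring(n_subunits: int = 8,
              radius: float = 22.0,
              helix_length: int = 16,
              centre=(0.0, 0.0, 0.0),
              first_residue: int = 1,
              gap: int = DEFAULT_SEGMENT_GAP,
              params: HelixBuildParams | None = None) -> BackboneModel:
    """A symmetric ring of vertical helices: a partner-chain (c-ring) stand-in.

    Subunit k sits at azimuth 2πk/n on a circle of the given radius; each
    subunit is one ideal helix, numbered consecutively with gaps.
    """
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    params = params or HelixBuildParams()
    centre = np.asarray(centre, dtype=float)
    half = (helix_length - 1) * 1.5 / 2.0
    models = []
    first = first_residue
    for k in range(n_subunits):
        phi = 2.0 * math.pi * k / n_subunits
        pos = centre + radius * np.array([math.cos(phi), math.sin(phi), 0.0])
        rod = RodAxis(pos - np.array([0.0, 0.0, half]),
                      pos + np.array([0.0, 0.0, half]))
        roll = math.degrees(phi)  # keep the ring exactly symmetric
        models.append(place_helix(helix_length, rod, "forward", 0, roll, params,
                                  first_residue=first))
        first += helix_length + gap
    return BackboneModel.concatenate(models)


def _candidate_pairs(numbers: np.ndarray, ca: np.ndarray,
                     min_separation: int) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial.distance import pdist, squareform

    dist = squareform(pdist(ca))
    n = len(numbers)
    ii, jj = np.triu_indices(n, k=1)
    sep_ok = np.abs(numbers[ii] - numbers[jj]) >= min_separation
    return np.stack([ii[sep_ok], jj[sep_ok]], axis=1), dist[ii[sep_ok], jj[sep_ok]]


def _assign_scores(rng: np.random.Generator, n: int) -> np.ndarray:
    """Strictly decreasing placeholder scores for a shuffled pair order."""
    return 2.0 - np.arange(n) / max(n, 1)


def make_contacts(truth: BundleTruth,
                  n_pairs: int = 90,
                  fp_rate: float = 0.06,
                  true_threshold: float = DEFAULT_TRUE_THRESHOLD,
                  rng_seed: int = 0,
                  min_separation: int = 5,
                  false_floor: float = DEFAULT_FALSE_FLOOR) -> list[ContactPair]:
    """Draw a contact list with a controlled false-positive fraction.

    round(n_pairs·(1−fp_rate)) true pairs are sampled without replacement
    from residue pairs with Cα–Cα ≤ ``true_threshold`` and sequence
    separation ≥ ``min_separation``; the remainder are false positives drawn
    from pairs with Cα–Cα > ``false_floor``.  Scores are strictly decreasing
    along a seeded shuffle, so top-N selection is reproducible.
    """
    if not (0 <= fp_rate < 1):
        raise ValueError("fp_rate must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    numbers = truth.model.numbers
    ca = truth.model.ca
    idx_pairs, dists = _candidate_pairs(numbers, ca, min_separation)

    true_pool = np.nonzero(dists <= true_threshold)[0]
    false_pool = np.nonzero(dists > false_floor)[0]
    n_true = round(n_pairs * (1.0 - fp_rate))
    n_false = n_pairs - n_true
    if len(true_pool) < n_true:
        raise ValueError(
            f"only {len(true_pool)} residue pairs under {true_threshold} Å "
            f"available; {n_true} true pairs requested "
            f"(shortfall {n_true - len(true_pool)})")
    if len(false_pool) < n_false:
        raise ValueError(
            f"only {len(false_pool)} residue pairs beyond {false_floor} Å "
            f"available; {n_false} false pairs requested")

    chosen = np.concatenate([
        rng.choice(true_pool, size=n_true, replace=False),
        rng.choice(false_pool, size=n_false, replace=False),
    ])
    rng.shuffle(chosen)
    scores = _assign_scores(rng, len(chosen))
    pairs = []
    for score, c in zip(scores, chosen):
        i, j = idx_pairs[c]
        pairs.append(ContactPair(int(numbers[i]), int(numbers[j]), float(score)))
    return pairs


def make_interchain_contacts(truth: BundleTruth,
                             partner: BackboneModel,
                             n_pairs: int = 6,
                             fp_rate: float = 0.0,
                             true_threshold: float = 12.0,
                             rng_seed: int = 0,
                             partner_chain: str = "C",
                             false_floor: float = DEFAULT_FALSE_FLOOR) -> list[ContactPair]:
    """Contacts between the bundle chain and a partner chain (e.g. the ring).

    ``true_threshold`` defaults to 12 Å: inter-chain couplings land on
    helix surfaces facing each other rather than in a packed core.
    """
    if not (0 <= fp_rate < 1):
        raise ValueError("fp_rate must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    from scipy.spatial.distance import cdist

    dist = cdist(truth.model.ca, partner.ca)
    ii, jj = np.nonzero(dist <= true_threshold)
    fi, fj = np.nonzero(dist > false_floor)
    n_true = round(n_pairs * (1.0 - fp_rate))
    n_false = n_pairs - n_true
    if len(ii) < n_true:
        raise ValueError(
            f"only {len(ii)} inter-chain pairs under {true_threshold} Å; "
            f"{n_true} requested (shortfall {n_true - len(ii)})")
    sel_t = rng.choice(len(ii), size=n_true, replace=False)
    sel_f = rng.choice(len(fi), size=n_false, replace=False) if n_false else []
    rows = [(int(truth.model.numbers[ii[s]]), int(partner.numbers[jj[s]]))
            for s in sel_t]
    rows += [(int(truth.model.numbers[fi[s]]), int(partner.numbers[fj[s]]))
             for s in sel_f]
    order = rng.permutation(len(rows))
    scores = _assign_scores(rng, len(rows))
    return [ContactPair(rows[k][0], rows[k][1], float(s), "A", partner_chain)
            for s, k in zip(scores, order)]


def render_map(model: BackboneModel | list[BackboneModel],
               spec: MapSpec = MapSpec(),
               rng_seed: int = 0) -> DensityMap:
    """Render a Cα Gaussian-kernel density with optional i.i.d. Gaussian noise.

    Each Cα contributes an isotropic Gaussian of width ``spec.kernel_sigma``
    and unit peak amplitude; kernels are accumulated on a cubic grid whose
    extent covers the model plus the margin (or the stated ``box_edge``).
    """
    if isinstance(model, (list, tuple)):
        model = BackboneModel.concatenate(list(model))
    ca = model.ca
    centre = (ca.min(axis=0) + ca.max(axis=0)) / 2.0
    edge = _box_edge(ca, spec)
    origin = centre - (edge - 1) / 2.0 * spec.voxel_size
    return _render(ca, edge, origin, spec, rng_seed)


def _box_edge(ca: np.ndarray, spec: MapSpec) -> int:
    if spec.box_edge is not None:
        return int(spec.box_edge)
    extent = float((ca.max(axis=0) - ca.min(axis=0)).max())
    return int(math.ceil((extent + 2 * spec.margin) / spec.voxel_size)) + 1


def _render(ca: np.ndarray, edge: int, origin: np.ndarray, spec: MapSpec,
            rng_seed: int) -> DensityMap:
    v = spec.voxel_size
    idx = (ca - origin) / v
    if np.any(idx < -0.5) or np.any(idx > edge - 0.5):
        raise ValueError("model does not fit in the requested box")

    grid = np.zeros((edge, edge, edge), dtype=float)
    sigma_vox = spec.kernel_sigma / v
    reach = int(math.ceil(4.0 * sigma_vox))
    rng_ax = np.arange(-reach, reach + 1)
    for p in idx:
        base = np.round(p).astype(int)
        ux, uy, uz = (np.unique(np.clip(base[d] + rng_ax, 0, edge - 1))
                      for d in range(3))
        gx = np.exp(-(ux - p[0]) ** 2 / (2 * sigma_vox ** 2))
        gy = np.exp(-(uy - p[1]) ** 2 / (2 * sigma_vox ** 2))
        gz = np.exp(-(uz - p[2]) ** 2 / (2 * sigma_vox ** 2))
        grid[np.ix_(ux, uy, uz)] += gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        grid = grid + rng.normal(0.0, spec.noise_sigma, grid.shape)
    return DensityMap(grid.astype(np.float32), v, origin)


def rotate_model(model: BackboneModel, axis_point, axis_dir,
                 angle_deg: float) -> BackboneModel:
    """Rigidly rotate a model about an axis (point + unit direction)."""
    axis_point = np.asarray(axis_point, dtype=float)
    axis_dir = np.asarray(axis_dir, dtype=float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    rot = _axis_rotation(axis_dir, angle_deg)
    return model.transformed(rot, axis_point - rot @ axis_point)


def make_state_ensemble(truth: BundleTruth,
                        mobile_part: set[int] | BackboneModel,
                        angles: list[float],
                        axis_point,
                        axis_dir,
                        spec: MapSpec = MapSpec(),
                        rng_seed: int = 0) -> tuple[list[DensityMap], list[BackboneModel]]:
    """One map per angle in which only the mobile part is rotated.

    ``mobile_part`` is a set of helix ids of the bundle, or a separate
    partner model (e.g. a ring) rotated rigidly against the static bundle.
    Noise is independent per map; the shared grid covers every state.
    Returns (maps, full models per state).
    """
    if not angles:
        raise ValueError("angles must be non-empty")
    if isinstance(mobile_part, set) and not mobile_part:
        raise ValueError("mobile_part must not be empty")

    if isinstance(mobile_part, BackboneModel):
        static = truth.model
        mobile = mobile_part
    else:
        unknown = mobile_part - set(truth.helices)
        if unknown:
            raise ValueError(f"unknown helix ids in mobile_part: {sorted(unknown)}")
        static_parts = [m for hid, m in truth.helices.items() if hid not in mobile_part]
        mobile_parts = [m for hid, m in truth.helices.items() if hid in mobile_part]
        static = BackboneModel.concatenate(static_parts) if static_parts else None
        mobile = BackboneModel.concatenate(mobile_parts)

    states = []
    for angle in angles:
        rotated = rotate_model(mobile, axis_point, axis_dir, angle)
        pieces = [rotated] if static is None else [static, rotated]
        states.append(pieces)

    # shared cubic grid sized to the union of all states
    all_ca = np.concatenate([np.concatenate([m.ca for m in s]) for s in states])
    v = spec.voxel_size
    centre = (all_ca.min(axis=0) + all_ca.max(axis=0)) / 2.0
    edge = _box_edge(all_ca, spec)
    origin = centre - (edge - 1) / 2.0 * v

    root = np.random.default_rng(rng_seed)
    seeds = root.integers(0, 2 ** 31, size=len(angles))
    maps = []
    models = []
    for pieces, seed in zip(states, seeds):
        combined = _merge(pieces)
        maps.append(_render(combined.ca, edge, origin, spec, int(seed)))
        models.append(combined)
    return maps, models


def _merge(pieces: list[BackboneModel]) -> BackboneModel:
    """Concatenate possibly number-overlapping chains for rendering only."""
    if len(pieces) == 1:
        return pieces[0]
    numbers = np.concatenate([m.numbers for m in pieces])
    coords = np.concatenate([m.coords for m in pieces])
    if len(np.unique(numbers)) == len(numbers):
        order = np.argsort(numbers)
        return BackboneModel(numbers[order], coords[order])
    return BackboneModel(np.arange(1, len(numbers) + 1), coords)


STUDY_LENGTHS = [30, 24, 26, 28, 34, 32]
STUDY_CONDITIONS = dict(spacing=9.2, max_tilt_deg=5.0, lateral_jitter=2.0,
                        axial_jitter=3.0, layout="subunit")


def make_study_case(rng_seed: int,
                    n_pairs: int = 90,
                    fp_rate: float = 0.06,
                    n_inter: int = 6,
                    noise_sigma: float = 0.0,
                    resolution: float = 7.0,
                    with_map: bool = True) -> dict:
    """One full instance of the emulated study: subunit, ring, couplings, map.

    The bundle is the six-helix subunit stand-in (five membrane-inserted
    helices, one surface helix, the final pair long and highly tilted), with
    a c₈-ring stand-in packed against the tilted pair; the coupling list is
    the top ``n_pairs`` with the stated false-positive fraction plus the top
    ``n_inter`` couplings to the ring.
    """
    truth = make_bundle(6, STUDY_LENGTHS, rng_seed=rng_seed, **STUDY_CONDITIONS)
    row_end = max(r.midpoint[0] for r in truth.rods)
    ring = make_ring(8, radius=22.0, helix_length=16,
                     centre=(row_end + 29.0, 0.0, 0.0), first_residue=301)
    pairs = make_contacts(truth, n_pairs, fp_rate, rng_seed=rng_seed + 10_000)
    inter = make_interchain_contacts(truth, ring, n_inter, fp_rate,
                                     rng_seed=rng_seed + 20_000)
    out = {"truth": truth, "ring": ring, "pairs": pairs, "inter_pairs": inter}
    if with_map:
        spec = MapSpec(resolution=resolution, noise_sigma=noise_sigma)
        out["map"] = render_map(truth.model, spec, rng_seed=rng_seed + 30_000)
        out["map_spec"] = spec
    return out


def true_geometry_in(truth: BundleTruth, rods: list[RodAxis]) -> Assignment | None:
    """Express the generating assignment in another rod list's indexing.

    Rods are matched one-to-one by midpoint proximity; returns None when any
    true rod has no counterpart (e.g. missed detection).  Directions are
    relabelled against the new rods' canonical endpoint order.
    """
    from .rod_assignment import match_rods  # local import: avoid cycle at load

    matches = match_rods(rods, truth.rods)
    if any(m is None for m in matches):
        return None
    entries = []
    for hid, e in truth.true_assignment.entries:
        new_rod = matches[e.rod]
        helix = truth.helices[hid]
        fwd = float(rods[new_rod].direction @ (helix.ca[-1] - helix.ca[0])) > 0
        entries.append((hid, AssignmentEntry(new_rod,
                                             "forward" if fwd else "reverse")))
    return Assignment(tuple(entries))


def save_truth(truth: BundleTruth, directory, partner: BackboneModel | None = None,
               pairs: list[ContactPair] | None = None,
               density: DensityMap | None = None) -> None:
    """Write a ground truth to disk: PDB, contacts, MRC map, JSON metadata."""
    import os

    os.makedirs(directory, exist_ok=True)
    chains = {"A": truth.model}
    if partner is not None:
        chains["C"] = partner
    write_pdb(os.path.join(directory, "truth.pdb"), chains)
    if pairs is not None:
        write_contacts(os.path.join(directory, "contacts.txt"), pairs)
    if density is not None:
        write_map(density, os.path.join(directory, "map.mrc"))
    meta = {
        "rng_seed": truth.rng_seed,
        "segments": [list(s) for s in truth.segments],
        "true_assignment": truth.true_assignment.to_dict(),
        "rods": [{"a": list(r.endpoint_a), "b": list(r.endpoint_b)}
                 for r in truth.rods],
    }
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
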