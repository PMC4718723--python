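"""Rod detection and combinatorial helix-to-rod assignment.

At 6–8 Å resolution a trans-membrane α-helix appears as an elongated tubular
density ("rod") with no visible side chains, so the sequence-to-density
mapping is ambiguous: any helix segment could occupy any rod in either
direction.  Co-evolving residue pairs break the ambiguity — a correct
assignment places the coupled Cα pairs close together.  This module makes
that reasoning explicit and exhaustive: detect rods, enumerate every
injective (rod, direction) choice, optimize each helix's axial register and
roll on discrete grids, and rank assignments by constraint satisfaction.
A unique maximizer corresponds to the claim that the helices fit the density
in only one orientation compatible with the couplings.

The exhaustive search is exact.  A relaxation bound (each helix pair scored
as if its register/roll choices were free of the other pairs' demands) lets
the search skip full optimisation of assignments that provably cannot reach
the current top-k; every assignment that could appear in the ranking is
scored exactly, so pruning never changes the result.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from . import ec_constraints
from .ec_constraints import ContactPair, SatisfactionReport
from .helix_geometry import (
    BackboneModel,
    HelixBuildParams,
    RodAxis,
    _axis_rotation,
    _rotation_between,
    build_ideal_helix,
    fit_axis,
    place_helix,
    segment_distance,
)
from .map_ops import DensityMap

__all__ = [
    "AssignmentProblem",
    "Assignment",
    "AssignmentEntry",
    "RankedSolutions",
    "rod_detect",
    "match_rods",
    "enumerate_assignments",
    "score_assignment",
    "search_best",
    "assignment_models",
]

EXHAUSTIVE_CAP = 8
MAX_SWEEPS = 4


@dataclass(frozen=True)
class AssignmentEntry:
    rod: int
    direction: str  # 'forward' | 'reverse'
    register_shift: int = 0
    roll: float = 0.0


@dataclass(frozen=True)
class Assignment:
    """Helix-id -> (rod, direction, register, roll); rod choice is injective."""

    entries: tuple  # ordered tuple of (helix_id, AssignmentEntry)

    def __post_init__(self) -> None:
        rods = [e.rod for _, e in self.entries]
        if len(set(rods)) != len(rods):
            raise ValueError("rod indices must be distinct across helices")

    @staticmethod
    def from_dict(d: dict[int, AssignmentEntry]) -> "Assignment":
        return Assignment(tuple(sorted(d.items())))

    def __getitem__(self, helix_id: int) -> AssignmentEntry:
        for hid, e in self.entries:
            if hid == helix_id:
                return e
        raise KeyError(helix_id)

    @property
    def helix_ids(self) -> list[int]:
        return [hid for hid, _ in self.entries]

    def geometry_key(self) -> tuple:
        """(rod, direction) part only, in helix order — the lexicographic tie key."""
        return tuple((e.rod, 0 if e.direction == "forward" else 1)
                     for _, e in self.entries)

    def same_geometry(self, other: "Assignment") -> bool:
        return self.geometry_key() == other.geometry_key()

    def to_dict(self) -> dict:
        return {
            str(hid): {"rod": e.rod, "direction": e.direction,
                       "register_shift": e.register_shift, "roll": e.roll}
            for hid, e in self.entries
        }


@dataclass
class AssignmentProblem:
    """One helix-to-rod search instance.

    ``segments`` are (helix_id, first_residue, last_residue) in 1-based
    inclusive numbering on the chain ``chain``; ``partner_models`` supplies
    fixed partner chains for inter-chain pairs.
    """

    segments: list[tuple[int, int, int]]
    rods: list[RodAxis]
    pairs: list[ContactPair]
    threshold: float = ec_constraints.DEFAULT_THRESHOLD
    roll_samples: int = 8
    register_range: int = 4
    register_slack: float = 2.0  # Å a helix end may overhang its rod
    min_rod_separation: float = 0.0  # Å; optional hard rod-pair exclusion
    partner_clash_distance: float = 2.5  # Å; options driving Cα into a fixed partner chain are excluded
    chain: str = "A"
    partner_models: dict[str, BackboneModel] = field(default_factory=dict)
    params: HelixBuildParams = field(default_factory=HelixBuildParams)

    def __post_init__(self) -> None:
        if len(self.segments) > len(self.rods):
            raise ValueError("need at least as many rods as helix segments")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def rod_conflicts(self) -> np.ndarray:
        """Boolean matrix of rod pairs too close to hold two helices at once.

        Disabled by default (``min_rod_separation = 0``).  When set, rod
        pairs with a smaller axis gap cannot both be occupied — a hard
        steric exclusion useful when the rod list may contain spurious
        near-duplicate detections.
        """
        n = len(self.rods)
        conflict = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                gap = segment_distance(self.rods[i].endpoint_a,
                                       self.rods[i].endpoint_b,
                                       self.rods[j].endpoint_a,
                                       self.rods[j].endpoint_b)
                if gap < self.min_rod_separation:
                    conflict[i, j] = conflict[j, i] = True
        return conflict


@dataclass
class RankedSolutions:
    """Ranked (Assignment, SatisfactionReport) list plus search metadata."""

    solutions: list[tuple[Assignment, SatisfactionReport]]
    n_evaluated: int
    n_scored: int
    exhaustive: bool
    unique_maximizer: bool

    @property
    def best(self) -> tuple[Assignment, SatisfactionReport]:
        return self.solutions[0]

    def to_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_scored": self.n_scored,
            "exhaustive": self.exhaustive,
            "unique_maximizer": self.unique_maximizer,
            "solutions": [
                {"assignment": a.to_dict(),
                 "n_satisfied": r.n_satisfied,
                 "fraction_satisfied": r.fraction_satisfied,
                 "mean_distance": r.mean_distance}
                for a, r in self.solutions
            ],
        }


# --- rod detection -----------------------------------------------------------

def rod_detect(density: DensityMap,
               density_threshold: float,
               min_length: float = 12.0,
               anisotropy_min: float = 2.5,
               method: str = "components") -> list[RodAxis]:
    """Detect elongated density features as straight rod axes.

    ``method="components"`` (the default) groups voxels >= threshold by
    26-connectivity; each component's principal axis comes from an SVD of the
    centred member-voxel cloud, components are kept when the axial extent
    reaches ``min_length`` (Å) and the first-to-second singular-value ratio
    reaches ``anisotropy_min``, and endpoints are the extreme member-voxel
    projections on the axis.  This is adequate when helices are spatially
    separated at the chosen threshold.

    ``method="centerline"`` handles helices in van-der-Waals contact, whose
    densities merge into one component at every threshold: it extracts ridge
    centerlines (voxels that are local maxima in the plane perpendicular to
    the local Hessian tube direction) and grows straight, direction-
    consistent lines through them.
    """
    lo, hi = float(density.grid.min()), float(density.grid.max())
    if not (lo <= density_threshold <= hi):
        raise ValueError(
            f"density_threshold {density_threshold} outside map range [{lo}, {hi}]")
    if method == "centerline":
        return _rod_detect_centerline(density, density_threshold, min_length)
    if method != "components":
        raise ValueError(f"unknown method {method!r}")
    mask = density.grid >= density_threshold
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    rods: list[RodAxis] = []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labels == comp)
        if len(idx) < 3:
            continue
        world = density.index_to_world(idx)
        centroid = world.mean(axis=0)
        centred = world - centroid
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        axis = vt[0]
        proj = centred @ axis
        extent = float(proj.max() - proj.min())
        if extent < min_length:
            continue
        anisotropy = float(s[0] / s[1]) if s[1] > 1e-12 else math.inf
        if anisotropy < anisotropy_min:
            continue
        rod = RodAxis(centroid + proj.min() * axis,
                      centroid + proj.max() * axis).canonical()
        rods.append(rod)
    rods.sort(key=lambda r: tuple(np.round(r.midpoint, 6)))
    return rods


def _rod_detect_centerline(density: DensityMap,
                           density_threshold: float,
                           min_length: float,
                           smooth_sigma: float = 1.2,
                           lateral: float = 2.0,
                           align: float = 0.85,
                           min_linear_density: float = 0.5,
                           min_separation: float = 4.5) -> list[RodAxis]:
    """Ridge-centerline rod detection for contact-packed helix bundles.

    Stage 1 extracts centerline voxels: above-threshold voxels that are
    local density maxima along both Hessian cross-tube directions (sampled
    at 1 and 2 voxels by trilinear interpolation).  Stage 2 fits straight
    lines globally: every centerline voxel proposes a line along its local
    tube direction, each candidate is refined against the full point set
    (claiming points within ``lateral`` Å whose own directions agree,
    |cos| >= ``align``), and candidates are accepted in descending-support
    order subject to a minimum axis separation of ``min_separation`` Å from
    every already-accepted rod.  Evaluating all candidates on the full point
    set, rather than claiming points greedily, keeps a helix's centerline
    intact even when a contact seam between touching tubes also produces a
    spurious line — the seam line carries less support than either flanking
    helix and is suppressed by the separation rule.  Deterministic.
    """
    g = ndimage.gaussian_filter(density.grid.astype(float), smooth_sigma)
    hess = np.empty(g.shape + (3, 3))
    for a in range(3):
        for b in range(a, 3):
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            d = ndimage.gaussian_filter(g, 1.0, order=order)
            hess[..., a, b] = d
            hess[..., b, a] = d
    fg = g >= density_threshold
    idx = np.argwhere(fg)
    if len(idx) == 0:
        return []
    _, eigvecs = np.linalg.eigh(hess[fg])
    pts = idx.astype(float)
    keep = np.ones(len(idx), dtype=bool)
    for ei in (0, 1):  # the two cross-tube eigen-directions
        e = eigvecs[..., :, ei]
        for r in (1.0, 2.0):
            for sgn in (1, -1):
                q = pts + sgn * r * e
                vals = ndimage.map_coordinates(g, q.T, order=1, mode="nearest")
                keep &= g[fg] >= vals - 1e-9
    world = density.index_to_world(idx[keep])
    dirs = eigvecs[keep][:, :, 2]  # along-tube direction

    candidates = []
    for i in range(len(world)):
        u = dirs[i]
        centre = world[i]
        dist = np.linalg.norm(np.cross(world - centre, u), axis=1)
        sel = (dist <= lateral) & (np.abs(dirs @ u) >= align)
        if sel.sum() < 4:
            continue
        for _ in range(3):
            line_pts = world[sel]
            centre = line_pts.mean(axis=0)
            _, _, vt = np.linalg.svd(line_pts - centre, full_matrices=False)
            u = vt[0]
            dist = np.linalg.norm(np.cross(world - centre, u), axis=1)
            proj = (world - centre) @ u
            pmin, pmax = proj[sel].min(), proj[sel].max()
            new = ((dist <= lateral) & (np.abs(dirs @ u) >= align)
                   & (proj >= pmin - 3.0) & (proj <= pmax + 3.0))
            if (new == sel).all() or new.sum() < 4:
                break
            sel = new
        if sel.sum() < 4:
            continue
        line_pts = world[sel]
        centre = line_pts.mean(axis=0)
        _, _, vt = np.linalg.svd(line_pts - centre, full_matrices=False)
        u = vt[0]
        proj = (line_pts - centre) @ u
        extent = float(proj.max() - proj.min())
        if extent >= min_length and sel.sum() / extent >= min_linear_density:
            candidates.append((sel, extent, int(sel.sum()), centre, u,
                               float(proj.min()), float(proj.max())))

    candidates.sort(key=lambda t: (-t[2], -t[1],
                                   tuple(np.round(t[3], 6))))
    accepted: list[RodAxis] = []
    for _, _, _, c, u, pmin, pmax in candidates:
        rod = RodAxis(c + pmin * u, c + pmax * u).canonical()
        if all(_segment_gap(rod, other) >= min_separation for other in accepted):
            accepted.append(rod)
    accepted.sort(key=lambda r: tuple(np.round(r.midpoint, 6)))
    return accepted


def _segment_gap(a: RodAxis, b: RodAxis) -> float:
    """Minimum distance between two rod segments."""
    return segment_distance(a.endpoint_a, a.endpoint_b,
                            b.endpoint_a, b.endpoint_b)


def match_rods(detected: list[RodAxis], reference: list[RodAxis]) -> list[int | None]:
    """One-to-one match detected rods to reference rods (minimum midpoint distance).

    Returns, for each reference rod, the index of the matched detected rod
    (or None when there are fewer detections than references).
    """
    if not detected:
        return [None] * len(reference)
    cost = np.array([[np.linalg.norm(r.midpoint - d.midpoint) for d in detected]
                     for r in reference])
    rows, cols = linear_sum_assignment(cost)
    out: list[int | None] = [None] * len(reference)
    for r, c in zip(rows, cols):
        out[r] = int(c)
    return out


def rod_angle(a: RodAxis, b: RodAxis) -> float:
    """Acute angle between two rod axes, degrees."""
    c = abs(float(np.dot(a.direction, b.direction)))
    return math.degrees(math.acos(min(1.0, c)))


# --- enumeration -------------------------------------------------------------

def count_assignments(n_segments: int, n_rods: int) -> int:
    """Closed form: n_rods!/(n_rods-K)! * 2^K injective geometric assignments."""
    return math.perm(n_rods, n_segments) * 2 ** n_segments


def enumerate_assignments(problem: AssignmentProblem):
    """Yield every injective (rod, direction) assignment, deterministically.

    Order is lexicographic in (rod indices, direction codes) over helices
    sorted by helix_id.  Register and roll are left at 0 — they are scoring
    variables, not enumeration variables.
    """
    k = problem.n_segments
    if k > EXHAUSTIVE_CAP:
        raise ValueError(
            f"{k} segments exceeds the exhaustive cap of {EXHAUSTIVE_CAP}; "
            "use search_best(mode='heuristic')")
    helix_ids = [hid for hid, _, _ in sorted(problem.segments)]
    rod_indices = range(len(problem.rods))
    for rods in itertools.permutations(rod_indices, k):
        for dirs in itertools.product(("forward", "reverse"), repeat=k):
            yield Assignment(tuple(
                (hid, AssignmentEntry(rod, direction))
                for hid, rod, direction in zip(helix_ids, rods, dirs)))


# --- scoring -----------------------------------------------------------------

class PlacementCache:
    """Precomputed Cα coordinates for every (segment, rod, direction, option).

    Options enumerate the register/roll grid in a fixed order (register
    ascending, then roll ascending).  Registers that would slide a helix end
    beyond the rod extent by more than ``register_slack`` Å are excluded for
    that (segment, rod) — the density constrains axial placement; a helix
    longer than its rod may only overhang symmetrically (register 0 band).
    Option arithmetic mirrors place_helix exactly so cached coordinates
    match a from-scratch rebuild bitwise.
    """

    def __init__(self, problem: AssignmentProblem):
        self.problem = problem
        self.segments = sorted(problem.segments)
        R = problem.register_range
        rolls = [k * 360.0 / problem.roll_samples for k in range(problem.roll_samples)]
        self.options = [(reg, roll) for reg in range(-R, R + 1) for roll in rolls]
        self.start_option = self.options.index((0, 0.0))

        self._ca: dict[tuple[int, int, str], np.ndarray] = {}
        self._valid: dict[tuple[int, int, str], np.ndarray] = {}
        partner_ca = ([np.concatenate([m.ca for m in problem.partner_models.values()])]
                      if problem.partner_models else [])
        base: dict[int, tuple] = {}
        for hid, first, last in self.segments:
            length = last - first + 1
            helix = build_ideal_helix(length, problem.params, first_residue=first)
            axis0 = fit_axis(helix)
            base[hid] = (helix.ca.copy(), axis0)
        for hid, first, last in self.segments:
            length = last - first + 1
            ca0, axis0 = base[hid]
            u0 = axis0.direction
            rise = axis0.length / (length - 1)
            for rod_idx, rod in enumerate(problem.rods):
                # symmetric-overhang band: |register·rise| limited by how much
                # rod extent remains once the helix is centred on it
                head = max(0.0, (rod.length - axis0.length) / 2.0)
                max_slide = head + problem.register_slack
                register_ok = np.array([abs(reg) * rise <= max_slide
                                        for reg, _ in self.options])
                for direction in ("forward", "reverse"):
                    u = rod.direction if direction == "forward" else -rod.direction
                    align = _rotation_between(u0, u)
                    coords = np.empty((len(self.options), length, 3))
                    for o, (reg, roll) in enumerate(self.options):
                        rot = _axis_rotation(u, roll) @ align
                        centre = rod.midpoint + reg * rise * u
                        trans = centre - rot @ axis0.midpoint
                        coords[o] = ca0 @ rot.T + trans
                    self._ca[(hid, rod_idx, direction)] = coords
                    valid = register_ok.copy()
                    # static steric context: fixed partner chains never move
                    if partner_ca and problem.partner_clash_distance > 0:
                        other = partner_ca[0]
                        near = other[np.linalg.norm(other - rod.midpoint, axis=1)
                                     <= rod.length / 2 + 12.0]
                        if len(near):
                            d2 = ((coords[:, :, None, :] - near[None, None, :, :]) ** 2
                                  ).sum(axis=3)
                            valid &= (d2.min(axis=(1, 2))
                                      >= problem.partner_clash_distance ** 2)
                    self._valid[(hid, rod_idx, direction)] = valid

        # rod-pair gaps, for restricting dynamic clash checks to nearby helices
        n_rods = len(problem.rods)
        self.rod_gaps = np.zeros((n_rods, n_rods))
        for i in range(n_rods):
            for j in range(i + 1, n_rods):
                g = segment_distance(problem.rods[i].endpoint_a,
                                     problem.rods[i].endpoint_b,
                                     problem.rods[j].endpoint_a,
                                     problem.rods[j].endpoint_b)
                self.rod_gaps[i, j] = self.rod_gaps[j, i] = g

    def ca_options(self, hid: int, rod: int, direction: str) -> np.ndarray:
        """Cα coordinates for all options, shape (n_options, length, 3)."""
        return self._ca[(hid, rod, direction)]

    def valid_options(self, hid: int, rod: int, direction: str) -> np.ndarray:
        """Options admissible on this rod (register clamp + static sterics)."""
        return self._valid[(hid, rod, direction)]


class _PairIndex:
    """Pair bookkeeping: which pairs touch which segment, at what offsets."""

    def __init__(self, problem: AssignmentProblem):
        seg_of: dict[int, tuple[int, int]] = {}
        for hid, first, last in problem.segments:
            for r in range(first, last + 1):
                seg_of[r] = (hid, r - first)

        partner_xyz: dict[tuple[str, int], np.ndarray] = {}
        for chain, model in problem.partner_models.items():
            for num, ca in zip(model.numbers, model.ca):
                partner_xyz[(chain, int(num))] = ca

        def resolve(chain: str, res: int):
            if chain == problem.chain and res in seg_of:
                return seg_of[res]
            if (chain, res) in partner_xyz:
                return ("partner", partner_xyz[(chain, res)])
            return None

        self.intra: dict[int, list[tuple[int, int]]] = {}   # hid -> offsets
        self.inter: list[tuple[int, int, int, int]] = []     # (hid_i, off_i, hid_j, off_j)
        self.partner: dict[int, list[tuple[int, np.ndarray]]] = {}  # hid -> (off, xyz)
        self.n_unresolved = 0
        self.n_resolvable = 0
        for p in problem.pairs:
            a = resolve(p.chain_i, p.res_i)
            b = resolve(p.chain_j, p.res_j)
            if a is None or b is None:
                self.n_unresolved += 1
                continue
            self.n_resolvable += 1
            a_partner = a[0] == "partner"
            b_partner = b[0] == "partner"
            if a_partner and b_partner:
                # both ends fixed: constant contribution, fold into intra bucket
                self.partner.setdefault(-1, [])
                self.partner[-1].append((a[1], b[1]))
            elif a_partner or b_partner:
                (hid, off) = b if a_partner else a
                xyz = a[1] if a_partner else b[1]
                self.partner.setdefault(hid, []).append((off, xyz))
            elif a[0] == b[0]:
                self.intra.setdefault(a[0], []).append((a[1], b[1]))
            else:
                self.inter.append((a[0], a[1], b[0], b[1]))
        if self.n_resolvable == 0:
            raise ValueError("no resolvable pairs: satisfaction fraction undefined")


def _optimize_assignment(problem: AssignmentProblem,
                         assignment: Assignment,
                         cache: PlacementCache,
                         index: _PairIndex) -> tuple[Assignment, int, float]:
    """Coordinate-ascent register/roll optimisation for one geometric assignment.

    Every helix starts at (register 0, roll 0); helices are revisited in
    helix-id order, each time picking the option maximizing the full model's
    (n_satisfied, −total distance) with ties broken by option order, until a
    sweep changes nothing (at most MAX_SWEEPS sweeps).  Returns the refined
    assignment, n_satisfied, and the total distance over resolvable pairs.
    """
    thr = problem.threshold
    helix_ids = [hid for hid, _, _ in sorted(problem.segments)]
    geo = {hid: assignment[hid] for hid in helix_ids}
    opt = {hid: cache.start_option for hid in helix_ids}

    coords = {hid: cache.ca_options(hid, geo[hid].rod, geo[hid].direction)
              for hid in helix_ids}

    # constant contributions: intra-segment pairs (rigid) and fixed-fixed pairs
    const_sat = 0
    const_dist = 0.0
    for hid, offsets in index.intra.items():
        ca = coords[hid][cache.start_option]
        for oi, oj in offsets:
            d = float(np.linalg.norm(ca[oi] - ca[oj]))
            const_dist += d
            if d <= thr:
                const_sat += 1
    for xa, xb in index.partner.get(-1, []):
        d = float(np.linalg.norm(np.asarray(xa) - np.asarray(xb)))
        const_dist += d
        if d <= thr:
            const_sat += 1

    # per-helix variable pair tables
    inter_by_helix: dict[int, list[tuple[int, int, int]]] = {hid: [] for hid in helix_ids}
    for (gi, oi, gj, oj) in index.inter:
        inter_by_helix[gi].append((oi, gj, oj))
        inter_by_helix[gj].append((oj, gi, oi))

    def stats_all_options(hid: int) -> tuple[np.ndarray, np.ndarray]:
        ca = coords[hid]
        rows = []
        partners = []
        for off, ghid, goff in inter_by_helix[hid]:
            rows.append(off)
            partners.append(coords[ghid][opt[ghid]][goff])
        for off, xyz in index.partner.get(hid, []):
            rows.append(off)
            partners.append(xyz)
        n_opt = ca.shape[0]
        valid = cache.valid_options(hid, geo[hid].rod, geo[hid].direction)
        if not rows:
            sat = np.zeros(n_opt, dtype=int)
            sat[~valid] = -1
            return sat, np.zeros(n_opt)
        diff = ca[:, rows, :] - np.asarray(partners)[None, :, :]
        d = np.linalg.norm(diff, axis=2)  # (n_opt, n_pairs)
        sat = (d <= thr).sum(axis=1)
        sat[~valid] = -1  # register outside the rod, or steric clash
        return sat, d.sum(axis=1)

    for _ in range(MAX_SWEEPS):
        changed = False
        for hid in helix_ids:
            sat, dist = stats_all_options(hid)
            # best: n_sat desc, dist asc, option index asc
            order = np.lexsort((np.arange(len(sat)), dist, -sat))
            best = int(order[0])
            if best != opt[hid]:
                cur_sat, cur_dist = sat[opt[hid]], dist[opt[hid]]
                if (sat[best], -dist[best]) > (cur_sat, -cur_dist):
                    opt[hid] = best
                    changed = True
        if not changed:
            break

    # total over variable pairs: each inter pair counted once
    total_sat = const_sat
    total_dist = const_dist
    for (gi, oi, gj, oj) in index.inter:
        d = float(np.linalg.norm(coords[gi][opt[gi]][oi] - coords[gj][opt[gj]][oj]))
        total_dist += d
        if d <= thr:
            total_sat += 1
    for hid in helix_ids:
        for off, xyz in index.partner.get(hid, []):
            d = float(np.linalg.norm(coords[hid][opt[hid]][off] - np.asarray(xyz)))
            total_dist += d
            if d <= thr:
                total_sat += 1

    refined = Assignment(tuple(
        (hid, AssignmentEntry(geo[hid].rod, geo[hid].direction,
                              cache.options[opt[hid]][0], cache.options[opt[hid]][1]))
        for hid in helix_ids))
    return refined, total_sat, total_dist


def assignment_models(problem: AssignmentProblem,
                      assignment: Assignment) -> dict[str, BackboneModel]:
    """Rebuild full backbone models (all chains) for an assignment from scratch."""
    placed = []
    for hid, first, last in sorted(problem.segments):
        e = assignment[hid]
        placed.append(place_helix(last - first + 1, problem.rods[e.rod],
                                  e.direction, e.register_shift, e.roll,
                                  problem.params, first_residue=first))
    models = {problem.chain: BackboneModel.concatenate(placed)}
    models.update(problem.partner_models)
    return models


def score_assignment(problem: AssignmentProblem,
                     assignment: Assignment,
                     cache: PlacementCache | None = None,
                     optimize: bool = True) -> tuple[Assignment, SatisfactionReport]:
    """Score one geometric assignment, optimizing register/roll on the grids.

    Returns the refined assignment (with the chosen register/roll) and the
    full satisfaction report of the rebuilt model.
    """
    cache = cache or PlacementCache(problem)
    index = _PairIndex(problem)
    if optimize:
        refined, _, _ = _optimize_assignment(problem, assignment, cache, index)
    else:
        refined = assignment
    report = ec_constraints.satisfaction(assignment_models(problem, refined),
                                         problem.pairs, problem.threshold)
    return refined, report


# --- relaxation bound --------------------------------------------------------

class _Bound:
    """Admissible upper bound on n_satisfied for a geometric assignment.

    Each helix pair (and each helix's partner-chain pairs) is scored with its
    register/roll options chosen freely for that group alone — a relaxation
    of the shared-option constraint, hence bound >= true optimum.
    """

    def __init__(self, problem: AssignmentProblem, cache: PlacementCache,
                 index: _PairIndex):
        thr = problem.threshold
        helix_ids = [hid for hid, _, _ in cache.segments]
        n_slots = len(problem.rods) * 2
        self.helix_ids = helix_ids

        self.const = 0
        for hid, offsets in index.intra.items():
            ca = cache.ca_options(hid, 0, "forward")[cache.start_option]
            for oi, oj in offsets:
                if np.linalg.norm(ca[oi] - ca[oj]) <= thr:
                    self.const += 1
        for xa, xb in index.partner.get(-1, []):
            if np.linalg.norm(np.asarray(xa) - np.asarray(xb)) <= thr:
                self.const += 1

        def slot(rod: int, direction_code: int) -> tuple[int, str]:
            return rod, ("forward", "reverse")[direction_code]

        # partner-chain pairs: best over options, per slot
        self.partner_tab: dict[int, np.ndarray] = {}
        for hid, plist in index.partner.items():
            if hid == -1:
                continue
            offs = [off for off, _ in plist]
            xyz = np.asarray([x for _, x in plist])
            tab = np.zeros(n_slots, dtype=int)
            for s in range(n_slots):
                rod_idx, direction = slot(*divmod(s, 2))
                ca = cache.ca_options(hid, rod_idx, direction)
                valid = cache.valid_options(hid, rod_idx, direction)
                if not valid.any():
                    continue
                d = np.linalg.norm(ca[valid][:, offs, :] - xyz[None], axis=2)
                tab[s] = int((d <= thr).sum(axis=1).max())
            self.partner_tab[hid] = tab

        # helix-pair tables: max satisfied over joint option choices per slot pair
        groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for (gi, oi, gj, oj) in index.inter:
            key = (gi, gj) if gi < gj else (gj, gi)
            off = (oi, oj) if gi < gj else (oj, oi)
            groups.setdefault(key, []).append(off)
        self.pair_tab: dict[tuple[int, int], np.ndarray] = {}
        for (gi, gj), offsets in groups.items():
            offs_i = [a for a, _ in offsets]
            offs_j = [b for _, b in offsets]
            tab = np.zeros((n_slots, n_slots), dtype=int)
            for si in range(n_slots):
                rod_i, dir_i = slot(*divmod(si, 2))
                valid_i = cache.valid_options(gi, rod_i, dir_i)
                if not valid_i.any():
                    continue
                ca_i = cache.ca_options(gi, rod_i, dir_i)[valid_i][:, offs_i, :]
                for sj in range(n_slots):
                    if si // 2 == sj // 2:
                        continue  # same rod: impossible (injective)
                    rod_j, dir_j = slot(*divmod(sj, 2))
                    valid_j = cache.valid_options(gj, rod_j, dir_j)
                    if not valid_j.any():
                        continue
                    ca_j = cache.ca_options(gj, rod_j, dir_j)[valid_j][:, offs_j, :]
                    d = np.linalg.norm(ca_i[:, None] - ca_j[None, :], axis=3)
                    tab[si, sj] = int((d <= thr).sum(axis=2).max())
            self.pair_tab[(gi, gj)] = tab

    def __call__(self, assignment: Assignment) -> int:
        slots = {hid: 2 * e.rod + (0 if e.direction == "forward" else 1)
                 for hid, e in assignment.entries}
        total = self.const
        for hid, tab in self.partner_tab.items():
            total += int(tab[slots[hid]])
        for (gi, gj), tab in self.pair_tab.items():
            total += int(tab[slots[gi], slots[gj]])
        return total


# --- search ------------------------------------------------------------------

def _rank_key(n_sat: int, dist: float, assignment: Assignment):
    return (-n_sat, dist, assignment.geometry_key())


def search_best(problem: AssignmentProblem,
                top_k: int | None = 10,
                prune: bool = True,
                mode: str = "exhaustive") -> RankedSolutions:
    """Exhaustively rank helix-to-rod assignments by constraint satisfaction.

    Ranking: n_satisfied descending, mean distance ascending, lexicographic
    assignment ascending — fully deterministic.  ``top_k=None`` keeps every
    assignment in the output (and disables pruning).  The unique-maximizer
    flag reports whether a single assignment attains the best n_satisfied.
    """
    if not problem.rods:
        raise ValueError("no rods to assign helices to")
    if mode == "heuristic":
        return _search_heuristic(problem)
    if mode != "exhaustive":
        raise ValueError(f"unknown mode {mode!r}")

    cache = PlacementCache(problem)
    index = _PairIndex(problem)
    if top_k is None:
        prune = False

    n_total = 0
    n_scored = 0
    conflicts = problem.rod_conflicts()
    results: list[tuple[int, float, Assignment]] = []
    if not prune:
        for geo in enumerate_assignments(problem):
            n_total += 1
            rods_used = [e.rod for _, e in geo.entries]
            if any(conflicts[a, b] for a, b in
                   itertools.combinations(rods_used, 2)):
                continue  # sterically impossible rod co-occupancy
            refined, n_sat, dist = _optimize_assignment(problem, geo, cache, index)
            n_scored += 1
            if n_sat >= 0:
                results.append((n_sat, dist, refined))
    else:
        results, n_scored = _search_pruned(problem, cache, index, top_k)
        n_total = count_assignments(problem.n_segments, len(problem.rods))

    if not results:
        raise ValueError("no admissible assignments: every injective rod "
                         "choice violates the minimum rod separation")
    results.sort(key=lambda r: _rank_key(r[0], r[1], r[2]))
    top_sat = results[0][0]
    # pruned candidates are provably below the k-th best n_satisfied, so
    # counting ties among scored results is exact
    unique = sum(1 for r in results if r[0] == top_sat) == 1
    if top_k is not None:
        results = results[:top_k]

    solutions = []
    for n_sat, dist, refined in results:
        report = ec_constraints.satisfaction(
            assignment_models(problem, refined), problem.pairs, problem.threshold)
        solutions.append((refined, report))
    expected = count_assignments(problem.n_segments, len(problem.rods))
    return RankedSolutions(solutions, n_evaluated=n_total, n_scored=n_scored,
                           exhaustive=(n_total == expected),
                           unique_maximizer=unique)


def _search_pruned(problem: AssignmentProblem, cache: PlacementCache,
                   index: _PairIndex, top_k: int) -> tuple[list, int]:
    """Exact top-k search with two-stage admissible-bound pruning.

    Rod permutations are triaged by a direction-free relaxation bound and
    processed in descending-bound order; directions are triaged per
    permutation; only candidates whose bound reaches the current k-th best
    n_satisfied are scored exactly.  Because the bound never underestimates
    the true score, the returned top-k equals the full scan's.
    """
    helix_ids = [hid for hid, _, _ in cache.segments]
    hid_pos = {hid: i for i, hid in enumerate(helix_ids)}
    K = len(helix_ids)
    R = len(problem.rods)
    bound = _Bound(problem, cache, index)

    perms = np.array(list(itertools.permutations(range(R), K)), dtype=np.int64)
    conflicts = problem.rod_conflicts()
    if conflicts.any():
        bad = np.zeros(len(perms), dtype=bool)
        for i in range(K):
            for j in range(i + 1, K):
                bad |= conflicts[perms[:, i], perms[:, j]]
        perms = perms[~bad]
    rod_bound = np.full(len(perms), bound.const, dtype=np.int64)
    pair_items = [((gi, gj), tab) for (gi, gj), tab in bound.pair_tab.items()]
    partner_items = list(bound.partner_tab.items())
    for (gi, gj), tab in pair_items:
        rod_max = tab.reshape(R, 2, R, 2).max(axis=(1, 3))
        rod_bound += rod_max[perms[:, hid_pos[gi]], perms[:, hid_pos[gj]]]
    for hid, tab in partner_items:
        rod_max = tab.reshape(R, 2).max(axis=1)
        rod_bound += rod_max[perms[:, hid_pos[hid]]]

    dir_grid = np.array(list(itertools.product((0, 1), repeat=K)), dtype=np.int64)
    order = np.argsort(-rod_bound, kind="stable")

    results: list[tuple[int, float, Assignment]] = []
    sats: list[int] = []
    floor = -1
    n_scored = 0
    for pi in order:
        if len(results) >= top_k and rod_bound[pi] < floor:
            break
        perm = perms[pi]
        slots = 2 * perm[None, :] + dir_grid  # (2^K, K)
        dir_bound = np.full(len(dir_grid), bound.const, dtype=np.int64)
        for (gi, gj), tab in pair_items:
            dir_bound += tab[slots[:, hid_pos[gi]], slots[:, hid_pos[gj]]]
        for hid, tab in partner_items:
            dir_bound += tab[slots[:, hid_pos[hid]]]
        for di in range(len(dir_grid)):
            if len(results) >= top_k and dir_bound[di] < floor:
                continue
            geo = Assignment(tuple(
                (hid, AssignmentEntry(int(perm[hid_pos[hid]]),
                                      "forward" if dir_grid[di, hid_pos[hid]] == 0
                                      else "reverse"))
                for hid in helix_ids))
            refined, n_sat, dist = _optimize_assignment(problem, geo, cache, index)
            n_scored += 1
            if n_sat < 0:
                continue  # steric clash: inadmissible
            results.append((n_sat, dist, refined))
            sats.append(n_sat)
            if len(results) >= top_k:
                floor = sorted(sats, reverse=True)[top_k - 1]
    return results, n_scored


def _search_heuristic(problem: AssignmentProblem) -> RankedSolutions:
    """Greedy construction + pairwise-swap refinement for K beyond the cap.

    Clearly heuristic: no optimality guarantee; returned metadata flags
    exhaustive=False.
    """
    cache = PlacementCache(problem)
    index = _PairIndex(problem)
    helix_ids = [hid for hid, _, _ in cache.segments]
    n_rods = len(problem.rods)

    def evaluate(geometry: dict[int, AssignmentEntry]):
        a = Assignment(tuple(sorted(geometry.items())))
        return _optimize_assignment(problem, a, cache, index)

    # greedy: assign helices in order of pair involvement, most constrained first
    involvement = {hid: 0 for hid in helix_ids}
    for gi, _, gj, _ in index.inter:
        involvement[gi] += 1
        involvement[gj] += 1
    for hid, plist in index.partner.items():
        if hid != -1:
            involvement[hid] += len(plist)
    order = sorted(helix_ids, key=lambda h: (-involvement[h], h))

    geometry: dict[int, AssignmentEntry] = {}
    used: set[int] = set()
    for hid in order:
        best = None
        for rod in range(n_rods):
            if rod in used:
                continue
            for direction in ("forward", "reverse"):
                trial = dict(geometry)
                trial[hid] = AssignmentEntry(rod, direction)
                # score the partial model over pairs fully inside it
                partial = {h: trial[h] for h in trial}
                try:
                    _, n_sat, dist = evaluate_partial(problem, partial, cache, index)
                except ValueError:
                    n_sat, dist = 0, 0.0
                key = (-n_sat, dist, rod, direction)
                if best is None or key < best[0]:
                    best = (key, rod, direction)
        geometry[hid] = AssignmentEntry(best[1], best[2])
        used.add(best[1])

    refined, n_sat, dist = evaluate(geometry)
    improved = True
    while improved:
        improved = False
        for ha, hb in itertools.combinations(helix_ids, 2):
            for variant in _swap_variants(geometry, ha, hb):
                r2, s2, d2 = evaluate(variant)
                if (s2, -d2) > (n_sat, -dist):
                    geometry = variant
                    refined, n_sat, dist = r2, s2, d2
                    improved = True
    report = ec_constraints.satisfaction(
        assignment_models(problem, refined), problem.pairs, problem.threshold)
    return RankedSolutions([(refined, report)], n_evaluated=0, n_scored=0,
                           exhaustive=False, unique_maximizer=False)


def _swap_variants(geometry, ha, hb):
    ea, eb = geometry[ha], geometry[hb]
    for da in ("forward", "reverse"):
        for db in ("forward", "reverse"):
            g = dict(geometry)
            g[ha] = AssignmentEntry(eb.rod, da)
            g[hb] = AssignmentEntry(ea.rod, db)
            yield g


def evaluate_partial(problem, geometry, cache, index):
    """Optimize/score a partial geometric assignment over the pairs it resolves."""
    sub_ids = set(geometry)
    sub_segments = [s for s in problem.segments if s[0] in sub_ids]
    sub_problem = replace(problem, segments=sub_segments)
    a = Assignment(tuple(sorted(geometry.items())))
    sub_index = _PairIndex(sub_problem)
    return _optimize_assignment(sub_problem, a, cache, sub_index)
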