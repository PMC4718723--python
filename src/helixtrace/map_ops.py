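"""Density-map operations: MRC I/O, segmentation, alignment, averaging, FSC.

Maps are plain 3D scalar grids with a cubic voxel size and a world-space
origin.  Real-space rigid alignment maximises normalized cross-correlation
over a coarse rotation lattice (with per-orientation translation scans via
the correlation theorem) followed by derivative-free local refinement —
the reproducible counterpart of aligning membrane regions interactively
before averaging.  Averaging aligned maps raises the signal-to-noise ratio
where states agree and inflates the voxelwise variance where they differ,
which is exactly the heterogeneity signal the variance map reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

__all__ = [
    "DensityMap",
    "RigidTransform",
    "FscCurve",
    "read_map",
    "write_map",
    "segment_map",
    "align_maps",
    "average_maps",
    "fsc",
]


@dataclass
class DensityMap:
    """A 3D scalar grid: ``grid[ix, iy, iz]`` sits at ``origin + index * voxel_size``."""

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3D with every dimension >= 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def centre(self) -> np.ndarray:
        """World coordinates of the geometric box centre."""
        return self.origin + (np.array(self.grid.shape) - 1) / 2.0 * self.voxel_size

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size, self.origin.copy())

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.voxel_size

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.voxel_size


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation 3x3, translation in Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthogonal")
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class FscCurve:
    """Fourier shell correlation: shell-centre frequencies (1/Å) and correlations."""

    frequencies: np.ndarray
    correlations: np.ndarray
    n_coefficients: np.ndarray

    def value_at(self, frequency: float) -> float:
        """FSC of the shell nearest to ``frequency`` (1/Å)."""
        return float(self.correlations[np.argmin(np.abs(self.frequencies - frequency))])

    def crossing(self, level: float = 0.143) -> float:
        """First frequency (1/Å) at which the curve drops below ``level``.

        Returns the Nyquist frequency if the curve never drops below.
        """
        below = np.nonzero(self.correlations < level)[0]
        if len(below) == 0:
            return float(self.frequencies[-1])
        k = below[0]
        if k == 0:
            return float(self.frequencies[0])
        f0, f1 = self.frequencies[k - 1], self.frequencies[k]
        c0, c1 = self.correlations[k - 1], self.correlations[k]
        if c0 == c1:
            return float(f1)
        return float(f0 + (c0 - level) / (c0 - c1) * (f1 - f0))


# --- MRC2014 I/O -------------------------------------------------------------

def write_map(density: DensityMap, path) -> None:
    """Write as MRC2014 mode 2 (32-bit float), preserving voxel size and origin."""
    ccp4 = gemmi.Ccp4Map()
    data = np.ascontiguousarray(density.grid, dtype=np.float32)
    ccp4.grid = gemmi.FloatGrid(data)
    nx, ny, nz = data.shape
    v = density.voxel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * v, ny * v, nz * v, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), density.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


def read_map(path) -> DensityMap:
    """Read an MRC2014 map; requires mode 2 and cubic voxels."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    mode = ccp4.header_i32(4)
    if mode != 2:
        raise ValueError(f"unsupported MRC mode {mode}; only mode 2 (float32) is supported")
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(ccp4.grid, copy=True)
    cell = ccp4.grid.unit_cell
    spacings = np.array([cell.a, cell.b, cell.c]) / np.array(grid.shape)
    if not np.allclose(spacings, spacings[0], atol=1e-4):
        raise ValueError(f"anisotropic voxels unsupported: spacings {spacings}")
    return DensityMap(grid, float(spacings[0]), origin)


# --- segmentation ------------------------------------------------------------

def segment_map(density: DensityMap, mask, crop: bool = False) -> DensityMap:
    """Zero voxels outside a mask; optionally crop to the mask bounding box.

    ``mask`` is one of
      ("sphere", centre_Å, radius_Å)
      ("box", corner_Å, extent_Å)
      ("threshold", level)
    or a boolean array of the grid's shape.
    """
    if isinstance(mask, np.ndarray):
        keep = mask.astype(bool)
        if keep.shape != density.grid.shape:
            raise ValueError("boolean mask shape must match the grid")
    else:
        kind = mask[0]
        idx = np.indices(density.grid.shape).reshape(3, -1).T
        world = density.index_to_world(idx)
        if kind == "sphere":
            _, centre, radius = mask
            keep = (np.linalg.norm(world - np.asarray(centre), axis=1) <= radius)
        elif kind == "box":
            _, corner, extent = mask
            corner = np.asarray(corner, dtype=float)
            extent = np.asarray(extent, dtype=float)
            keep = np.all((world >= corner) & (world <= corner + extent), axis=1)
        elif kind == "threshold":
            keep = (density.grid >= mask[1]).reshape(-1)
        else:
            raise ValueError(f"unknown mask kind {kind!r}")
        keep = keep.reshape(density.grid.shape)
    if not keep.any():
        raise ValueError("mask does not intersect the grid")
    out = np.where(keep, density.grid, 0.0).astype(np.float32)
    origin = density.origin.copy()
    if crop:
        nz = np.nonzero(keep)
        lo = [int(x.min()) for x in nz]
        hi = [int(x.max()) + 1 for x in nz]
        out = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        origin = origin + np.array(lo) * density.voxel_size
    return DensityMap(out, density.voxel_size, origin)


# --- alignment and averaging -------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a.ravel(), b.ravel()) / denom)


def _rotate_grid(grid: np.ndarray, rot: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    """Resample ``grid`` rotated by ``rot`` about its centre then shifted (voxels)."""
    centre = (np.array(grid.shape) - 1) / 2.0
    inv = rot.T
    offset = centre - inv @ (centre + shift_vox)
    return ndimage.affine_transform(grid, inv, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def _best_shift(fixed_ft: np.ndarray, moved: np.ndarray) -> tuple[np.ndarray, float]:
    """Translation (voxels) maximizing the raw cross-correlation, via FFT."""
    cc = np.fft.ifftn(fixed_ft * np.conj(np.fft.fftn(moved))).real
    peak = np.unravel_index(int(np.argmax(cc)), cc.shape)
    shape = np.array(cc.shape)
    shift = np.array(peak, dtype=float)
    shift[shift > shape / 2] -= shape[shift > shape / 2]
    # peak s maximizes sum_x fixed(x)·moved(x−s): translate moved by +s
    return shift, float(cc[peak])


def _rotation_lattice(step_deg: float, max_angle_deg: float) -> list[np.ndarray]:
    """Rotation vectors (degrees) on a cubic lattice within the angle cap."""
    n = int(math.floor(max_angle_deg / step_deg))
    vecs = [np.zeros(3)]
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                v = step_deg * np.array([i, j, k], dtype=float)
                norm = np.linalg.norm(v)
                if 0 < norm <= max_angle_deg:
                    vecs.append(v)
    return vecs


def align_maps(moving: DensityMap, fixed: DensityMap,
               coarse_step: float = 10.0,
               max_angle: float = 180.0,
               local_refine: bool = True) -> tuple[RigidTransform, DensityMap, float]:
    """Rigid real-space alignment of ``moving`` onto ``fixed``.

    Searches rotations on a rotation-vector lattice (``coarse_step`` degrees,
    capped at ``max_angle``), scans translations per orientation with the
    correlation theorem, then refines rotation + translation with Nelder–Mead
    on the normalized cross-correlation.  Returns the world-space transform
    mapping moving onto fixed, the resampled (trilinear) moving map on the
    fixed grid, and the final correlation.
    """
    if not math.isclose(moving.voxel_size, fixed.voxel_size, rel_tol=1e-6):
        raise ValueError("maps must share a voxel size")
    if moving.grid.shape != fixed.grid.shape:
        raise ValueError("maps must share a grid shape (pad before aligning)")
    if np.ptp(moving.grid) == 0 or np.ptp(fixed.grid) == 0:
        raise ValueError("featureless (constant) map: correlation undefined")

    fgrid = fixed.grid.astype(float)
    mgrid = moving.grid.astype(float)
    fixed_ft = np.fft.fftn(fgrid - fgrid.mean())

    best = None
    for rotvec in _rotation_lattice(coarse_step, max_angle):
        rot = Rotation.from_rotvec(rotvec, degrees=True).as_matrix()
        moved = _rotate_grid(mgrid, rot, np.zeros(3))
        shift, raw = _best_shift(fixed_ft, moved - moved.mean())
        if best is None or raw > best[0]:
            best = (raw, rotvec, shift)
    _, rotvec0, shift0 = best

    def objective(x: np.ndarray) -> float:
        rot = Rotation.from_rotvec(x[:3], degrees=True).as_matrix()
        return -_ncc(_rotate_grid(mgrid, rot, x[3:]), fgrid)

    x0 = np.concatenate([rotvec0, shift0])
    if local_refine:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 0.02, "fatol": 1e-7,
                                         "maxiter": 600})
        x0 = res.x

    rot = Rotation.from_rotvec(x0[:3], degrees=True).as_matrix()
    shift_vox = x0[3:]
    aligned_grid = _rotate_grid(mgrid, rot, shift_vox)
    corr = _ncc(aligned_grid, fgrid)
    shift_w = shift_vox * fixed.voxel_size
    translation = fixed.centre + shift_w - rot @ moving.centre
    transform = RigidTransform(rot, translation)
    aligned = DensityMap(aligned_grid.astype(np.float32), fixed.voxel_size,
                         fixed.origin.copy())
    return transform, aligned, corr


def average_maps(maps: list[DensityMap]) -> tuple[DensityMap, DensityMap]:
    """Voxelwise mean and unbiased (N−1) variance of aligned maps."""
    if len(maps) < 2:
        raise ValueError("averaging requires at least 2 maps")
    shape = maps[0].grid.shape
    v = maps[0].voxel_size
    for m in maps[1:]:
        if m.grid.shape != shape or not math.isclose(m.voxel_size, v, rel_tol=1e-6):
            raise ValueError("all maps must share grid shape and voxel size")
    stack = np.stack([m.grid.astype(float) for m in maps])
    mean = DensityMap(stack.mean(axis=0).astype(np.float32), v, maps[0].origin.copy())
    var = DensityMap(stack.var(axis=0, ddof=1).astype(np.float32), v, maps[0].origin.copy())
    return mean, var


def fsc(map_a: DensityMap, map_b: DensityMap, shell_width: float = 1.0) -> FscCurve:
    """Fourier shell correlation over concentric frequency shells.

    ``shell_width`` is in reciprocal voxels (cycles per box edge); returned
    frequencies are shell centres in 1/Å.
    """
    if map_a.grid.shape != map_b.grid.shape:
        raise ValueError("maps must share a grid shape")
    if not math.isclose(map_a.voxel_size, map_b.voxel_size, rel_tol=1e-6):
        raise ValueError("maps must share a voxel size")
    fa = np.fft.fftn(map_a.grid.astype(float))
    fb = np.fft.fftn(map_b.grid.astype(float))
    shape = map_a.grid.shape
    freqs = [np.fft.fftfreq(n) * n for n in shape]  # cycles per box
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij")
    radius = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    nyquist = min(shape) / 2.0
    shell_idx = np.floor(radius / shell_width).astype(int)
    n_shells = int(nyquist / shell_width) + 1

    num = np.real(fa * np.conj(fb)).ravel()
    pa = np.abs(fa).ravel() ** 2
    pb = np.abs(fb).ravel() ** 2
    flat = shell_idx.ravel()
    valid = flat < n_shells
    sums_num = np.bincount(flat[valid], num[valid], minlength=n_shells)
    sums_a = np.bincount(flat[valid], pa[valid], minlength=n_shells)
    sums_b = np.bincount(flat[valid], pb[valid], minlength=n_shells)
    counts = np.bincount(flat[valid], minlength=n_shells)

    denom = np.sqrt(sums_a * sums_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, sums_num / denom, 0.0)
    box_edge = shape[0] * map_a.voxel_size
    centres = (np.arange(n_shells) + 0.5) * shell_width / box_edge
    centres[0] = 0.0  # DC shell
    return FscCurve(centres, corr, counts)


def write_fsc(curve: FscCurve, path) -> None:
    """FSC curve as 2-column delimited text (frequency 1/Å, correlation)."""
    with open(path, "w") as fh:
        fh.write("# frequency_inv_A\tfsc\n")
        for f, c in zip(curve.frequencies, curve.correlations):
            fh.write(f"{f:.6f}\t{c:.6f}\n")
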