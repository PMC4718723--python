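"""Ideal α-helix backbone construction and rod-axis geometry.

Backbones are built residue-by-residue from internal coordinates (bond
length, bond angle, dihedral), the same construction used by interactive
modelling tools when asked for a "straight" helix at fixed (φ, ψ).  The
defaults φ = −57°, ψ = −47° give the canonical right-handed α-helix with a
rise of ~1.5 Å per residue, ~3.6 residues per turn and a Cα radius of
~2.3 Å.  Only backbone atoms (N, Cα, C, O) are built: every score in this
package is a Cα–Cα distance, and poly-alanine output is sufficient for
visual inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "HelixBuildParams",
    "BackboneModel",
    "RodAxis",
    "build_ideal_helix",
    "fit_axis",
    "place_helix",
    "helix_parameters",
    "read_pdb",
    "write_pdb",
]

ATOM_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class HelixBuildParams:
    """Internal-coordinate parameter set for the helix builder.

    Dihedrals are the standard α-helical values; bond lengths and angles are
    the conventional peptide geometry (Engh–Huber-like).  All lengths in Å,
    all angles in degrees.
    """

    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0
    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.5


@dataclass
class BackboneModel:
    """Ordered per-residue backbone (N, Cα, C, O) for one chain segment.

    ``numbers`` are 1-based sequence indices, strictly increasing but not
    necessarily contiguous (gaps mark unbuilt loops).  ``coords`` has shape
    ``(n_residues, 4, 3)`` with atoms ordered N, Cα, C, O, in Å.
    """

    numbers: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.numbers = np.asarray(self.numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.numbers), 4, 3):
            raise ValueError("coords must have shape (n_residues, 4, 3)")
        if len(self.numbers) > 1 and not np.all(np.diff(self.numbers) > 0):
            raise ValueError("sequence indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.numbers)

    @property
    def ca(self) -> np.ndarray:
        """Cα coordinates, shape (n_residues, 3)."""
        return self.coords[:, 1, :]

    def index_of(self, number: int) -> int:
        idx = int(np.searchsorted(self.numbers, number))
        if idx >= len(self.numbers) or self.numbers[idx] != number:
            raise KeyError(f"residue {number} not in model")
        return idx

    def has_residue(self, number: int) -> bool:
        idx = np.searchsorted(self.numbers, number)
        return idx < len(self.numbers) and self.numbers[idx] == number

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneModel":
        """Return a rigidly moved copy: x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new = self.coords @ rotation.T + translation
        return BackboneModel(self.numbers.copy(), new)

    def renumbered(self, first: int) -> "BackboneModel":
        """Shift numbering so the first residue is ``first`` (gaps preserved)."""
        offset = first - int(self.numbers[0])
        return BackboneModel(self.numbers + offset, self.coords.copy())

    @staticmethod
    def concatenate(models: "list[BackboneModel]") -> "BackboneModel":
        numbers = np.concatenate([m.numbers for m in models])
        coords = np.concatenate([m.coords for m in models])
        order = np.argsort(numbers)
        return BackboneModel(numbers[order], coords[order])


@dataclass(frozen=True)
class RodAxis:
    """A straight axis segment: the rod abstraction of a tubular density."""

    endpoint_a: np.ndarray
    endpoint_b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "endpoint_a", np.asarray(self.endpoint_a, dtype=float))
        object.__setattr__(self, "endpoint_b", np.asarray(self.endpoint_b, dtype=float))
        if self.length <= 0:
            raise ValueError("rod must have positive length")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.endpoint_b - self.endpoint_a))

    @property
    def direction(self) -> np.ndarray:
        d = self.endpoint_b - self.endpoint_a
        return d / np.linalg.norm(d)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.endpoint_a + self.endpoint_b)

    def canonical(self) -> "RodAxis":
        """Endpoints ordered so the dominant axis component is positive.

        Gives rods from different sources (ground truth, detection) a shared
        endpoint convention, so 'forward'/'reverse' is comparable.
        """
        d = self.endpoint_b - self.endpoint_a
        k = int(np.argmax(np.abs(d)))
        if d[k] < 0 or (d[k] == 0 and tuple(self.endpoint_a) > tuple(self.endpoint_b)):
            return RodAxis(self.endpoint_b, self.endpoint_a)
        return self


def _extend(a: np.ndarray, b: np.ndarray, c: np.ndarray,
            bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |cd|=bond, angle(b,c,d)=angle, dihedral(a,b,c,d)=torsion."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_ideal_helix(n_residues: int,
                      params: HelixBuildParams | None = None,
                      first_residue: int = 1) -> BackboneModel:
    """Build an ideal helix of ``n_residues`` by successive internal-coordinate steps.

    The first residue is placed in a canonical frame at the origin (N at the
    origin, Cα on +x, C in the xy-plane); every later atom follows from the
    previous three via (bond, angle, dihedral).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    p = params or HelixBuildParams()

    n_atoms: list[np.ndarray] = []
    ca_atoms: list[np.ndarray] = []
    c_atoms: list[np.ndarray] = []

    n0 = np.zeros(3)
    ca0 = np.array([p.bond_n_ca, 0.0, 0.0])
    theta = math.radians(180.0 - p.angle_n_ca_c)
    c0 = ca0 + p.bond_ca_c * np.array([math.cos(theta), math.sin(theta), 0.0])
    n_atoms.append(n0)
    ca_atoms.append(ca0)
    c_atoms.append(c0)

    for _ in range(1, n_residues):
        n_next = _extend(n_atoms[-1], ca_atoms[-1], c_atoms[-1],
                         p.bond_c_n, p.angle_ca_c_n, p.psi)
        ca_next = _extend(ca_atoms[-1], c_atoms[-1], n_next,
                          p.bond_n_ca, p.angle_c_n_ca, p.omega)
        c_next = _extend(c_atoms[-1], n_next, ca_next,
                         p.bond_ca_c, p.angle_n_ca_c, p.phi)
        n_atoms.append(n_next)
        ca_atoms.append(ca_next)
        c_atoms.append(c_next)

    # Carbonyl O in the peptide plane: torsion N-Cα-C-O = ψ + 180 mirrors the
    # position of the next residue's N across the C=O bond plane.
    o_atoms = [
        _extend(n_atoms[i], ca_atoms[i], c_atoms[i],
                p.bond_c_o, p.angle_ca_c_o, p.psi + 180.0)
        for i in range(n_residues)
    ]

    coords = np.stack(
        [np.stack(x) for x in (n_atoms, ca_atoms, c_atoms, o_atoms)], axis=1
    )
    numbers = np.arange(first_residue, first_residue + n_residues)
    return BackboneModel(numbers, coords)


def fit_axis(model: BackboneModel) -> RodAxis:
    """Total-least-squares line through the Cα trace.

    Endpoints are the projections of the first and last Cα onto the fitted
    line; the direction therefore runs N-terminus → C-terminus.
    """
    ca = model.ca
    if len(ca) < 3:
        raise ValueError("axis fit requires at least 3 residues")
    centroid = ca.mean(axis=0)
    centred = ca - centroid
    if np.allclose(centred, 0.0):
        raise ValueError("all Cα coincide; axis undefined")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    if direction @ (ca[-1] - ca[0]) < 0:
        direction = -direction
    t_first = (ca[0] - centroid) @ direction
    t_last = (ca[-1] - centroid) @ direction
    return RodAxis(centroid + t_first * direction, centroid + t_last * direction)


def segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between 3D segments p1p2 and q1q2 (clamped form)."""
    p1, p2, q1, q2 = (np.asarray(x, dtype=float) for x in (p1, p2, q1, q2))
    d1 = p2 - p1
    d2 = q2 - q1
    r = p1 - q1
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    b = d1 @ d2
    c = d1 @ r
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0)
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm((p1 + s * d1) - (q1 + t * d2)))


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # antiparallel: rotate 180° about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return _axis_rotation(perp, 180.0)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    angle = math.degrees(math.atan2(s, c))
    return _axis_rotation(axis, angle)


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = math.radians(angle_deg)
    kx, ky, kz = axis
    K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + math.sin(a) * K + (1.0 - math.cos(a)) * (K @ K)


def place_helix(segment_length: int,
                rod: RodAxis,
                direction: str = "forward",
                register_shift: int = 0,
                roll: float = 0.0,
                params: HelixBuildParams | None = None,
                first_residue: int = 1) -> BackboneModel:
    """Rigidly place an ideal helix of ``segment_length`` residues onto a rod.

    ``direction='forward'`` puts residue 1 nearest ``endpoint_a``, 'reverse'
    nearest ``endpoint_b``.  The helix is centred on the rod midpoint (longer
    helices overhang symmetrically); ``register_shift`` slides it along the
    axis in whole-residue rise increments and ``roll`` (degrees) rotates it
    about the axis.
    """
    if abs(register_shift) > segment_length:
        raise ValueError("|register_shift| must not exceed segment_length")
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    helix = build_ideal_helix(segment_length, params, first_residue=first_residue)
    axis0 = fit_axis(helix)
    u0 = axis0.direction
    u = rod.direction if direction == "forward" else -rod.direction
    rot = _axis_rotation(u, roll) @ _rotation_between(u0, u)
    rise = axis0.length / (segment_length - 1)
    target_centre = rod.midpoint + register_shift * rise * u
    trans = target_centre - rot @ axis0.midpoint
    return helix.transformed(rot, trans)


def helix_parameters(model: BackboneModel) -> dict:
    """Measure rise/residue, residues/turn and Cα radius against the fitted axis."""
    axis = fit_axis(model)
    u = axis.direction
    centroid = model.ca.mean(axis=0)
    rel = model.ca - centroid
    axial = rel @ u
    radial = rel - np.outer(axial, u)
    radius = float(np.linalg.norm(radial, axis=1).mean())

    idx = np.arange(len(model))
    rise = float(np.polyfit(idx, axial, 1)[0])

    # unwrap the azimuth of the radial component in a fixed plane basis
    e1 = radial[0] / np.linalg.norm(radial[0])
    e2 = np.cross(u, e1)
    az = np.unwrap(np.arctan2(radial @ e2, radial @ e1))
    twist = float(np.polyfit(idx, az, 1)[0])  # radians per residue
    residues_per_turn = float(2.0 * math.pi / abs(twist))
    return {
        "rise": rise,
        "residues_per_turn": residues_per_turn,
        "radius": radius,
        "axis_length": axis.length,
    }


# --- PDB I/O (poly-alanine) -------------------------------------------------

def write_pdb(path, models: dict[str, BackboneModel] | BackboneModel) -> None:
    """Write one or more chains as a poly-alanine PDB file.

    ``models`` maps chain id -> model; a bare model is written as chain A.
    Occupancy/B-factor are fixed at 1.00/0.00.
    """
    if isinstance(models, BackboneModel):
        models = {"A": models}
    structure = gemmi.Structure()
    structure.name = "helixtrace"
    gm = gemmi.Model("1")
    elements = ("N", "C", "C", "O")
    serial = 1
    for chain_id, model in models.items():
        chain = gemmi.Chain(chain_id)
        for number, residue_coords in zip(model.numbers, model.coords):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(number), " ")
            for name, elem, xyz in zip(ATOM_NAMES, elements, residue_coords):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(elem)
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                atom.b_iso = 0.0
                atom.serial = serial
                serial += 1
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    structure.add_model(gm)
    structure.setup_entities()
    structure.write_pdb(str(path))


def read_pdb(path) -> dict[str, BackboneModel]:
    """Read backbone chains from a PDB file, keyed by chain id.

    Residues missing any of N/CA/C/O are skipped (partial models are legal
    inputs; scoring treats absent residues as unresolved).
    """
    structure = gemmi.read_structure(str(path))
    out: dict[str, BackboneModel] = {}
    for chain in structure[0]:
        numbers = []
        coords = []
        for res in chain:
            positions = {}
            for atom in res:
                if atom.name in ATOM_NAMES:
                    positions[atom.name] = [atom.pos.x, atom.pos.y, atom.pos.z]
            if all(name in positions for name in ATOM_NAMES):
                numbers.append(res.seqid.num)
                coords.append([positions[name] for name in ATOM_NAMES])
        if numbers:
            out[chain.name] = BackboneModel(np.array(numbers), np.array(coords))
    return out
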