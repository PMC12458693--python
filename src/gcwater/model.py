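"""Domain types for hosts, rigid waters, water models and simulation regions.

All coordinates are lab-frame Cartesian angstroms; there are no periodic
boundaries (the solvent is a restrained droplet).  Hosts are rigid collections
of point charge + Lennard-Jones sites; waters are rigid multi-site molecules
whose orientation is carried as a proper rotation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParticleSite",
    "WaterModel",
    "WaterMolecule",
    "HostStructure",
    "SimulationRegion",
    "gcmc_box_from_waters",
    "random_rotation",
    "rotation_from_axis_angle",
]


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("coordinates must be finite")
    return v


@dataclass(frozen=True)
class ParticleSite:
    """A rigid nonbonded interaction site (point charge + LJ)."""

    position: np.ndarray
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    charge: float = 0.0
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "position", _as_vec3(self.position))
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError("LJ sigma and epsilon must be non-negative")


@dataclass(frozen=True)
class WaterModel:
    """A rigid n-site water model.

    Site 0 is the oxygen, at the origin of the molecular frame, and is the only
    LJ-bearing site.  TIP4P is the default model used throughout: O-H 0.9572 A,
    H-O-H 104.52 deg, massless M site 0.15 A along the HOH bisector carrying the
    negative charge.
    """

    site_offsets: np.ndarray  # (n_sites, 3), molecular frame, A
    site_charges: np.ndarray  # (n_sites,), e
    oxygen_lj_sigma: float
    oxygen_lj_epsilon: float
    name: str = "water"

    def __post_init__(self):
        off = np.array(self.site_offsets, dtype=float)
        chg = np.array(self.site_charges, dtype=float)
        if off.ndim != 2 or off.shape[1] != 3 or off.shape[0] != chg.shape[0]:
            raise ValueError("site_offsets must be (n,3) matching site_charges")
        if not np.allclose(off[0], 0.0):
            raise ValueError("site 0 (oxygen) must sit at the molecular origin")
        if abs(chg.sum()) > 1e-10:
            raise ValueError(f"water model must be neutral, net charge {chg.sum():g} e")
        off.setflags(write=False)
        chg.setflags(write=False)
        object.__setattr__(self, "site_offsets", off)
        object.__setattr__(self, "site_charges", chg)

    @property
    def n_sites(self) -> int:
        return self.site_offsets.shape[0]

    @classmethod
    def tip4p(cls) -> "WaterModel":
        r_oh = 0.9572
        theta = np.deg2rad(104.52)
        r_om = 0.15
        # bisector along +z; hydrogens in the xz plane
        h1 = r_oh * np.array([np.sin(theta / 2), 0.0, np.cos(theta / 2)])
        h2 = r_oh * np.array([-np.sin(theta / 2), 0.0, np.cos(theta / 2)])
        m = np.array([0.0, 0.0, r_om])
        return cls(
            site_offsets=np.array([[0.0, 0.0, 0.0], h1, h2, m]),
            site_charges=np.array([0.0, 0.52, 0.52, -1.04]),
            oxygen_lj_sigma=3.15365,
            oxygen_lj_epsilon=0.1550,
            name="TIP4P",
        )


def rotation_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle`` (Rodrigues)."""
    axis = _as_vec3(axis)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    x, y, z = axis / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a uniform unit quaternion)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _check_rotation(R: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("orientation must be a 3x3 rotation matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=tol * 10) or abs(np.linalg.det(R) - 1) > 1e-6:
        raise ValueError("orientation is not a proper rotation")
    return R


@dataclass
class WaterMolecule:
    """A rigid water: oxygen position plus orientation (molecular -> lab)."""

    oxygen_position: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.oxygen_position = _as_vec3(self.oxygen_position)
        self.orientation = _check_rotation(self.orientation)

    def site_positions(self, model: WaterModel) -> np.ndarray:
        """Lab-frame coordinates of every site, (n_sites, 3)."""
        return self.oxygen_position + self.site_offsets_lab(model)

    def site_offsets_lab(self, model: WaterModel) -> np.ndarray:
        return model.site_offsets @ self.orientation.T


class HostStructure:
    """A rigid host: an ordered list of ParticleSites plus crystallographic
    water oxygens kept only for evaluation (never part of the energy).
    """

    def __init__(self, sites, crystal_water_oxygens=None, rigid: bool = True):
        sites = list(sites)
        if not sites:
            raise ValueError("host must contain at least one site")
        self.sites = sites
        self.rigid = bool(rigid)
        cw = np.zeros((0, 3)) if crystal_water_oxygens is None else np.atleast_2d(
            np.asarray(crystal_water_oxygens, dtype=float)
        )
        if cw.size and cw.shape[1] != 3:
            raise ValueError("crystal water oxygens must be (n, 3)")
        self.crystal_water_oxygens = cw
        self.positions = np.array([s.position for s in sites])
        self.lj_sigma = np.array([s.lj_sigma for s in sites])
        self.lj_epsilon = np.array([s.lj_epsilon for s in sites])
        self.charges = np.array([s.charge for s in sites])

    def __len__(self) -> int:
        return len(self.sites)

    def with_extra_sites(self, extra) -> "HostStructure":
        """A new host with additional rigid sites (e.g. a bound ligand)."""
        return HostStructure(
            self.sites + list(extra),
            crystal_water_oxygens=self.crystal_water_oxygens,
            rigid=self.rigid,
        )

    def translated(self, shift) -> "HostStructure":
        shift = _as_vec3(shift)
        moved = [
            ParticleSite(s.position + shift, s.lj_sigma, s.lj_epsilon, s.charge, s.label)
            for s in self.sites
        ]
        cw = self.crystal_water_oxygens + shift if self.crystal_water_oxygens.size else None
        return HostStructure(moved, crystal_water_oxygens=cw, rigid=self.rigid)


@dataclass
class SimulationRegion:
    """Droplet restraint geometry plus the GCMC sampling box.

    The droplet is a sphere (center/radius) outside which waters feel a
    half-harmonic restraint of force constant ``restraint_k``; the GCMC box is
    an axis-aligned closed box that must lie entirely inside the droplet.
    """

    box_min: np.ndarray
    box_max: np.ndarray
    droplet_center: np.ndarray = None
    droplet_radius: float = 30.0
    restraint_k: float = 1.5

    def __post_init__(self):
        self.box_min = _as_vec3(self.box_min)
        self.box_max = _as_vec3(self.box_max)
        if np.any(self.box_max <= self.box_min):
            raise ValueError("GCMC box must have positive volume")
        if self.droplet_center is None:
            self.droplet_center = 0.5 * (self.box_min + self.box_max)
        self.droplet_center = _as_vec3(self.droplet_center)
        if self.restraint_k < 0:
            raise ValueError("restraint force constant must be >= 0")
        corners = np.array(
            [
                [lo if b else hi for lo, hi, b in zip(self.box_min, self.box_max, bits)]
                for bits in np.ndindex(2, 2, 2)
            ]
        )
        if np.any(np.linalg.norm(corners - self.droplet_center, axis=1) > self.droplet_radius):
            raise ValueError("GCMC box must lie entirely inside the droplet")

    @property
    def volume(self) -> float:
        """Box volume in A^3."""
        return float(np.prod(self.box_max - self.box_min))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Closed-box membership test on oxygen coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inside = np.all((pts >= self.box_min) & (pts <= self.box_max), axis=1)
        return inside if np.asarray(points).ndim == 2 else bool(inside[0])

    def translated(self, shift) -> "SimulationRegion":
        shift = _as_vec3(shift)
        return SimulationRegion(
            self.box_min + shift,
            self.box_max + shift,
            self.droplet_center + shift,
            self.droplet_radius,
            self.restraint_k,
        )


def gcmc_box_from_waters(
    oxygen_positions,
    padding: float = 1.0,
    droplet_center=None,
    droplet_radius: float = 30.0,
    restraint_k: float = 1.5,
) -> SimulationRegion:
    """Bounding box around a set of water oxygens, padded on every side.

    This is how the sampling region is defined in practice: the box spans the
    crystallographic network oxygens plus ``padding`` (default 1 A).
    """
    pts = np.atleast_2d(np.asarray(oxygen_positions, dtype=float))
    if pts.size == 0:
        raise ValueError("need at least one oxygen position to define the box")
    if padding < 0:
        raise ValueError("padding must be >= 0")
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    if np.any(hi <= lo):
        raise ValueError("degenerate (zero-volume) GCMC box; increase padding")
    return SimulationRegion(lo, hi, droplet_center, droplet_radius, restraint_k)
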