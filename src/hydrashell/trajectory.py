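"""Trajectory/topology data model and periodic-boundary geometry primitives.

Positions are in Å, times in ps, velocities in Å/ps. Boxes are orthorhombic
(three edge lengths); all distance computations go through the minimum-image
convention. Atom indices are 0-based internally and 1-based only at file
boundaries and in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# Domain partition of the 140-residue alpha-synuclein chain (1-based residue ids).
DOMAIN_RANGES = {
    "N-terminal": (1, 60),
    "NAC": (61, 95),
    "C-terminal": (96, 140),
}

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "NE": 20.180, "AR": 39.948, "KR": 83.798, "HE": 4.003,
    "FE": 55.845, "ZN": 65.38,
}


def mass_of(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}")


def domain_of_residue(resid_1based: int) -> str:
    """Map a 1-based protein residue id to its chain domain label."""
    for label, (lo, hi) in DOMAIN_RANGES.items():
        if lo <= resid_1based <= hi:
            return label
    raise ValueError(f"residue {resid_1based} outside the 1-140 protein range")


def minimum_image_displacement(a, b, box):
    """Displacement b - a under the minimum-image convention.

    Each component of the result lies in (-box/2, box/2]. Works on single
    vectors or broadcastable arrays of shape (..., 3).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    d = b - a
    d = np.remainder(d + box / 2.0, box) - box / 2.0  # [-box/2, box/2)
    # close the interval on the right instead of the left
    half = box / 2.0
    d = np.where(d == -half, half, d)
    return d


def minimum_image_distance(a, b, box):
    """Minimum-image Euclidean distance(s) between points a and b."""
    d = minimum_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_positions(positions: np.ndarray, box) -> np.ndarray:
    """Wrap coordinates into [0, box) per component."""
    box = np.asarray(box, dtype=float)
    return np.remainder(positions, box)


@dataclass
class Frame:
    """One trajectory frame: coordinates, optional velocities, periodic box."""

    positions: np.ndarray          # (N, 3) Å
    box: np.ndarray                # (3,) Å, orthorhombic edges
    time: float = 0.0              # ps
    velocities: Optional[np.ndarray] = None  # (N, 3) Å/ps

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Ordered frames with a uniform time step.

    ``velocity_provenance`` records where velocities came from: ``"file"``
    (read from disk), ``"generated"`` (synthetic), ``"estimated"``
    (central differences), or ``None``.
    """

    frames: list[Frame]
    dt: float                       # ps
    velocity_provenance: Optional[str] = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        n = self.frames[0].n_atoms
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {fr.n_atoms} atoms, expected {n}")
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def atom_count(self) -> int:
        return self.frames[0].n_atoms

    @property
    def box(self) -> np.ndarray:
        return self.frames[0].box

    def positions_array(self) -> np.ndarray:
        """All positions stacked as (n_frames, n_atoms, 3)."""
        return np.stack([fr.positions for fr in self.frames])

    def velocities_array(self) -> np.ndarray:
        if any(fr.velocities is None for fr in self.frames):
            raise ValueError(
                "trajectory carries no velocities; run estimate_velocities "
                "or read a file with velocity columns")
        return np.stack([fr.velocities for fr in self.frames])

    @property
    def has_velocities(self) -> bool:
        return all(fr.velocities is not None for fr in self.frames)


@dataclass
class Topology:
    """Static atom/residue/domain description of a system.

    ``residue_index`` is 0-based internally. ``water_groups`` holds (O, H, H)
    atom-index triples, one per water molecule.
    """

    elements: np.ndarray                    # (N,) str
    residue_index: np.ndarray               # (N,) int, 0-based
    residue_names: list[str]                # per residue
    residue_charges: np.ndarray             # per residue, formal charge at pH 7
    residue_domains: list[str]              # per residue label
    water_groups: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=int))
    atom_roles: Optional[np.ndarray] = None  # per atom, e.g. PDB atom names

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_charges = np.asarray(self.residue_charges, dtype=float)
        self.water_groups = np.asarray(self.water_groups, dtype=int).reshape(-1, 3)
        n_res = len(self.residue_names)
        if self.residue_index.min(initial=0) < 0 or (
                len(self.residue_index) and self.residue_index.max() >= n_res):
            raise ValueError("residue_index out of range")
        if len(self.residue_charges) != n_res or len(self.residue_domains) != n_res:
            raise ValueError("per-residue arrays must align with residue_names")
        for g in self.water_groups:
            if self.elements[g[0]].upper() != "O":
                raise ValueError(f"water group {g} must start with its oxygen")
            if any(self.elements[h].upper() != "H" for h in g[1:]):
                raise ValueError(f"water group {g} must contain two hydrogens")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.elements])

    def atoms_of_residue(self, res_idx: int) -> np.ndarray:
        return np.where(self.residue_index == res_idx)[0]

    def protein_residues(self) -> np.ndarray:
        """Residue indices (0-based) whose domain label is a protein domain."""
        prot = [i for i, d in enumerate(self.residue_domains)
                if d in DOMAIN_RANGES]
        return np.array(prot, dtype=int)

    def protein_atoms(self) -> np.ndarray:
        prot = set(self.protein_residues().tolist())
        return np.where([r in prot for r in self.residue_index])[0]

    def water_oxygens(self) -> np.ndarray:
        return self.water_groups[:, 0]


@dataclass
class Selection:
    """An ordered, duplicate-free set of atom indices with a label."""

    atom_indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        if len(np.unique(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.atom_indices)

    def validate(self, topology: Topology) -> None:
        if len(self) and (self.atom_indices.min() < 0
                          or self.atom_indices.max() >= topology.n_atoms):
            raise ValueError(f"selection {self.label!r} has indices outside "
                             f"the topology's {topology.n_atoms} atoms")


def estimate_velocities(traj: Trajectory) -> Trajectory:
    """Central-difference velocities from positions, with PBC unwrapping.

    v(t) = (r(t+dt) - r(t-dt)) / (2 dt), where each consecutive displacement
    is taken under the minimum image. The first and last frames are dropped
    (no centred difference exists there). Raises if any single-step
    displacement component reaches half a box edge, since the minimum image
    is then ambiguous.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames for central differences")
    pos = traj.positions_array()
    box = traj.box
    steps = np.empty((traj.n_frames - 1, traj.atom_count, 3))
    for i in range(traj.n_frames - 1):
        d = minimum_image_displacement(pos[i], pos[i + 1], box)
        bad = np.abs(d) >= box / 2.0 - 1e-12
        if np.any(bad):
            at = np.argwhere(bad)[0]
            raise ValueError(
                f"atom {at[0]} jumps more than half a box edge between "
                f"frames {i} and {i + 1}; velocities are not recoverable")
        steps[i] = d
    frames = []
    for i in range(1, traj.n_frames - 1):
        v = (steps[i - 1] + steps[i]) / (2.0 * traj.dt)
        old = traj.frames[i]
        frames.append(Frame(old.positions.copy(), old.box.copy(),
                            time=old.time, velocities=v))
    return Trajectory(frames, dt=traj.dt, velocity_provenance="estimated")
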