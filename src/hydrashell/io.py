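"""Readers and writers for trajectories and topologies.

Trajectory format: a Tinker-flavoured extended XYZ dialect. Each frame is

    <n_atoms>  t= <time_ps>
    <box_x> <box_y> <box_z> [90.0 90.0 90.0]
    <element> <x> <y> <z> [<vx> <vy> <vz>]   (n_atoms lines)

Coordinates in Å, velocities in Å/ps. Velocity columns are optional but
must be present for all atoms or none. Topologies come from PDB files
(parsed with biotite) or are built programmatically.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional

import numpy as np

from .trajectory import (
    DOMAIN_RANGES,
    Frame,
    Selection,
    Topology,
    Trajectory,
    domain_of_residue,
)

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "H2O"}
ION_RESNAMES = {"NA", "CL", "NA+", "CL-", "SOD", "CLA", "K", "K+", "MG", "CA2"}


class TrajectoryParseError(ValueError):
    pass


def load_residue_charges(path: Optional[str] = None) -> dict[str, int]:
    """Residue-name → formal-charge table (neutral pH defaults shipped)."""
    if path is None:
        source = importlib.resources.files("hydrashell.data").joinpath(
            "residue_charges.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    charges: dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, q = line.split()
        charges[name.upper()] = int(q)
    return charges


def _parse_box_line(tokens: list[str], frame_idx: int) -> np.ndarray:
    try:
        vals = [float(t) for t in tokens]
    except ValueError:
        raise TrajectoryParseError(
            f"frame {frame_idx}: box line is not numeric: {tokens!r}")
    if len(vals) not in (3, 6):
        raise TrajectoryParseError(
            f"frame {frame_idx}: box line needs 3 edges (plus optional "
            f"angles), got {len(vals)} numbers")
    if len(vals) == 6 and any(abs(a - 90.0) > 1e-6 for a in vals[3:]):
        raise TrajectoryParseError(
            f"frame {frame_idx}: only orthorhombic boxes (90° angles) "
            "are supported")
    box = np.array(vals[:3])
    if np.any(box <= 0):
        raise TrajectoryParseError(f"frame {frame_idx}: box edges must be > 0")
    return box


def read_trajectory(path, dt: float, format: str = "tinker-xyz") -> Trajectory:
    """Read a trajectory file; ``dt`` is the inter-frame spacing in ps.

    ``format`` is ``"tinker-xyz"`` (multi-frame extended XYZ/ARC dialect)
    or ``"pdb"`` (single-model PDB, no box required in the file only if a
    CRYST1 record exists).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if format == "pdb":
        top, frame = read_pdb(path)
        return Trajectory([frame], dt=dt)
    if format != "tinker-xyz":
        raise ValueError(f"unknown trajectory format {format!r}")

    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    elements_ref: Optional[list[str]] = None
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        header = lines[i].split()
        try:
            n_atoms = int(header[0])
        except ValueError:
            raise TrajectoryParseError(
                f"frame {frame_idx}: expected an atom count, got {lines[i]!r}")
        time = frame_idx * dt
        if "t=" in lines[i]:
            time = float(lines[i].split("t=")[1].split()[0])
        if i + 1 >= len(lines):
            raise TrajectoryParseError(f"frame {frame_idx}: missing box line")
        box = _parse_box_line(lines[i + 1].split(), frame_idx)
        body = lines[i + 2: i + 2 + n_atoms]
        if len(body) < n_atoms:
            raise TrajectoryParseError(
                f"frame {frame_idx}: expected {n_atoms} atom lines, file "
                f"ended after {len(body)}")
        elements, rows = [], []
        for j, line in enumerate(body):
            parts = line.split()
            if len(parts) not in (4, 7):
                raise TrajectoryParseError(
                    f"frame {frame_idx}, atom {j + 1}: expected element plus "
                    f"3 or 6 numbers, got {line!r}")
            elements.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if len({len(r) for r in rows}) != 1:
            raise TrajectoryParseError(
                f"frame {frame_idx}: mixed velocity/no-velocity atom lines")
        rows = np.array(rows)
        if elements_ref is None:
            elements_ref = elements
        elif len(elements) != len(elements_ref):
            raise TrajectoryParseError(
                f"frame {frame_idx}: atom count {len(elements)} differs "
                f"from first frame ({len(elements_ref)})")
        vel = rows[:, 3:6] if rows.shape[1] == 6 else None
        frames.append(Frame(rows[:, :3], box, time=time, velocities=vel))
        i += 2 + n_atoms
        frame_idx += 1
    if not frames:
        raise TrajectoryParseError("file contains no frames")
    has_vel = all(fr.velocities is not None for fr in frames)
    if not has_vel:
        for fr in frames:
            fr.velocities = None
    traj = Trajectory(frames, dt=dt,
                      velocity_provenance="file" if has_vel else None)
    traj.elements = elements_ref  # carried for convenience
    return traj


def write_trajectory(path, traj: Trajectory, elements=None) -> None:
    """Write the extended-XYZ dialect; includes velocity columns if present."""
    if elements is None:
        elements = getattr(traj, "elements", None)
    if elements is None:
        elements = ["X"] * traj.atom_count
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{fr.n_atoms}  t= {fr.time:.6f}\n")
            fh.write("  {:.6f} {:.6f} {:.6f} 90.0 90.0 90.0\n".format(*fr.box))
            if fr.velocities is not None:
                for el, p, v in zip(elements, fr.positions, fr.velocities):
                    fh.write(f"{el} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                             f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            else:
                for el, p in zip(elements, fr.positions):
                    fh.write(f"{el} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_pdb(path, charge_table: Optional[dict] = None):
    """Read a PDB file into a (Topology, Frame) pair.

    Residues are labelled by domain: protein residues by their 1-based id
    (1-60 N-terminal, 61-95 NAC, 96-140 C-terminal), water residues as
    ``solvent``, monatomic ions as ``ion``. Water (O, H, H) triples are
    collected into the topology's water groups.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1)
    if charge_table is None:
        charge_table = load_residue_charges()

    box = None
    if atoms.box is not None:
        box = np.diag(np.asarray(atoms.box, dtype=float))
    if box is None or np.any(box <= 0):
        # fall back to a bounding box with padding; callers may override
        span = atoms.coord.max(axis=0) - atoms.coord.min(axis=0)
        box = span + 10.0

    elements = np.array([e.capitalize() if len(e) > 1 else e.upper()
                         for e in atoms.element], dtype=object)
    res_ids = atoms.res_id
    res_names = atoms.res_name
    chain_ids = atoms.chain_id

    residue_keys: list[tuple] = []
    key_to_idx: dict[tuple, int] = {}
    residue_index = np.empty(len(atoms), dtype=int)
    for i in range(len(atoms)):
        key = (chain_ids[i], int(res_ids[i]), str(res_names[i]))
        if key not in key_to_idx:
            key_to_idx[key] = len(residue_keys)
            residue_keys.append(key)
        residue_index[i] = key_to_idx[key]

    residue_names, residue_charges, residue_domains = [], [], []
    for (_chain, rid, rname) in residue_keys:
        rname_u = rname.upper()
        residue_names.append(rname_u)
        if rname_u in WATER_RESNAMES:
            residue_charges.append(0)
            residue_domains.append("solvent")
        elif rname_u in ION_RESNAMES:
            residue_charges.append(1 if rname_u.startswith(("NA", "K", "SOD"))
                                   else -1)
            residue_domains.append("ion")
        else:
            residue_charges.append(charge_table.get(rname_u, 0))
            residue_domains.append(domain_of_residue(rid))

    water_groups = []
    for key, idx in key_to_idx.items():
        if key[2].upper() not in WATER_RESNAMES:
            continue
        members = np.where(residue_index == idx)[0]
        o = [a for a in members if elements[a].upper() == "O"]
        h = [a for a in members if elements[a].upper() == "H"]
        if len(o) != 1 or len(h) != 2:
            raise ValueError(
                f"water residue {key} is incomplete: {len(o)} O, {len(h)} H")
        water_groups.append([o[0], h[0], h[1]])

    top = Topology(
        elements=elements,
        residue_index=residue_index,
        residue_names=residue_names,
        residue_charges=np.array(residue_charges, dtype=float),
        residue_domains=residue_domains,
        water_groups=np.array(water_groups, dtype=int).reshape(-1, 3),
        atom_roles=np.array(atoms.atom_name, dtype=object),
    )
    frame = Frame(np.asarray(atoms.coord, dtype=float), box)
    return top, frame


def protein_selection(top: Topology, label: str = "protein") -> Selection:
    return Selection(top.protein_atoms(), label=label)


def domain_selection(top: Topology, domain: str) -> Selection:
    if domain not in DOMAIN_RANGES:
        raise ValueError(f"unknown domain {domain!r}")
    residues = [i for i, d in enumerate(top.residue_domains) if d == domain]
    mask = np.isin(top.residue_index, residues)
    return Selection(np.where(mask)[0], label=domain)
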