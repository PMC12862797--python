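"""Hydration-shell structure: shell selection, RDF, tetrahedral order, H-bonds.

The hydration shell is the set of waters whose oxygen lies within a cutoff
(default 3.1 Å) of any atom of the target selection, evaluated in a single
assignment frame; downstream time-window analyses keep that selection
frozen. Per-residue shells can instead use a dynamic cutoff taken from the
first peak of the residue–oxygen radial distribution function.

Periodic neighbour searches use a cKDTree with periodic boxsize; an O(N²)
minimum-image scan serves as the oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import (
    Frame,
    Selection,
    Topology,
    Trajectory,
    minimum_image_displacement,
    wrap_positions,
)


@dataclass
class RdfResult:
    """Radial pair distribution function g(r) with running coordination n(r)."""

    bin_centers: np.ndarray    # Å
    g_values: np.ndarray       # dimensionless
    coordination: np.ndarray   # running integral n(r)
    pair_label: str
    n_frames: int


@dataclass
class ShellAssignment:
    """Waters assigned to a hydration shell in one frame."""

    frame_index: int
    water_group_indices: np.ndarray   # indices into topology.water_groups
    oxygen_indices: np.ndarray        # atom indices of the shell oxygens
    cutoff_used: float                # Å
    target_label: str = ""


@dataclass
class OtoDistribution:
    """Per-molecule orientational tetrahedral order values and histogram."""

    q_values: np.ndarray
    bin_centers: np.ndarray
    probabilities: np.ndarray         # sums to 1

    def mean(self) -> float:
        return float(np.mean(self.q_values))


@dataclass
class HbondCount:
    counts: np.ndarray                # per frame
    d_cut: float                      # Å, donor–acceptor
    angle_cut: float                  # degrees, D–H···A at the hydrogen


def _periodic_tree(points: np.ndarray, box: np.ndarray) -> cKDTree:
    return cKDTree(wrap_positions(points, box), boxsize=box)


def select_hydration_shell(frame: Frame, topology: Topology,
                           target: Selection, cutoff: float = 3.1,
                           frame_index: int = 0) -> ShellAssignment:
    """Waters whose oxygen is within ``cutoff`` of any target atom.

    Distances are minimum-image; the boundary is inclusive (an oxygen at
    exactly the cutoff is in the shell). The assignment is tied to a single
    frame: the paper-style protocol freezes the selection made in the
    initial frame of each analysis window.
    """
    if len(target) == 0:
        raise ValueError("target selection is empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    target.validate(topology)
    oxy = topology.water_oxygens()
    if len(oxy) == 0:
        return ShellAssignment(frame_index, np.empty(0, int),
                               np.empty(0, int), cutoff, target.label)
    box = frame.box
    tree = _periodic_tree(frame.positions[target.atom_indices], box)
    o_wrapped = wrap_positions(frame.positions[oxy], box)
    # small epsilon keeps the boundary inclusive despite wrap round-off
    hits = tree.query_ball_point(o_wrapped, r=cutoff * (1 + 1e-12) + 1e-9)
    in_shell = np.array([len(h) > 0 for h in hits], dtype=bool)
    groups = np.where(in_shell)[0]
    return ShellAssignment(frame_index, groups, oxy[groups], cutoff,
                           target.label)


def per_residue_shells(frame: Frame, topology: Topology,
                       cutoffs) -> dict[int, ShellAssignment]:
    """Shell assignment per protein residue.

    ``cutoffs`` is a scalar (global cutoff) or a mapping residue-index →
    cutoff, e.g. from :func:`first_shell_cutoff` on per-residue RDFs.
    """
    out = {}
    for res in topology.protein_residues():
        cut = cutoffs if np.isscalar(cutoffs) else cutoffs[res]
        sel = Selection(topology.atoms_of_residue(res), label=f"res{res + 1}")
        out[res] = select_hydration_shell(frame, topology, sel, cut)
    return out


def compute_rdf(traj: Trajectory, sel_a: Selection, sel_b: Selection,
                r_max: float, n_bins: int = 100,
                pair_label: str = "") -> RdfResult:
    """Frame-averaged radial distribution function between two selections.

    g(r) is the shell-volume-normalised pair histogram with the reference
    density taken from ``sel_b``; the running coordination number is the
    cumulative pair count per ``sel_a`` atom, equal to
    4πρ_b ∫ g(r') r'² dr' by construction.
    """
    box = traj.box
    if r_max > box.min() / 2 + 1e-9:
        raise ValueError(
            f"r_max {r_max} exceeds half the smallest box edge "
            f"({box.min() / 2:.3f} Å)")
    a_idx, b_idx = sel_a.atom_indices, sel_b.atom_indices
    same = (len(a_idx) == len(b_idx)) and np.array_equal(
        np.sort(a_idx), np.sort(b_idx))
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    for fr in traj.frames:
        tree_a = _periodic_tree(fr.positions[a_idx], box)
        tree_b = _periodic_tree(fr.positions[b_idx], box)
        # cumulative=False with edges[0]=0 puts self pairs (d=0) in the
        # leading d<=0 element, which [1:] drops
        c = tree_a.count_neighbors(tree_b, edges, cumulative=False)[1:]
        counts += c
    volume = float(np.prod(box))
    n_b_eff = len(b_idx) - (1 if same else 0)
    rho_b = n_b_eff / volume
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = len(a_idx) * traj.n_frames
    g = counts / (norm * rho_b * shell_vol)
    coordination = np.cumsum(counts) / norm
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RdfResult(centers, g, coordination, pair_label, traj.n_frames)


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average with edge replication."""
    padded = np.concatenate([y[:1], y, y[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Interior indices strictly greater than both neighbours."""
    return np.where((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0] + 1


def first_shell_cutoff(rdf: RdfResult, convention: str = "peak") -> float:
    """Dynamic shell cutoff from the first feature of g(r).

    ``convention="peak"`` returns the r of the first local maximum of g(r)
    with g > 1 (the protocol used throughout this package);
    ``convention="minimum"`` returns the first local minimum after that
    peak, the conventional shell boundary.
    """
    g = _smooth3(rdf.g_values)
    maxima = [i for i in _local_maxima(g) if rdf.g_values[i] > 1.0]
    if not maxima:
        raise ValueError(
            "no first-shell peak found in g(r); fall back to the global "
            "3.1 Å cutoff")
    peak = maxima[0]
    if convention == "peak":
        return float(rdf.bin_centers[peak])
    if convention == "minimum":
        minima = _local_maxima(-g)
        after = [i for i in minima if i > peak]
        if not after:
            raise ValueError("no first minimum after the first peak")
        return float(rdf.bin_centers[after[0]])
    raise ValueError(f"unknown convention {convention!r}")


def qtet_from_neighbors(vectors: np.ndarray) -> float:
    """Tetrahedral order parameter from 4 centre→neighbour vectors.

    q = 1 - 3/8 Σ_{j<k} (cos ψ_{jk} + 1/3)², summed over the 6 angle pairs
    among the four nearest neighbours; 1 for a perfect tetrahedron, 0 on
    average for random directions, -3 when all four coincide.
    """
    v = np.asarray(vectors, dtype=float)
    if v.shape != (4, 3):
        raise ValueError("need exactly four neighbour vectors")
    u = v / np.linalg.norm(v, axis=1, keepdims=True)
    s = 0.0
    for j in range(3):
        for k in range(j + 1, 4):
            c = float(np.dot(u[j], u[k]))
            s += (c + 1.0 / 3.0) ** 2
    return 1.0 - 3.0 / 8.0 * s


def oto_qtet(frame: Frame, oxygen_sel: Selection,
             bin_width: float = 0.02) -> OtoDistribution:
    """Orientational tetrahedral order of each selected oxygen.

    For every oxygen the four nearest oxygen neighbours are found under
    minimum image (ties broken by atom index) and q is evaluated from the
    six inter-neighbour angles at the central oxygen. The histogram uses
    ``bin_width`` over [-3, 1].
    """
    idx = oxygen_sel.atom_indices
    if len(idx) < 5:
        raise ValueError("need at least 5 oxygens for tetrahedral order")
    box = frame.box
    pts = wrap_positions(frame.positions[idx], box)
    tree = cKDTree(pts, boxsize=box)
    # k=5: self plus four nearest; cKDTree orders ties by index
    _, nbrs = tree.query(pts, k=5)
    q = np.empty(len(idx))
    for i in range(len(idx)):
        nn = [j for j in nbrs[i] if j != i][:4]
        vecs = minimum_image_displacement(pts[i], pts[nn], box)
        q[i] = qtet_from_neighbors(vecs)
    edges = np.arange(-3.0, 1.0 + bin_width, bin_width)
    hist, _ = np.histogram(q, bins=edges)
    probs = hist / hist.sum()
    centers = 0.5 * (edges[1:] + edges[:-1])
    return OtoDistribution(q, centers, probs)


def oto_population_ratio(dist: OtoDistribution) -> tuple[float, float, float]:
    """Locate the ordered (q_o) and disordered (q_d) population maxima.

    Returns (q_o, q_d, P(q_d)/P(q_o)): q_o is the highest-q local maximum
    of the (3-bin smoothed) histogram, q_d the next local maximum below
    it, and the ratio uses the raw histogram probabilities at those bins.
    Raises if the histogram is unimodal.
    """
    smoothed = _smooth3(dist.probabilities)
    occupied = dist.probabilities > 0
    maxima = [i for i in _local_maxima(smoothed) if occupied[i]]
    if len(maxima) < 2:
        where = (f" (single mode at q = {dist.bin_centers[maxima[0]]:.3f})"
                 if maxima else "")
        raise ValueError("histogram is not bimodal" + where)
    maxima = sorted(maxima, key=lambda i: dist.bin_centers[i])
    i_o = maxima[-1]
    i_d = maxima[-2]
    q_o = float(dist.bin_centers[i_o])
    q_d = float(dist.bin_centers[i_d])
    ratio = float(dist.probabilities[i_d] / dist.probabilities[i_o])
    return q_o, q_d, ratio


def count_hbonds_frame(frame: Frame, donor_pairs: np.ndarray,
                       acceptors: np.ndarray, d_cut: float = 3.5,
                       angle_cut: float = 150.0) -> int:
    """Geometric hydrogen-bond count in one frame.

    ``donor_pairs`` is an (M, 2) array of (donor-heavy-atom, hydrogen)
    atom indices; ``acceptors`` an array of acceptor heavy atoms. A bond
    is counted when donor–acceptor distance ≤ d_cut and the D–H···A angle
    (at the hydrogen) ≥ angle_cut. The donor's own heavy atom is never its
    acceptor.
    """
    donor_pairs = np.asarray(donor_pairs, int).reshape(-1, 2)
    acceptors = np.asarray(acceptors, int)
    if len(donor_pairs) == 0 or len(acceptors) == 0:
        return 0
    box = frame.box
    pos = frame.positions
    tree_a = _periodic_tree(pos[acceptors], box)
    d_wrapped = wrap_positions(pos[donor_pairs[:, 0]], box)
    cand = tree_a.query_ball_point(d_wrapped, r=d_cut + 1e-9)
    cos_cut = np.cos(np.deg2rad(angle_cut))
    count = 0
    for (d_idx, h_idx), acc_list in zip(donor_pairs, cand):
        if not acc_list:
            continue
        h = pos[h_idx]
        hd = minimum_image_displacement(h, pos[d_idx], box)
        hd /= np.linalg.norm(hd)
        for a_local in acc_list:
            a_idx = acceptors[a_local]
            if a_idx == d_idx:
                continue
            ha = minimum_image_displacement(h, pos[a_idx], box)
            dist_da = np.linalg.norm(
                minimum_image_displacement(pos[d_idx], pos[a_idx], box))
            if dist_da > d_cut:
                continue
            ha = ha / np.linalg.norm(ha)
            # angle at H between H→D and H→A; 180° (linear) gives cos = -1
            if float(np.dot(hd, ha)) <= cos_cut:
                count += 1
    return count


def protein_water_donors_acceptors(frame: Frame, topology: Topology,
                                   bond_cut: float = 1.25):
    """Donor/acceptor lists for protein–water hydrogen bonding.

    Water donors/acceptors come from the topology's water groups. Protein
    polar hydrogens are identified geometrically: an H within ``bond_cut``
    Å of a protein N or O is bonded to it. Returns
    (protein_donor_pairs, protein_acceptors, water_donor_pairs, water_oxygens).
    """
    prot = topology.protein_atoms()
    elems = topology.elements
    prot_no = np.array([i for i in prot if elems[i].upper() in ("N", "O")])
    prot_h = np.array([i for i in prot if elems[i].upper() == "H"])
    donor_pairs = []
    if len(prot_no) and len(prot_h):
        box = frame.box
        tree = _periodic_tree(frame.positions[prot_no], box)
        h_wrapped = wrap_positions(frame.positions[prot_h], box)
        dist, nearest = tree.query(h_wrapped, k=1)
        for h, d, j in zip(prot_h, dist, nearest):
            if d <= bond_cut:
                donor_pairs.append((prot_no[j], h))
    water_donors = []
    for o, h1, h2 in topology.water_groups:
        water_donors.append((o, h1))
        water_donors.append((o, h2))
    return (np.array(donor_pairs, int).reshape(-1, 2), prot_no,
            np.array(water_donors, int).reshape(-1, 2),
            topology.water_oxygens())


def count_hbonds(traj_or_frame, topology: Topology, d_cut: float = 3.5,
                 angle_cut: float = 150.0) -> HbondCount:
    """Protein–water hydrogen bonds per frame (both donation directions)."""
    frames = (traj_or_frame.frames if isinstance(traj_or_frame, Trajectory)
              else [traj_or_frame])
    counts = []
    for fr in frames:
        pd_pairs, prot_acc, wd_pairs, wat_acc = \
            protein_water_donors_acceptors(fr, topology)
        n = count_hbonds_frame(fr, pd_pairs, wat_acc, d_cut, angle_cut)
        n += count_hbonds_frame(fr, wd_pairs, prot_acc, d_cut, angle_cut)
        counts.append(n)
    return HbondCount(np.array(counts, int), d_cut, angle_cut)
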