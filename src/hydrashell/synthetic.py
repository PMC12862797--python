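"""Synthetic trajectory generators with known ground truth.

Every analysis stage in this package can be validated by parameter
recovery against these generators:

* :func:`gen_langevin` — Ornstein–Uhlenbeck (OU) velocities with the exact
  discretisation, so the velocity autocorrelation is ``kT/m · exp(-γt)``
  at any step size and the diffusion coefficient is ``D = kT/(mγ)``.
* :func:`gen_rotational_diffusion` — isotropic small-step rotational
  diffusion of unit dipoles; the rank-1 orientational correlation decays
  as ``exp(-2 D_r t)``, i.e. τ = 1/(2 D_r), β = 1.
* :func:`gen_two_population` — a static probe plus "shell" (initially
  within a probe radius) and "bulk" OU populations with a prescribed
  retardation factor D_bulk / D_shell.
* :func:`gen_oto_configs` — point configurations of known tetrahedral
  order (diamond-cubic lattice, ideal gas, square-planar clusters).
* :func:`gen_grouped_samples` — grouped Gaussian replicates for the
  ANOVA / regression layer.

All generators are pure functions of their spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .trajectory import Frame, Selection, Topology, Trajectory, wrap_positions


@dataclass(frozen=True)
class LangevinSpec:
    """OU velocity process: dv = -γ v dt + √(2γ kT/m) dW, exact stepping."""

    n_particles: int
    gamma: float          # friction, ps⁻¹
    kT_over_m: float      # velocity variance, Å²/ps²
    dt: float             # ps
    n_steps: int
    seed: int
    box: tuple = (50.0, 50.0, 50.0)

    def __post_init__(self):
        if self.gamma <= 0 or self.kT_over_m <= 0:
            raise ValueError("gamma and kT_over_m must be positive")
        if self.dt <= 0 or self.n_steps < 1 or self.n_particles < 1:
            raise ValueError("dt, n_steps and n_particles must be positive")

    @property
    def diffusion_coefficient(self) -> float:
        """Implied D = kT/(mγ) in Å²/ps."""
        return self.kT_over_m / self.gamma


@dataclass(frozen=True)
class RotDiffSpec:
    """Isotropic rotational diffusion of unit dipoles on the sphere."""

    n_dipoles: int
    D_r: float            # rotational diffusion coefficient, ps⁻¹
    dt: float             # ps
    n_steps: int
    seed: int
    initial: str = "random"   # "random" (uniform on sphere) or "aligned" (+z)

    def __post_init__(self):
        if self.D_r <= 0:
            raise ValueError("D_r must be positive")
        if self.initial not in ("random", "aligned"):
            raise ValueError("initial must be 'random' or 'aligned'")
        if self.D_r * self.dt >= 0.05:
            raise ValueError(
                f"D_r*dt = {self.D_r * self.dt:.3g} too large for the "
                "small-step scheme (need < 0.05)")

    @property
    def tau(self) -> float:
        """Implied rank-1 relaxation time 1/(2 D_r), ps."""
        return 1.0 / (2.0 * self.D_r)


@dataclass(frozen=True)
class TwoPopulationSpec:
    """Shell + bulk OU populations around a static probe."""

    shell_spec: LangevinSpec
    bulk_spec: LangevinSpec
    probe_radius: float   # Å

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.shell_spec.dt != self.bulk_spec.dt or \
                self.shell_spec.n_steps != self.bulk_spec.n_steps:
            raise ValueError("shell and bulk specs must share dt and n_steps")

    @property
    def retardation(self) -> float:
        return (self.bulk_spec.diffusion_coefficient
                / self.shell_spec.diffusion_coefficient)


@dataclass(frozen=True)
class GroupedSamplesSpec:
    """Gaussian replicates per concentration level."""

    group_levels: tuple     # concentrations, M
    replicates_per_group: int
    means: tuple            # true mean per level
    sd: float
    seed: int

    def __post_init__(self):
        if self.replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if len(self.means) != len(self.group_levels):
            raise ValueError("means must align with group_levels")


class DipoleSeries(NamedTuple):
    """Unit-dipole orientations over time: values[(t, dipole, xyz)]."""

    values: np.ndarray    # (n_steps, n_dipoles, 3)
    dt: float             # ps


def gen_langevin(spec: LangevinSpec) -> Trajectory:
    """Exact-discretisation OU velocities integrated to wrapped positions.

    v(t+dt) = v(t) e^{-γ dt} + ξ,  ξ ~ N(0, kT/m (1 - e^{-2γ dt})) per
    component, started from the stationary distribution. Positions use a
    forward step r(t+dt) = r(t) + v(t) dt and are wrapped into the box.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    n, T = spec.n_particles, spec.n_steps
    decay = np.exp(-spec.gamma * spec.dt)
    noise_sd = np.sqrt(spec.kT_over_m * (1.0 - decay ** 2))
    v = rng.normal(0.0, np.sqrt(spec.kT_over_m), size=(n, 3))
    r = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    frames = []
    for t in range(T):
        frames.append(Frame(wrap_positions(r, box), box,
                            time=t * spec.dt, velocities=v.copy()))
        r = r + v * spec.dt
        v = v * decay + rng.normal(0.0, noise_sd, size=(n, 3))
    return Trajectory(frames, dt=spec.dt, velocity_provenance="generated")


def gen_rotational_diffusion(spec: RotDiffSpec) -> DipoleSeries:
    """Small-step isotropic diffusion of unit vectors on the sphere.

    Each step displaces every dipole by a Gaussian tangent-plane kick with
    variance 2 D_r dt per tangent axis, then renormalises. The ensemble
    rank-1 correlation converges to exp(-2 D_r t).
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_dipoles, spec.n_steps
    if spec.initial == "aligned":
        u = np.tile([0.0, 0.0, 1.0], (n, 1))
    else:
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    sd = np.sqrt(2.0 * spec.D_r * spec.dt)
    out = np.empty((T, n, 3))
    for t in range(T):
        out[t] = u
        # orthonormal tangent basis for each dipole
        ref = np.where(np.abs(u[:, [2]]) < 0.9,
                       np.tile([0.0, 0.0, 1.0], (n, 1)),
                       np.tile([1.0, 0.0, 0.0], (n, 1)))
        e1 = np.cross(u, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(u, e1)
        kicks = rng.normal(0.0, sd, size=(n, 2))
        u = u + kicks[:, [0]] * e1 + kicks[:, [1]] * e2
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    return DipoleSeries(out, spec.dt)


class TwoPopulationSystem(NamedTuple):
    trajectory: Trajectory
    topology: Topology
    shell: Selection
    bulk: Selection
    probe: Selection
    true_retardation: float


def gen_two_population(spec: TwoPopulationSpec) -> TwoPopulationSystem:
    """A static central probe plus shell and bulk OU populations.

    Shell particles start uniformly inside ``probe_radius`` of the probe;
    bulk particles start outside. Atom order: probe (index 0), shell,
    bulk. Elements are Kr (probe), Ne (shell), Ar (bulk).
    """
    sh, bu = spec.shell_spec, spec.bulk_spec
    box = np.asarray(sh.box, dtype=float)
    if not np.allclose(box, bu.box):
        raise ValueError("shell and bulk specs must share the box")
    centre = box / 2.0
    rng = np.random.default_rng(hash((sh.seed, bu.seed, 7)) % (2 ** 31))

    shell_traj = gen_langevin(sh)
    bulk_traj = gen_langevin(bu)

    # re-seat initial positions: shell inside the probe radius, bulk outside
    def _inside(n):
        pts = np.empty((n, 3))
        k = 0
        while k < n:
            cand = rng.uniform(-1, 1, size=(n, 3)) * spec.probe_radius
            ok = np.linalg.norm(cand, axis=1) <= spec.probe_radius
            take = min(n - k, ok.sum())
            pts[k:k + take] = cand[ok][:take]
            k += take
        return centre + pts

    def _outside(n):
        pts = np.empty((n, 3))
        k = 0
        while k < n:
            cand = rng.uniform(0, 1, size=(n, 3)) * box
            d = np.linalg.norm(cand - centre, axis=1)
            ok = d > spec.probe_radius + 1e-9
            take = min(n - k, ok.sum())
            pts[k:k + take] = cand[ok][:take]
            k += take
        return pts

    shell0 = _inside(sh.n_particles)
    bulk0 = _outside(bu.n_particles)

    def _rebase(traj, new0):
        pos0 = traj.frames[0].positions
        shift = new0 - pos0
        return [wrap_positions(fr.positions + shift, box) for fr in traj.frames]

    shell_pos = _rebase(shell_traj, shell0)
    bulk_pos = _rebase(bulk_traj, bulk0)

    n_frames = sh.n_steps
    frames = []
    for t in range(n_frames):
        pos = np.vstack([centre[None, :], shell_pos[t], bulk_pos[t]])
        vel = np.vstack([np.zeros((1, 3)),
                         shell_traj.frames[t].velocities,
                         bulk_traj.frames[t].velocities])
        frames.append(Frame(pos, box, time=t * sh.dt, velocities=vel))
    traj = Trajectory(frames, dt=sh.dt, velocity_provenance="generated")

    n_total = 1 + sh.n_particles + bu.n_particles
    elements = np.array(["Kr"] + ["Ne"] * sh.n_particles
                        + ["Ar"] * bu.n_particles, dtype=object)
    top = Topology(
        elements=elements,
        residue_index=np.arange(n_total),
        residue_names=["PRB"] + ["SHL"] * sh.n_particles
                      + ["BLK"] * bu.n_particles,
        residue_charges=np.zeros(n_total),
        residue_domains=["ion"] + ["solvent"] * (n_total - 1),
    )
    traj.elements = list(elements)
    shell_sel = Selection(np.arange(1, 1 + sh.n_particles), label="shell")
    bulk_sel = Selection(np.arange(1 + sh.n_particles, n_total), label="bulk")
    probe_sel = Selection(np.array([0]), label="probe")
    return TwoPopulationSystem(traj, top, shell_sel, bulk_sel, probe_sel,
                               spec.retardation)


def gen_oto_configs(kind: str, n: int, box, seed: int = 0) -> tuple[Frame, Selection]:
    """Point configurations of known orientational tetrahedral order.

    * ``"ideal-tetrahedral"`` — diamond-cubic lattice (8 sites per cubic
      cell); under periodic boundaries every site has q_tet = 1. ``n``
      must be 8·m³ and the box cubic.
    * ``"ideal-gas"`` — uniform random points; the ensemble mean of q_tet
      is 0 by the 3/8 normalisation.
    * ``"square-planar"`` — isolated 5-point clusters: a centre plus four
      coplanar neighbours at 90° spacing (q_tet = 0.5 at each centre).
      ``n`` must be a multiple of 5.

    Returns the frame and a selection of the reference sites (all sites
    for lattice and gas; cluster centres for square-planar).
    """
    box = np.asarray(box, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)
    if kind == "ideal-tetrahedral":
        m = round((n / 8) ** (1 / 3))
        if 8 * m ** 3 != n:
            raise ValueError("ideal-tetrahedral needs n = 8·m³ sites")
        if not np.allclose(box, box[0]):
            raise ValueError("ideal-tetrahedral needs a cubic box")
        a = box[0] / m
        basis = np.array([
            [0.00, 0.00, 0.00], [0.00, 0.50, 0.50],
            [0.50, 0.00, 0.50], [0.50, 0.50, 0.00],
            [0.25, 0.25, 0.25], [0.25, 0.75, 0.75],
            [0.75, 0.25, 0.75], [0.75, 0.75, 0.25],
        ])
        cells = np.array([[i, j, k] for i in range(m)
                          for j in range(m) for k in range(m)], dtype=float)
        pts = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
        ref = np.arange(n)
    elif kind == "ideal-gas":
        pts = rng.uniform(0, 1, size=(n, 3)) * box
        ref = np.arange(n)
    elif kind == "square-planar":
        if n % 5 != 0:
            raise ValueError("square-planar needs n divisible by 5")
        n_clusters = n // 5
        side = int(np.ceil(n_clusters ** (1 / 3)))
        spacing = box / side
        if np.min(spacing) < 8.0:
            raise ValueError("box too small to isolate square-planar clusters")
        d = 1.0  # neighbour distance, Å (well below cluster spacing)
        offsets = np.array([[d, 0, 0], [-d, 0, 0], [0, d, 0], [0, -d, 0]])
        pts, ref = [], []
        c = 0
        for i in range(side):
            for j in range(side):
                for k in range(side):
                    if c >= n_clusters:
                        break
                    centre = (np.array([i, j, k]) + 0.5) * spacing
                    ref.append(len(pts))
                    pts.append(centre)
                    pts.extend(centre + offsets)
                    c += 1
        pts = np.array(pts)
        ref = np.array(ref)
    else:
        raise ValueError(f"unknown configuration kind {kind!r}")
    return Frame(wrap_positions(pts, box), box), Selection(ref, label=kind)


def gen_grouped_samples(spec: GroupedSamplesSpec) -> pd.DataFrame:
    """Long-format table of (concentration, replicate, value)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for level, mu in zip(spec.group_levels, spec.means):
        vals = mu + rng.normal(0.0, spec.sd, size=spec.replicates_per_group)
        for rep, v in enumerate(vals):
            rows.append((level, rep, v))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "value"])
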