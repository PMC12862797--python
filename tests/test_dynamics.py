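import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydrashell.dynamics import (
    AcfSeries,
    dipole_dacf,
    end_to_end_distance,
    fit_stretched_exponential,
    kabsch_rmsd,
    protein_dipole_acf,
    protein_dipole_vectors,
    radius_of_gyration,
    rmsd,
    truncate_renormalize,
    vacf_diffusion,
    water_dipole_vectors,
)
from hydrashell.synthetic import (
    DipoleSeries,
    LangevinSpec,
    RotDiffSpec,
    gen_langevin,
    gen_rotational_diffusion,
)
from hydrashell.trajectory import Frame, Selection, Topology, Trajectory
from conftest import make_water_topology


def _const_velocity_traj(v, n_atoms=5, n_frames=50, dt=0.01):
    box = np.array([100.0, 100.0, 100.0])
    rng = np.random.default_rng(0)
    r0 = rng.uniform(10, 90, (n_atoms, 3))
    vel = np.tile(np.asarray(v, float), (n_atoms, 1))
    frames = [Frame(np.remainder(r0 + vel * t * dt, box), box, time=t * dt,
                    velocities=vel.copy()) for t in range(n_frames)]
    return Trajectory(frames, dt=dt, velocity_provenance="generated")


class TestVacfDiffusion:
    def test_constant_velocity_closed_form(self):
        """C_v(t) = |v|² for ballistic motion, so D = |v|² t_max / 3."""
        traj = _const_velocity_traj([1.0, 2.0, -1.0], n_frames=40)
        sel = Selection(np.arange(5))
        res = vacf_diffusion(traj, sel, t_max=0.2)
        v2 = 1.0 + 4.0 + 1.0
        assert res.mean == pytest.approx(v2 * 0.2 / 3.0 * 1e-8, rel=1e-9)
        assert res.sd == pytest.approx(0.0, abs=1e-20)

    def test_quadratic_in_velocity_scaling(self):
        spec = LangevinSpec(100, 2.0, 1.0, 0.01, 150, seed=3)
        traj = gen_langevin(spec)
        sel = Selection(np.arange(100))
        base = vacf_diffusion(traj, sel, t_max=1.0)
        scaled_frames = [Frame(f.positions, f.box, time=f.time,
                               velocities=2.0 * f.velocities)
                         for f in traj.frames]
        scaled = vacf_diffusion(Trajectory(scaled_frames, dt=traj.dt,
                                           velocity_provenance="generated"),
                                sel, t_max=1.0)
        assert scaled.mean == pytest.approx(4.0 * base.mean, rel=1e-9)

    def test_ou_fixture_recovers_green_kubo_d(self):
        spec = LangevinSpec(500, 2.0, 1.0, 0.01, 500, seed=9)
        traj = gen_langevin(spec)
        res = vacf_diffusion(traj, Selection(np.arange(500)), t_max=2.0)
        assert res.mean == pytest.approx(0.5e-8, rel=0.10)
        assert res.velocity_provenance == "generated"

    def test_missing_velocities_names_the_remedy(self):
        box = np.array([10.0] * 3)
        frames = [Frame(np.zeros((2, 3)) + t, box, time=t * 0.1)
                  for t in range(5)]
        traj = Trajectory(frames, dt=0.1)
        with pytest.raises(ValueError, match="estimate_velocities"):
            vacf_diffusion(traj, Selection(np.arange(2)), t_max=0.2)

    def test_empty_selection_rejected(self):
        traj = _const_velocity_traj([1.0, 0, 0])
        with pytest.raises(ValueError, match="empty"):
            vacf_diffusion(traj, Selection(np.array([], int)), t_max=0.1)


class TestDipoleDacf:
    def test_frozen_dipoles_stay_at_one(self):
        u = np.tile([0.0, 0.0, 1.0], (50, 20, 1))
        acf = dipole_dacf(DipoleSeries(u, 0.1), window=3.0)
        assert np.allclose(acf.values, 1.0)
        assert acf.values[0] == 1.0

    def test_rerandomised_dipoles_decorrelate(self, rng):
        u = rng.normal(size=(60, 400, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        acf = dipole_dacf(DipoleSeries(u, 0.1), window=2.0)
        n_eff = acf.n_particles * acf.n_origins
        assert np.max(np.abs(acf.values[1:])) < 3.0 / np.sqrt(n_eff) + 0.01

    def test_sphere_diffusion_closed_form(self):
        spec = RotDiffSpec(1000, D_r=0.1, dt=0.05, n_steps=500, seed=6)
        acf = dipole_dacf(gen_rotational_diffusion(spec), window=15.0)
        assert np.max(np.abs(acf.values - np.exp(-0.2 * acf.lags))) < 0.03

    def test_non_unit_vectors_rejected(self):
        u = np.full((20, 5, 3), 0.5)
        with pytest.raises(ValueError, match="unit"):
            dipole_dacf(DipoleSeries(u, 0.1), window=1.0)

    def test_cauchy_schwarz_bound(self, rng):
        spec = RotDiffSpec(500, D_r=0.2, dt=0.05, n_steps=300, seed=7)
        acf = dipole_dacf(gen_rotational_diffusion(spec), window=10.0)
        assert np.all(np.abs(acf.values) <= 1.0 + 1e-12)


class TestWaterDipoles:
    def _traj(self, positions, box=None):
        box = np.array([20.0] * 3) if box is None else box
        return Trajectory([Frame(positions, box, time=0.0),
                           Frame(positions, box, time=0.1)], dt=0.1)

    def test_symmetric_water_points_along_z(self):
        top = make_water_topology(1)
        pos = np.array([[5.0, 5.0, 5.0],
                        [5.0 + 0.76, 5.0, 5.59],
                        [5.0 - 0.76, 5.0, 5.59]])
        dip = water_dipole_vectors(self._traj(pos), top)
        assert np.allclose(dip.values[0, 0], [0.0, 0.0, 1.0], atol=1e-12)

    def test_equivariant_under_rigid_rotation(self):
        top = make_water_topology(1)
        pos = np.array([[5.0, 5.0, 5.0],
                        [5.76, 5.0, 5.59], [4.24, 5.0, 5.59]])
        R = Rotation.from_euler("xyz", [20, -40, 70], degrees=True)
        centre = pos[0]
        rotated = (pos - centre) @ R.as_matrix().T + centre
        d0 = water_dipole_vectors(self._traj(pos), top).values[0, 0]
        d1 = water_dipole_vectors(self._traj(rotated), top).values[0, 0]
        assert np.allclose(R.as_matrix() @ d0, d1, atol=1e-10)

    def test_periodic_straddling_matches_unwrapped_image(self):
        top = make_water_topology(1)
        box = np.array([10.0] * 3)
        whole = np.array([[5.0, 5.0, 5.0],
                          [5.76, 5.0, 5.59], [4.24, 5.0, 5.59]])
        near_edge = whole + np.array([4.9, 0.0, 0.0])   # O at x=9.9
        wrapped = np.remainder(near_edge, box)           # H's wrap to x≈0.66
        d0 = water_dipole_vectors(self._traj(near_edge, box), top)
        d1 = water_dipole_vectors(self._traj(wrapped, box), top)
        assert np.allclose(d0.values, d1.values, atol=1e-10)


class TestTruncateRenormalize:
    def test_pure_exponential_is_invariant(self):
        lags = np.linspace(0, 15, 301)
        acf = AcfSeries(lags, np.exp(-lags / 4.0), 1, 1)
        out = truncate_renormalize(acf, 2.0)
        assert np.allclose(out.values, np.exp(-out.lags / 4.0), atol=1e-12)
        assert out.lags[0] == 0.0

    def test_biexponential_fast_component_removed(self):
        lags = np.linspace(0, 60, 1201)
        y = 0.5 * np.exp(-lags / 0.2) + 0.5 * np.exp(-lags / 10.0)
        out = truncate_renormalize(AcfSeries(lags, y, 1, 1), 2.0)
        fit = fit_stretched_exponential(out)
        assert fit.tau == pytest.approx(10.0, rel=0.05)

    def test_zero_skip_is_identity(self):
        lags = np.linspace(0, 5, 51)
        acf = AcfSeries(lags, np.exp(-lags), 1, 1)
        out = truncate_renormalize(acf, 0.0)
        assert np.array_equal(out.values, acf.values)

    def test_nonpositive_pivot_rejected(self):
        lags = np.linspace(0, 5, 51)
        vals = np.exp(-lags)
        vals[20:] = -0.01
        with pytest.raises(ValueError, match="renormalization"):
            truncate_renormalize(AcfSeries(lags, vals, 1, 1), 2.5)


class TestStretchedExponentialFit:
    def test_pure_exponential_self_consistency(self):
        lags = np.linspace(0, 15, 151)
        fit = fit_stretched_exponential(AcfSeries(lags, np.exp(-lags / 5), 1, 1))
        assert fit.tau == pytest.approx(5.0, abs=0.01)
        assert fit.beta == pytest.approx(1.0, abs=0.01)

    def test_stretched_self_consistency(self):
        lags = np.linspace(0, 15, 151)
        y = np.exp(-((lags / 3.0) ** 0.7))
        fit = fit_stretched_exponential(AcfSeries(lags, y, 1, 1))
        assert fit.tau == pytest.approx(3.0, rel=0.02)
        assert fit.beta == pytest.approx(0.7, rel=0.02)

    @pytest.mark.parametrize("tau,beta", [(1.0, 0.4), (5.0, 0.6),
                                          (20.0, 0.8), (50.0, 1.0)])
    def test_noiseless_fits_are_near_perfect(self, tau, beta):
        lags = np.linspace(0, 3 * tau, 200)
        y = np.exp(-((lags / tau) ** beta))
        fit = fit_stretched_exponential(AcfSeries(lags, y, 1, 1))
        assert fit.r_squared > 0.999
        assert fit.tau == pytest.approx(tau, rel=0.02)

    def test_rotational_fixture_is_single_exponential(self):
        spec = RotDiffSpec(1000, D_r=0.1, dt=0.05, n_steps=600, seed=8)
        acf = dipole_dacf(gen_rotational_diffusion(spec), window=15.0)
        fit = fit_stretched_exponential(acf)
        assert 0.95 <= fit.beta <= 1.0


def _two_charge_topology():
    """Two single-atom residues with +1/0 formal charges (termini add ±1)."""
    return Topology(
        elements=np.array(["C", "C"], dtype=object),
        residue_index=np.array([0, 1]),
        residue_names=["LYS", "GLY"],
        residue_charges=np.array([1.0, 0.0]),
        residue_domains=["N-terminal", "N-terminal"],
        atom_roles=np.array(["CA", "CA"], dtype=object),
    )


class TestProteinDipole:
    def test_translation_leaves_unit_dipole_unchanged(self):
        top = _two_charge_topology()
        box = np.array([50.0] * 3)
        base = np.array([[10.0, 10.0, 10.0], [14.0, 10.0, 10.0]])
        frames = [Frame(base + t * np.array([0.3, 0.2, 0.1]), box,
                        time=t * 0.1) for t in range(30)]
        traj = Trajectory(frames, dt=0.1)
        acf, fit = protein_dipole_acf(traj, top, window=1.0)
        assert np.allclose(acf.values, 1.0, atol=1e-12)

    def test_com_reference_makes_dipole_origin_free(self):
        top = _two_charge_topology()
        box = np.array([50.0] * 3)
        base = np.array([[10.0, 10.0, 10.0], [14.0, 10.0, 10.0]])
        shifted = base + 7.0
        traj_a = Trajectory([Frame(base, box, time=0.0),
                             Frame(base, box, time=0.1)], dt=0.1)
        traj_b = Trajectory([Frame(shifted, box, time=0.0),
                             Frame(shifted, box, time=0.1)], dt=0.1)
        da = protein_dipole_vectors(traj_a, top).values
        db = protein_dipole_vectors(traj_b, top).values
        assert np.allclose(da, db, atol=1e-12)

    def test_rigid_rotor_relaxation_time(self):
        """A rigid dipole rotating by sphere diffusion relaxes with
        τ = 1/(2 D_r)."""
        top = _two_charge_topology()
        box = np.array([50.0] * 3)
        spec = RotDiffSpec(1, D_r=0.5, dt=0.02, n_steps=20000, seed=11)
        axis = gen_rotational_diffusion(spec).values[:, 0, :]
        com = np.array([25.0, 25.0, 25.0])
        frames = [Frame(np.vstack([com + 2.0 * u, com - 2.0 * u]), box,
                        time=t * 0.02) for t, u in enumerate(axis)]
        traj = Trajectory(frames, dt=0.02)
        acf, fit = protein_dipole_acf(traj, top, window=4.0)
        assert fit.tau == pytest.approx(1.0, rel=0.10)
        assert fit.beta == 1.0

    def test_all_zero_charges_rejected(self):
        top = _two_charge_topology()
        top.residue_charges = np.array([0.0, 0.0])
        # termini cancel at +1/-1 on a symmetric pair; dipole still defined,
        # so zero out the termini contribution by equal positions instead
        box = np.array([50.0] * 3)
        frames = [Frame(np.array([[10.0, 10, 10], [10.0, 10, 10]]), box,
                        time=t * 0.1) for t in range(3)]
        with pytest.raises(ValueError, match="dipole"):
            protein_dipole_acf(Trajectory(frames, dt=0.1), top, window=0.2)


class TestProteinGeometry:
    def test_two_point_radius_of_gyration(self):
        top = Topology(
            elements=np.array(["C", "C"], dtype=object),
            residue_index=np.array([0, 1]),
            residue_names=["GLY", "GLY"],
            residue_charges=np.zeros(2),
            residue_domains=["N-terminal", "N-terminal"],
        )
        frame = Frame(np.array([[0.0, 0, 0], [10.0, 0, 0]]),
                      np.array([50.0] * 3))
        sel = Selection(np.array([0, 1]))
        assert radius_of_gyration(frame, top, sel) == pytest.approx(5.0)

    def test_rg_invariant_under_rigid_motion(self, rng):
        n = 30
        top = Topology(
            elements=np.array(["C"] * n, dtype=object),
            residue_index=np.arange(n),
            residue_names=["GLY"] * n,
            residue_charges=np.zeros(n),
            residue_domains=["N-terminal"] * n,
        )
        pos = rng.normal(25, 3, (n, 3))
        sel = Selection(np.arange(n))
        box = np.array([200.0] * 3)
        r0 = radius_of_gyration(Frame(pos, box), top, sel)
        R = Rotation.random(random_state=1).as_matrix()
        moved = pos @ R.T + np.array([5.0, -3.0, 2.0])
        r1 = radius_of_gyration(Frame(moved, box), top, sel)
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_uniform_sphere_rg_limit(self, rng):
        n = 40000
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= rng.uniform(0, 1, (n, 1)) ** (1 / 3) * 8.0
        top = Topology(
            elements=np.array(["C"] * n, dtype=object),
            residue_index=np.arange(n),
            residue_names=["GLY"] * n,
            residue_charges=np.zeros(n),
            residue_domains=["N-terminal"] * n,
        )
        frame = Frame(pts + 50.0, np.array([200.0] * 3))
        rg = radius_of_gyration(frame, top, Selection(np.arange(n)))
        assert rg == pytest.approx(8.0 * np.sqrt(3.0 / 5.0), rel=0.01)

    def test_straight_chain_end_to_end(self):
        n = 140
        top = Topology(
            elements=np.array(["C"] * n, dtype=object),
            residue_index=np.arange(n),
            residue_names=["GLY"] * n,
            residue_charges=np.zeros(n),
            residue_domains=[("N-terminal" if i < 60 else
                              "NAC" if i < 95 else "C-terminal")
                             for i in range(n)],
            atom_roles=np.array(["CA"] * n, dtype=object),
        )
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n) * 3.8
        frame = Frame(pos + 1.0, np.array([1000.0] * 3))
        assert end_to_end_distance(frame, top) == pytest.approx(139 * 3.8)

    def test_rmsd_zero_for_identical_and_rotated(self, rng):
        pos = rng.normal(0, 5, (25, 3))
        ref = pos.copy()
        assert kabsch_rmsd(pos, ref) == pytest.approx(0.0, abs=1e-9)
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        assert kabsch_rmsd(pos @ R.T, ref) == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_atom_count_mismatch(self):
        box = np.array([10.0] * 3)
        f1 = Frame(np.zeros((3, 3)), box)
        f2 = Frame(np.zeros((4, 3)), box)
        with pytest.raises(ValueError):
            rmsd(f1, f2, Selection(np.arange(3)))
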