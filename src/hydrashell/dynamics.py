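"""Time-correlation analyses and protein geometry.

Translational diffusion uses the Green–Kubo relation: the velocity
autocorrelation function (VACF) of a selection is integrated over
[0, t_max] and divided by three,

    D = (1/3) ∫₀^{t_max} ⟨v_i(t₀)·v_i(t₀+t)⟩ dt,

with sliding time origins t₀ = frame 1, 2, … until fewer than t_max of
trajectory remain; each origin yields one replicate D, reported as
mean ± sd. Rotational relaxation uses the dipole autocorrelation function
(DACF) of unit dipole vectors, fitted to a stretched exponential
C(t) = exp(-(t/τ)^β); sub-picosecond libration can be removed by
truncating the first ~2 ps and renormalising before the fit.

Units: positions Å, time ps, velocities Å/ps; diffusion coefficients are
reported in m²/s (1 Å²/ps = 1e-8 m²/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import DipoleSeries
from .trajectory import (
    Frame,
    Selection,
    Topology,
    Trajectory,
    mass_of,
    minimum_image_displacement,
)

A2_PER_PS_TO_M2_PER_S = 1e-8


@dataclass
class AcfSeries:
    """Origin- and ensemble-averaged autocorrelation on a uniform lag grid."""

    lags: np.ndarray           # ps, starting at 0
    values: np.ndarray         # normalized (dipole) or raw (velocity)
    n_origins: int
    n_particles: int
    kind: str = ""             # "velocity" | "dipole"


@dataclass
class DiffusionResult:
    """Green–Kubo diffusion coefficient with per-origin replicates (m²/s)."""

    D_per_window: np.ndarray
    mean: float
    sd: float
    t_max: float               # ps
    selection_label: str = ""
    velocity_provenance: Optional[str] = None
    acf: Optional[AcfSeries] = None


@dataclass
class StretchedExpFit:
    """Fit of C(t) = exp(-(t/τ)^β)."""

    tau: float                 # ps
    beta: float
    r_squared: float
    fit_window: tuple          # (t_start, t_end) ps
    truncation: float = 0.0    # ps omitted and renormalized before fitting


def _sliding_correlation(data: np.ndarray, n_lags: int,
                         stride: int = 1) -> np.ndarray:
    """Per-origin particle-averaged dot correlations.

    ``data`` has shape (T, N, 3); returns a matrix M[origin, lag] =
    ⟨x(t₀)·x(t₀+lag)⟩ averaged over particles, with origins
    0, stride, 2·stride, … while a full window of ``n_lags`` frames fits.
    """
    T, N, _ = data.shape
    if n_lags > T:
        raise ValueError(f"window of {n_lags} frames exceeds the "
                         f"trajectory span of {T} frames")
    n_origins_full = T - n_lags + 1
    origins = np.arange(0, n_origins_full, stride)
    M = np.empty((len(origins), n_lags))
    base = data[origins]                      # (O, N, 3)
    for lag in range(n_lags):
        shifted = data[origins + lag]
        M[:, lag] = np.einsum("oid,oid->o", base, shifted) / N
    return M


def vacf_diffusion(traj: Trajectory, sel: Selection, t_max: float = 1.0,
                   window_stride: int = 1) -> DiffusionResult:
    """Green–Kubo diffusion coefficient from the VACF of a selection.

    Each sliding time origin contributes one VACF window, integrated by
    the trapezoid rule over [0, t_max] and divided by 3; windows are the
    replicates behind the reported mean ± sd. Raises if the trajectory
    carries no velocities (see ``estimate_velocities``) or the selection
    is empty.
    """
    if len(sel) == 0:
        raise ValueError("selection is empty")
    if not traj.has_velocities:
        raise ValueError("trajectory has no velocities; call "
                         "estimate_velocities or load a velocity file")
    vel = traj.velocities_array()[:, sel.atom_indices, :]
    n_lags = int(round(t_max / traj.dt)) + 1
    M = _sliding_correlation(vel, n_lags, stride=window_stride)
    D_win = np.trapezoid(M, dx=traj.dt, axis=1) / 3.0 * A2_PER_PS_TO_M2_PER_S
    lags = np.arange(n_lags) * traj.dt
    acf = AcfSeries(lags, M.mean(axis=0), n_origins=M.shape[0],
                    n_particles=len(sel), kind="velocity")
    return DiffusionResult(D_win, float(D_win.mean()),
                           float(D_win.std(ddof=1)) if len(D_win) > 1 else 0.0,
                           t_max, sel.label, traj.velocity_provenance, acf)


def dipole_dacf(dipoles: DipoleSeries, window: float = 15.0,
                stride: int = 1) -> AcfSeries:
    """Origin-averaged, normalised dipole autocorrelation function.

    ``dipoles.values`` must hold unit vectors (norm within 1e-6 of 1).
    The correlation is normalised so values[0] = 1 exactly.
    """
    u = np.asarray(dipoles.values, dtype=float)
    norms = np.linalg.norm(u, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("dipoles must be unit vectors (deviation > 1e-6)")
    n_lags = int(round(window / dipoles.dt)) + 1
    M = _sliding_correlation(u, n_lags, stride=stride)
    values = M.mean(axis=0)
    values = values / values[0]
    lags = np.arange(n_lags) * dipoles.dt
    return AcfSeries(lags, values, n_origins=M.shape[0],
                     n_particles=u.shape[1], kind="dipole")


def water_dipole_vectors(traj: Trajectory, topology: Topology,
                         groups: Optional[np.ndarray] = None) -> DipoleSeries:
    """Unit dipole along the H–O–H bisector of each selected water.

    ``groups`` selects rows of ``topology.water_groups`` (all by default).
    Hydrogens are taken relative to their oxygen under minimum image, so
    waters straddling a periodic boundary behave like their unwrapped
    image.
    """
    wg = topology.water_groups
    if groups is not None:
        wg = wg[np.asarray(groups, int)]
    if len(wg) == 0:
        raise ValueError("no water groups selected")
    box = traj.box
    T = traj.n_frames
    out = np.empty((T, len(wg), 3))
    for t, fr in enumerate(traj.frames):
        o = fr.positions[wg[:, 0]]
        h1 = minimum_image_displacement(o, fr.positions[wg[:, 1]], box)
        h2 = minimum_image_displacement(o, fr.positions[wg[:, 2]], box)
        mid = 0.5 * (h1 + h2)
        norm = np.linalg.norm(mid, axis=1, keepdims=True)
        if np.any(norm < 1e-9):
            bad = int(np.argmin(norm))
            raise ValueError(f"degenerate water group {wg[bad]} in frame {t}")
        out[t] = mid / norm
    return DipoleSeries(out, traj.dt)


def truncate_renormalize(acf: AcfSeries, t_skip: float) -> AcfSeries:
    """Drop lags below ``t_skip``, restart the lag grid at 0, renormalise.

    Removes sub-picosecond libration from a raw DACF: all retained values
    are divided by the value at the first retained lag, so the result
    again starts at 1.
    """
    if t_skip <= 0:
        return acf
    if t_skip >= acf.lags[-1]:
        raise ValueError("t_skip must be below the last lag")
    keep = acf.lags >= t_skip - 1e-12
    first = acf.values[keep][0]
    if first <= 0:
        raise ValueError("ACF value at the truncation point is not positive; "
                         "renormalization undefined")
    return AcfSeries(acf.lags[keep] - acf.lags[keep][0],
                     acf.values[keep] / first,
                     acf.n_origins, acf.n_particles, acf.kind)


def _stretched(t, tau, beta):
    # 0**beta = 0 for beta > 0, so C(0) = 1 without special-casing
    return np.exp(-np.power(np.asarray(t, float) / tau, beta))


def fit_stretched_exponential(acf: AcfSeries,
                              fix_beta: Optional[float] = None
                              ) -> StretchedExpFit:
    """Nonlinear least-squares fit of C(t) = exp(-(t/τ)^β).

    Bounds: τ > 0, 0 < β ≤ 1. Initial τ is the lag where C first drops
    below 1/e (or the last lag), initial β = 0.9. ``fix_beta`` pins the
    exponent (e.g. 1.0 for a pure exponential fit). A β at the upper
    bound of 1 is an exponential decay; β < 1 signals heterogeneous
    relaxation.
    """
    t = np.asarray(acf.lags, float)
    y = np.asarray(acf.values, float)
    if len(t) < 10:
        raise ValueError("need at least 10 lag points to fit")
    below = np.where(y < np.exp(-1.0))[0]
    tau0 = float(t[below[0]]) if len(below) else float(t[-1])
    tau0 = max(tau0, t[1] if len(t) > 1 else 1e-3)

    if fix_beta is not None:
        def model(tt, tau):
            return _stretched(tt, tau, fix_beta)
        p0s = [(tau0,), (tau0 * 3,), (tau0 / 3,)]
        bounds = ([1e-8], [np.inf])
    else:
        def model(tt, tau, beta):
            return _stretched(tt, tau, beta)
        p0s = [(tau0, 0.9), (tau0 * 3, 0.7), (tau0 / 3, 1.0)]
        bounds = ([1e-8, 1e-3], [np.inf, 1.0])

    last_err = None
    for p0 in p0s:
        try:
            popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds,
                                maxfev=20000)
            resid = y - model(t, *popt)
            ss_res = float(np.sum(resid ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            tau = float(popt[0])
            beta = fix_beta if fix_beta is not None else float(popt[1])
            return StretchedExpFit(tau, beta, r2,
                                   (float(t[0]), float(t[-1])))
        except RuntimeError as err:  # pragma: no cover - rare non-convergence
            last_err = err
    raise RuntimeError(f"stretched-exponential fit did not converge: "
                       f"{last_err}")


def protein_dipole_vectors(traj: Trajectory, topology: Topology) -> DipoleSeries:
    """Per-frame unit dipole of the protein from residue formal charges.

    μ(t) = Σ_i q_i (r_i(t) - r_COM(t)), where r_i is the residue's Cα
    (falling back to the residue centroid when no Cα role is recorded),
    q_i the residue formal charge at neutral pH with chain termini
    contributing +1/-1, and the COM is the mass-weighted centre of the
    protein atoms.
    """
    prot_res = topology.protein_residues()
    if len(prot_res) == 0:
        raise ValueError("topology has no protein residues")
    charges = topology.residue_charges[prot_res].copy()
    charges[0] += 1.0    # N-terminus
    charges[-1] -= 1.0   # C-terminus
    if np.all(charges == 0):
        raise ValueError("all residue charges are zero; unit dipole undefined")

    ref_atoms = []
    roles = topology.atom_roles
    for res in prot_res:
        members = topology.atoms_of_residue(res)
        ca = None
        if roles is not None:
            hits = [a for a in members if str(roles[a]).strip() == "CA"]
            ca = hits[0] if hits else None
        ref_atoms.append(ca if ca is not None else -1)

    prot_atoms = topology.protein_atoms()
    masses = np.array([mass_of(topology.elements[a]) for a in prot_atoms])
    out = np.empty((traj.n_frames, 1, 3))
    for t, fr in enumerate(traj.frames):
        com = np.average(fr.positions[prot_atoms], axis=0, weights=masses)
        mu = np.zeros(3)
        for q, res, ca in zip(charges, prot_res, ref_atoms):
            if ca >= 0:
                r = fr.positions[ca]
            else:
                r = fr.positions[topology.atoms_of_residue(res)].mean(axis=0)
            mu += q * (r - com)
        norm = np.linalg.norm(mu)
        if norm < 1e-12:
            raise ValueError(f"zero protein dipole in frame {t}")
        out[t, 0] = mu / norm
    return DipoleSeries(out, traj.dt)


def protein_dipole_acf(traj: Trajectory, topology: Topology,
                       window: Optional[float] = None,
                       stretched: bool = False
                       ) -> tuple[AcfSeries, StretchedExpFit]:
    """Protein rotational relaxation: unit-dipole ACF plus decay fit.

    By default the ACF is fitted to a single exponential (β pinned at 1);
    ``stretched=True`` frees β.
    """
    dip = protein_dipole_vectors(traj, topology)
    if window is None:
        window = (traj.n_frames - 1) * traj.dt / 2
    acf = dipole_dacf(dip, window=window)
    fit = fit_stretched_exponential(
        acf, fix_beta=None if stretched else 1.0)
    return acf, fit


def radius_of_gyration(frame: Frame, topology: Topology,
                       sel: Selection) -> float:
    """Mass-weighted radius of gyration of a selection (Å)."""
    if len(sel) == 0:
        raise ValueError("selection is empty")
    pos = frame.positions[sel.atom_indices]
    masses = np.array([mass_of(topology.elements[a])
                       for a in sel.atom_indices])
    com = np.average(pos, axis=0, weights=masses)
    sq = np.sum((pos - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def end_to_end_distance(frame: Frame, topology: Topology) -> float:
    """Cα(first residue)–Cα(last residue) distance of the protein chain (Å).

    Uses plain (unwrapped) coordinates: the chain is assumed whole in the
    frame, as the end-to-end vector of a 140-residue chain can legitimately
    exceed half a box edge.
    """
    prot_res = topology.protein_residues()
    if len(prot_res) < 2:
        raise ValueError("need at least two protein residues")
    roles = topology.atom_roles

    def _ca(res):
        members = topology.atoms_of_residue(res)
        if roles is not None:
            hits = [a for a in members if str(roles[a]).strip() == "CA"]
            if hits:
                return hits[0]
        return members[0]

    a = frame.positions[_ca(prot_res[0])]
    b = frame.positions[_ca(prot_res[-1])]
    return float(np.linalg.norm(b - a))


def kabsch_rmsd(coords: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (Kabsch algorithm)."""
    P = np.asarray(coords, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape:
        raise ValueError(f"coordinate shapes differ: {P.shape} vs {Q.shape}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ Pc.T).T - Qc
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def rmsd(frame: Frame, reference: Frame, sel: Selection) -> float:
    """RMSD of a selection versus a reference frame, after superposition."""
    if reference.n_atoms != frame.n_atoms:
        raise ValueError("frame and reference atom counts differ")
    idx = sel.atom_indices
    return kabsch_rmsd(frame.positions[idx], reference.positions[idx])


def protein_geometry(traj: Trajectory, topology: Topology,
                     reference: Optional[Frame] = None):
    """Per-frame Rg, Ree and RMSD series for the protein selection."""
    from .io import protein_selection
    sel = protein_selection(topology)
    ref = reference if reference is not None else traj.frames[0]
    rg = np.array([radius_of_gyration(fr, topology, sel)
                   for fr in traj.frames])
    ree = np.array([end_to_end_distance(fr, topology)
                    for fr in traj.frames])
    rms = np.array([rmsd(fr, ref, sel) for fr in traj.frames])
    return rg, ree, rms
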