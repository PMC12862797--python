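"""End-to-end orchestration: synthetic study generation and the analysis
pipeline (shell selection → dynamics → statistical aggregation).

:func:`simulate_study` lays a study out on disk the way the source MD
protocol is shaped — a grid of pseudo-concentration levels, each with
replicate analysis windows — using the two-population Langevin generator
(a slow "shell" population around a static probe plus fast "bulk") and a
rotational-diffusion dipole ensemble per cell, together with a
ground-truth JSON and a ready-to-run config.

:func:`run_pipeline` consumes such a config: per (level, window) cell it
reads the trajectory, selects the shell by the frozen initial-frame
distance criterion, computes VACF diffusion for shell and bulk and the
DACF relaxation of the dipole ensemble, then aggregates retardation
factors, concentration slopes and ANOVA across levels, writing CSV/JSON
outputs plus a reproducibility manifest with per-stage hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import dipole_dacf, fit_stretched_exponential, vacf_diffusion
from .io import read_trajectory, write_trajectory
from .stats import concentration_trend, one_way_anova, retardation_factor
from .structure import select_hydration_shell
from .synthetic import (
    DipoleSeries,
    LangevinSpec,
    RotDiffSpec,
    TwoPopulationSpec,
    gen_rotational_diffusion,
    gen_two_population,
)
from .trajectory import Selection, Topology

log = logging.getLogger("hydrashell.pipeline")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the reference MD protocol."""

    cells: list              # dicts: concentration, temperature, trajectory, dipoles
    output_dir: str
    shell_cutoff: float = 3.1       # Å
    dynamic_cutoff: bool = False
    vacf_t_max: float = 1.0         # ps
    dacf_window: float = 15.0       # ps
    dacf_truncation: float = 2.0    # ps
    replicates: int = 50
    dt: float = 0.01                # ps between frames
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def validate(self) -> None:
        for cell in self.cells:
            p = Path(cell["trajectory"])
            if not p.exists():
                raise FileNotFoundError(f"trajectory missing: {p}")
            if "dipoles" in cell and not Path(cell["dipoles"]).exists():
                raise FileNotFoundError(f"dipole file missing: "
                                        f"{cell['dipoles']}")


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)   # name -> {hash, seconds, rows}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "version": self.version,
             "stages": self.stages}, indent=2, default=str))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.round(12).to_csv(index=False).encode()).hexdigest()


def simulate_study(outdir, seed: int, n_levels: int = 8,
                   windows_per_level: int = 50,
                   n_particles: int = 500, n_steps: int = 400,
                   dt: float = 0.01, box_edge: float = 60.0,
                   probe_radius: float = 12.0,
                   retardation: float = 2.5,
                   shell_d_slope: float = 0.10,   # Å²/ps per M
                   bulk_d_slope: float = 0.0,
                   tau0: float = 1.2, tau_slope: float = -0.3,  # ps, ps/M
                   n_dipoles: int = 100,
                   max_level: float = 0.9) -> Path:
    """Write a synthetic study to ``outdir``; returns the config path.

    Levels are pseudo-concentrations 0 … ``max_level`` M. Per cell a
    two-population trajectory (with velocities) and a dipole ensemble are
    written as extended-XYZ files. Ground truth — D per population and
    level, τ per level, and the implied concentration slopes — goes to
    ``truth.json``; a ready RunConfig goes to ``config.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    levels = np.linspace(0.0, max_level, n_levels)
    box = (box_edge,) * 3

    gamma_bulk, gamma_shell = 2.0, 5.0
    kt_bulk0 = gamma_bulk * 0.5              # D_bulk(0) = 0.5 Å²/ps
    d_shell0 = 0.5 / retardation

    truth = {"levels": levels.tolist(), "retardation": retardation,
             "D_bulk": {}, "D_shell": {}, "tau": {},
             "shell_d_slope_A2ps_per_M": shell_d_slope,
             "shell_d_slope_m2s_per_M": shell_d_slope * 1e-8,
             "bulk_d_slope_A2ps_per_M": bulk_d_slope,
             "tau_slope_ps_per_M": tau_slope, "beta": 1.0,
             "seed": seed}
    cells = []
    for li, level in enumerate(levels):
        d_shell = d_shell0 + shell_d_slope * level
        d_bulk = 0.5 + bulk_d_slope * level
        tau = tau0 + tau_slope * level
        if d_shell <= 0 or tau <= 0:
            raise ValueError("slopes drive D or tau non-positive")
        truth["D_shell"][f"{level:.4f}"] = d_shell
        truth["D_bulk"][f"{level:.4f}"] = d_bulk
        truth["tau"][f"{level:.4f}"] = tau
        for w in range(windows_per_level):
            sub = int(rng.integers(0, 2 ** 31 - 1))
            spec = TwoPopulationSpec(
                shell_spec=LangevinSpec(n_particles, gamma_shell,
                                        d_shell * gamma_shell, dt, n_steps,
                                        seed=sub, box=box),
                bulk_spec=LangevinSpec(n_particles, gamma_bulk,
                                       d_bulk * gamma_bulk, dt, n_steps,
                                       seed=sub + 1, box=box),
                probe_radius=probe_radius)
            system = gen_two_population(spec)
            tpath = outdir / f"traj_L{li}_W{w}.xyz"
            write_trajectory(tpath, system.trajectory)

            rspec = RotDiffSpec(n_dipoles, D_r=1.0 / (2.0 * tau), dt=dt,
                                n_steps=n_steps, seed=sub + 2)
            dip = gen_rotational_diffusion(rspec)
            dpath = outdir / f"dipoles_L{li}_W{w}.xyz"
            _write_dipoles(dpath, dip)
            cells.append({"concentration": float(level),
                          "temperature": 300.0,
                          "window": w,
                          "trajectory": str(tpath),
                          "dipoles": str(dpath)})

    (outdir / "truth.json").write_text(json.dumps(truth, indent=2,
                                                  sort_keys=True))
    # integrate the VACF over ≥4 friction times where the window allows
    t_max = min(2.0, (n_steps - 1) * dt * 0.5)
    config = RunConfig(cells=cells, output_dir=str(outdir / "results"),
                       shell_cutoff=probe_radius, vacf_t_max=t_max,
                       dacf_window=(n_steps - 1) * dt * 0.8,
                       dacf_truncation=0.0,
                       replicates=windows_per_level, dt=dt, seed=seed)
    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)
    return cfg_path


def _write_dipoles(path, dip: DipoleSeries) -> None:
    """Store unit dipoles in the XYZ dialect (vectors as coordinates)."""
    n = dip.values.shape[1]
    with open(path, "w") as fh:
        for t in range(dip.values.shape[0]):
            fh.write(f"{n}  t= {t * dip.dt:.6f}\n")
            fh.write("  10.0 10.0 10.0 90.0 90.0 90.0\n")
            for v in dip.values[t]:
                fh.write(f"D {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")


def _read_dipoles(path, dt: float) -> DipoleSeries:
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        block = lines[i + 2: i + 2 + n]
        arr = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        frames.append(arr)
        i += 2 + n
    vals = np.stack(frames)
    vals /= np.linalg.norm(vals, axis=-1, keepdims=True)
    return DipoleSeries(vals, dt)


def _two_population_topology(traj) -> Topology:
    """Rebuild the probe/shell/bulk topology from the element column."""
    elements = np.asarray(getattr(traj, "elements"), dtype=object)
    n = len(elements)
    names = {"Kr": "PRB", "Ne": "SHL", "Ar": "BLK"}
    return Topology(
        elements=elements,
        residue_index=np.arange(n),
        residue_names=[names.get(e, "UNK") for e in elements],
        residue_charges=np.zeros(n),
        residue_domains=["ion" if e == "Kr" else "solvent"
                         for e in elements],
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the study: per-cell dynamics, then cross-level statistics.

    Failures in a single (concentration, window) cell are logged and
    skipped; the run fails only if no cell succeeds.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(config.__dict__, cells=len(config.cells)),
                           version=__version__)

    t0 = time.perf_counter()
    rows = []
    for cell in config.cells:
        try:
            rows.append(_analyse_cell(cell, config))
        except Exception as err:
            log.warning("cell %s failed: %s", cell, err)
    if not rows:
        raise RuntimeError("no (concentration, temperature) cell succeeded")
    per_window = pd.DataFrame(rows)
    per_window.to_csv(outdir / "per_window.csv", index=False)
    manifest.stages["dynamics"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "rows": len(per_window), "hash": _hash_df(per_window)}

    t0 = time.perf_counter()
    summary = _aggregate(per_window)
    (outdir / "trends.json").write_text(json.dumps(summary, indent=2))
    per_level = per_window.groupby("concentration").agg(
        D_shell_mean=("D_shell", "mean"), D_shell_sd=("D_shell", "std"),
        D_bulk_mean=("D_bulk", "mean"), D_bulk_sd=("D_bulk", "std"),
        tau_mean=("tau", "mean"), tau_sd=("tau", "std"),
        beta_mean=("beta", "mean")).reset_index()
    per_level.to_csv(outdir / "per_level.csv", index=False)
    manifest.stages["aggregation"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "rows": len(per_level), "hash": _hash_df(per_level)}
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _analyse_cell(cell: dict, config: RunConfig) -> dict:
    traj = read_trajectory(cell["trajectory"], dt=config.dt)
    top = _two_population_topology(traj)
    probe = Selection(np.where(np.asarray(traj.elements) == "Kr")[0],
                      label="probe")
    bulk = Selection(np.where(np.asarray(traj.elements) == "Ar")[0],
                     label="bulk")
    non_probe = Selection(
        np.where(np.asarray(traj.elements) != "Kr")[0], label="particles")
    # frozen initial-frame distance criterion around the probe
    shell_assign = _distance_shell(traj.frames[0], non_probe, probe,
                                   config.shell_cutoff)
    d_shell = vacf_diffusion(traj, shell_assign, t_max=config.vacf_t_max)
    d_bulk = vacf_diffusion(traj, bulk, t_max=config.vacf_t_max)

    out = {"concentration": cell["concentration"],
           "temperature": cell.get("temperature", 300.0),
           "window": cell.get("window", 0),
           "n_shell": len(shell_assign), "n_bulk": len(bulk),
           "D_shell": d_shell.mean, "D_shell_sd": d_shell.sd,
           "D_bulk": d_bulk.mean, "D_bulk_sd": d_bulk.sd,
           "tau": np.nan, "beta": np.nan}
    if "dipoles" in cell:
        dip = _read_dipoles(cell["dipoles"], dt=config.dt)
        acf = dipole_dacf(dip, window=config.dacf_window)
        if config.dacf_truncation > 0:
            from .dynamics import truncate_renormalize
            acf = truncate_renormalize(acf, config.dacf_truncation)
        fit = fit_stretched_exponential(acf)
        out["tau"], out["beta"] = fit.tau, fit.beta
    return out


def _distance_shell(frame, candidates: Selection, target: Selection,
                    cutoff: float) -> Selection:
    from .trajectory import minimum_image_displacement
    pos = frame.positions
    keep = []
    for i in candidates.atom_indices:
        d = minimum_image_displacement(pos[target.atom_indices], pos[i],
                                       frame.box)
        if np.min(np.linalg.norm(d, axis=-1)) <= cutoff:
            keep.append(i)
    return Selection(np.array(keep, int), label="shell")


def _aggregate(per_window: pd.DataFrame) -> dict:
    levels = np.sort(per_window["concentration"].unique())
    base = per_window[per_window["concentration"] == levels[0]]
    ratio, ratio_sd = retardation_factor(
        (base["D_bulk"].mean(), base["D_bulk"].std(ddof=1)),
        (base["D_shell"].mean(), base["D_shell"].std(ddof=1)))

    def _slope(col):
        g = per_window.groupby("concentration")[col]
        return concentration_trend(g.mean().index.to_numpy(),
                                   g.mean().to_numpy(),
                                   g.std(ddof=1).to_numpy())

    shell_slope, shell_p = _slope("D_shell")
    bulk_slope, bulk_p = _slope("D_bulk")
    summary = {
        "retardation_factor": ratio, "retardation_sd": ratio_sd,
        "shell_D_slope_m2s_per_M": shell_slope,
        "shell_D_slope_p": shell_p,
        "bulk_D_slope_m2s_per_M": bulk_slope,
        "bulk_D_slope_p": bulk_p,
    }
    shell_groups = [per_window.loc[per_window["concentration"] == c,
                                   "D_shell"].to_numpy() for c in levels]
    if all(len(g) >= 2 for g in shell_groups) and len(shell_groups) >= 2:
        summary["anova_shell_D"] = one_way_anova(shell_groups).to_dict()
    if per_window["tau"].notna().all():
        tau_slope, tau_p = _slope("tau")
        summary["tau_slope_ps_per_M"] = tau_slope
        summary["tau_slope_p"] = tau_p
        summary["beta_mean"] = float(per_window["beta"].mean())
    return summary
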