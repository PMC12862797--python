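# Methods

This note documents the models, conventions and numerical choices behind
hydrashell, in the spirit of a simulation-analysis package's methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## System model and conventions

Trajectories are ordered frames of positions (Å) with a uniform time step
(ps) in an orthorhombic periodic box; velocities (Å/ps) are optional.
Coordinates are treated as wrapped; every distance goes through the
minimum-image convention, whose displacement components lie in
(−L/2, L/2]. Triclinic boxes and binary trajectory formats are out of
scope. Atom indices are 0-based internally and 1-based at file boundaries.

Velocities can come from two provenances, recorded in every diffusion
result: `file` (velocity columns in the trajectory), or `estimated`
(central differences v(t) = [r(t+Δt) − r(t−Δt)]/2Δt with minimum-image
unwrapping, dropping the first and last frames). Central differencing
low-passes the velocity process: for an Ornstein–Uhlenbeck (OU) velocity
with friction γ, the estimated variance is kT/m · (1+e^{−γΔt})/2, a ~2.5%
deficit at γΔt = 0.05. The tests therefore require variance recovery at
the 10% level, not exactness.

Topology holds atoms → residues → domains (N-terminal 1–60, NAC 61–95,
C-terminal 96–140 for the 140-residue chain; `solvent` and `ion`
otherwise), residue formal charges at neutral pH from a shipped plain-text
table (Asp/Glu −1, Lys/Arg +1, His 0), and (O, H, H) water triples.

## Hydration-shell selection

A shell is the set of waters whose oxygen lies within a cutoff of any
atom of the target selection in a single assignment frame; the boundary is
inclusive. Downstream time-window analyses freeze the selection made at
the window's first frame — waters that later leave the cutoff remain in
the window's ensemble, which is the standard windowed-protocol choice and
is what the synthetic two-population system emulates.

The default global cutoff is 3.1 Å. Per-residue analysis can instead use
a dynamic cutoff equal to the *first peak* of the residue–oxygen g(r).
Using the peak rather than the conventional first minimum is a deliberate
protocol-fidelity choice: the first minimum is available via
`first_shell_cutoff(..., convention="minimum")` for users who prefer the
conventional shell boundary, and the function errors (recommending the
3.1 Å fallback) when no interior peak with g > 1 exists.

Neighbour searches use a periodic cKDTree; the test suite checks exact
agreement with an O(N²) minimum-image scan on random frames, including
atoms far outside the primary box image.

## Water structure

**RDF.** g(r) is the frame-averaged, shell-volume-normalised pair
histogram with reference density ρ_b = (N_b − δ_ab)/V; the coordination
number n(r) is the raw cumulative pair count per reference atom, which
equals 4πρ_b ∫ g r'² dr' by construction and integrates to N_b − δ_ab at
half-box range. r_max must not exceed half the smallest box edge.

**Tetrahedral order.** For each selected oxygen the four nearest oxygen
neighbours (minimum image; rank ties broken deterministically) define
q = 1 − (3/8) Σ_{j<k} (cos ψ_{jk} + 1/3)². The 3/8 normalisation zeroes
the ideal-gas expectation; a diamond-cubic lattice scores exactly 1 and a
degenerate all-collinear arrangement −3. Histograms use bin width 0.02
over [−3, 1] and are normalised to probabilities (a density-vs-count
ambiguity resolved as probability). Population analysis smooths with a
3-bin moving average, takes q_o as the highest-q local maximum and q_d as
the next maximum below it, and reports P(q_d)/P(q_o) from the raw bin
probabilities; a unimodal histogram is an error rather than a silent 1.0.

**Hydrogen bonds.** Geometric criterion, configurable, defaulting to
donor–acceptor ≤ 3.5 Å and D–H···A angle (at the hydrogen) ≥ 150° — the
community-standard definition, adopted because the analysed protocol
treats H-bond counts qualitatively. Protein polar hydrogens are
identified geometrically (H within 1.25 Å of a protein N/O), since the
topology model carries no bond table.

## Dynamics

**Translational diffusion.** Green–Kubo:
D = (1/3) ∫₀^{t_max} ⟨v(t₀)·v(t₀+t)⟩ dt, trapezoid rule on the uniform
frame grid, sliding origins t₀ = 0, 1, 2, … frames until a full window no
longer fits. Each origin yields one replicate D; results report
mean ± sd and the velocity provenance. Units: Å²/ps × 10⁻⁸ = m²/s.

The window t_max matters: truncating the integral at t_max biases D by a
factor 1 − e^{−γ t_max} for an OU process. The protocol default is
t_max = 1 ps (appropriate for real water, whose VACF has decayed by then);
the synthetic recovery suites integrate to t_max = 2 ps ≈ 4 friction
times of their γ = 2 ps⁻¹ ground truth so the truncation bias (1.8%) is
well inside the 10% recovery tolerance. An MSD/Einstein estimator exists
in the tests only, as an independent cross-check of the VACF route.

**Rotational relaxation.** The dipole ACF averages û(t₀)·û(t₀+t) over
molecules and sliding origins and is normalised to 1 at zero lag. Water
dipoles are unit vectors along the H–O–H bisector (geometric, force-field
agnostic; hydrogens taken minimum-image relative to their oxygen so
boundary-straddling waters behave like their unwrapped image). Libration
removal drops lags below 2 ps (configurable), restarts the lag grid and
renormalises; a pure exponential is invariant under this operation.

Fits minimise least squares of C(t) = exp(−(t/τ)^β) with bounds τ > 0,
0 < β ≤ 1; β free by default, β ≡ 1 for the protein fit. Initialisation:
τ₀ at the first lag where C < 1/e (else the last lag), β₀ = 0.9, with two
fallback starts before declaring non-convergence. β at its upper bound is
reported as 1.0 and means single-exponential (homogeneous) relaxation;
β < 1 signals heterogeneous relaxation.

**Protein dipole.** μ(t) = Σ_i q_i (r_i − r_COM) over residues, with
r_i the residue Cα (centroid fallback), q_i the integer formal charge
plus +1/−1 termini, and a mass-weighted COM — making μ independent of the
coordinate origin even though the charges need not sum to zero. The ACF
of the unit dipole is fitted with β pinned at 1 (an exponential decay);
a stretched fit is available behind a flag because the operative protocol
and its figure caption disagree on this point.

**Geometry.** Rg is mass-weighted about the selection COM; Ree is the
Cα(1)–Cα(140) distance on plain coordinates (the chain is assumed whole —
its end-to-end vector may legitimately exceed half a box edge); RMSD uses
Kabsch superposition via SVD with a determinant correction against
improper rotations.

## Statistics

One-way ANOVA reports F = MS_between/MS_within and
p = 1 − F_CDF(F; k−1, N−k). The within-group degrees of freedom N − k
(392 for the reference 8×50 design) is exposed in JSON under the key
`df_total`, preserving the analysed protocol's (non-standard) name for
it. Zero within-group variance with unequal means yields p = 0 with a
degeneracy flag. The implementation delegates to `scipy.stats.f_oneway`;
the test suite checks it against an independent sum-of-squares
decomposition to 1e-10 and verifies null-p uniformity by KS test.

Per-residue slopes regress D on concentration over all replicate rows
(OLS); the slope t-test is the primary p-value, with a companion
concentration-group ANOVA p, because a slope claim and a group-difference
claim are different tests and the protocol conflates them. No multiple-
testing correction is applied across the 140 residues by default
(fidelity to the analysed protocol); a Benjamini–Hochberg column is
available. Moving averages are trailing with period 10 by default, with
partial leading windows flagged. Concentration trends use weighted least
squares (1/sd²) when dispersions are available. The windows entering
these statistics are treated as independent replicates, as in the
analysed protocol; no autocorrelation-aware inference is attempted.

## Synthetic ground truth

The generators are pure functions of their specs, seeds included.

* **OU / Langevin** velocities use the exact discretisation
  v(t+Δt) = v e^{−γΔt} + ξ, ξ ~ N(0, kT/m (1−e^{−2γΔt})), started
  stationary, so C_v(t) = kT/m · e^{−γt} holds at any Δt and
  D = kT/(mγ) exactly. Positions are forward-integrated and wrapped.
* **Rotational diffusion** applies Gaussian tangent-plane kicks of
  variance 2 D_r Δt per axis with renormalisation (unit norm preserved to
  1e-12), valid for D_r Δt < 0.05, giving C₁(t) → e^{−2 D_r t}, i.e.
  τ = 1/(2 D_r), β = 1. Initial orientations are uniform or aligned.
* **Two-population systems** place a static probe at the box centre,
  "shell" particles uniformly inside the probe radius and "bulk" outside,
  each population an independent OU process with its own γ and kT/m; the
  prescribed retardation is D_bulk/D_shell. This emulates the *selection
  and windowing structure* of shell-vs-bulk water analysis, not water's
  interactions: there is no exchange between populations, no structured
  g(r), and no coupling to the probe.
* **Order-parameter configurations**: diamond-cubic lattice (8m³ sites,
  every site q = 1 under PBC), uniform ideal gas (mean q = 0), and
  isolated square-planar clusters (centres q = 0.5).
* **Grouped replicates** are Gaussian draws around per-level means for
  the ANOVA/regression layer.

Passing recovery tests therefore demonstrates the *estimators* are
correct and calibrated on processes with known answers; they do not
demonstrate anything about real water structure, hydrogen-bond networks,
or force-field physics, which enter only through real trajectories.

## Problem sizes and study shape

`simulate_study` defaults to the reference design — 8 concentration
levels × 50 replicate windows — which is what gives ANOVA df = (7, 392).
Its per-window defaults (500 particles per population, 400 steps of
0.01 ps, probe radius 12 Å in a 60 Å box, 100 dipoles) are chosen so
that a single window estimates D to a few percent and a 4-level × 4-window
study resolves retardation 2.5 and the prescribed slope signs; the test
and acceptance suites run that reduced 4×4 shape at three seeds as the
package's standard desk-scale configuration. Default pseudo-concentration
trends: shell D rising at +0.1 Å²/ps per M from D_shell = 0.2 Å²/ps
(retardation 2.5 against bulk 0.5 Å²/ps), τ falling at −0.3 ps/M from
1.2 ps — slopes whose signs mirror the opposing shell/bulk trends the
protocol was built to detect, at magnitudes a 4-point design can resolve.

## Known limitations

* No triclinic boxes, no binary/compressed trajectory formats.
* The two-population generator has no shell↔bulk exchange, so it cannot
  probe selection-leakage effects of long windows.
* Protein dipole charges are integer formal charges at pH 7; no
  force-field partial charges or polarisation.
* H-bond donor detection is geometric and will misclassify exotic
  protonation states.
* The statistical layer treats windows as independent; overlapping-origin
  correlations inside a window are absorbed into the reported sd, not
  modelled.
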