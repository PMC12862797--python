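"""Rotational relaxation: dipole ACF with a stretched-exponential fit.

A sphere-diffusion ensemble with D_r = 0.1 ps⁻¹ has the closed-form
rank-1 relaxation C(t) = exp(-2 D_r t), i.e. τ = 5 ps and β = 1. The
libration-removal step (truncate the first 2 ps, renormalise) leaves a
pure exponential unchanged — demonstrated below.
"""

from hydrashell import (
    RotDiffSpec,
    dipole_dacf,
    fit_stretched_exponential,
    gen_rotational_diffusion,
    truncate_renormalize,
)

spec = RotDiffSpec(n_dipoles=1500, D_r=0.1, dt=0.05, n_steps=900, seed=3)
dip = gen_rotational_diffusion(spec)
acf = dipole_dacf(dip, window=15.0)

fit_raw = fit_stretched_exponential(acf)
fit_cut = fit_stretched_exponential(truncate_renormalize(acf, 2.0))

print(f"raw fit:       tau = {fit_raw.tau:.2f} ps, beta = "
      f"{fit_raw.beta:.3f}, R² = {fit_raw.r_squared:.5f}")
print(f"2 ps truncated: tau = {fit_cut.tau:.2f} ps, beta = "
      f"{fit_cut.beta:.3f}")
print(f"truth: tau = {spec.tau:.2f} ps, beta = 1 (single-exponential)")
print("-> beta at the upper bound 1 means homogeneous relaxation; "
      "truncation barely moves tau because the decay is memoryless.")
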