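"""Fit the nonlinear influence model to a simulated cultivar panel.

Builds a small synthetic panel (markers, kinship, major genes), generates
bivariate phenotypes in which the phenological trait nonlinearly influences
the second trait, fits the spline structural model by MCMC, and prints the
WAIC decomposition plus the posterior influence trajectory at a few
phenology values.
"""

import numpy as np

import splinesem as ss
from splinesem.sampler import MCMCConfig

fx = ss.simulate_fixture(n_lines=80, n_markers=400, seed=1)
truth = ss.draw_true_params(fx, scheme=ss.SimScheme("nonlinear"), seed=1)
kv = ss.reference_knots(truth, fx)
data, truth = ss.simulate_dataset(truth, fx, kv, seed=2)

samples = ss.run_chain(
    data, ss.ModelSpec("nse"),
    MCMCConfig(n_iter=12_000, burn_in=3_000, thin=10, seed=3),
)
fit = ss.compute_waic(samples)
print(f"mean log-likelihood: {fit.mean_loglik:.2f}")
print(f"lppd: {fit.lppd:.2f}  p_waic: {fit.p_waic:.2f}  WAIC: {fit.waic:.2f}")
print(f"weight acceptance rates: {np.round(samples.acceptance, 3)}")

traj = ss.summarize_trajectory(samples, grid_size=5)
print("\ninfluence L(y) by centered phenology value (cm/day):")
for g, m, lo, hi in zip(traj.grid, traj.mean_L, traj.q025_L, traj.q975_L):
    print(f"  y = {g:7.1f} d   L = {m:5.2f}  [{lo:5.2f}, {hi:5.2f}]")
print(
    "\nA positive L at negative (early) phenology means early lines have"
    "\ntheir second trait reduced by the influence; the 95% band shows"
    "\nwhere the trajectory is resolved by the data."
)
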