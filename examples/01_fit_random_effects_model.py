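"""Fit the two-level random-effects model to a simulated multi-ensemble set.

Simulates 8 ensembles of 6 conformations each (n = 20 Cα atoms) from the
hierarchical model Y_ij = M + Z_i + E_ij, hides every conformation behind a
random rigid motion, and fits by EM.  The fit recovers the transforms, the
population mean M̂, and the inter-/intra-ensemble covariances Ŵ and Σ̂.
"""

import numpy as np

from multisup import SimulationSpec, generate, make_truth, mae_sqrt_diag
from multisup.pca import align_to_reference
from multisup.rem import REMConfig, rem_fit

M, W_true, Sigma_true = make_truth(n=20, style="low_rank_plus_diag",
                                   scale=0.5, rank=2, seed=1)
es, truth = generate(SimulationSpec(n=20, nu=8, m=6, M_true=M,
                                    W_true=W_true, Sigma_true=Sigma_true, seed=7))

fit = rem_fit(es, REMConfig(tol=1e-8, max_iter=300))
print(f"EM iterations: {fit.n_iter}  converged: {fit.converged}")
print(f"log-likelihood: first {fit.loglik_trace[0]:.1f} -> last {fit.loglik_trace[-1]:.1f}"
      " (non-decreasing by construction)")

# compare to the ground truth: rotate into its frame, then fix the rigid
# gauge (covariances from superposition are only defined modulo the six
# rigid-motion directions, so comparisons happen in one declared gauge)
from multisup.simulate import weighted_gauge_project

_, (W_hat, Sigma_hat), _ = align_to_reference(fit.M_hat, M, [fit.W_hat, fit.Sigma_hat])
w = 1.0 / np.diagonal(Sigma_true).reshape(-1, 3).mean(axis=1)
W_hat = weighted_gauge_project(W_hat, M, w)
Sigma_hat = weighted_gauge_project(Sigma_hat, M, w)
print(f"mean per-coordinate sd, truth W: {np.mean(np.sqrt(np.diag(W_true))):.3f} A, "
      f"fitted: {np.mean(np.sqrt(np.diag(W_hat))):.3f} A")
print(f"MAE of sd  W: {mae_sqrt_diag(W_hat, W_true):.3f} A   "
      f"Sigma: {mae_sqrt_diag(Sigma_hat, Sigma_true):.3f} A")
print("(errors well below the 0.5 A signal: the per-atom variability profile "
      "is recovered from 48 structures)")
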