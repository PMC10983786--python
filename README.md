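# multisup — multilevel superposition of protein conformational ensembles

Comparative structural biology increasingly works with *groups* of
structures: all X-ray chains of each enzyme in a family, the NMR bundles and
crystal forms of one protein, clusters of predicted models.  Interpreting
the conformational variability in such data requires answering two distinct
questions — how do the groups differ from each other, and what variability
do all groups share once those differences are adjusted out?  `multisup`
answers both with a single statistical model, for structural biologists and
method developers who want covariance-level (essential-dynamics style)
analysis of experimentally determined ensembles rather than MD trajectories.

## Model

Each observed Cα coordinate matrix X_ij (member j of ensemble i, n atoms) is
a rigidly displaced copy of a latent structure following a two-level
random-effects model:

    Y_ij = (X_ij − 1_n t_ijᵀ) R_ij = M + Z_i + E_ij
    vec(Z_iᵀ) ~ N(0, W),   vec(E_ijᵀ) ~ N(0, Σ)

M is the population mean structure; W (3n×3n) is the **inter-ensemble**
covariance — systematic differences between groups; Σ (3n×3n) is the
**intra-ensemble** covariance — anisotropic, heteroscedastic variability
shared across groups.  Superposition (t_ij, R_ij), M, W and Σ are estimated
jointly by maximum likelihood via a generalized EM algorithm, with the
ensemble deviations Z_i handled by empirical-Bayes shrinkage — small
ensembles borrow strength from the rest, which is precisely the regime of
X-ray data (a handful of chains per condition).  Two-stage (TS/IWLS,
TS/OLS) and single-pooled-ensemble (SPE, Δ ≈ W + Σ) baselines, and the
heteroscedasticity-aware IWLS superposition they build on, are included.
Principal component analysis of Ŵ and Σ̂ then yields scores, per-residue
displacement profiles and extreme structures for interpretation.

## Worked example

```python
from multisup import SimulationSpec, generate, make_truth, mae_sqrt_diag
from multisup.pca import align_to_reference
from multisup.rem import REMConfig, rem_fit
from multisup.simulate import weighted_gauge_project
import numpy as np

M, W_true, Sigma_true = make_truth(n=20, style="low_rank_plus_diag",
                                   scale=0.5, rank=2, seed=1)
es, truth = generate(SimulationSpec(n=20, nu=8, m=6, M_true=M,
                                    W_true=W_true, Sigma_true=Sigma_true, seed=7))
fit = rem_fit(es, REMConfig(tol=1e-8, max_iter=300))

_, (W_hat, Sigma_hat), _ = align_to_reference(fit.M_hat, M,
                                              [fit.W_hat, fit.Sigma_hat])
w = 1.0 / np.diagonal(Sigma_true).reshape(-1, 3).mean(axis=1)
Sigma_hat = weighted_gauge_project(Sigma_hat, M, w)
print(fit.n_iter, mae_sqrt_diag(Sigma_hat, Sigma_true))
```

Running `python examples/01_fit_random_effects_model.py` (this example with
reporting) prints:

```
EM iterations: 300  converged: False
log-likelihood: first 5672.4 -> last 5702.6 (non-decreasing by construction)
mean per-coordinate sd, truth W: 0.500 A, fitted: 0.390 A
MAE of sd  W: 0.130 A   Sigma: 0.034 A
(errors well below the 0.5 A signal: the per-atom variability profile is
recovered from 48 structures)
```

Forty-eight simulated structures in eight ensembles suffice to recover the
per-atom standard-deviation profile of the shared variability Σ to 0.03 Å
against a 0.5 Å signal; the inter-ensemble profile W, estimated from only
eight ensemble deviations, is correspondingly rougher.  The other scripts in
`examples/` demonstrate estimator comparison at small ensemble sizes, PCA
interpretation of a fitted hinge motion (scores, displacement profile,
extreme structures), and building a complete-case dataset from PDB files.

A thin command line mirrors the library for scripted runs:

```sh
multisup simulate --n 20 --nu 8 --m 6 --out-dir sim/
multisup fit sim/dataset.tsv --method rem --out-dir fit/
multisup pca fit/ sim/dataset.tsv --which Sigma --k 2 --out-dir pca/
```

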