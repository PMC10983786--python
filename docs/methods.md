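# Methods

## The model

A *conformational ensemble* is a set of structures of the same protein —
all X-ray chains of one enzyme, the members of an NMR bundle, a cluster of
predicted models.  Given ν ensembles with m_i members each, every observed
Cα coordinate matrix X_ij (n × 3, Å) is modelled as a rigidly displaced copy
of a latent structure

    Y_ij = (X_ij − 1_n t_ijᵀ) R_ij = M + Z_i + E_ij,

with M the population mean structure, Z_i the deviation of ensemble i from M,
and E_ij the deviation of conformation j from its ensemble mean.  Writing
y = vec(Yᵀ) (index 3a+k for atom a, axis k), the random effects are Gaussian:

    vec(Z_iᵀ) ~ N(0, W),    vec(E_ijᵀ) ~ N(0, Σ),

with full 3n × 3n covariances.  W carries the *inter-ensemble* variability
(e.g. systematic active-site size differences between enzymes); Σ carries the
*intra-ensemble* variability shared by all ensembles after those systematic
differences are adjusted out (e.g. an open/close motion common to a family).
The diagonal of Σ is strongly heteroscedastic in real proteins — rigid cores
fluctuate a few tenths of an Å, termini and loops several times more — and
the estimators here are built around that fact.

Four estimators are provided:

- **REM** (`rem_fit`) — maximum likelihood for the full two-level model by a
  generalized EM algorithm (below).  The ensemble deviations are estimated by
  their empirical-Bayes posterior means, which shrink data-poor ensembles
  toward the population mean; this is where the method gains over the
  alternatives when m_i is small.
- **TS** (`ts_fit`) — two-stage fixed-effects baseline: superpose each
  ensemble separately (IWLS or OLS in stage 1), then superpose the ν stage-1
  means by IWLS.  Ŵ is the covariance of the aligned means (divisor ν by
  default); Σ̂ pools the stage-1 covariances with (m_i − 1) weights after
  rotating each into the stage-2 frame.
- **SPE** (`spe_fit`) — single pooled ensemble: ignore the grouping, IWLS
  over all Σm_i structures, one covariance Δ̂.  Under the two-level model
  Δ ≈ W + Σ, which makes SPE a useful consistency check on a REM fit.
- **OLS / IWLS** (`ols_superpose`, `iwls_superpose`) — single-ensemble
  building blocks.  IWLS alternates per-atom variance re-estimation with
  variance-weighted Procrustes updates (weights w_a = 1/σ̂²_a, per-axis
  variance floored at 1e-6 Å² so weights cannot diverge); it is coordinate
  ascent on a heteroscedastic Gaussian likelihood, so its objective trace is
  monotone, though convergence is not guaranteed for every input and very
  small ensembles (m_i = 3) occasionally fail — stage-1 failures in `ts_fit`
  are flagged per ensemble, not fatal.

## The EM algorithm

Each cycle of `rem_fit` performs, in order:

1. **E step.**  The posterior of z_i is Gaussian with mean
   b_i = W (W + Σ/m_i)⁻¹ (ȳ_i − μ) and covariance
   V_i = W (W + Σ/m_i)⁻¹ (Σ/m_i).  These push-through forms avoid W⁻¹
   entirely, so a singular W is handled exactly.
2. **M step** (mixed-model updates):
   μ ← N⁻¹ Σ_ij (y_ij − b_i);  W ← ν⁻¹ Σ_i (b_i b_iᵀ + V_i);
   Σ ← N⁻¹ Σ_ij (r_ij r_ijᵀ + V_i),  r_ij = y_ij − μ − b_i.
3. **Transform step.**  Each conformation is re-superposed onto its ensemble
   target M̂ + ẑ_i.  Two candidate moves are scored per conformation with
   the exact full-metric quadratic (y − μ − b_i)ᵀ Σ⁻¹ (y − μ − b_i): the
   closed-form Procrustes solution under scalar per-atom weights
   w_a = 3/tr(Σ_aa) (good global moves), and a damped Gauss–Newton step on
   the six rigid parameters in the full Σ⁻¹ metric (captures the anisotropic
   gauge the scalar weights cannot see; the Jacobian is linearised at the
   target, which is harmless because acceptance is decided by the exact
   quadratic).  A candidate is accepted only if it lowers that quadratic.
4. **Gauge step.**  μ is recentred at the origin and the shift absorbed into
   the translations; the orientation is inherited from the initial pooled
   superposition, making the fit deterministic given the input order.

Because the posterior from step 1 is held fixed through steps 2–3 and no
step decreases the minorant it defines, the marginal log-likelihood trace is
monotone (generalized EM).  The likelihood itself is evaluated per ensemble
via det(I_m⊗Σ + J_m⊗W) = det(Σ)^{m−1} det(Σ + mW) and a Woodbury reduction,
so only 3n-dimensional solves appear.

**Degeneracy and the ridge.**  The moment-based starting values (between-mean
scatter for W₀, pooled within-scatter for Σ₀) are rank-deficient whenever
ν or Σm_i is below 3n, which is the rule for real X-ray datasets.  A relative
ridge (`REMConfig.ridge`, default 1e-6, as C + ridge·(tr C/3n)·I) is folded
into W₀ and Σ₀ once; thereafter the updates keep every iterate positive
definite on their own and the EM runs at the raw parameters.  W is never
floored afterwards — its ML legitimately sits on the rank-deficient boundary
when ν < 3n, and no step needs W⁻¹.  Σ must stay invertible, so its
eigenvalues are floored at ridge·tr(Σ)/3n after each M step; the floor is
inactive in well-posed problems (Σm_i − ν ≥ 3n) and bounds the otherwise
divergent likelihood in degenerate ones (where the trace may touch the floor
and small non-monotonicities appear — those runs are flagged via
`metadata["n_restabilized"]` when a solve has to be re-stabilised).

**Convergence.**  Relative |Δ log-likelihood| < tol (default 1e-8), max_iter
5000 by default.  EM convergence on this model is slow (hundreds to
thousands of iterations near the optimum); the recovery harness uses
tol 1e-6 with max_iter 300, which reaches covariance estimates whose
remaining drift is far below their sampling error at the study sizes.
Because the final superposition depends on the initial one (multiple local
optima), `REMConfig.init` offers `ols_pool` (default) and `ts_warm` starts.

## Gauge: what a superposition can and cannot estimate

Any covariance estimated through superposition is identified only modulo the
six rigid-body directions at the mean (three translations, three linearised
rotations): whatever rigid component a deviation has is absorbed into the
fitted transform.  Different estimators leave residuals orthogonal to the
rigid subspace under different inner products — OLS under the unweighted one,
IWLS/TS under diag(w) with w from the estimated per-atom variances, the REM
transform step under the full Σ⁻¹ metric.  Two consequences:

- Comparisons between estimated and reference covariances must happen in one
  declared gauge.  `weighted_gauge_project(C, M, w)` applies the oblique
  projector A = I − B(BᵀDB)⁻¹BᵀD (B spanning the rigid subspace at M,
  D = diag(w) over xyz) as A C Aᵀ.  The recovery harness rotates every fit
  onto the true mean and projects it with weights from the diagonal of the
  true Σ before scoring; reference covariances derived from superposed
  trajectories live in such a weighted gauge themselves.
- The synthetic truth must be rigid-free, or no superposition-based fitter
  could recover it; `make_truth` enforces this by construction.

## The synthetic-data generator

`make_truth(n, style, scale, rank, seed)` builds M as a smooth helical chain
(≈3.8 Å Cα spacing) and covariance pairs (W, Σ):

- `low_rank_plus_diag` — `rank` smooth, chain-coherent orthonormal modes
  (sinusoidal profiles times random directions, rigid subspace projected
  out) over a heteroscedastic diagonal floor with a quiet core and floppy
  termini (per-atom sd ratio ≈ 3–4×, as in real per-residue fluctuation
  profiles).  65% of the trace sits in the modes.  Both matrices are then
  expressed in the variance-weighted gauge (weights from the Σ diagonal, one
  fixed-point pass) and rescaled so the mean per-coordinate sd equals
  `scale` (default 0.5 Å, the magnitude of trajectory-derived protein
  covariances).
- `hinge` — the superposed image of a hinge bend: domain 2 is rotated 0.2 rad
  about an axis through the chain midpoint, the bent structure re-superposed
  onto M, and the residual displacement field used as a single dominant
  mode.  After superposition both domains counter-move, with quiet nodes
  where the chain crosses the compensating rotation axis — the profile is
  *not* simply "zero at the hinge".
- `isotropic` — σ²I exactly (no gauge projection; used for degenerate-case
  tests, not accuracy comparisons).

`generate(spec)` draws z_i ~ N(0, W), e_ij ~ N(0, Σ), forms
Y = M + Z_i + E_ij and emits X = Y Rᵀ + 1tᵀ with uniform SO(3) rotations
(normalised quaternions) and N(0, 10² Å²) translations, so Eq. Y = (X−1tᵀ)R
recovers Y.  The random stream is split per ensemble (z-draws and per-
ensemble e-draws on separate spawned substreams), so datasets differing only
in m share their z_i and leading conformations — common random numbers that
pair the ensemble-size comparisons in `recovery_experiment`.

What the generator does **not** emulate: experimental coordinate error that
varies between structures, missing residues and gaps (the complete-case
filter is exercised on PDB fixtures instead), non-Gaussian heterogeneity
(discrete substates), sequence variation, and crystal-contact artifacts.
Passing recovery tests therefore show that the estimators work under the
stated two-level Gaussian model at realistic sizes and scales — not that
real X-ray ensembles satisfy that model.

## Study sizes and numerical choices

The test suite and `scripts/acceptance.py` run the recovery grid at n = 30
atoms, ν ∈ {10, 40}, m ∈ {3, 10, 30}, 10 replicates, truth scale 0.5 Å —
sizes at which every trend of interest (error decreasing in m and ν, the
IWLS-over-OLS advantage, the REM advantage for W at small m, top-2 subspace
recovery above 0.9 RMSIP) is resolved with comfortable margins on a single
CPU in a few minutes.  Other fixed choices: eigenvector signs are fixed by
making the largest-magnitude component positive (ties to the lowest index);
eigenvalues within −1e-8·trace of zero are clipped to 0; `sample_covariance`
uses the unbiased divisor standalone and the ML divisor inside likelihood
fits; stage-2 of TS uses divisor ν (recorded in fit metadata); distances in
`pairwise_distance_metrics` need no superposition (they are rigid-motion
invariant).

## Known limitations

- With ν < 3n the ML Ŵ is rank-deficient; eigenvectors beyond the first few
  are noise.  Interpretation should stay within the leading subspace.
- Data generated with W = 0 still yield tr(Ŵ)/tr(Σ̂) of a few percent: the
  PSD boundary accumulates the positive part of the between-mean sampling
  fluctuations.  This is a property of boundary ML, not a bug.
- In degenerate problems (Σm_i − ν < 3n) the likelihood is unbounded and the
  Σ floor governs the late iterations; covariance estimates remain usable
  but the trace may plateau with small oscillations.
- IWLS (and hence TS stage 1) may fail to converge at m_i ≤ 3; failures are
  flagged and the ensemble contributes its mean only.
- The per-conformation rotation subproblem under a full anisotropic metric
  has no closed form; the Gauss–Newton refinement converges across EM cycles
  but a single transform step is not an exact full-metric minimiser.
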