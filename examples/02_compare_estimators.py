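"""Compare REM, two-stage and pooled estimators on small ensembles.

The random-effects fit borrows strength across ensembles via empirical-Bayes
shrinkage, which matters most when each ensemble holds only a few structures.
This script fits the same datasets (ν = 20 ensembles of m = 3) with REM and
both two-stage variants and prints the error of the recovered inter-ensemble
standard deviations.
"""

from multisup import make_truth, recovery_experiment

M, W, Sigma = make_truth(n=20, style="low_rank_plus_diag", scale=0.5, rank=2, seed=3)
df = recovery_experiment(M, W, Sigma, nu_list=[20], m_list=[3], replicates=4,
                         methods=("rem", "ts-iwls", "ts-ols"), seed=1)

print("MAE of per-coordinate standard deviations (A), mean over 4 replicates:")
print(df.groupby("method")[["mae_W_sd", "mae_Sigma_sd"]].mean().round(4))
print()
print("Lower is better.  REM <= TS/IWLS for W at this small ensemble size;")
print("TS/OLS trails both because it ignores the per-atom variance differences")
print("when superposing (flexible termini drag the fit).")
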