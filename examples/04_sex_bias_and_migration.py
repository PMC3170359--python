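"""Sex-biased dispersal tests and Bayesian recent-migration estimation.

Simulates strictly female-biased dispersal and shows the expected signature
(lower female F_ST, negative female mAIC); then plants a known recent
migration rate between two diverged demes and recovers it with the
migrant-ancestry MCMC, comparing the posterior against the no-information
prior.
"""

import numpy as np

from volescape import (
    SimulationConfig,
    migration_prior_summary,
    run_migration_mcmc,
    sexbias_tests,
    simulate_metapopulation,
)

# --- sex-biased dispersal -------------------------------------------------
P = 5
ang = 2 * np.pi * np.arange(P) / P
coords = np.column_stack([3000 * np.cos(ang), 3000 * np.sin(ang)])
cfg = SimulationConfig(
    seed=1, n_demes=P, deme_coords=coords, deme_size=50, generations=150,
    migration="kernel", migration_model="individual",
    sigma_f=4000.0, sigma_m=1.0,  # females disperse, males stay
    n_loci=10, mu_nuc=5e-4, sample_size=20, mt_sample_size=0,
    mt_length=8, mu_mt=0,
)
table, _, _ = simulate_metapopulation(cfg)
report = sexbias_tests(table, n_perm=199, seed=2)
print("Sex-biased dispersal tests (simulated female-only dispersal):")
for stat, vals in report.stats.items():
    print(f"  {stat:5s} female {vals['female']:9.4f}  male {vals['male']:9.4f}"
          f"  p = {vals['p']:.3f}")
print("The dispersing sex shows the lower F_ST and the negative mAIC.\n")

# --- recent migration -----------------------------------------------------
m = np.array([[1.0, 0.0], [0.2, 0.8]])  # 20% of deme2 arrives from deme1
cfg = SimulationConfig(
    seed=3, n_demes=2, deme_size=60, generations=122,
    migration="matrix", migration_matrix=m, migration_onset=120,
    n_loci=10, mu_nuc=1e-3, sample_size=30, mt_sample_size=0,
    mt_length=8, mu_mt=0,
)
table2, _, truth = simulate_metapopulation(cfg)
post = run_migration_mcmc(table2, iters=12_000, burnin=4_000, thin=4, seed=4)
print("Recent migration into deme2 from deme1 (true rate 0.20):")
print(f"  posterior mean {post.mean[1, 0]:.3f}, 95% CI "
      f"[{post.ci_low[1, 0]:.3f}, {post.ci_high[1, 0]:.3f}]")
prior = migration_prior_summary(2)
print(f"  no-information reference: mean {prior['offdiagonal_mean']:.3f}, "
      f"diagonal uniform on [2/3, 1]")
print("A posterior interval well inside the prior's shows the genotypes "
      "carry real information about recent migration.")
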