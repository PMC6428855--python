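"""Recover ground-truth selection coefficients from a simulated campaign.

The estimator fits the slope of log(frequency) against round for every
sequence observed in at least three cycles and centres on the pool mean,
yielding relative per-round fitness on the natural-log scale. Ranking
accuracy is limited by per-species PCR-efficiency bias, which is
indistinguishable from tissue selection in trajectory data.
"""

from scipy.stats import spearmanr

import selexseed as sx

cfg = sx.SimConfig(n_species=1_000, rounds=10, sigma_s=0.5,
                   sequencing_depth=1_000_000, seed=11)
sim = sx.run_campaign(cfg)
trajectories = sx.build_trajectories(sim.tumour_pools)
s_hat = sx.estimate_selection_coefficients(trajectories, depth_aware=True)

truth = {s: sp.s for s, sp in sim.ground_truth.items()}
common = [s for s in s_hat if s in truth]
rho = spearmanr([truth[s] for s in common], [s_hat[s] for s in common]).statistic
print(f"estimated {len(common)}/{cfg.n_species} species")
print(f"Spearman(true s, estimated s) = {rho:.3f}")
print("(>= 0.9 indicates the per-round selection ranking is recovered; the "
      "residual gap is mostly PCR-efficiency bias confounded with selection)")
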