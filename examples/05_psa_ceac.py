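"""Probabilistic sensitivity analysis and the acceptability curve.

Samples test-performance and adherence parameters from their published
uncertainty distributions (Beta / PERT), reruns the status-quo and
CTC-only strategies per draw, and prints the cost-effectiveness
acceptability curve (CEAC): the fraction of draws in which each strategy
has the highest net monetary benefit at each willingness-to-pay.
Desk-scale sizes; the full analysis uses 5000 draws.
"""

from crcsim.pipeline import RunConfig, calibrate_group, psa_group
from crcsim.states import Group

config = RunConfig.desk(seed=3)
config.psa_draws = 40
config.psa_n = 2_000
config.calib_budget = 30
config.calib_top_k = 2

group = Group.parse("Black men")
calib_sets = calibrate_group(config, group)
result = psa_group(config, group, calib_sets)

wide = result.ceac_wide()
print("CEAC (probability each strategy is optimal):")
print(wide.loc[[10_000, 50_000, 100_000, 200_000, 500_000]].round(2))
print("\nfrontier (highest mean NMB):")
print(result.frontier.set_index("wtp").loc[[10_000, 100_000, 500_000]])

# Probabilities sum to 1 at every threshold; for Black adults the CTC-only
# strategy tends to dominate the acceptability curve, mirroring the
# adherence advantage built into its derivation.
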