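"""Compare six screening strategies and build the ICER ladder.

Runs every strategy on one seed-aligned cohort (common random numbers),
accumulates discounted costs and QALYs gained versus no screening, then
ranks strategies by cost, removes dominated ones, and chains incremental
cost-effectiveness ratios (ICERs).
"""

from crcsim import build_icer_ladder, make_truth
from crcsim.scenario import STRATEGY_ORDER

truth = make_truth(seed=1, group="Black women")
scenario = truth.scenario()

outcomes = scenario.outcomes_frame(STRATEGY_ORDER, n=20_000, seed=11)
print(outcomes[["strategy", "crc_cases_per_1000", "qalyg_per_1000",
                "cost_per_1000_million_usd"]].round(2).to_string(index=False))

ladder = build_icer_ladder(outcomes[["strategy", "cost", "qalyg"]])
print("\nICER ladder (ascending cost):")
print(ladder.table.round(2).to_string(index=False))
if ladder.dominant:
    print(f"\ndominant strategy (more QALYG at lower cost than all others): {ladder.dominant}")
print(f"cost-effective at $100,000/QALYG: {ladder.cost_effective(100_000)}")

# Strategies above the frontier are 'dominated' (a cheaper strategy gains
# more QALYs) or 'extended-dominated' (beaten by a mix of two neighbours);
# the ICER column reads $ per QALY gained between consecutive frontier rows.
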