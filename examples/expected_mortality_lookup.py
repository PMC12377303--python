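"""Life-table lookups and observed-vs-expected death counts.

Shows the expected (general-population) hazard for a few person-moments,
then computes the O/E ratio on a simulated cohort with zero excess hazard:
such a cohort experiences exactly general-population mortality, so O/E
should be close to 1.
"""

from exhazard import (
    SimulationConfig,
    expand_cohort,
    expected_deaths,
    make_toy_lifetable,
    simulate_cohort,
)

table = make_toy_lifetable()
print("expected hazard (deaths per person-year):")
for sex, age in [("female", 30), ("male", 30), ("female", 65), ("male", 65)]:
    h = table.lookup_hazard(sex, "White", 2010, age)
    print(f"  {sex:>6}, age {age}: {h:.5f}")

config = SimulationConfig(
    n_candidates=20_000, seed=2, excess_rates=(0.0,) * 6
)
result = simulate_cohort(config, table)
persontime = expand_cohort(result.cohort, table)
tot = expected_deaths(persontime)
print(
    f"\nzero-excess cohort: O = {tot['O'].iloc[0]}, "
    f"E = {tot['E'].iloc[0]:.1f}, "
    f"O/E = {tot['O'].iloc[0] / tot['E'].iloc[0]:.3f} (expect ~1)"
)
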