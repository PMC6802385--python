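"""Sex differences in decoded behavior: time budgets and transitions.

Uses the published sex x state allocation (dive counts, cumulative
seconds) to rebuild the time-budget table and chi-square test, and a
fitted model to report per-sex transition matrices.
"""

import numpy as np

import divehmm
from divehmm import srkw
from divehmm.analysis import allocation_summary, chisq_independence

# rebuild the allocation from per-dive records
states, durations, sexes = [], [], []
for sex in ("F", "M"):
    for s in range(5):
        n = srkw.ALLOCATION_COUNTS[sex][s]
        states += [s + 1] * n
        durations += [srkw.ALLOCATION_SECONDS[sex][s] / n] * n
        sexes += [sex] * n
alloc = allocation_summary(np.array(states), np.array(durations),
                           np.array(sexes))
print(alloc.table.to_string(index=False))

chi = chisq_independence(alloc.seconds_matrix().to_numpy())
print(f"\nchi-square on cumulative seconds: {chi.statistic:.1f} "
      f"(df {chi.df}, p {chi.p:.2g})")

# The female column shows 1324 dives with 42.1% of sampled time in the
# intermediate state; the chi-square (~7883, df 4) rejects identical
# male/female time budgets decisively.

cfg = srkw.reference_config(seed=3, dives_per_deployment=(150, 200))
table, _ = divehmm.generate_dive_dataset(cfg, srkw.reference_emissions())
fit = divehmm.em_fit(table, 5, "sex", n_restarts=1, max_iter=150,
                     tol=1e-4, seed=3)
mats = divehmm.transition_report(divehmm.canonical_relabel(fit))
np.set_printoptions(precision=2, suppress=True)
print("\nfitted female transition matrix (canonical state order):")
print(mats["F"])
print("male:")
print(mats["M"])
# Rows are origin states; diagonals show state persistence.
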