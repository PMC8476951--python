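"""Simulate a dual-precursor feeding experiment and detect peak pairs.

Builds a synthetic 3-tissue x (12C/13C) x (Phe/Tyr) x 3-replicate feature
table with planted ground truth, applies the standard retention-time and
fed-amino-acid filters, and runs isotopologue pair detection for each
feeding design.
"""

import dualtrace as dt
from dualtrace import benchmark as bm

config = dt.SimulationConfig(seed=1)
table, truth = dt.simulate_experiment(config)
print(f"simulated {table.n_features} features x {table.n_samples} samples")

table = dt.filter_rt_window(table)          # keep 100-1100 s elution window
table = dt.exclude_fed_precursors(table)    # drop fed Phe/Tyr masses
print(f"{table.n_features} features after RT and fed-precursor filters")

for precursor in ("Phe", "Tyr"):
    pairs = dt.find_pairs(table, precursor)
    dual = sum(g.dual_labeled for g in pairs)
    score = bm.pairing_confusion(pairs, truth, precursor, min_frac=0.05)
    print(f"{precursor}: {len(pairs)} pair groups ({dual} with >= 2 labeled "
          f"rings), sensitivity {score['sensitivity']:.2f}, "
          f"FDP {score['fdp']:.2f}")

# Each pair group ties a 12C anchor to its +6/+12/+18 isotopologues.  The
# sensitivity line says what share of planted label-incorporating features
# (labeled fraction >= 5%) the gates recovered; FDP is the share of
# detected groups that are not planted anchors.
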