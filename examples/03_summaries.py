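"""Descriptive summaries: ion-count shares, regressions and PCA.

Shows how much of the total MS signal the annotated library explains, how
much of the 13C-fed signal sits in heavy isotopologues, and how samples
separate by tissue and feeding in PCA space.
"""

import numpy as np

import dualtrace as dt

table, truth = dt.simulate_experiment(dt.SimulationConfig(seed=1))
table = dt.exclude_fed_precursors(dt.filter_rt_window(table))
pairs_phe = dt.find_pairs(table, "Phe")
pairs_tyr = dt.find_pairs(table, "Tyr")
library = dt.build_library(pairs_phe, pairs_tyr, table)

pct12 = dt.pct_total_ion_labeled(table, library)
print("share of total ion count in Phe/Tyr-derived features (12C arms):")
print(pct12.round(1).to_string())
# how much of the metabolome, by signal, traces back to the two amino acids

for precursor in ("Phe", "Tyr"):
    pct13 = dt.pct_13c_ion(table, library, precursor)
    print(f"\nshare of ion count in 13C isotopologues, {precursor}-fed:")
    print(pct13.round(1).to_string())

# log2 regression between two 13C-fed replicate samples of the same design:
# near-perfect correlation, unlike cross-design comparisons
heavy = sorted({fid for e in library
                for ids in e.all_labeled_ids().values() for fid in ids
                if fid in table.features.index})
r1, r2 = table.select_samples(tissue="leaf", precursor="Phe",
                              isotope="13C")[:2]
res = dt.log2_regression(table.features.loc[heavy, r1],
                         table.features.loc[heavy, r2])
print(f"\nlog2 regression of replicate {r2} on {r1} over heavy features: "
      f"slope {res.slope:.2f}, R^2 {res.r_squared:.3f}")

# PCA over heavy-feature intensities separates the two feeding designs
sids = table.select_samples(isotope="13C")
scores = dt.sample_pca(table, feature_ids=heavy, sample_ids=sids)
for design in ("Phe", "Tyr"):
    sub = scores.loc[[s for s in sids if f"_{design}_" in s]]
    print(f"13C-{design} samples: PC1 mean {sub['PC1'].mean():.1f}")
# opposite PC1 signs for the two designs = distinct de-novo labeling
# patterns from Phe vs Tyr
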