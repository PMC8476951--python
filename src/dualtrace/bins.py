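"""Five-bin precursor-bias classification of dual-quantified features.

Features labeled by both precursors are sorted by their dominant mol%
bias, with a significance filter on the Phe-vs-Tyr incorporation test:

====  ==========================  ==============
bin   dominant bias (mol%)        t-test
====  ==========================  ==============
bin1  [50, 60) toward either      not required
bin2  [60, 80) toward Phe         p < alpha
bin3  [60, 80) toward Tyr         p < alpha
bin4  [80, 100] toward Phe        p < alpha
bin5  [80, 100] toward Tyr        p < alpha
====  ==========================  ==============

Features with a bias >= 60 that fail the test are ``unbinned``.  The
boundaries are half-open so the bins are exhaustive and non-overlapping
over the [50, 100] bias range; a bias of exactly 60 falls in bin 2/3 and
exactly 80 in bin 4/5.  With ``require_test=False`` bins are assigned from
mol% alone (the no-filter display mode).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .feature_table import FeatureTable
from .pairing import LibraryEntry

BINS = ("bin1", "bin2", "bin3", "bin4", "bin5", "unbinned")


class BinAssignment(NamedTuple):
    bin: str
    dominant_precursor: str   # "Phe", "Tyr" or "neither"
    mol_dominant: float


def assign_bin(mol_phe: float, mol_tyr: float, p_value: float,
               alpha: float = 0.05, require_test: bool = True
               ) -> BinAssignment:
    """Assign one feature's bias to a bin.

    Raises on undefined (NaN) mol values — callers filter those first.
    A failed or missing t-test leaves biased features (>= 60 mol%)
    unbinned when ``require_test`` is on.
    """
    if np.isnan(mol_phe) or np.isnan(mol_tyr):
        raise ValidationError("mol% undefined; filter undefined records first")
    bias = max(mol_phe, mol_tyr)
    if mol_phe > mol_tyr:
        dominant = "Phe"
    elif mol_tyr > mol_phe:
        dominant = "Tyr"
    else:
        dominant = "neither"
    if bias < 60.0:
        return BinAssignment("bin1", dominant, bias)
    significant = (not require_test) or (not np.isnan(p_value)
                                         and p_value < alpha)
    if not significant:
        return BinAssignment("unbinned", dominant, bias)
    if bias < 80.0:
        return BinAssignment("bin2" if dominant == "Phe" else "bin3",
                             dominant, bias)
    return BinAssignment("bin4" if dominant == "Phe" else "bin5",
                         dominant, bias)


def assign_bins(records: pd.DataFrame, alpha: float = 0.05,
                require_test: bool = True) -> pd.DataFrame:
    """Vectorized :func:`assign_bin` over a quantification frame.

    Undefined records (``defined == False``) are dropped.  Returns one row
    per (anchor_id, tissue) with ``bin``, ``dominant_precursor``,
    ``mol_dominant`` alongside the input columns.
    """
    recs = records[records["defined"].astype(bool)].copy()
    assigned = [assign_bin(r.mol_phe, r.mol_tyr, r.p_value, alpha=alpha,
                           require_test=require_test)
                for r in recs.itertuples()]
    recs["bin"] = [a.bin for a in assigned]
    recs["dominant_precursor"] = [a.dominant_precursor for a in assigned]
    recs["mol_dominant"] = [a.mol_dominant for a in assigned]
    return recs


def bin_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Percent of labeled features per bin, per tissue.

    ``pct_of_labeled`` uses all labeled features (binned + unbinned) as the
    denominator; ``pct_of_binned`` uses only binned features.  Percentages
    over assigned + unbinned sum to 100 per tissue.
    """
    if assignments.empty:
        raise ValidationError("no assignments to summarize")
    rows = []
    for tissue, grp in assignments.groupby("tissue", sort=False):
        n_all = len(grp)
        n_binned = int((grp["bin"] != "unbinned").sum())
        for b in BINS:
            n = int((grp["bin"] == b).sum())
            rows.append({
                "tissue": tissue, "bin": b, "n": n,
                "pct_of_labeled": 100.0 * n / n_all,
                "pct_of_binned": (100.0 * n / n_binned
                                  if b != "unbinned" and n_binned
                                  else np.nan),
            })
    return pd.DataFrame(rows)


def bin_flux(assignments: pd.DataFrame, library: Sequence[LibraryEntry],
             table: FeatureTable, precursor: str) -> pd.DataFrame:
    """Percent of 13C ion signal per bin, per tissue, for one precursor.

    For each tissue, sums the 13C-isotopologue ion counts (mean over the
    13C-fed replicates of ``precursor``) of the features in each bin and
    expresses them as a percentage of the summed 13C signal over all
    library features quantified in that tissue — the aggregate flux split.
    """
    by_anchor = {e.anchor_id: e for e in library}
    rows = []
    for tissue, grp in assignments.groupby("tissue", sort=False):
        sids = table.select_samples(tissue=tissue, precursor=precursor,
                                    isotope="13C")
        signal = {}
        for r in grp.itertuples():
            entry = by_anchor.get(r.anchor_id)
            if entry is None:
                continue
            heavy = [fid for ids in entry.all_labeled_ids().values()
                     for fid in ids if fid in table.features.index]
            s = float(table.features.loc[heavy, sids].to_numpy().mean(axis=1)
                      .sum()) if heavy and sids else 0.0
            signal[r.anchor_id] = (r.bin, s)
        total = sum(s for _, s in signal.values())
        for b in BINS:
            s = sum(v for bb, v in signal.values() if bb == b)
            rows.append({"tissue": tissue, "precursor": precursor, "bin": b,
                         "pct_13c_signal": 100.0 * s / total if total else 0.0})
    return pd.DataFrame(rows)
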