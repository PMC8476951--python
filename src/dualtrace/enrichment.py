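"""Labeled-fraction and mol%-of-origin quantification.

For a detected pair group in a 13C-fed sample, the labeled fraction of the
metabolite pool is

    f = (I6 + I12 + I18) / (I0 + I6 + I12 + I18)

computed within each replicate and averaged.  When the same feature is
labeled by both fed precursors, the two fractions are normalized into
mol%-of-origin values

    mol_Phe = 100 * f_Phe / (f_Phe + f_Tyr),    mol_Tyr = 100 - mol_Phe

which compare the two amino acids' de-novo contributions directly,
independent of how much of the pool turned over during the feeding window.
A two-sided Welch t-test on the per-replicate incorporation values supplies
the significance filter used downstream by the bin classifier.

Multi-ring isotopologues contribute their raw ion counts with no
ring-multiplicity weighting, and fractions are averaged over replicates
rather than computed from summed pools (a pooled mode is available);
no multiple-testing correction is applied by default.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .feature_table import FeatureTable
from .pairing import LibraryEntry, PairGroup
from .stats import welch_p


def labeled_fraction(table: FeatureTable, anchor_id: str,
                     labeled_ids: Sequence[str],
                     sample_ids: Sequence[str],
                     pooled: bool = False
                     ) -> Tuple[float, pd.Series, int]:
    """Labeled fraction of a feature's pool within a 13C-fed sample subset.

    Returns ``(mean fraction, per-sample fractions, n_excluded)`` where
    samples with a zero total pool are excluded (and counted).  With
    ``pooled=True`` the fraction is computed from intensities summed over
    samples instead of averaged per replicate.
    """
    if not sample_ids:
        raise ValidationError("sample subset must be non-empty")
    ids = [anchor_id] + [i for i in labeled_ids if i in table.features.index]
    block = table.features.loc[ids, list(sample_ids)].to_numpy(float)
    total = block.sum(axis=0)
    labeled = block[1:].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, labeled / np.where(total > 0, total, 1.0),
                        np.nan)
    per = pd.Series(frac, index=list(sample_ids))
    valid = per.dropna()
    n_excluded = int(per.isna().sum())
    if pooled:
        mean = float(labeled.sum() / total.sum()) if total.sum() > 0 \
            else float("nan")
    else:
        mean = float(valid.mean()) if len(valid) else float("nan")
    return mean, per, n_excluded


def mol_percent(frac_phe: float, frac_tyr: float) -> Tuple[float, float]:
    """Convert a pair of labeled fractions into mol%-of-origin values.

    ``mol_percent(0.25, 0.042)`` -> (85.6..., 14.3...), i.e. ~86 mol% Phe.
    Raises when both fractions are zero (origin undefined).
    """
    for f in (frac_phe, frac_tyr):
        if not 0.0 <= f <= 1.0:
            raise ValidationError("fractions must lie in [0, 1]")
    tot = frac_phe + frac_tyr
    if tot == 0:
        raise ValidationError("mol% undefined when both fractions are zero")
    mol_phe = 100.0 * frac_phe / tot
    return mol_phe, 100.0 - mol_phe


def incorporation_test(frac_phe_reps, frac_tyr_reps) -> float:
    """Two-sided Welch t-test on per-replicate percent incorporation
    between the Phe-fed and Tyr-fed arms.  NaN with < 2 replicates."""
    a = 100.0 * np.asarray(frac_phe_reps, float)
    b = 100.0 * np.asarray(frac_tyr_reps, float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    return welch_p(a, b, alternative="two-sided")


def quantify(table: FeatureTable, library: Sequence[LibraryEntry],
             tissues: Sequence[str] | None = None,
             pooled: bool = False) -> pd.DataFrame:
    """Quantify per-feature, per-tissue incorporation from both precursors.

    For each library entry and tissue, the labeled fraction is measured in
    the 13C-Phe-fed and 13C-Tyr-fed replicates (using the union of the
    entry's isotopologue features across designs), converted to mol% where
    defined, and tested for differential incorporation.

    Returns a tidy frame with one row per (anchor_id, tissue):
    ``frac_phe, frac_tyr, mol_phe, mol_tyr, p_value, n_phe, n_tyr,
    defined``.  Rows where both fractions are zero/undefined carry
    ``defined=False`` and NaN mol values.
    """
    tissues = list(tissues) if tissues is not None else table.tissues()
    rows: List[dict] = []
    for entry in library:
        heavy_ids = sorted({fid for ids in entry.all_labeled_ids().values()
                            for fid in ids})
        for tissue in tissues:
            rec: Dict[str, object] = {"anchor_id": entry.anchor_id,
                                      "tissue": tissue}
            reps = {}
            for precursor in ("Phe", "Tyr"):
                sids = table.select_samples(tissue=tissue,
                                            precursor=precursor,
                                            isotope="13C")
                anchor = entry.anchor_ids.get(precursor, entry.anchor_id)
                if anchor not in table.features.index:
                    anchor = entry.anchor_id
                if sids and anchor in table.features.index:
                    mean, per, _ = labeled_fraction(table, anchor, heavy_ids,
                                                    sids, pooled=pooled)
                else:
                    mean, per = float("nan"), pd.Series(dtype=float)
                key = precursor.lower()
                rec[f"frac_{key}"] = mean
                rec[f"n_{key}"] = int(per.notna().sum())
                reps[precursor] = per.dropna().to_numpy()
            fp = rec["frac_phe"]
            ft = rec["frac_tyr"]
            fp0 = 0.0 if np.isnan(fp) else fp
            ft0 = 0.0 if np.isnan(ft) else ft
            if fp0 + ft0 > 0:
                rec["mol_phe"], rec["mol_tyr"] = mol_percent(fp0, ft0)
                rec["defined"] = True
            else:
                rec["mol_phe"] = rec["mol_tyr"] = float("nan")
                rec["defined"] = False
            rec["p_value"] = incorporation_test(reps["Phe"], reps["Tyr"])
            rows.append(rec)
    cols = ["anchor_id", "tissue", "frac_phe", "frac_tyr", "mol_phe",
            "mol_tyr", "p_value", "n_phe", "n_tyr", "defined"]
    return pd.DataFrame(rows, columns=cols)
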