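"""Scoring pipeline output against planted synthetic ground truth.

These helpers turn detected pairs, quantified records and bin assignments
into the recovery metrics used throughout the test suite: pairing
sensitivity and false-discovery proportion, mol% estimation error, and bin
accuracy for features planted safely away from the bin boundaries.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .pairing import PairGroup
from .simulate import GroundTruthFeature


def expected_bin(feat: GroundTruthFeature) -> str | None:
    """The bin a planted feature should land in, from its true mol%."""
    mol = feat.true_mol_phe
    if mol is None:
        return None
    bias = max(mol, 100.0 - mol)
    if bias < 60.0:
        return "bin1"
    phe = mol >= 50.0
    if bias < 80.0:
        return "bin2" if phe else "bin3"
    return "bin4" if phe else "bin5"


def bias_margin(feat: GroundTruthFeature) -> float | None:
    """Distance of the planted bias from the nearest bin boundary (60/80)."""
    mol = feat.true_mol_phe
    if mol is None:
        return None
    bias = max(mol, 100.0 - mol)
    if bias < 60.0:
        return 60.0 - bias
    if bias < 80.0:
        return min(bias - 60.0, 80.0 - bias)
    return bias - 80.0


def pairing_confusion(pairs: Sequence[PairGroup],
                      truth: Sequence[GroundTruthFeature],
                      precursor: str, min_frac: float = 0.05
                      ) -> Dict[str, float]:
    """Sensitivity and false-discovery proportion of one design's pairing.

    A planted feature counts toward the sensitivity denominator when its
    true labeled fraction for the fed precursor is at least ``min_frac``.
    A detected group is a false discovery when its anchor is not a planted
    anchor.
    """
    frac_key = "true_frac_phe" if precursor == "Phe" else "true_frac_tyr"
    anchors = {f.anchor_id for f in truth if f.anchor_id}
    detected = {g.anchor_id for g in pairs}
    eligible = [f for f in truth
                if getattr(f, frac_key) >= min_frac and f.anchor_id]
    tp = sum(f.anchor_id in detected for f in eligible)
    fp = len(detected - anchors)
    return {
        "sensitivity": tp / len(eligible) if eligible else float("nan"),
        "fdp": fp / len(detected) if detected else 0.0,
        "n_eligible": len(eligible),
        "n_detected": len(detected),
    }


def mol_errors(records: pd.DataFrame,
               truth: Sequence[GroundTruthFeature]) -> pd.Series:
    """Absolute mol%(Phe) estimation errors for quantified planted features
    (one value per feature x tissue where both are defined)."""
    true_mol = {f.anchor_id: f.true_mol_phe for f in truth
                if f.anchor_id and f.true_mol_phe is not None}
    recs = records[records["defined"].astype(bool)]
    errs = []
    for r in recs.itertuples():
        t = true_mol.get(r.anchor_id)
        if t is not None and not np.isnan(r.mol_phe):
            errs.append(abs(r.mol_phe - t))
    return pd.Series(errs, dtype=float)


def bin_accuracy(assignments: pd.DataFrame,
                 truth: Sequence[GroundTruthFeature],
                 min_margin: float = 5.0) -> Dict[str, float]:
    """Fraction of planted features assigned their expected bin.

    Restricted to features whose planted bias sits at least ``min_margin``
    mol% points from the 60/80 bin boundaries, so the score reflects
    classification rather than boundary jitter.
    """
    expected = {}
    for f in truth:
        margin = bias_margin(f)
        exp = expected_bin(f)
        if exp is not None and margin is not None and margin >= min_margin:
            expected[f.anchor_id] = exp
    sub = assignments[assignments["anchor_id"].isin(expected)]
    if sub.empty:
        return {"accuracy": float("nan"), "n": 0}
    correct = sum(r.bin == expected[r.anchor_id] for r in sub.itertuples())
    return {"accuracy": correct / len(sub), "n": len(sub)}
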