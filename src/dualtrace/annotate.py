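"""Retrospective library annotation and differential abundance testing.

Once a precursor-origin library exists, any later unlabeled experiment
(e.g. pathway mutants vs wild type) can be annotated by matching features
to library anchors on m/z and retention time, then tested for abundance
differences on log2 ion counts.  RT matching uses a looser default window
than pairing because the runs differ; an optional global RT offset absorbs
systematic drift between experiments.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError
from .feature_table import FeatureTable
from .pairing import LibraryEntry
from .stats import welch_p


def annotate(table: FeatureTable, library: Sequence[LibraryEntry],
             tol_ppm: float = 15.0, tol_rt: float = 10.0,
             rt_offset: float = 0.0) -> pd.DataFrame:
    """Match table features to library entries.

    Each table feature is matched to at most one entry: the one with the
    smallest combined normalized distance ``|dmz|/tol_mz + |drt|/tol_rt``
    among entries within both tolerances.  ``rt_offset`` is added to the
    library RT before comparison.  Returns one row per matched feature
    (``feature_id, anchor_id, origin, dual_labeled, d_ppm, d_rt``); the
    result is independent of library row order.
    """
    if tol_ppm <= 0 or tol_rt <= 0:
        raise ValidationError("tolerances must be > 0")
    lib = sorted(library, key=lambda e: (e.mz, e.rt, e.anchor_id))
    lib_mz = np.array([e.mz for e in lib])
    lib_rt = np.array([e.rt + rt_offset for e in lib])
    rows = []
    for fid, feat in table.features.iterrows():
        mz, rt = float(feat["mz"]), float(feat["rt"])
        tol_mz = tol_ppm * 1e-6 * mz
        dmz = np.abs(lib_mz - mz)
        drt = np.abs(lib_rt - rt)
        ok = (dmz <= tol_mz) & (drt <= tol_rt)
        if not ok.any():
            continue
        dist = np.where(ok, dmz / tol_mz + drt / tol_rt, np.inf)
        j = int(np.argmin(dist))
        entry = lib[j]
        rows.append({"feature_id": fid, "anchor_id": entry.anchor_id,
                     "origin": ";".join(sorted(entry.origin)),
                     "dual_labeled": entry.dual_labeled,
                     "d_ppm": 1e6 * (mz - entry.mz) / entry.mz,
                     "d_rt": rt - (entry.rt + rt_offset)})
    return pd.DataFrame(rows, columns=["feature_id", "anchor_id", "origin",
                                       "dual_labeled", "d_ppm", "d_rt"])


def differential_test(table: FeatureTable, annotation: pd.DataFrame,
                      groups: Mapping[str, Sequence[str]], wild_type: str,
                      alpha: float = 0.05, pseudocount: float = 1.0,
                      bias_context: Mapping[str, float] | None = None
                      ) -> pd.DataFrame:
    """Per-feature Welch t-tests of each genotype against wild type.

    ``groups`` maps genotype name -> sample ids; each arm needs >= 2
    replicates (violations raise).  Intensities are log2-transformed with a
    pseudocount; ``log2_fc`` is the mutant-minus-wild-type mean difference;
    ``direction`` is up/down when p < alpha, else unchanged.
    ``bias_context`` optionally attaches a signed mol% bias (positive =
    Phe-leaning) from the labeling experiment to each result row.
    """
    if wild_type not in groups:
        raise DesignError(f"wild type {wild_type!r} missing from groups")
    for g, sids in groups.items():
        if len(sids) < 2:
            raise DesignError(f"genotype {g!r} has < 2 replicates")
    wt_ids = list(groups[wild_type])
    rows: List[dict] = []
    for r in annotation.itertuples():
        fid = r.feature_id
        if fid not in table.features.index:
            continue
        vals = table.features.loc[fid]
        wt = np.log2(vals[wt_ids].to_numpy(float) + pseudocount)
        for genotype, sids in groups.items():
            if genotype == wild_type:
                continue
            mut = np.log2(vals[list(sids)].to_numpy(float) + pseudocount)
            p = welch_p(mut, wt, alternative="two-sided")
            lfc = float(mut.mean() - wt.mean())
            if not np.isnan(p) and p < alpha:
                direction = "up" if lfc > 0 else "down"
            else:
                direction = "unchanged"
            rows.append({"feature_id": fid, "anchor_id": r.anchor_id,
                         "genotype": genotype, "log2_fc": lfc, "p_value": p,
                         "direction": direction,
                         "mol_bias_context":
                             (bias_context or {}).get(r.anchor_id,
                                                      float("nan"))})
    return pd.DataFrame(rows, columns=["feature_id", "anchor_id", "genotype",
                                       "log2_fc", "p_value", "direction",
                                       "mol_bias_context"])


def partition_overlap(results_a: pd.DataFrame,
                      results_b: pd.DataFrame) -> Dict[str, int]:
    """Disjoint partition of significantly changed features by direction
    and mutant membership.

    Returns counts for ``down_a_only, down_b_only, down_both, up_a_only,
    up_b_only, up_both, opposing``; counts sum to the number of features
    significant in either mutant.  ``opposing`` holds features significant
    in both mutants with opposite directions.
    """
    def sig(df):
        changed = df[df["direction"] != "unchanged"]
        return {r.feature_id: r.direction for r in changed.itertuples()}

    a, b = sig(results_a), sig(results_b)
    counts = dict(down_a_only=0, down_b_only=0, down_both=0,
                  up_a_only=0, up_b_only=0, up_both=0, opposing=0)
    for fid in set(a) | set(b):
        da, db = a.get(fid), b.get(fid)
        if da and db:
            if da != db:
                counts["opposing"] += 1
            else:
                counts[f"{da}_both"] += 1
        elif da:
            counts[f"{da}_a_only"] += 1
        else:
            counts[f"{db}_b_only"] += 1
    return counts


# -- library serialization ---------------------------------------------------

def library_to_frame(library: Sequence[LibraryEntry]) -> pd.DataFrame:
    rows = []
    for e in library:
        rows.append({
            "anchor_id": e.anchor_id, "mz": e.mz, "rt": e.rt,
            "origin": ";".join(sorted(e.origin)),
            "dual_labeled": e.dual_labeled,
            "labeled_ids": "|".join(
                f"{prec}:" + ";".join(f"{k}:{v}"
                                      for k, v in sorted(ids.items()))
                for prec, ids in sorted(e.labeled_ids.items())),
        })
    return pd.DataFrame(rows)


def write_library(library: Sequence[LibraryEntry], path) -> None:
    library_to_frame(library).to_csv(path, index=False)


def read_library(path) -> List[LibraryEntry]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        labeled: Dict[str, Dict[int, str]] = {}
        if isinstance(r.labeled_ids, str) and r.labeled_ids:
            for chunk in r.labeled_ids.split("|"):
                prec, _, rest = chunk.partition(":")
                ids = {}
                for item in rest.split(";"):
                    if item:
                        k, _, v = item.partition(":")
                        ids[int(k)] = v
                labeled[prec] = ids
        out.append(LibraryEntry(r.anchor_id, float(r.mz), float(r.rt),
                                set(str(r.origin).split(";")),
                                labeled_ids=labeled,
                                dual_labeled=bool(r.dual_labeled)))
    return out
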