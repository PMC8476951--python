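"""Isotopologue peak-pair detection and cross-precursor library building.

A metabolite feature that incorporates ``n`` ring-13C6 labeled phenyl rings
appears in a feature table as a co-eluting partner of its natural-abundance
(12C) anchor, shifted by ``n * 6 * 1.0033548`` Th.  Candidate pairs are
gated three ways:

1. mass shift within a ppm tolerance (with an absolute floor);
2. co-elution within an RT tolerance;
3. enrichment of the heavy feature in 13C-fed relative to 12C-fed samples
   (fold-change floor plus a one-sided Welch t-test), which separates real
   incorporation from gap-filling artifacts and co-chromatographing ions.

Groups sharing an unlabeled anchor are merged across ``n`` into a single
:class:`PairGroup`.  Because the +6 member of a multi-ring group is itself
six 13C masses below the +12 member, it would anchor a spurious nested
group; groups whose anchor is a labeled member of another group are
suppressed (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set

import numpy as np

from .constants import RING_SHIFT
from .errors import DesignError, ValidationError
from .feature_table import FeatureTable
from .stats import welch_p


@dataclass
class PairingParams:
    """Gates for isotopologue pair detection.

    The m/z tolerance mirrors the upstream peak-picking tolerance (15 ppm)
    with a 0.005 Th floor for light ions; the RT window assumes the table
    is already chromatographically aligned.  ``min_fold`` and ``alpha``
    gate the enrichment of the heavy feature in 13C-fed samples;
    ``require_absent`` additionally demands zero mean heavy signal in the
    12C-fed arm.  ``test=False`` disables the t-test gate.
    """

    tol_ppm: float = 15.0
    tol_mz_floor: float = 0.005
    tol_rt: float = 5.0
    min_fold: float = 2.0
    alpha: float = 0.05
    test: bool = True
    require_absent: bool = False
    max_rings: int = 3
    suppress_chains: bool = True

    def mz_tolerance(self, target_mz: float) -> float:
        return max(self.tol_ppm * 1e-6 * target_mz, self.tol_mz_floor)


@dataclass
class PairGroup:
    """An unlabeled anchor plus its detected +6n isotopologues."""

    anchor_id: str
    precursor_context: str
    labeled: Dict[int, str] = field(default_factory=dict)
    p_values: Dict[int, float] = field(default_factory=dict)
    folds: Dict[int, float] = field(default_factory=dict)
    dual_labeled: bool = False

    @property
    def ring_count(self) -> int:
        return max(self.labeled) if self.labeled else 0

    @property
    def enrichment_p(self) -> float:
        """Enrichment p-value of the lowest-n labeled member."""
        return self.p_values[min(self.p_values)] if self.p_values else np.nan

    @property
    def mean_fold_enrichment(self) -> float:
        return self.folds[min(self.folds)] if self.folds else np.nan


def _enrichment_gates(i13: np.ndarray, i12: np.ndarray,
                      params: PairingParams) -> tuple[bool, float, float]:
    """(passes, fold, p) for one candidate heavy feature."""
    m13 = float(i13.mean())
    m12 = float(i12.mean())
    if m13 <= 0:
        return False, 0.0, 1.0
    fold = np.inf if m12 == 0 else m13 / m12
    ok = fold >= params.min_fold
    if params.require_absent:
        ok = ok and m12 == 0
    p = np.nan
    if ok and params.test:
        p = welch_p(i13, i12, alternative="greater")
        ok = p < params.alpha
    return ok, fold, p


def find_pairs(table: FeatureTable, precursor: str,
               params: PairingParams | None = None) -> List[PairGroup]:
    """Detect isotopologue pair groups for one feeding design.

    Scans every feature as a potential 12C anchor and, for each
    ``n = 1..max_rings``, selects the candidate at
    ``anchor m/z + n * 6 * 1.0033548`` that passes the mass, co-elution and
    enrichment gates with the smallest combined normalized distance
    ``|dmz|/tol_mz + |drt|/tol_rt`` (ties broken by input order).

    Raises :class:`DesignError` if the design lacks a 12C or 13C arm for
    the precursor, or has fewer than two replicates per arm while the
    enrichment t-test is enabled.
    """
    params = params or PairingParams()
    ids13 = table.select_samples(precursor=precursor, isotope="13C")
    ids12 = table.select_samples(precursor=precursor, isotope="12C")
    if not ids13 or not ids12:
        raise DesignError(
            f"design lacks a 12C or 13C arm for precursor {precursor!r}")
    if params.test and (len(ids13) < 2 or len(ids12) < 2):
        raise DesignError("enrichment testing needs >= 2 replicates per arm")

    feats = table.features
    fids = np.asarray(table.feature_ids)
    mz = feats["mz"].to_numpy(float)
    rt = feats["rt"].to_numpy(float)
    i13 = feats[ids13].to_numpy(float)
    i12 = feats[ids12].to_numpy(float)
    n = len(fids)

    order = np.argsort(mz, kind="stable")
    mz_sorted = mz[order]

    # gate results are per candidate feature; cache them
    gate_cache: dict[int, tuple[bool, float, float]] = {}

    def gates(j: int) -> tuple[bool, float, float]:
        if j not in gate_cache:
            gate_cache[j] = _enrichment_gates(i13[j], i12[j], params)
        return gate_cache[j]

    groups: List[PairGroup] = []
    for i in range(n):
        labeled: Dict[int, str] = {}
        pvals: Dict[int, float] = {}
        folds: Dict[int, float] = {}
        for k in range(1, params.max_rings + 1):
            target = mz[i] + k * RING_SHIFT
            tol = params.mz_tolerance(target)
            lo = np.searchsorted(mz_sorted, target - tol, side="left")
            hi = np.searchsorted(mz_sorted, target + tol, side="right")
            best = None
            for j in order[lo:hi]:
                if j == i:
                    continue
                dmz = abs(mz[j] - target)
                drt = abs(rt[j] - rt[i])
                if dmz > tol or drt > params.tol_rt:
                    continue
                ok, fold, p = gates(j)
                if not ok:
                    continue
                dist = dmz / tol + drt / params.tol_rt
                key = (dist, j)
                if best is None or key < best[0]:
                    best = (key, j, fold, p)
            if best is not None:
                _, j, fold, p = best
                labeled[k] = str(fids[j])
                folds[k] = fold
                pvals[k] = p
        if labeled:
            groups.append(PairGroup(str(fids[i]), precursor, labeled,
                                    pvals, folds))

    if params.suppress_chains:
        labeled_members: Set[str] = set()
        for g in groups:
            labeled_members.update(g.labeled.values())
        groups = [g for g in groups if g.anchor_id not in labeled_members]
    return merge_dual_labeled(groups)


def merge_dual_labeled(pairs: Sequence[PairGroup]) -> List[PairGroup]:
    """Flag groups that incorporated two or more labeled phenyl rings
    (lignan/neolignan candidates)."""
    out = list(pairs)
    for g in out:
        g.dual_labeled = g.ring_count >= 2
    return out


@dataclass
class LibraryEntry:
    """A precursor-origin-annotated feature usable for retrospective
    matching of unlabeled experiments.

    ``anchor_ids`` / ``labeled_ids`` keep the per-design feature ids (keys
    are precursor names); ``mol_phe`` per tissue and ``bin`` per tissue are
    attached after quantification.
    """

    anchor_id: str
    mz: float
    rt: float
    origin: Set[str]
    anchor_ids: Dict[str, str] = field(default_factory=dict)
    labeled_ids: Dict[str, Dict[int, str]] = field(default_factory=dict)
    dual_labeled: bool = False
    mol_phe: Dict[str, float] = field(default_factory=dict)
    bin: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.origin:
            raise ValidationError("library entry must have a non-empty origin")

    def all_labeled_ids(self) -> Dict[int, Set[str]]:
        """Union of labeled feature ids across designs, keyed by ring count."""
        out: Dict[int, Set[str]] = {}
        for per_n in self.labeled_ids.values():
            for k, fid in per_n.items():
                out.setdefault(k, set()).add(fid)
        return out


def build_library(pairs_phe: Sequence[PairGroup],
                  pairs_tyr: Sequence[PairGroup],
                  table_phe: FeatureTable,
                  table_tyr: FeatureTable | None = None,
                  tol_ppm: float = 15.0, tol_rt: float = 5.0
                  ) -> List[LibraryEntry]:
    """Union pair groups from the two feeding designs into one library.

    Anchors are matched across designs by m/z (ppm tolerance) and RT;
    identical anchor ids (single-table designs) match exactly.  Each entry
    records which precursor(s) labeled it.
    """
    table_tyr = table_tyr if table_tyr is not None else table_phe

    def coords(table, g):
        row = table.features.loc[g.anchor_id]
        return float(row["mz"]), float(row["rt"])

    entries: List[LibraryEntry] = []
    tyr_by_id = {g.anchor_id: g for g in pairs_tyr}
    unmatched_tyr = dict(tyr_by_id)

    tyr_coords = [(g, *coords(table_tyr, g)) for g in pairs_tyr]
    for g in pairs_phe:
        mzp, rtp = coords(table_phe, g)
        match = None
        if g.anchor_id in unmatched_tyr:
            match = unmatched_tyr[g.anchor_id]
        else:
            best = None
            for gt, mzt, rtt in tyr_coords:
                if gt.anchor_id not in unmatched_tyr:
                    continue
                tol = max(tol_ppm * 1e-6 * mzp, 1e-12)
                dmz, drt = abs(mzt - mzp), abs(rtt - rtp)
                if dmz <= tol and drt <= tol_rt:
                    dist = dmz / tol + drt / tol_rt
                    if best is None or dist < best[0]:
                        best = (dist, gt)
            if best is not None:
                match = best[1]
        if match is not None:
            del unmatched_tyr[match.anchor_id]
            entries.append(LibraryEntry(
                g.anchor_id, mzp, rtp, {"Phe", "Tyr"},
                anchor_ids={"Phe": g.anchor_id, "Tyr": match.anchor_id},
                labeled_ids={"Phe": dict(g.labeled),
                             "Tyr": dict(match.labeled)},
                dual_labeled=g.dual_labeled or match.dual_labeled))
        else:
            entries.append(LibraryEntry(
                g.anchor_id, mzp, rtp, {"Phe"},
                anchor_ids={"Phe": g.anchor_id},
                labeled_ids={"Phe": dict(g.labeled)},
                dual_labeled=g.dual_labeled))
    for g in pairs_tyr:
        if g.anchor_id in unmatched_tyr:
            mzt, rtt = coords(table_tyr, g)
            entries.append(LibraryEntry(
                g.anchor_id, mzt, rtt, {"Tyr"},
                anchor_ids={"Tyr": g.anchor_id},
                labeled_ids={"Tyr": dict(g.labeled)},
                dual_labeled=g.dual_labeled))
    return entries
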