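"""Descriptive summaries: labeled ion-count shares, bias-vs-property
tables, log2 regressions and PCA over feature tables."""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .feature_table import FeatureTable
from .pairing import LibraryEntry


def pct_total_ion_labeled(table: FeatureTable,
                          library: Sequence[LibraryEntry]) -> pd.Series:
    """Percent of the total ion count carried by library-annotated 12C
    features, per tissue, within the 12C-fed samples.

    Measures how much of the metabolome (by signal) derives from the two
    aromatic amino acids.
    """
    anchor_ids = [e.anchor_id for e in library
                  if e.anchor_id in table.features.index]
    out = {}
    for tissue in table.tissues():
        sids = table.select_samples(tissue=tissue, isotope="12C")
        denom = float(table.features[sids].to_numpy().sum())
        if denom == 0:
            out[tissue] = float("nan")
            continue
        num = float(table.features.loc[anchor_ids, sids].to_numpy().sum())
        out[tissue] = 100.0 * num / denom
    return pd.Series(out, name="pct_total_ion_labeled")


def pct_13c_ion(table: FeatureTable, library: Sequence[LibraryEntry],
                precursor: str) -> pd.Series:
    """Percent of the total ion count carried by 13C isotopologues, per
    tissue, within the 13C-fed samples of one precursor."""
    heavy_ids = sorted({fid for e in library
                        for ids in e.all_labeled_ids().values()
                        for fid in ids if fid in table.features.index})
    out = {}
    for tissue in table.tissues():
        sids = table.select_samples(tissue=tissue, precursor=precursor,
                                    isotope="13C")
        denom = float(table.features[sids].to_numpy().sum())
        if denom == 0:
            out[tissue] = float("nan")
            continue
        num = float(table.features.loc[heavy_ids, sids].to_numpy().sum())
        out[tissue] = 100.0 * num / denom
    return pd.Series(out, name="pct_13c_ion")


def bias_property_table(records: pd.DataFrame,
                        table: FeatureTable) -> pd.DataFrame:
    """One row per quantified feature relating its precursor bias to its
    abundance, retention time and m/z.

    ``mol_dominant`` is the dominant precursor's mol% (>= 50);
    ``signed_bias`` is positive for Phe-dominant and negative for
    Tyr-dominant features, 50/-50 ties resolved to 'neither' with +50.
    ``intensity`` is the mean 12C-fed ion count of the anchor in the row's
    tissue.
    """
    recs = records[records["defined"].astype(bool)]
    rows = []
    for r in recs.itertuples():
        if r.mol_phe > r.mol_tyr:
            dom, bias = "Phe", r.mol_phe
        elif r.mol_tyr > r.mol_phe:
            dom, bias = "Tyr", r.mol_tyr
        else:
            dom, bias = "neither", 50.0
        sids = table.select_samples(tissue=r.tissue, isotope="12C")
        if r.anchor_id in table.features.index:
            feat = table.features.loc[r.anchor_id]
            intensity = float(feat[sids].mean()) if sids else float("nan")
            mz, rt = float(feat["mz"]), float(feat["rt"])
        else:
            intensity = mz = rt = float("nan")
        rows.append({"anchor_id": r.anchor_id, "tissue": r.tissue,
                     "dominant_precursor": dom, "mol_dominant": bias,
                     "signed_bias": -bias if dom == "Tyr" else bias,
                     "intensity": intensity, "rt": rt, "mz": mz})
    return pd.DataFrame(rows)


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    n: int


def log2_regression(x, y, pseudocount: float = 1.0) -> RegressionResult:
    """Ordinary least squares on log2-transformed intensities.

    Zeros are offset by ``pseudocount`` (added to every value for
    continuity).  Requires at least 3 points.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("regression needs >= 3 points")
    lx = np.log2(x + pseudocount)
    ly = np.log2(y + pseudocount)
    res = sps.linregress(lx, ly)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), len(x))


def pca_scores(matrix, n_components: int = 2
               ) -> tuple[np.ndarray, np.ndarray]:
    """Sample scores on the leading principal components of a (samples x
    features) matrix of log2 intensities.

    Columns are centered (not scaled); scores come from the SVD of the
    centered matrix.  Component signs are fixed so the largest-magnitude
    loading of each component is positive.  Returns ``(scores,
    explained_variance_ratio)``; a warning-free flag for rank deficiency is
    the number of non-trivial singular values, reflected in zero-variance
    trailing components.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValidationError("PCA needs a 2-D matrix with >= 3 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s ** 2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = u * s
    k = min(n_components, scores.shape[1])
    return scores[:, :k], ratio[:k]


def sample_pca(table: FeatureTable, feature_ids: Sequence[str] | None = None,
               sample_ids: Sequence[str] | None = None,
               pseudocount: float = 1.0) -> pd.DataFrame:
    """Convenience wrapper: PCA of log2 ion counts for a sample subset."""
    sids = list(sample_ids) if sample_ids is not None else table.sample_ids
    fids = list(feature_ids) if feature_ids is not None \
        else table.feature_ids
    X = np.log2(table.features.loc[fids, sids].to_numpy(float).T
                + pseudocount)
    scores, ratio = pca_scores(X)
    out = pd.DataFrame(scores, index=sids,
                       columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    out.attrs["explained_variance_ratio"] = ratio
    return out
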