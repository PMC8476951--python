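"""Feature tables, sample metadata, and the IO / filtering primitives.

The universal currency of the pipeline is a *feature table*: a wide matrix
of LC-MS features (rows, each with an m/z and a retention time) by samples
(columns of integrated ion counts), exactly the shape produced by standard
feature-detection software after peak grouping and gap filling.  A companion
metadata table keys each sample column to the experimental design
(tissue, fed precursor, isotope, replicate).

Conventions
-----------
* m/z values are negative-ionization [M-H]- values in Thomson.
* Retention times are in seconds.
* Ion counts are non-negative; missing cells are read as 0 and counted in
  the table's ``provenance["n_filled"]`` diagnostic, because upstream
  gap filling makes true zeros and small fills indistinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import default_exclusion_masses
from .errors import FormatError, ValidationError

TISSUES = ("leaf", "base", "root")
PRECURSORS = ("Phe", "Tyr")
ISOTOPES = ("12C", "13C")

#: default retention-time window (s) retained for analysis
RT_WINDOW = (100.0, 1100.0)

META_COLUMNS = ("tissue", "precursor", "isotope", "replicate")
_RESERVED = ("feature_id", "mz", "rt")


@dataclass(frozen=True)
class SampleMeta:
    """Design record for one sample column."""

    sample_id: str
    tissue: str
    precursor: str
    isotope: str
    replicate: int

    def __post_init__(self):
        if self.precursor not in PRECURSORS:
            raise ValidationError(
                f"precursor must be one of {PRECURSORS}, got {self.precursor!r}")
        if self.isotope not in ISOTOPES:
            raise ValidationError(
                f"isotope must be one of {ISOTOPES}, got {self.isotope!r}")
        if int(self.replicate) < 1:
            raise ValidationError("replicate must be a positive integer")


def _normalize_isotope(value: str) -> str:
    v = str(value).strip().upper()
    if v in ("12C", "C12", "12"):
        return "12C"
    if v in ("13C", "C13", "13"):
        return "13C"
    raise ValidationError(f"unrecognized isotope value {value!r}")


def make_feature_id(mz: float, rt: float) -> str:
    """Feature naming convention: ``M{round(mz)}T{round(rt)}``.

    ``make_feature_id(310.0935, 325)`` -> ``"M310T325"``.
    """
    if not (math.isfinite(mz) and math.isfinite(rt)):
        raise ValidationError("mz and rt must be finite")
    if mz <= 0 or rt < 0:
        raise ValidationError("require mz > 0 and rt >= 0")
    return f"M{round(float(mz))}T{round(float(rt))}"


def assign_feature_ids(mz: Sequence[float], rt: Sequence[float]) -> list[str]:
    """Deterministic ids from (mz, rt); collisions get ``_2``, ``_3``, ...
    suffixes in input order (the naming convention is lossy)."""
    seen: dict[str, int] = {}
    out = []
    for m, t in zip(mz, rt):
        fid = make_feature_id(m, t)
        n = seen.get(fid, 0) + 1
        seen[fid] = n
        out.append(fid if n == 1 else f"{fid}_{n}")
    return out


@dataclass
class FeatureTable:
    """An ordered collection of MS features with per-sample ion counts.

    Attributes
    ----------
    features : DataFrame indexed by feature_id with columns ``mz``, ``rt``
        and one intensity column per sample_id.
    samples : DataFrame indexed by sample_id with the design columns
        (``tissue``, ``precursor``, ``isotope``, ``replicate``) plus any
        extra columns (e.g. ``genotype``) carried through untouched.
    provenance : free-form metadata (instrument, polarity, diagnostics).
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    # -- accessors --------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def intensities(self) -> pd.DataFrame:
        return self.features[self.sample_ids]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def select_samples(self, tissue: str | None = None,
                       precursor: str | None = None,
                       isotope: str | None = None,
                       **extra: str) -> list[str]:
        """Sample ids matching the given design cell."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in dict(tissue=tissue, precursor=precursor,
                             isotope=isotope, **extra).items():
            if val is not None:
                if col not in self.samples.columns:
                    raise ValidationError(f"no metadata column {col!r}")
                mask &= self.samples[col] == val
        return list(self.samples.index[mask])

    def subset_features(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.features.loc[ids].copy(), self.samples.copy(),
                            dict(self.provenance))

    def tissues(self) -> list[str]:
        return list(pd.unique(self.samples["tissue"])) \
            if "tissue" in self.samples.columns else []


def validate_table(features: pd.DataFrame, samples: pd.DataFrame,
                   provenance: dict | None = None) -> FeatureTable:
    """Validate and assemble a FeatureTable.

    Enforces: positive m/z, non-negative rt and intensities, unique feature
    ids, no duplicated (mz, rt) coordinates, intensity columns exactly
    matching the metadata sample set (missing columns filled with 0 and
    counted in ``provenance["n_filled"]``; unknown columns are an error).
    """
    prov = dict(provenance or {})
    feats = features.copy()
    meta = samples.copy()

    if meta.index.name != "sample_id":
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id")
        else:
            raise FormatError("sample metadata must contain a sample_id column")
    meta.index = meta.index.astype(str)
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    if "isotope" in meta.columns:
        meta["isotope"] = [_normalize_isotope(v) for v in meta["isotope"]]
    if "precursor" in meta.columns:
        bad = set(meta["precursor"]) - set(PRECURSORS)
        if bad:
            raise ValidationError(f"unrecognized precursor values {sorted(bad)}")
    if "replicate" in meta.columns:
        meta["replicate"] = meta["replicate"].astype(int)
        if (meta["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be >= 1")

    if feats.index.name != "feature_id":
        if "feature_id" in feats.columns:
            feats = feats.set_index("feature_id")
        elif {"mz", "rt"} <= set(feats.columns):
            feats.index = pd.Index(
                assign_feature_ids(feats["mz"], feats["rt"]), name="feature_id")
        else:
            raise FormatError("feature table must contain mz and rt columns")
    feats.index = feats.index.astype(str)
    for col in ("mz", "rt"):
        if col not in feats.columns:
            raise FormatError(f"feature table missing required column {col!r}")
        feats[col] = pd.to_numeric(feats[col], errors="raise")
    if feats.index.duplicated().any():
        dup = feats.index[feats.index.duplicated()][0]
        raise ValidationError(f"duplicate feature_id {dup!r}")
    if (feats["mz"] <= 0).any():
        raise ValidationError("all m/z values must be > 0")
    if (feats["rt"] < 0).any():
        raise ValidationError("all retention times must be >= 0")
    if feats.duplicated(subset=["mz", "rt"]).any():
        row = feats[feats.duplicated(subset=["mz", "rt"])].index[0]
        raise ValidationError(f"features share identical (mz, rt): {row!r}")

    sample_cols = [c for c in feats.columns if c not in ("mz", "rt")]
    unknown = [c for c in sample_cols if c not in meta.index]
    if unknown:
        raise ValidationError(
            f"intensity columns not present in sample metadata: {unknown}")

    n_filled = 0
    for sid in meta.index:
        if sid not in feats.columns:
            feats[sid] = 0.0
            n_filled += len(feats)
    inten = feats[list(meta.index)].apply(pd.to_numeric, errors="coerce")
    bad = inten.isna() & feats[list(meta.index)].notna()
    if bad.any().any():
        raise FormatError("non-numeric intensity value in feature table")
    n_filled += int(inten.isna().sum().sum())
    inten = inten.fillna(0.0)
    if (inten.to_numpy() < 0).any():
        raise ValidationError("intensities must be non-negative")
    feats = pd.concat([feats[["mz", "rt"]], inten.astype(float)], axis=1)
    prov["n_filled"] = prov.get("n_filled", 0) + n_filled
    return FeatureTable(feats, meta, prov)


# -- IO -------------------------------------------------------------------

def read_feature_table(path, meta_path) -> FeatureTable:
    """Read a CSV feature table (rows = features, one intensity column per
    sample) plus its sample-metadata CSV, and validate both."""
    try:
        feats = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse feature table {path}: {exc}") from exc
    try:
        meta = pd.read_csv(meta_path)
    except Exception as exc:
        raise FormatError(f"cannot parse sample metadata {meta_path}: {exc}") from exc
    if "sample_id" not in meta.columns:
        raise FormatError("sample metadata must have a sample_id column")
    meta["sample_id"] = meta["sample_id"].astype(str)
    return validate_table(feats, meta, {"source": str(path)})


def write_feature_table(table: FeatureTable, path, meta_path=None) -> None:
    """Write a FeatureTable (and optionally its metadata) to CSV."""
    out = table.features.reset_index()
    out.to_csv(path, index=False)
    if meta_path is not None:
        table.samples.reset_index().to_csv(meta_path, index=False)


# -- filters --------------------------------------------------------------

def filter_rt_window(table: FeatureTable, lo: float = RT_WINDOW[0],
                     hi: float = RT_WINDOW[1]) -> FeatureTable:
    """Retain features with ``lo <= rt <= hi`` (bounds inclusive).

    The default window drops early- and late-eluting features outside the
    chromatographically informative region of the gradient.
    """
    if not lo < hi:
        raise ValidationError("require lo < hi")
    keep = table.features.index[(table.features["rt"] >= lo)
                                & (table.features["rt"] <= hi)]
    return table.subset_features(keep)


def exclude_fed_precursors(table: FeatureTable, tol_ppm: float = 15.0,
                           masses: Sequence[tuple[str, float]] | None = None
                           ) -> FeatureTable:
    """Remove features matching the [M-H]- m/z of the fed amino acids.

    By default the exclusion list holds Phe, Tyr and their ring-13C6
    isotopologues, computed from monoisotopic atomic masses; any feature
    within ``tol_ppm`` of an exclusion mass is dropped.  An empty ``masses``
    list is the identity.
    """
    if tol_ppm <= 0:
        raise ValidationError("tol_ppm must be > 0")
    if masses is None:
        masses = default_exclusion_masses()
    mz = table.features["mz"].to_numpy()
    drop = np.zeros(len(mz), dtype=bool)
    for _name, m in masses:
        drop |= np.abs(mz - m) <= tol_ppm * 1e-6 * m
    keep = table.features.index[~drop]
    return table.subset_features(keep)
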