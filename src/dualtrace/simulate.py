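"""Synthetic dual-precursor labeling experiments with planted ground truth.

The generator emulates the structure of a ring-13C6 Phe / Tyr feeding
experiment on seedlings: three tissues (leaf, base, root), two fed
precursors, 12C and 13C isotope arms, and three biological replicates —
36 samples in total.  Planted features follow the archetypes the analysis
is meant to resolve:

``unbiased``        labeled by both precursors, 50-55 mol% bias;
``phe_biased``      63-77 mol% toward Phe;
``tyr_biased``      63-77 mol% toward Tyr;
``exclusive_phe``   labeled only from Phe (benzoate/phenylacetate-like);
``exclusive_tyr``   labeled only from Tyr (dhurrin-like);
``decoy``           non-aromatic features that never incorporate label.

For a feature with ``r`` labeled phenyl rings and pool-label fraction
``f`` (the share of the metabolite pool that is de-novo synthesized from
the fed 13C precursor), rings are assumed labeled independently with
probability ``q`` solving ``1-(1-q)^r = f``, so the +6/+12/+18 isotopologue
shares are binomial in ``q`` and the total labeled share of the pool equals
``f`` exactly.  Replicate pool intensities are log-normal; integration
noise is applied per isotopologue and renormalized so the isotopologues of
a feature always sum to the replicate's pool draw (conservation).

The generator does not model natural-abundance M+1/M+2 envelopes,
chromatographic peak shapes, or detection limits; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import RING_SHIFT, default_exclusion_masses
from .errors import ValidationError
from .feature_table import (FeatureTable, assign_feature_ids, validate_table)

ARCHETYPES = ("unbiased", "phe_biased", "tyr_biased",
              "exclusive_phe", "exclusive_tyr", "decoy")

DEFAULT_N_FEATURES: Dict[str, int] = {
    "unbiased": 40,
    "phe_biased": 14,
    "tyr_biased": 6,
    "exclusive_phe": 5,
    "exclusive_tyr": 5,
    "decoy": 150,
}

# planted mol% bias ranges per archetype (dominant precursor)
_BIAS_RANGE = {
    "unbiased": (50.0, 55.0),
    "phe_biased": (63.0, 77.0),
    "tyr_biased": (63.0, 77.0),
}


@dataclass
class GroundTruthFeature:
    """One planted metabolite feature and its true labeling behavior."""

    base_mz: float
    rt: float
    ring_count: int
    true_frac_phe: float
    true_frac_tyr: float
    archetype: str
    base_intensity: Dict[str, float]
    anchor_id: str | None = None
    labeled_ids: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValidationError(f"unknown archetype {self.archetype!r}")
        decoy = self.archetype == "decoy"
        if decoy != (self.ring_count == 0):
            raise ValidationError("decoy features and only decoy features "
                                  "have ring_count 0")
        if decoy and (self.true_frac_phe or self.true_frac_tyr):
            raise ValidationError("decoys must have zero labeled fractions")
        if self.archetype == "exclusive_tyr" and self.true_frac_phe != 0:
            raise ValidationError("exclusive_tyr requires true_frac_phe = 0")
        if self.archetype == "exclusive_phe" and self.true_frac_tyr != 0:
            raise ValidationError("exclusive_phe requires true_frac_tyr = 0")
        for f in (self.true_frac_phe, self.true_frac_tyr):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("labeled fractions must lie in [0, 1]")

    @property
    def true_mol_phe(self) -> float | None:
        tot = self.true_frac_phe + self.true_frac_tyr
        if tot == 0:
            return None
        return 100.0 * self.true_frac_phe / tot


@dataclass
class SimulationConfig:
    """Study conditions for one simulated feeding experiment.

    ``intensity_cv`` is the replicate-to-replicate coefficient of variation
    of a feature's pool (biology + extraction, shared by co-eluting
    isotopologues); ``integration_cv`` is the smaller per-isotopologue peak
    integration noise that actually propagates into labeled-fraction
    estimates.  ``artifact_rate`` is the fraction of labeled features given
    a spurious small 13C-feature signal in 12C-fed samples, mimicking
    gap filling / co-chromatographing ions.
    """

    n_features: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_FEATURES))
    tissues: Tuple[str, ...] = ("leaf", "base", "root")
    replicates: int = 3
    mz_error_ppm: float = 5.0
    rt_jitter_sd: float = 2.0      # common to all isotopologues of a feature
    rt_iso_sd: float = 0.3         # extra per-isotopologue rt noise
    intensity_cv: float = 0.2
    integration_cv: float = 0.05
    labeled_frac_range: Tuple[float, float] = (0.04, 0.40)
    ring_probs: Tuple[float, ...] = (0.88, 0.10, 0.02)   # P(rings = 1, 2, 3)
    artifact_rate: float = 0.1
    artifact_size: Tuple[float, float] = (0.01, 0.05)
    mz_range: Tuple[float, float] = (120.0, 900.0)
    rt_range: Tuple[float, float] = (100.0, 1100.0)
    decoy_rt_range: Tuple[float, float] = (60.0, 1150.0)
    intensity_range: Tuple[float, float] = (1e5, 1e7)    # log-uniform
    tissue_scale: Dict[str, float] = field(
        default_factory=lambda: {"leaf": 1.0, "base": 1.0, "root": 0.5})
    treatment_effect: float = 1.0  # multiplicative 12C-pool perturbation, off
    include_fed_precursors: bool = True
    seed: int = 0

    def __post_init__(self):
        for rate in (self.artifact_rate, *self.labeled_frac_range):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates and fractions must lie in [0, 1]")
        if self.replicates < 2:
            raise ValidationError("the design needs >= 2 replicates")
        if abs(sum(self.ring_probs) - 1.0) > 1e-9:
            raise ValidationError("ring_probs must sum to 1")


def isotopologue_shares(frac: float, ring_count: int) -> np.ndarray:
    """Expected pool shares of the 0..ring_count labeled-ring isotopologues.

    Index ``k`` holds the share of molecules with exactly ``k`` labeled
    rings.  Rings are labeled independently with probability ``q`` chosen so
    the total labeled share ``1-(1-q)^r`` equals ``frac``; shares are then
    binomial(r, q).  The k=0 share is ``1-frac`` exactly.
    """
    if not 0.0 <= frac <= 1.0:
        raise ValidationError("frac must lie in [0, 1]")
    if ring_count == 0 or frac == 0.0:
        out = np.zeros(ring_count + 1)
        out[0] = 1.0
        return out
    r = ring_count
    q = 1.0 - (1.0 - frac) ** (1.0 / r)
    shares = np.array([comb(r, k) * q ** k * (1 - q) ** (r - k)
                       for k in range(r + 1)])
    shares[0] = 1.0 - frac  # exact by construction; avoid rounding drift
    return shares


def _sample_grid(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for tissue in config.tissues:
        for precursor in ("Phe", "Tyr"):
            for isotope in ("12C", "13C"):
                for rep in range(1, config.replicates + 1):
                    sid = f"{tissue}_{precursor}_{isotope}_r{rep}"
                    rows.append((sid, tissue, precursor, isotope, rep))
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "precursor",
                                       "isotope", "replicate"]
                        ).set_index("sample_id")


def draw_ground_truth(config: SimulationConfig,
                      rng: np.random.Generator) -> List[GroundTruthFeature]:
    """Draw the planted features for one experiment."""
    lo_f, hi_f = config.labeled_frac_range
    lo_i, hi_i = np.log10(config.intensity_range)
    truth: List[GroundTruthFeature] = []
    for archetype in ARCHETYPES:
        for _ in range(config.n_features.get(archetype, 0)):
            decoy = archetype == "decoy"
            ring = 0 if decoy else int(
                rng.choice((1, 2, 3), p=config.ring_probs))
            mz = float(rng.uniform(*config.mz_range))
            rt = float(rng.uniform(*(config.decoy_rt_range if decoy
                                     else config.rt_range)))
            leaf = 10.0 ** rng.uniform(lo_i, hi_i)
            base_int = {t: float(leaf * config.tissue_scale.get(t, 1.0)
                                 * rng.uniform(0.7, 1.3))
                        for t in config.tissues}
            if decoy:
                fp = ft = 0.0
            elif archetype == "exclusive_phe":
                fp, ft = float(rng.uniform(lo_f, hi_f)), 0.0
            elif archetype == "exclusive_tyr":
                fp, ft = 0.0, float(rng.uniform(lo_f, hi_f))
            else:
                bias = float(rng.uniform(*_BIAS_RANGE[archetype]))
                dom = float(rng.uniform(lo_f, hi_f))
                other = dom * (100.0 - bias) / bias
                phe_dominant = (archetype == "phe_biased"
                                or (archetype == "unbiased"
                                    and rng.random() < 0.5))
                fp, ft = (dom, other) if phe_dominant else (other, dom)
            truth.append(GroundTruthFeature(mz, rt, ring, fp, ft, archetype,
                                            base_int))
    return truth


def realize_feature_table(truth: Sequence[GroundTruthFeature],
                          config: SimulationConfig,
                          rng: np.random.Generator) -> FeatureTable:
    """Emit the observed feature table for a list of planted features.

    Mutates each truth record in place to record its emitted ``anchor_id``
    and ``labeled_ids``.
    """
    meta = _sample_grid(config)
    sample_ids = list(meta.index)
    tissue_arr = meta["tissue"].to_numpy()
    isotope_arr = meta["isotope"].to_numpy()
    precursor_arr = meta["precursor"].to_numpy()
    sig_pool = float(np.sqrt(np.log1p(config.intensity_cv ** 2)))
    sig_int = float(np.sqrt(np.log1p(config.integration_cv ** 2)))

    mz_rows: list[float] = []
    rt_rows: list[float] = []
    inten_rows: list[np.ndarray] = []
    owners: list[tuple[int, int]] = []   # (truth index, k labeled rings)

    for ti, feat in enumerate(truth):
        r = feat.ring_count
        rt_common = feat.rt + (rng.normal(0.0, config.rt_jitter_sd)
                               if config.rt_jitter_sd > 0 else 0.0)
        block = np.zeros((r + 1, len(sample_ids)))
        for si in range(len(sample_ids)):
            tissue = tissue_arr[si]
            isotope = isotope_arr[si]
            precursor = precursor_arr[si]
            pool = feat.base_intensity[tissue]
            if sig_pool > 0:
                pool *= float(np.exp(rng.normal(-0.5 * sig_pool ** 2,
                                                sig_pool)))
            if isotope == "12C" and config.treatment_effect != 1.0:
                pool *= config.treatment_effect
            if isotope == "13C":
                f = feat.true_frac_phe if precursor == "Phe" \
                    else feat.true_frac_tyr
            else:
                f = 0.0
            shares = isotopologue_shares(f, r)
            if sig_int > 0:
                w = shares * np.exp(rng.normal(0.0, sig_int, size=r + 1))
                w = np.where(shares > 0, w, 0.0)
                shares = w / w.sum()
            block[:, si] = pool * shares
        for k in range(r + 1):
            theo = feat.base_mz + k * RING_SHIFT
            eps = (rng.normal(0.0, config.mz_error_ppm * 1e-6)
                   if config.mz_error_ppm > 0 else 0.0)
            mz_rows.append(theo * (1.0 + eps))
            rt_rows.append(rt_common + (rng.normal(0.0, config.rt_iso_sd)
                                        if config.rt_iso_sd > 0 else 0.0))
            inten_rows.append(block[k])
            owners.append((ti, k))

    inten = np.array(inten_rows) if inten_rows \
        else np.zeros((0, len(sample_ids)))

    # peak-filling artifacts: spurious small 13C-feature signal in 12C samples
    artifact_rows: list[int] = []
    if config.artifact_rate > 0 and len(inten):
        mask12 = (meta["isotope"] == "12C").to_numpy()
        mask13 = ~mask12
        for row, (ti, k) in enumerate(owners):
            if k == 0:
                continue
            if rng.random() < config.artifact_rate:
                ref = inten[row, mask13].mean()
                if ref > 0:
                    u = rng.uniform(*config.artifact_size, size=mask12.sum())
                    inten[row, mask12] += u * ref
                    artifact_rows.append(row)

    # fed amino acids: abundant, early-eluting; heavy form only in the
    # matching 13C arm.  Excluded from ground truth on purpose.
    if config.include_fed_precursors:
        for (name, m), rt_aa in zip(default_exclusion_masses(),
                                    (150.0, 120.0, 150.0, 120.0)):
            heavy = name.endswith("+6")
            aa = name[:3]
            counts = np.zeros(len(sample_ids))
            for si in range(len(sample_ids)):
                fed13 = (isotope_arr[si] == "13C"
                         and precursor_arr[si] == aa)
                if heavy != fed13 and heavy:
                    continue
                if heavy or not fed13:
                    level = 5e7
                else:  # 12C form in a 13C-fed sample: residual endogenous pool
                    level = 5e6
                noise = float(np.exp(rng.normal(-0.5 * sig_pool ** 2,
                                                sig_pool))) if sig_pool > 0 \
                    else 1.0
                counts[si] = level * noise
            mz_rows.append(m)
            rt_rows.append(rt_aa)
            inten = np.vstack([inten, counts])
            owners.append((-1, -1))

    fids = assign_feature_ids(mz_rows, rt_rows)
    for row, (ti, k) in enumerate(owners):
        if ti < 0:
            continue
        if k == 0:
            truth[ti].anchor_id = fids[row]
        else:
            truth[ti].labeled_ids[k] = fids[row]

    feats = pd.DataFrame({"mz": mz_rows, "rt": rt_rows},
                         index=pd.Index(fids, name="feature_id"))
    feats[sample_ids] = inten
    prov = {"generator": "dualtrace.simulate", "seed": config.seed,
            "polarity": "negative", "artifact_rows":
                [fids[r] for r in artifact_rows]}
    return validate_table(feats, meta.reset_index(), prov)


def simulate_experiment(config: SimulationConfig
                        ) -> Tuple[FeatureTable, List[GroundTruthFeature]]:
    """Simulate a full dual-precursor feeding experiment.

    Returns the observed feature table and the planted ground truth.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = draw_ground_truth(config, rng)
    if not truth and not config.include_fed_precursors:
        meta = _sample_grid(config)
        feats = pd.DataFrame(columns=["mz", "rt", *meta.index])
        feats.index.name = "feature_id"
        return FeatureTable(feats, meta, {"seed": config.seed}), []
    table = realize_feature_table(truth, config, rng)
    return table, truth


def zero_noise_config(**overrides) -> SimulationConfig:
    """Study conditions with every stochastic nuisance switched off, for
    exact-recovery checks."""
    base = dict(mz_error_ppm=0.0, rt_jitter_sd=0.0, rt_iso_sd=0.0,
                intensity_cv=0.0, integration_cv=0.0, artifact_rate=0.0)
    base.update(overrides)
    return SimulationConfig(**base)


# -- ground-truth IO --------------------------------------------------------

TRUTH_COLUMNS = ["anchor_id", "archetype", "ring_count", "base_mz", "rt",
                 "true_frac_phe", "true_frac_tyr", "true_mol_phe",
                 "labeled_ids"]


def truth_to_frame(truth: Sequence[GroundTruthFeature]) -> pd.DataFrame:
    rows = []
    for f in truth:
        rows.append({
            "anchor_id": f.anchor_id,
            "archetype": f.archetype,
            "ring_count": f.ring_count,
            "base_mz": f.base_mz,
            "rt": f.rt,
            "true_frac_phe": f.true_frac_phe,
            "true_frac_tyr": f.true_frac_tyr,
            "true_mol_phe": (np.nan if f.true_mol_phe is None
                             else f.true_mol_phe),
            "labeled_ids": ";".join(f"{k}:{v}"
                                    for k, v in sorted(f.labeled_ids.items())),
            **{f"base_intensity_{t}": v for t, v in f.base_intensity.items()},
        })
    return pd.DataFrame(rows)


def write_ground_truth(truth: Sequence[GroundTruthFeature], path) -> None:
    """One CSV row per planted feature (archetype, ring count, true
    fractions, true mol%, emitted feature ids)."""
    truth_to_frame(truth).to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- genotype abundance panels ---------------------------------------------

def simulate_abundance_panel(table: FeatureTable, tissue: str,
                             effects: Mapping[str, Mapping[str, float]],
                             wild_type: str = "WT", replicates: int = 3,
                             cv: float = 0.1, seed: int = 0) -> FeatureTable:
    """Simulate an unlabeled genotype panel (e.g. mutants vs wild type)
    over the features of an existing table.

    ``effects`` maps genotype -> {feature_id: fold change vs wild type};
    genotypes absent from a feature's effect map accumulate it at the
    wild-type level.  Baselines are the mean 12C-fed intensities of the
    requested tissue.  Used for retrospective-annotation demonstrations.
    """
    rng = np.random.default_rng(seed)
    base_ids = table.select_samples(tissue=tissue, isotope="12C")
    if not base_ids:
        raise ValidationError(f"no 12C samples for tissue {tissue!r}")
    baseline = table.features[base_ids].mean(axis=1)
    sig = float(np.sqrt(np.log1p(cv ** 2)))
    genotypes = [wild_type] + [g for g in effects if g != wild_type]
    rows = []
    cols = {}
    for g in genotypes:
        fold = effects.get(g, {})
        for rep in range(1, replicates + 1):
            sid = f"{g}_r{rep}"
            rows.append((sid, tissue, g, rep))
            mult = np.exp(rng.normal(-0.5 * sig ** 2, sig,
                                     size=len(baseline))) if sig > 0 else 1.0
            vals = baseline.to_numpy() * mult
            scale = np.array([fold.get(fid, 1.0)
                              for fid in table.feature_ids])
            cols[sid] = vals * scale
    meta = pd.DataFrame(rows, columns=["sample_id", "tissue", "genotype",
                                       "replicate"])
    feats = table.features[["mz", "rt"]].copy()
    for sid, vals in cols.items():
        feats[sid] = vals
    return validate_table(feats.reset_index(), meta,
                          {"generator": "simulate_abundance_panel"})
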