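# Methods

## The analysis problem

In grasses, soluble phenylpropanoids can be built from phenylalanine (Phe,
via PAL) or from tyrosine (Tyr, via the bifunctional PTAL), so a metabolite
pool downstream of *p*-coumarate may draw on either amino acid.  Feeding
ring-labeled ¹³C₆-Phe or ¹³C₆-Tyr to seedlings tags every de-novo-made
phenyl ring with a +6.0201 Da mass shift (6 × 1.0033548 Da).  In an
untargeted negative-mode LC-MS feature table this shows up as a co-eluting
*isotopologue pair*: a ¹²C anchor feature plus +6/+12/+18 partners, one
shift per labeled ring.  `dualtrace` detects these pairs, quantifies how
much of each feature's pool each precursor labeled, normalizes the two
fractions into a mol%-of-origin value, classifies features into five
precursor-bias bins, and reuses the resulting library to annotate
unlabeled experiments (e.g. lignin-pathway mutants).

The pipeline consumes *feature tables* — the wide matrices produced by
standard peak-picking/grouping/gap-filling software — not raw spectra.
Centroiding, chromatographic alignment and peak filling are upstream
concerns; tables are assumed aligned and, if normalization (fresh mass,
internal standard) is wanted, already normalized.

## Pair detection

For each potential anchor *i* and ring count *n* ∈ {1, 2, 3}, candidates at
`mz_i + n·6·1.0033548` are accepted when they pass:

1. **mass gate** — |Δm/z| ≤ max(15 ppm of the target, 0.005 Th).  15 ppm
   echoes the usual peak-picking tolerance of the instruments this targets;
   the absolute floor keeps the window sane for light ions.
2. **co-elution gate** — |ΔRT| ≤ 5 s on aligned tables.
3. **enrichment gates** — the heavy feature's mean intensity in ¹³C-fed
   samples must be ≥ 2× its mean in ¹²C-fed samples *and* a one-sided
   Welch t-test (¹³C > ¹²C) must give p < 0.05.  This separates genuine
   incorporation from gap-filling artifacts, which put small spurious
   heavy signal into ¹²C-fed samples.  Both gates are configurable; a
   `require_absent` mode demands zero mean heavy signal in the ¹²C arm,
   and `test=False` disables the t-test (then one replicate per arm
   suffices).

Among candidates passing all gates, the one minimizing the combined
normalized distance `|Δmz|/tol_mz + |Δrt|/tol_rt` wins; exact ties resolve
by input order.  Groups sharing an anchor merge across *n*.

**Chain suppression.**  In a 2-ring group the +6 member sits exactly one
ring shift below the +12 member and is itself enriched in ¹³C-fed samples,
so it would anchor a spurious nested group.  Groups whose anchor is a
labeled member of any other group are therefore dropped (single pass; on
by default).  Groups with any member at *n* ≥ 2 are flagged
`dual_labeled` — candidates for lignans/neolignans, which contain two
phenyl rings.

Degenerate t-test inputs (both arms with zero sample variance, which arise
in noise-free simulations) are resolved deterministically: p = 0 when the
means differ in the tested direction, 1 otherwise.

## Quantification

Within each ¹³C-fed replicate, the labeled fraction of a feature's pool is

    f = (I₆ + I₁₂ + I₁₈) / (I₀ + I₆ + I₁₂ + I₁₈)

computed per replicate and then averaged (a pooled-sum mode exists; the
per-replicate default matches the replicate-level t-test).  Replicates
with a zero total pool are excluded and counted.  Multi-ring isotopologues
contribute raw ion counts with no ring-multiplicity weighting.  The two
per-precursor fractions normalize to

    mol%_Phe = 100 · f_Phe / (f_Phe + f_Tyr),  mol%_Tyr = 100 − mol%_Phe

which is undefined (flagged, not silently zeroed) when both fractions are
zero.  A two-sided Welch t-test on the per-replicate percent-incorporation
values supplies the significance filter for binning.  No multiple-testing
correction is applied by default, matching the uniform raw p < 0.05
convention of the experimental design this emulates; a Benjamini–Hochberg
helper is available.

## Bin classification

Features quantified from both designs are classified by the dominant mol%
bias: bin 1 = [50, 60) toward either precursor (no test required); bins
2/3 = [60, 80) toward Phe/Tyr; bins 4/5 = [80, 100] toward Phe/Tyr; bins
2–5 additionally require p < α (default 0.05), otherwise the feature is
*unbinned*.  The half-open boundaries make the bins exhaustive and
non-overlapping over the [50, 100] bias range: exactly 60 falls in bin
2/3, exactly 80 in bin 4/5.  Bin summaries report percentages against two
denominators (all labeled features, and binned features only) because
either convention is defensible; flux summaries aggregate ¹³C ion signal
per bin as a share of the summed ¹³C signal over all library features for
that precursor and tissue.

## Retrospective annotation

Library entries carry the anchor m/z, RT, origin set and bin/mol% context.
Features of a new unlabeled table match the nearest entry by the same
normalized-distance rule within 15 ppm and ±10 s (looser RT than pairing
because runs differ); an optional global RT offset absorbs systematic
drift.  Matching is injective per query feature and independent of library
row order.  Differential abundance uses two-sided Welch t-tests on
log2(intensity + 1) per genotype against wild type, with direction calls
at p < α, and an exhaustive disjoint overlap partition across two mutants
(down/up × only-A/only-B/both, plus structurally-possible opposing calls).

## The synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every recovery claim is made.  It emulates a
3-tissue × 2-precursor × 2-isotope × 3-replicate feeding design (36
samples) with six planted archetypes — unbiased (50–55 mol% bias),
Phe-biased and Tyr-biased (63–77 mol%), exclusive-Phe, exclusive-Tyr
(dhurrin-like) and non-aromatic decoys.  Defaults, chosen once as
realistic conditions for this kind of experiment:

| parameter | default | rationale |
|---|---|---|
| archetype counts | 40/14/6/5/5 labeled + 150 decoys | labeled mix echoes the observed leaf-tissue bin proportions; the decoy mass puts the labeled share of total ion count in the reported 20–45% range and the ¹³C share in the 5–13% range |
| labeled fraction range | 0.04–0.40 | observed per-pool ¹³C shares (e.g. 10–40% of the dhurrin pool) |
| ring-count probabilities | 0.88/0.10/0.02 for 1/2/3 rings | most soluble phenylpropanoids carry one ring; lignans/neolignans are a minority |
| m/z error | 5 ppm (per feature row) | typical Q-TOF mass accuracy, inside the 15 ppm pairing gate |
| RT jitter | 2 s shared per pair group + 0.3 s per isotopologue | co-eluting isotopologues drift together |
| pool CV | 0.20 log-normal per replicate | biological + extraction variance |
| integration CV | 0.05 log-normal per isotopologue | peak-integration error for resolved peaks; see below |
| artifact rate | 0.10, at 1–5% of the ¹³C-fed intensity | gap-filling artifacts in ¹²C-fed samples |
| base intensity | log-uniform 10⁵–10⁷ counts; root scaled ×0.5 | heavy-tailed feature abundances; weaker root signal |

Fed Phe/Tyr themselves (and their +6 forms) are emitted as abundant
early-eluting rows so the exclusion filter has real work to do; they are
not part of the planted truth.

**Isotopologue split.**  `true_frac` is defined as the labeled share of
the pool — the quantity the method measures.  For an *r*-ring feature the
per-ring label probability *q* solves `1 − (1−q)^r = frac`, and the
+6k shares are binomial(r, q) conditioned on that total, so the labeled
pool share equals `frac` exactly while the split across +6/+12/+18 follows
the independent-ring model.

**Noise structure.**  Each feature × sample draws one log-normal pool
(CV = `intensity_cv`), shared by all of its isotopologues; the split is
then jittered per isotopologue (log-normal, `integration_cv`) and
renormalized so the isotopologues still sum exactly to the pool draw
(conservation).  The pool-level noise deliberately cancels out of the
labeled-fraction ratio — co-eluting isotopologues share extraction and
injection — so the error that propagates into mol% estimates is the
smaller integration term, which is what makes n = 3 t-tests at p < 0.05
realistic rather than hopeless.  A single seeded generator drives every
draw; outputs are byte-identical for a fixed seed.

**What the generator does not model**, and hence what passing tests do not
show about real data: natural-abundance M+1/M+2 envelopes (real pairing
must not confuse +1 with +6; this simulator never generates +1), detection
limits (gap filling is assumed to give every row a value in every sample),
chromatographic peak shapes, adducts/in-source fragments sharing an
elution profile, exogenous-precursor perturbation of ¹²C pools (available
as an optional multiplicative `treatment_effect`, off by default), and
precursor uptake/pool-size kinetics — labeled fractions reflect uptake and
pool turnover, not pure pathway flux, and no kinetic correction is
attempted.

## Numerical and design choices

* Feature ids follow the `M{round(mz)}T{round(rt)}` convention; the
  convention is lossy, so collisions get `_2`, `_3`… suffixes in input
  order and ids regenerate deterministically from (m/z, RT).
* The RT analysis window defaults to [100, 1100] s, inclusive at both
  edges; missing intensity cells read as 0 and are counted in a
  `n_filled` diagnostic rather than erroring, because upstream gap filling
  makes zeros and small fills indistinguishable.
* Exclusion masses for the fed amino acids are computed from monoisotopic
  atomic masses (Phe C₉H₁₁NO₂, Tyr C₉H₁₁NO₃, [M−H]⁻, ±6 ring carbons) and
  the list is user-extensible.
* Enrichment tests run on raw ion counts (simple fold semantics);
  differential-abundance tests run on log2 counts with a pseudocount of 1.
  Both choices are configurable.
* PCA is centered, not scaled, on log2 counts, with component signs fixed
  by the largest-magnitude loading; regression uses ordinary least squares
  on log2 values with the same pseudocount.
* Problem sizes in the test-suite and acceptance runs (~300-feature
  tables, 20–100 brute-force comparison tables of ≤ 150 features) were
  chosen as the smallest designs that exercise every archetype and keep
  the quadratic oracle comparisons comfortable; recovery metrics are
  stable across seeds at these sizes.

## Known limitations

* The worked mol% example (25%/4.2% → 86 mol%) reflects rounding of
  unprinted underlying values in its source; the complement prints as 14.4
  here, and only the dominant value is asserted.
* Whether bin-share denominators should include QC-failing features is
  ambiguous; both denominators are reported.
* An anchor may belong to only one pair group per design, but a heavy
  feature can in principle be claimed by two anchors; no global matching
  is attempted.
* Retrospective annotation assumes comparable chromatography between
  experiments up to a global RT offset; nonlinear drift is out of scope.
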