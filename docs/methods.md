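# Methods

## Problem setting

Enzyme-based identification (EBI) addresses the annotation of xenobiotic
metabolites in untargeted LC-HRMS feature tables when authentic chemical
standards do not exist. Pooled human liver S9 fraction incubations produce
phase I and phase II metabolites of a test compound in vitro; these
enzyme-generated products, characterized by accurate mass, retention time
and (when collectable) MS2, act as the reference material against which
study samples are matched. Because no purified standard is involved,
identification confidence is built from *orthogonal criteria* rather than
from spectral match alone.

`ebimet` implements the computational stages of this workflow. It consumes
aligned MS1 feature tables (peak picking and alignment are upstream) and a
metabolite library, and produces time-course screens, isotope-pair
confirmations, study-sample identifications with confidence levels, and
mass-shift biotransformation networks.

## Mass arithmetic

Monoisotopic masses use the IUPAC table (1H 1.0078250319, 2H 2.0141018,
12C 12 exactly, 13C 13.0033548, N 14.0030740, O 15.9949146, S 31.9720707,
Cl 34.9688527 Da; electron 0.00054858 Da). Isotope labels are
*substitutions*: a formula stores the total atom count per element plus the
number of positions carrying the heavy isotope, so a d3 form of C8H12N4O3 is
the same skeleton with three of twelve hydrogens replaced, adding
3 × (m(2H) − m(1H)).

Ion m/z handles the electron explicitly. Proton-transfer ions add or remove
a proton (m(1H) − mₑ = 1.007276 Da), so [M+H]+ − [M−H]− = 2 × 1.007276 for
any formula. Intact cations/anions subtract/add one electron mass; this is
required to reproduce instrument-reported fragment masses (C9H11ClNO2+ is
200.0473, not 200.0478). Only singly charged species are supported — the
metabolite classes targeted here ionize singly.

Biotransformations are named signed element-count deltas with derived mass
shifts; the packaged table covers hydroxylation (+O), reduction (±2H),
hydration (+H2O), the mass-equivalent oxidation+reduction composite (+O+2H),
dihydrodiol (+2O+2H), de/methylation (±CH2), glucuronidation (+C6H8O6,
+176.0321), sulfation (+SO3, +79.9568), acetylation (+C2H2O), glutathione
conjugation (+C10H15N3O6S), plus adduct/isotope spacings (13C isotopologue
+1.00336 expressed as a 13C-for-12C substitution; Na-for-H +21.98194)
flagged with phase "adduct/isotope" so chemistry and ionization artifacts
stay separable. Users can supply their own TSV in the same
(name, delta, phase) format. Expected-product enumeration applies rule
chains breadth-first to a parent formula, pruning chemically impossible
branches (negative counts) and deduplicating by formula; the default depth
of 2 captures one functionalization plus one conjugation (e.g. hydroxy
→ glucuronide), which covers the chained products that matter in practice.
Note that mass-equivalent interpretations (+O+2H vs +H2O) collapse to one
formula; annotation reports the formula, not a unique mechanism.

## S9 time-course screen

Incubations are sampled at 0/2/6/24 h with duplicate biological replicates.
Replicate intensities are averaged per time point, missing values imputed as
zero, and raw (untransformed) intensity is correlated against time in hours.
A feature passes with Pearson r > 0.9 **and** averaged t = 0 intensity at or
below a threshold (default 0: "not detected at time zero"). Zero-variance
features have undefined r and fail. Raising the r threshold is monotone.
Passing features are annotated against enumerated expected products via ion
m/z within ±3 ppm; a feature may match several mass-equivalent products and
all are reported ordered by |ppm|. Annotated features become library entries
carrying their satisfied criteria (xenobiotic-specific presence, mass match,
time dependence, MS2 when available); entries with MS2 are MSI level 2
(spectral data exist but no purified standard), otherwise level 3.

## Stable-isotope pairing

For a labeling scheme with n heavy atoms, each time-trend-passing unlabeled
feature is searched in the labeled experiment at mz + k·Δ for k between
n − max_label_loss and n, within ±3 ppm evaluated on the labeled m/z and
co-eluting within ±5 s. Defaults for max_label_loss: 0 for 13C (the carbon
skeleton survives biotransformation) and n for 2H (deuterium can be lost
metabolically or by exchange — the d9-bupropion → d8-hydroxybupropion case).
The best match per k is kept, and matches at several k are all reported
because the ambiguity is chemically informative (label position). Features
with no twin are nonspecific: they rose with incubation time for reasons
unrelated to the test compound. The co-elution window for label pairing is
taken equal to the study-sample coelution window (±5 s), which is not
independently specified by the source protocol.

## Identification and confidence levels

Study features match library entries of the same chromatographic method
within ±3 ppm and ±5 s; multiple candidate features for one entry are ranked
by |ppm| then |Δrt|. Detection in a sample means intensity present and
strictly above the floor (default 0); missing cells and explicit zeros both
count as not detected, since alignment software emits both. The presence
matrix has one row per (precursor, metabolite) and one column per sample;
relative abundance is min–max scaled per row over its detected cells (a
single-valued row maps to 1), mirroring the usual heatmap convention.

Criteria per identification:

* mass match (±3 ppm) — true by construction for matched features;
* co-elution (±5 s) with the enzyme-generated metabolite;
* exposure-specific presence — assessed only when documented-exposure
  records are supplied; true iff every sample the metabolite is detected in
  belongs to the documented set. Without records the flag is "not assessed"
  and excluded from the count (the undocumented-exposure use case);
* co-occurrence — at least one *other* metabolite of the same precursor
  detected in the same sample. Cross-biofluid concordance is reported
  separately and never folded into the level;
* MS2 match, when spectra were collected, as a further criterion.

Satisfying ≥3 criteria is level 1, exactly 2 is level 2, exactly 1 is
level 3. Adding a satisfied criterion can never lower the level.

MS2 similarity is a greedy cosine: candidate fragment pairs within a ppm
tolerance (default 10 ppm) are accepted in order of increasing mass
discrepancy, each peak used once; the score is the matched dot product over
the full spectrum norms. Defaults (10 ppm, min cosine 0.7) suit
high-resolution fragment data; both are configurable.

## Biotransformation networks

For each parent feature, association with every other feature is computed
across samples on zero-imputed intensities. The default score is Pearson
correlation; "pls1" is accepted as a method name for fidelity to
PLS-regression-based association tools, and is computed identically because
for a single response the first PLS component's weights on standardized data
are proportional to the per-feature correlations — the ordering and
thresholding at |r| > 0.4 coincide. Associated features become edges only
when child − parent m/z matches a delta from the rule table within ±3 ppm
(evaluated on the child m/z). Biotransformation deltas apply with their
chemical sign only (conjugations add mass, dealkylations remove it);
adduct/isotope spacings are tried in both directions. Every retained edge
therefore satisfies both the association and the mass-shift criterion, and
tightening either threshold prunes monotonically. The per-parent stars are
unioned into a graph whose connected components are pathway clusters; nodes
reachable from more than one parent are flagged ambiguous.

## Synthetic data

The generators emulate the three study designs end to end, with all
randomness drawn from a single seed (identical configuration ⇒ identical
tables).

* **S9 time course**: products follow first-order formation
  A·(1 − e^(−kt)), exactly zero (missing) at t = 0; the parent declines
  mildly (2%/h, substrate consumption); background features are
  time-independent. The default formation rate is 0.05/h so products are
  still rising at 24 h — the regime the time-trend filter is designed for
  (a product that saturates within hours correlates poorly with a 0–24 h
  time axis and would not be discovered by this screen in the first place).
* **Label pair**: the labeled run mirrors the unlabeled one with planted
  features shifted by retained × Δ and sharing the same base retention
  time; background features are drawn independently per run so none has a
  twin.
* **Cohort**: each pathway's exposed sample subset is drawn once and shared
  across biofluids; within exposed samples, pathway members share a
  log-scale subject factor (sd 0.8, loading 1.0), producing the
  parent–metabolite correlation the networking threshold of 0.4 is meant to
  exercise; unexposed samples carry no pathway signal. Background features
  are present everywhere. The demonstration pathway set plants nicotine
  (with cotinine, hydroxycotinine and the glucuronide) in 7 of 120 samples
  and five drug pathways (bupropion, acetaminophen, metoprolol, carvedilol,
  warfarin) at single-digit-to-low-teens prevalences plausible for a general
  adult cohort.

Defaults elsewhere: 0.5 ppm mass jitter and 1 s retention jitter
(Orbitrap-class acquisition), log-normal intensities around 1e5 counts,
retention times uniform over 18–300 s (void volume to run end of a
five-minute dual-chromatography method), 50 background features, duplicate
replicates.

What the simulations do **not** model: chromatographic peak shape, isotope
envelopes and natural-abundance 13C, adduct/in-source-fragment families,
matrix effects, batch drift, or correlated background structure. Passing
tests on this synthetic data therefore demonstrate the correctness of the
filtering/matching logic and its parameter recovery under the stated noise
model — not performance on real instrument data, where nonspecific features
can correlate with time or with parents for reasons the generators do not
produce.

## Numerical choices and degenerate inputs

Formula canonicalization is Hill order with bracketed heavy isotopes
("C8H9[2H]3N4O3"); parsing accepts D as 2H shorthand and round-trips through
the writer. ppm errors are signed, two-sided, and always evaluated against
the stated theoretical reference (labeled m/z for isotope pairs, child m/z
for network deltas). Zero-variance features: a flat time course fails the
trend filter (undefined r); a zero-variance parent is an error for
association; zero-variance children score 0. A zero denominator in an
isomer intensity ratio returns infinity with a flag rather than raising.
Library entries enforce internal consistency (stored theoretical m/z within
3 ppm of the formula's ion m/z). Retention time is seconds everywhere;
readers accept a minutes flag.

## Known limitations

Single charge only; no isotope fine structure or envelope deconvolution; no
structure-aware metabolism prediction (the rule table is composition-level,
so positional isomers are indistinguishable and metabolites should carry
broad nomenclature, e.g. "hydroxybupropion"); no FDR control across the
library (matching is tolerance-based, as in the underlying workflow); the
PLS association is the documented Pearson-equivalent, not a multi-block
implementation. For the d9-4′-hydroxybupropion ion, theory gives 265.1664
and nearby published figures disagree at the fourth decimal (265.1666 /
265.1674); the package reports theory.
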