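# Methods

This note documents the models, conventions and design choices behind
`taascan`, and what the synthetic-data generators do and do not emulate.

## Selection cascade

The cascade operates on two categorical immunohistochemistry (IHC) tables:
a normal-tissue table (gene × tissue × cell type → detection level in
{Not detected, Low, Medium, High}, with an optional reliability grade) and a
pathology table (gene × cancer → patient counts per level, with optional
best-cutoff prognostic annotations). Five filters are applied in fixed
order; each can only remove genes, so survivor sets are nested and the audit
counts are non-increasing.

Conventions that were genuinely open and how they were fixed:

* **"High in more than one sample"** is encoded as `n_high ≥ 2`
  (configurable). The strict reading of "more than one" is ≥ 2.
* **Genes never measured in liver target cells** are excluded at stage 1 and
  reported separately rather than passed through: absence of evidence is not
  evidence of absence.
* **"Absent in all normal tissues"** admits no non-zero level at any
  reliability by default; `require_reliable=True` restricts the check to
  records graded better than *Uncertain* (source data do not state whether
  reliability filtering was applied).
* **Prognostic direction** must be explicitly *unfavorable*; a significant
  *favorable* association does not pass. The boundary is strict
  (p = 0.05 exactly is excluded).
* Stage 2 requires detection in ≥ 1 patient; a fractional threshold was
  considered and rejected because the upstream description is per-sample.

The published stage counts of the original atlas-wide analysis
(5446 → 3283 → 310 → 40 → 9) depend on the atlas release and are treated as
audit fields, not assertions; correctness is instead established on planted
synthetic tables where recall and precision of the final stage must both be
1.0.

## Survival analysis

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines`; times are in years and ties follow the standard life-table
convention (deaths precede censorings at equal times). The 5-year readout is
a reporting constant, configurable per call.

The best-cutoff scan dichotomizes expression at each quantile from 20% to
80% in 5% steps (configurable), tests each split by log-rank, and returns
the minimizing cutoff. Distinct cutoffs inducing the same partition are
tested once. Two properties are documented deliberately:

* **Anti-conservatism.** Minimum-p selection over ~13 splits inflates small
  p under the null. The suite quantifies this (300 null replicates at
  n = 100: the fraction of best-p < 0.05 must exceed the nominal 5% and stay
  ≤ 40%) rather than correcting it, because the scan mirrors how
  atlas-style prognostic p-scores are produced and is used for ranking.
* **No multiple-testing correction**, for the same reason.

The scan grid of any public atlas pipeline is not published, so scan output
is validated by simulation (planted effects recovered with the right
direction), never against published per-gene p-scores.

## Expression comparison

Values are transformed as log2(x+1) by default (count-like RNA-seq scale).
The paired test is a two-sided paired t-test over matched tumor/normal
samples with incomplete pairs dropped (warned and counted); the unpaired
test is Welch's unequal-variance t-test, chosen over the pooled form because
group sizes and variances of public cohorts differ substantially. Star
labels follow the universal convention (* < 0.05, ** < 0.01, *** < 0.001,
**** < 0.0001). Scale invariance under a common positive factor is exact
for a pure log transform; with the +1 pseudocount it holds approximately on
count-scale data, and the test asserts it with a 5% relative tolerance on p.

## Epitope selection

A protein of length L yields exactly L−8 overlapping 9-mers (1-based starts
1..L−8). Affinity tiers use half-open boundaries [10, 50) and [50, 100) nM —
the tier edges at exactly 10 and 50 nM fall in the upper tier; the source
description uses strict inequalities on both sides and leaves the boundary
undefined, so the convention is fixed here and tested. Strong-binder
selection requires the predictor's own SB call *and* affinity strictly below
100 nM; stability intersection then requires the stability predictor's SB
call (optionally a minimum Thalf), dropping peptides without a stability row
(counted). Default alleles are HLA-A\*02:01 and HLA-A\*24:02; arbitrary
allele strings are accepted.

The **toy predictor** exists so the full selection path runs without the
external neural-network tools: affinity = base (5 nM) × 20 per broken anchor
(positions 2 ∈ {L,M} and 9 ∈ {V,L,I}) × a CRC32-seeded factor in [1, 3);
Thalf decreases monotonically with affinity. It is deterministic, monotone
in anchor quality, and explicitly not a scientific binding model. Real
predictor output is consumed through file parsers (a whitespace
`simple_tsv` dialect and NetMHCpan-4.1 / NetMHCstabpan-1.0 style block
formats); non-9-mer rows are skipped with a reported count.

## Mimicry scan

The scan computes position-wise identity between each candidate epitope and
every 9-residue window of every viral protein, keeping windows at or above
the identity floor (default 7/9, the weakest validated pair). Design
choices:

* An exhaustive scan replaces a heuristic homology search: at desk scale
  (≤ 10⁷ residues) the O(N·L) loop runs in seconds and is exact, whereas a
  local-alignment heuristic only approximates the position-wise identity
  criterion that defines the retained pairs. Correctness is asserted as set
  equality with an independently coded naive double loop over 200 random
  instances.
* Ambiguous residues (X) never match anything, including another X.
* The viral-binder filter defaults to classes {SB, WB} with Thalf > 3 h:
  validated pairs include weak-binder viral peptides with adequate
  stability, so requiring SB would be too strict. Both knobs are exposed.
* Report rows sort by (allele, tumor protein, identity desc), ties broken by
  viral accession then position, making output invariant to proteome record
  order.

One printed pair in the source material (MLAGNEFQV vs MLAGNAFTA, described
as 7/9) computes to 6/9 by position-wise comparison of the printed
sequences; the package reports the computed value.

## Assay quantification

* **FI**: (MFI_sample − MFI_background)/MFI_background, binder iff FI > 0.5
  (strict, per the printed ">"); scale-invariant by construction.
* **DC50**: default *discrete* mode returns the first sampled timepoint with
  percent-remaining ≤ 50 (plus a 1e-9 absolute tolerance so an exact 50% at
  a sampled time is counted), because timecourse readouts sampled every 2 h
  are reported as the sampled time; *interpolated* mode linearly
  interpolates the crossing and is never later than the discrete value.
  A series that never reaches 50% reports not-reached beyond the last
  timepoint.
* **Multimers**: the denominator is live ∧ CD3⁺ ∧ CD8⁺ events under explicit
  per-channel thresholds — no automated gating, because gating strategy
  beyond live/CD3/CD8 is typically unspecified in published summaries.
  Cross-reactivity is operationalized as double positivity in the paired
  TAA and viral channels within the same event; the alternative
  (sequential single-multimer comparison) would not bound cross % by the
  single-channel % and was rejected. Group summaries are arithmetic means
  over donors.
* **Replicates** are averaged to a single MFI before FI/DC50, with SEM
  reported alongside.

## Synthetic-data generators

The generators define the conditions the package is tested under:

* **Cascade tables**: default 1000 genes over 5 tissues × 2 cell types, 9
  planted full-cascade positives; every distractor fails exactly one named
  stage (round-robin), so each stage demonstrably drops someone. Planted
  data are noise-free by design: the cascade is deterministic set algebra,
  and the interesting failure modes are schema and boundary errors, not
  noise.
* **Survival cohorts**: exponential event times with rate λ = −ln(S₅)/5 per
  group, so the true 5-year survival equals the target exactly; censoring
  (uniform) is off by default so the product-limit estimate equals the
  empirical surviving fraction and closed-form checks are exact. Default
  calibration 28%/53% (the widest published prognosis gap), n = 500/group.
  One binomial SE of the 5-year delta at that size is ≈ 3 pp; recovery tests
  therefore average several independent cohorts.
* **Proteomes**: i.i.d. uniform residues over the 20 amino acids (not
  proteome-weighted), which makes chance-match rates exactly analyzable;
  homologs are planted by mutating 9−identity random positions of the target
  epitope to different residues at a recorded accession/position.
* **Assay data**: decay series are exact exponentials with optional
  log-normal noise (time 0 noise-free so normalization is exact; default
  half-life 4 h matching the validated fast-dissociating pairs); multimer
  events are two-component log-normal mixtures (background median 100, clone
  median 10,000, σ_log = 0.25 — ~18 log-SD separation, so threshold gating
  at 1000 is unambiguous). Cross-reactive clones are planted first and count
  toward both member channels, keeping cross ≤ min(singles) by
  construction. Default planted frequencies are the published group
  averages (0.88% TAA, 0.46% viral, 0.298% cross at 100,000 events ×
  4 donors).

**What passing tests do not show**: real IHC calls are noisy and
release-dependent; real expression is not log-normal with a single planted
effect; real proteomes have biased residue composition (raising chance-match
rates above the uniform-background estimate); real flow data have spillover,
autofluorescence and gate ambiguity. The generators establish that the
*computations* are correct, not that the biological discovery pipeline is
robust to those artifacts.

## Numerical conventions

Seeds are mandatory everywhere randomness exists (`numpy.random.default_rng`
with integer seeds); fixed seed implies byte-identical emitted files. Tier
and threshold boundaries are documented above and tested at the boundary.
Problem sizes in the suite (300-replicate null scans, 200 oracle instances,
1000-replicate log-rank calibration at n = 50/50, 100,000-event donors) were
chosen so the whole suite runs in under two minutes on one CPU.
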