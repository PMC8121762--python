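# Methods

This note records the models, conventions and numerical choices behind
the package, and what the synthetic study does and does not emulate.

## Coordinates and naming

All peptide coordinates are 1-based inclusive on the **prepro** sequence
(signal peptide included).  A peptide from gene *G* spanning prepro
positions *s*–*e* is named `G ps-e`, with a trailing `a` when its
C-terminus is amidated (`ChgA p435-462a`).  This matches how endogenous
gut peptides are reported when their exact termini, rather than legacy
hormone names, are the object of study.

## Mass arithmetic

Monoisotopic residue masses are embedded as constants (sum + water +
modification deltas); average masses are never used, matching
high-resolution Orbitrap identification practice.  Modification deltas
are the standard values: amidation −0.98402 Da (OH→NH2), pyroGlu from
Gln −17.02655 / from Glu −18.01056, acetyl +42.01057, carbamidomethyl
+57.02146, phospho +79.96633, octanoyl +126.10447, decanoyl +154.13577.
Peptides are limited to 65 residues, the upstream database-search
constraint, and nonstandard letters (B, J, O, U, X, Z) are rejected
rather than approximated.  m/z uses a proton mass of 1.007276 Da.

## Homolog alignment and projection

Mouse/human precursor pairs are aligned globally (Needleman–Wunsch via
Biopython's PairwiseAligner) with BLOSUM62, gap open 10, gap extend 1,
end gaps penalised.  The match line marks `|` for identity and `:` for
"chemically similar", defined here as a positive BLOSUM62 score between
non-identical residues — a concrete rule standing in for the informal
figure convention.  Ties between equally optimal alignments are broken
by the first traceback, deterministically.  Interval projection maps a
mouse interval to the smallest human interval covering all non-gap
images; coverage is the fraction of source positions with an image, and
span identity is the fraction of source positions in identical columns.
Ile and Leu are treated as distinct (isobaric resolution is assumed to
have happened upstream).

## Cleavage and PTM rules

Prohormone convertases cleave C-terminal of mono-/dibasic K/R sites;
carboxypeptidase-E then trims the exposed basic residues, and PAM
converts a C-terminal Gly into an amide.  The terminus classifier
therefore calls a cut **dibasic** when KK/KR/RK/RR immediately precedes
it, allowing the effective cut to sit up to two still-present basic
residues downstream (the trimmed case); **monobasic** when exactly one
K/R precedes; **signal_boundary** when the cut coincides with the
annotated signal-peptidase site (which takes precedence); otherwise
**nonbasic**.  These motif rules encode standard processing biology,
stated here as the package's own convention.  An observed amide is
consistent iff the precursor residue after the peptide is Gly.  For
candidate scoring, precursor N-/C-termini count as valid flanks, and an
amidated C-terminus is classified after skipping the consumed Gly.

## Ladders and the 10 % filter

Exoproteolytic ladders (series differing by 1–2 terminal residues) are
clustered by single linkage: two observations link when they overlap
and either terminus differs by ≤ 2 residues.  Clusters are reported but
**not** merged into a longest variant — variant information is retained
deliberately.  The minor-fragment filter drops, within each propeptide,
peptides whose maximum peak area across samples is below 10 % of the
propeptide's most abundant peptide.  Using the per-peptide maximum
across samples (rather than per-sample areas) makes the filter
idempotent and stable to sample-level noise; the choice of a global
rather than per-sample comparison is a design decision of this package.

## Differential and secretion statistics

Peak areas are compared on the natural scale; group means are
arithmetic means over non-missing samples (missing = not detected, never
zero).  `log2fc = log2(mean_lean / mean_DIO)`, so decreases in the
obese group are positive.  The per-peptide test is Mann–Whitney U
(robust to the log-normal skew of label-free areas), switchable to
Welch's t on log areas; q-values are Benjamini–Hochberg within each gut
region, and regions are always analysed independently.  The test and
alpha are this package's choices — the underlying study design leaves
them open.  Peptides with fewer than two finite values in a group get
no p-value; an all-missing group yields a flagged NaN fold change.
Fold over basal is stimulated/basal area, NaN when basal is undetected;
folds > 2 are treated as regulated (vesicular) secretion.

## Candidate scoring

Four booleans per unique peptide: *basic_flanked* (both termini
dibasic/monobasic/signal-boundary or precursor ends),
*abundant_both_species* (mouse max area ≥ 1e5 and an overlapping human
peptide ≥ 1e5 within the projected interval), *conserved* (span
identity ≥ 0.7), *regulated_secretion* (fold over basal > 2 in ≥ 1
region).  The abundance and identity cut-offs quantify criteria that
are qualitative in the field ("highly abundant", "conserved"); they are
configurable defaults of this package, while the > 2-fold secretion
cut-off is the standard stimulated-release criterion.  Composite =
count of true criteria; ranking by composite, then maximum mouse area,
then identifier — a deterministic total order.  A literature-prior
criterion (peptides previously described as bioactive) is out of scope;
no text mining is attempted.

## Pharmacokinetics

One compartment with first-order absorption, chosen over two
compartments because the short peptide half-lives and sparse ≤ 90-min
sampling cannot support more structure.  Closed forms replace numerical
integration; the s.c. solution is the Bateman function with the
`ka == ke` limiting form `C(t) = (D·ka·t/(V/F))·e^(−ka·t)` handled
explicitly.  Fitting minimises least squares on log concentrations
(equal weights; zeros/below-LOQ excluded) with multi-start over a
(ka, ke) grid; extravascular fits identify V/F and CL/F only.  The
flip-flop ambiguity — (ka, ke, V) and (ke, ka, V·ke/ka) trace identical
curves — is resolved by reporting ka > ke, with a warning flag when the
two rates are within 5 %.  `fit_replicates` pools replicate animals by
geometric-mean collapsing of shared time points before a joint fit.

NCA uses the linear-up/log-down trapezoid; λz comes from a log-linear
regression on the last ≥ 3 positive points, and AUC(0–∞) adds
C_last/λz.  Profiles whose first sample is after t = 0 are anchored at
zero: i.v. bolus by log-linear back-extrapolation of C0 from the first
two descending points, extravascular by C(0) = 0 — without this the
bolus AUC systematically misses the initial segment and biases the
bioavailability ratio upward.  Bioavailability is
(AUC_sc/D_sc)/(AUC_iv/D_iv).  The steady-state delivery rate is
Css × CL/F × 1440 min/day, with a nanomolar target converted to mass
units via the analyte's molecular weight (nM × g/mol / 1000 → ng/mL).

## The synthetic study

The generator's defaults are the study conditions: five gut regions,
10 lean + 10 DIO animals per region, a 4-fold decrease of the L-cell
precursors (Pyy, Gcg, Insl5) confined to the distal colon, a 70 %
prevalence structure with ~5 % random missingness (50 % for the
low-prevalence secretin-like gene), 6-fold stimulated release for
vesicular peptides versus ~1-fold for the cytosolic decoy, mouse/human
identity 0.85 with candidate spans fully conserved, exoprotease ladders
up to 2 residues, and log-normal areas (canonical peptides ~2e5,
candidates ~2e6, within-group spread σ = 0.25).  PK truths use the
published subcutaneous half-lives (18.1 min gastrin candidate, 36.0 min
granin candidate, bioavailability 0.5 for the granin candidate),
ka = 5·ke, V = 0.15 L/kg, sampled at 8 points over 90 min with 10 %
lognormal noise — desk-scale sizes that keep every simulation in
seconds.

Sequences are built from a uniform residue alphabet *excluding* K, R
and G so that every cleavage site and amidation motif is planted, not
accidental; the human homolog is derived by point mutations only (no
indels), with motif and candidate positions protected.  Consequently
the generator does **not** emulate: real amino-acid composition or
codon bias, indel divergence between species, chimeric/ambiguous
peptide matches across precursors, retention-time or spectrum-level
structure, inter-run normalisation artefacts, or missingness that
correlates with abundance.  Passing tests therefore demonstrate that
the statistics and classifiers recover planted structure under the
assumed noise model — not that they are robust to every pathology of
real label-free data.  Randomness is one named PRNG stream per artefact
(seeded from the master seed + a CRC of the artefact label), so outputs
are byte-identical under a fixed seed and adding artefact types never
perturbs existing ones.

## Known limitations

- The steady-state delivery rates depend on clearance estimates that
  live outside the package's inputs; the formula is implemented and
  dimension-checked, but absolute rates reflect the synthetic V and ke.
- Single-linkage ladder clustering can chain overlapping variants into
  clusters whose extremes no longer overlap the canonical member; with
  ≤ 2-residue trims this does not arise, but deep ladders on short
  peptides could produce it.
- Sulfation-aware searching, isotope envelopes and MS2 fragment masses
  are out of scope; only the named modification set is registered.
- Peptides mapping to multiple precursors keep all hits with an
  ambiguity flag; downstream statistics use the first hit in accession
  order as a deterministic tie-break.
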