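# Methods

## Problem setting

Targeted protein quantitation by LC-MS/MS in multiple-reaction-monitoring
(MRM) mode measures a proteotypic tryptic peptide of the target protein
against an internal standard (IS). The gold-standard IS is a
stable-isotope-labelled (SIL) copy of the analyte peptide, spiked at known
amount after digestion. A cheaper alternative is to co-digest the sample
with serum of another species (e.g. fetal bovine serum) and use the
homologous bovine tryptic peptides as internal standards. This package
implements the computational side of that strategy: designing
species-specific analyte/surrogate peptide pairs and MRM transitions, and
validating the resulting calibration data against bioanalytical acceptance
rules.

## In-silico digestion

Trypsin is modelled by the classical rule: cleavage C-terminal to K or R
except when the following residue is P; the protein C-terminus always
closes a peptide. Peptides carry 1-based inclusive coordinates and an
internal missed-cleavage count. Defaults are `max_missed = 0`,
`min_len = 5`, `max_len = 30`: typical quantotypic peptides are 7–13
residues and fully cleaved, and 5 residues is the shortest fragment worth
monitoring. Partial-digestion behaviour is *not* modelled here; the
synthetic-data generator carries it as a per-sample efficiency scalar
(below). No digestion-kinetics or missed-cleavage probability model is
attempted.

## Peptide properties

Monoisotopic masses use the standard residue-mass table with water
18.010565 Da and proton 1.007276 Da; precursor m/z at charge z is
(M + z·1.007276)/z and b/y fragment ions follow the usual neutral-mass
conventions (y retains water, b does not). No fixed modifications are
applied by default — none of the panel peptides contain cysteine — but
per-residue mass deltas can be supplied. Comparisons against printed
method-sheet values round half-away-from-zero at 1 dp (m/z) and 2 dp
(GRAVY), matching print conventions rather than banker's rounding.

GRAVY (grand average of hydropathy) is the mean Kyte–Doolittle value per
residue and serves as the retention-time-similarity proxy when scoring
pairs. Known limitation: the published method sheet's hydrophobicity
column follows Kyte–Doolittle for the ALB/DBP analyte rows (0.17, 0.13,
0.69, 0.64, 0.17) but not for several other rows (e.g. TSALSDK prints
0.56 where Kyte–Doolittle gives −0.59); the scale used for those rows is
not recoverable, so this package uses Kyte–Doolittle uniformly and the
tests pin only the reproducible values. Two printed product ions are
similarly inconsistent with their labels — ILESTLK "448.3 [y5]" computes
as the y4 ion, and DHHVLLGTTYR "299.2 [y5]" as the doubly charged y5 —
and are tested as such.

## Surrogate-pair design

1. **Digest** both species' proteins.
2. **Species specificity**: a peptide is usable iff its sequence occurs
   exactly once in its own species' digest index (proteotypic) and never
   in the other species' index. This is an absolute filter: no emitted
   pair may cross species.
3. **Homology anchoring**: the two proteins are globally aligned
   (BLOSUM62, gap open 10, extend 0.5, end gaps penalized — standard
   protein-alignment parameters; the published identity percentages are
   aligner-dependent and are not targets). A surrogate peptide is a
   candidate for a target peptide when at least half of the target's
   aligned positions fall inside the surrogate's span
   (`overlap_threshold = 0.5`, admitting small indel shifts while
   rejecting unrelated peptides). Sub-threshold overlaps are reported
   with a `low_homology` flag rather than silently dropped.
4. **Isobaric screening**: a pair is excluded when either peptide has no
   interference-free transition against the assay background (default:
   the union of both species' digests of the panel proteins; a full
   matrix proteome FASTA can be screened instead). A transition
   conflicts when a background peptide's precursor falls within
   `precursor_tol` AND any of its b/y products within `product_tol`;
   defaults are 0.7 Da on both, the unit-resolution quadrupole window.
5. **Scoring**: surviving pairs get
   `score = w_len·|Δlength| + w_gravy·|ΔGRAVY| + w_sub·substitutions`
   (defaults 1, 1, 0.25; lower is better), ranked ascending with
   deterministic tie-breaks. The weights express the design doctrine that
   the surrogate should co-elute (GRAVY), fly similarly (length) and
   differ in sequence only as far as needed for m/z separation.
   Empirical instrument-response ranking is deliberately a pluggable
   no-op hook: detectability prediction is an external concern.

## Transition design

Candidates are the cross-product of requested precursor charges (default
{2+}), series (default {y}) and fragment indices. Role assignment takes
the top-ranked unconflicted candidate as the quantifier and the next
`n_qualifiers` (default 3) as qualifiers; the default ranking prefers
y-ions, then longer fragments, then lower product charge. Collision
energies are instrument-specific pass-through metadata. Exports are plain
CSV with m/z at 4 dp and round-trip through the provided reader.

## Calibration validation

The calibration model is a straight line of peak-area ratio
(analyte/IS) on nominal concentration, fitted per analysis by least
squares. Replicates enter as individual observations by default — the
intercept dispersion that feeds the detection limit needs raw replicate
scatter, not level means — with a means-per-level mode available to mirror
published calibration plots. Optional 1/x and 1/x² weighting handles
heteroscedastic data (requires positive nominals). R² is the (weighted)
coefficient of determination; a single-level design raises a degenerate-
design error.

Lower limits follow the ICH Q2 intercept-dispersion construction:
σ is the sample SD (n−1) of the per-analysis y-intercepts, S the mean
slope, LLOD = 3.3σ/S and LLOQ = 10σ/S (at least 3 replicate analyses by
default). A residual-based σ is a documented alternative but not the
default, because the multi-analysis intercept SD is what the plural
"y-intercepts of the regression lines" denotes.

Acceptance rules are applied verbatim: per level, mean back-calculated
recovery, %CV and %RE must all sit within ±15%, relaxed to ±20% at the
LLOQ-level calibrator (by default the lowest nonzero level); an analysis
passes when at least six nonzero calibrators pass. QCs use ±15% at every
level. Zero calibrators are excluded from recovery statistics (recovery
against zero is undefined). Failed calibrators are reported, never
automatically dropped and refitted.

Method comparison uses the two-sided Wilcoxon rank-sum test per sample:
the exact distribution when the combined sample is tie-free and n ≤ 20,
otherwise the normal approximation with tie correction; significance is
flagged at 0.05 and 0.01. A paired signed-rank mode exists for
replicate-paired designs. Samples with fewer than two replicates per
method get a diagnostic note instead of a p-value. No multiple-testing
correction is applied.

## Synthetic data

The generator emulates replicate calibration analyses and study samples
with the statistical structure the method assumes:

- ratio = (slope·nominal + intercept)·exp(ε), ε ~ N(0, `noise_cv`) —
  multiplicative lognormal noise, because peak areas are positive and
  instrument precision is relative;
- a per-sample digestion efficiency d ~ exp(N(0, `digestion_cv`)), drawn
  once per sample and shared between the analyte and a co-digested matrix
  IS but **not** a post-digestion SIL spike. The ratio therefore cancels
  d exactly in matrix mode and carries it in SIL mode — the normalization
  property that motivates matrix internal standards.

Defaults are the study conditions used throughout: nine calibrator
levels 0.49–1000 fmol on column, 3 replicates, 4 analyses, QCs at
32/125/600 fmol, `noise_cv = 0.05`, `digestion_cv = 0.15`. Slope
(0.005 ratio/fmol), intercept (0.01 ratio) and IS area (10⁵ counts) are
this package's choices, giving a ratio of ~5 at the top calibrator and a
blank-equivalent intercept of ~2 fmol. Seeds are explicit arguments;
there is no global random state and identical seeds give byte-identical
tables.

A consequence worth knowing: because the noise is multiplicative while
the default fit is *unweighted*, the top calibrators dominate the
intercept estimate, its cross-analysis SD lands around 1–2 fmol
equivalent, and the sub-15-fmol calibrators of a typical simulated plate
fail their recovery bands — most default plates fail the ≥6-calibrator
rule outright. That is the textbook symptom of unweighted regression on
relative-error data spanning three decades, reproduced on purpose. With
the inverse-variance-appropriate `1/x` or `1/x²` weighting the same
plates yield LLOD ≈ 0.2 fmol (below the lowest calibrator) and every
analysis passes — the regime validated assays of this design report.
The Monte-Carlo acceptance checks use the unweighted default and its
matching analytic oracle.

What the generator does **not** emulate: chromatographic peak shape and
integration, ionization suppression, carryover, between-lot matrix
variation, calibration nonlinearity, and correlated (run-order) drift.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated noise model, not robustness of a real assay.

### Numerical and statistical checks

Monte-Carlo checks in the test suite run at these problem sizes: 500
seeded plates for slope/LLOD calibration, 200 seeds × 24 samples × 3
replicates for the IS-mode contrast, 1,000 random peptides for the mass
identities, and a 200-peptide background for the all-pairs isobaric
oracle. The analytic LLOD oracle combines the delta-method SD of the OLS
intercept under the lognormal noise model, the c₄(4) correction for the
expectation of a 4-sample SD, and the exp(σ²/2) lognormal mean factor on
the slope; agreement is asserted within two Monte-Carlo standard errors.
At `digestion_cv = 0.05` — equal to the measurement noise — the IS-mode
CV ordering is asserted on the 200-seed mean (plus ≥95% per-seed wins),
since per-seed strictness at that operating point fails occasionally by
pure sampling noise; at `digestion_cv ≥ 0.15` it is asserted per seed.

## Known limitations

- Criterion "instrument response" from empirical/ML detectability tools
  is out of scope (hook only), as are UniProt fetching, PTM-aware
  quantotypicity screening, retention-time prediction, spectral-library
  intensity ranking and vendor method files.
- Identity percentages of protein alignments depend on the aligner and
  sequence versions; only the gap-free peptide correspondences are
  load-bearing.
- Unit bridging between prepared concentration (fmol/μL) and on-column
  amount is the caller's responsibility; nominal values are opaque labels
  with user-declared units.
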