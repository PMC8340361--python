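# Methods

## The model

PX domains read the phosphoinositide (PIP) code through a conserved surface
made of three sequence elements: the membrane-insertion loop between the β1
and β2 strands (site 1), the β3 strand running into helix α1 and carrying
the PIP-coordinating RRY motif (site 2), and the long loop containing the
proline-rich element before helix α2 (site 3). The package treats these
sites as inclusive column windows on a superfamily alignment, so that every
residue of every aligned domain classifies deterministically as inside one
site or outside all three. A modification of a Lys/Arg sidechain inside a
site (a candidate MET-stop) or a phospho-site on Ser/Thr/Tyr there (a
PIP-stop) is positioned to block headgroup coordination and membrane
insertion.

Three indices summarize each domain:

* **LSI** = 10 − n₁ − 2·n₂ over a two-class PIP scheme (mono vs poly ring
  phosphates), where the domain's class is the strict majority class of its
  ligand set, n₁ counts additional in-class ligands and n₂ out-of-class
  ligands. Ties between the classes are provably symmetric — when mono and
  poly counts are equal the two candidate values 10−(m−1)−2p and
  10−(p−1)−2m coincide — so no tie-break rule is needed beyond labeling the
  result `tie`; the package verifies this exhaustively over all 2⁷ ligand
  subsets. Empty sets score 0; any nonempty set scores in 1..10.
* **MSS / PSS**: per domain, modification records are first pooled by
  (protein, species, residue number, modification type) with study counts
  merged by maximum, so one study never counts twice for one modification;
  each pooled modification whose residue classifies as in-site then adds an
  evidence weight of 1 (single study), 2 (2–4 studies) or 3 (≥5 studies).
  Cross-species records contribute by default on the assumption that
  homolog evidence shares the domain's residue numbering — homolog
  modification of the same conserved residue is evidence that the site is
  modifiable — and a `same_species_only` switch restricts scoring to one
  species when that assumption fails.
* **MAI**: S / W / N by affinity category, with a numeric dissociation
  constant cut at 1 µM between S and W. The underlying evidence is only
  categorical ("roughly nanomolar / micromolar"), so the 1 µM boundary is a
  convention chosen to make the classifier deterministic.

## Statistics

The battery runs five simple regressions (PSS~MSS, PSS~LSI, MSS~LSI,
expression~MSS, expression~PSS) with their matching Pearson correlations,
selectivity/MAI class tallies, and a paired t-test comparing the proportion
of modified K/R residues inside vs outside the sites. Conventions:

* Missing values are deleted pairwise per analysis, not listwise; on the
  packaged table this yields n = 50 for analyses not involving LSI and
  n = 49 for those that do (one domain's ligand set is undetermined). Every
  exclusion is recorded in the report notes.
* All p-values are two-sided. For simple OLS, F = R²/((1−R²)/(n−2)) on
  (1, n−2) df, which equals the square of the correlation's t statistic, so
  the reported R² always equals the matching r² (asserted to 1e−10 in the
  tests).
* The inside/outside quantity for the paired test is (modified K/R
  residues)/(total K/R residues) within each region, counted over unique
  residue positions. This normalization is the natural reading of a
  "proportion of modified residues" but is a reconstruction: other
  denominators (e.g. per-column rates) are conceivable, and the packaged
  data do not include per-domain outside-site inventories, so the paired
  test is exercised and calibrated on synthetic data only.

## Packaged data

The curated human PX-domain feature table has 50 rows (both NOXO1 splice
forms), of which one (PXDC1) has undetermined ligands/LSI/MAI, three are
non-binders with empty ligand sets and LSI 0, and two (SNX30, SNX33) carry
LSI values inferred from their closest characterized relatives, flagged
with an `lsi_inferred` note. Undetermined cells are a typed sentinel
(`None`), never zero, so the undetermined row drops out of LSI-dependent
statistics without perturbing the MSS/PSS columns. The modification table
holds 86 records in flanking-nonamer notation (modified residue lowercase
at position 5 of a 9-mer, `-`-padded at termini). Study counts per
modification are not part of the published record, so the packaged table
carries the default of one study per row and the weighting rule is
exercised on synthetic and user-declared counts.

Because "number of modified residues" depends on the counting unit, the
package reports both conventions side by side (unique residue×species:
80, of which 45 human; unique residue×species×type: 86, of which 50 human)
rather than asserting either.

The default site windows shipped as YAML (columns 30–45, 57–75, 95–117 of a
~140-column superfamily alignment) are a reconstruction from the structural
description of the consensus docking area; the exact alignment columns used
in the original curation are not published. Consequently MSS/PSS
recomputation from raw modification tables is validated against synthetic
planted truth, not against the packaged score columns, and users aligning
their own sequences should supply windows matched to their alignment. The
membrane-propensity profile (per-residue docking scores, threshold 30,
strict inequality) is an optional input consumed from CSV; the predictor
producing such scores is external and all scoring and statistics run
without it. In SNX5/SNX6/SNX32 the site-1 loop is a protein-binding rather
than membrane-insertion element; the default still counts it as a window
(the uniform alignment rule), and a per-domain masking can be achieved by
passing windows with that site moved off the domain's columns.

## Synthetic data

`SynthConfig` defaults define the study conditions: 50 domains of length
120 (PX-domain scale), three site windows jointly covering 25% of columns,
K/R density 0.3, a 10% chance that an outside K/R carries a reported
modification, threefold enrichment inside sites, and study counts from a
unit-shifted Poisson(1) — skewed like citation counts while keeping all
three weight bins reachable. One integer seed drives a single generator
threaded through all draws, making emitted files byte-reproducible.

The generator emulates: site-enriched K/R modifications with correct
flanking nonamers cut from the true sequences, and feature tables drawn
from a latent Gaussian with a target correlation matrix (defaults
approximate the relationships observed in the curated table), discretized
to nonnegative integers (MSS/PSS), 0–10 integers (LSI) and zero-truncated
reals (expression). The truth record stores the *latent* sample
correlations because discretization and zero-truncation attenuate the
observable ones (a target of 0.40 on the MSS/PSS pair shows up as ≈0.34 in
the integer columns at the default margins); recovery tests therefore
check the latent scale and only bound the attenuated observable.

What the generator does not emulate: real alignments with gaps (synthetic
domains are generated ungapped and equal-length), phylogenetic structure
among homolog records, composition biases of real PX sequences, and any
dependence of modification probability on structural context beyond the
inside/outside dichotomy. Passing calibration tests therefore demonstrate
correctness of the pipeline's bookkeeping and the test's nominal behavior
under the stated sampling model — not that real modification data meet
that model.

Calibration of the paired t-test samples the sufficient binomial counts of
the same per-position model directly (vectorized over replicates; the
per-replicate t values are asserted identical to the reference paired-test
implementation). At the defaults, the type-I error over 1000 null
replicates sits within 0.05 ± 0.02 and power at threefold enrichment
exceeds 0.8 over 500 replicates; both checks run in well under a second.

## Numerical and design choices

* Ligand codes are stored exactly as curated (`"345"` for PI(3,4,5)P₃),
  with a normalizer accepting long names; serialization orders codes by
  (length, value) so table round-trips are byte-identical.
* Flank parsing is strict: exactly one lowercase letter, at the center.
  Sequence anchoring is pad-tolerant at termini; a record whose flank fails
  at the stated position but matches elsewhere raises an ambiguity error
  listing the candidate positions rather than guessing.
* Degenerate statistical inputs (zero variance, fewer than 3 pairs, all
  differences zero) raise a typed error instead of returning NaNs; the
  battery collects per-analysis failures and only aborts when nothing is
  computable.
* Two curated reference statistics for this dataset are mutually
  inconsistent with the table's own columns (the MSS–LSI correlation and
  the expression-on-MSS slope); the battery reports the values the columns
  force (0.0855 and 3.7153), which are consistent with every other
  reference statistic to printed precision.

## Known limitations

The site windows are alignment-dependent and the defaults are a
reconstruction; stop scores computed with them are comparable within one
alignment, not across alignments. Study-count weighting saturates at 3, so
heavily studied modifications are deliberately not dominant. The MAI
classifier reduces heterogeneous binding evidence to three labels with a
fixed 1 µM cut. The paired t-test treats domains as independent, ignoring
phylogenetic relatedness of paralogs.
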