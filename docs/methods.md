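# Methods

## Problem and model

A pre-miRNA is a ~60–150 nt RNA that folds back on itself into a stem–loop.
Dicer excises a miRNA:miRNA\* duplex from the stem; the mature miRNA is one
strand of that duplex, the star strand pairs with it on the opposite arm,
and the excision leaves a 2-nt 3′ overhang on each strand. The modelling
assumption throughout the package is that *the duplex carries the signal*:
what distinguishes a real mature miRNA from an arbitrary same-length window
of the same hairpin is the local structure of its duplex (pairing density,
bulge geometry, stability, position relative to the terminal loop) much more
than its primary sequence. The classifier is therefore trained on candidate
intervals described by 100 duplex-centric features, with negatives drawn
from the *same* hairpins by random relocation, so hairpin-level properties
cancel and only the positional/duplex signal remains.

Two user-facing operations derive from one scoring function. Validation
scores a given interval and thresholds it (default 0.5; the threshold is a
parameter, not a property of the model). Prediction scores all
(start, length) candidates with 16 ≤ length ≤ 30 and picks the interval
maximizing the positional consensus S(p) + E(p+l−1), where S sums candidate
scores over lengths at a common start and E sums them over candidates with a
common end. Consensus aggregation uses plain sums by default; a `mean` mode
(dividing by the number of contributing cells) is exposed because the
normalization is a genuinely open design choice — on the synthetic corpus
the two agree in the large majority of hairpins, and the sum is kept as the
default. Ties in the argmax go to the smaller start, then the smaller
length, making prediction fully deterministic.

The selected interval's star is derived from the structure: the star spans
the partners of the candidate's first and last paired bases, extended by
2 nt at its 3′ end (the overhang) and clamped to the hairpin. Both intervals
are scored and the higher-scoring one is reported as the miRNA, the other
as the miRNA\*. Localization error against an annotation is the minimum
distance of either reported interval to the truth, computed separately for
starts and ends, because an annotation may sit on either arm of the duplex.

## Secondary structure

Structures are accepted from the input (Vienna dot-bracket, one line per
record, optional trailing energy) or computed. Two folding backends exist:

- **external** — any RNAfold-compatible executable, used verbatim with
  default parameters; RNAduplex, when present, supplies the duplex MFE.
- **builtin** — a deterministic maximum-weight pairing dynamic program
  (weights GC=3, AU=2, GU=1; minimum hairpin loop of 3; among equal-weight
  pairings the traceback returns the lexicographically smallest pair list,
  i.e. prefers 5′-most pairs). Its negated pairing score serves as a
  pseudo-energy, and −(3·GC + 2·AU + 1·GU) over paired candidate positions
  serves as the duplex-energy surrogate.

The builtin folder exists so that every code path is testable and
reproducible with no external binary; the test suite pins it. It is a
combinatorial, not thermodynamic, model: it maximizes weighted pair count,
not free energy, and equal-weight optima of repetitive sequences can differ
from the "intended" nested stem. Pairing masks for feature extraction are
always read from the hairpin's global structure restricted to the
(miRNA, star) intervals, so that validation and prediction see the same
pairing regardless of backend; an external duplex co-fold only refines the
energy feature.

Terminal-loop resolution in multiloop precursors is underdetermined by the
published description; the rule here is: among all hairpin loops (maximal
unpaired runs closed by a pair), take the one nearest the candidate
midpoint, ties toward 5′. A structure with zero pairs has no loop; features
then fall back to treating the whole sequence as loop, and a fully unpaired
candidate receives an all-false pairing mask with a star reflected about the
loop midpoint — degenerate but featurizable, which matters because relocated
negatives do land in unstructured regions.

## Features: conventions and degenerate cases

- Frequencies are fractions: mono-, di- and triplet-frequency blocks each
  sum to 1; first/last-nucleotide indicator blocks are one-hot.
- Triplets use the *global* structure's pairing status at the candidate's
  interior positions, with both bracket orientations collapsed to "paired";
  contexts are normalized by (length − 2).
- Sliding-window pairing means average over all windows fully inside the
  candidate and are fractions in [0, 1].
- With zero paired positions, all pairing and pair-type features are 0 and
  the perfect-stem start positions are −1 ("no such region").
- Coordinates are 0-based half-open internally and 1-based inclusive in all
  user-facing output.
- T is normalized to U and case is raised; any other character is an error.

Feature ranking uses information gain with continuous features discretized
into 10 equal-frequency bins (the bin count is exposed); ties are broken by
registry order.

## Classifier

AdaBoost.M1 in reweighting mode (SAMME), 10 rounds, over random forests of
50 trees with unlimited depth and √100 = 10 features per split; no
resampling cutoff (all weighted examples are kept every round). The reported
score is the boosting-weighted fraction of rounds voting positive,
normalized by the total boosting weight — a bounded [0, 1] vote score, not
a calibrated probability. Training, fold assignment and scoring are
deterministic given the base seed. Evaluation uses stratified 10-fold CV
with pooled out-of-fold scores: confusion counts at threshold 0.5 give
SE/SP/ACC/MCC (MCC defined as 0 when a denominator factor vanishes), and
AUC is computed from the pooled scores (equivalently, the normalized
Mann–Whitney U with ties counted half).

## Synthetic generator

The generator plants an explicit duplex: 5′flank + miRNA + loop + star +
3′flank, with the star the reverse complement of the miRNA carrying
per-position mismatches (both strands unpaired there) at `mismatch_rate`
and unpaired single-base insertions at `bulge_rate`. The intended
dot-bracket is emitted with each record, so dataset-level tests are
independent of any folding backend, and the planted interval is the truth.

Defaults (chosen once as a realistic animal-like regime): miRNA length law
over 19–24 nt with mode 22 (probabilities .05/.12/.20/.35/.18/.10), loop
8–15 nt, flanks 5–20 nt, mismatch 0.10, bulge 0.05, GC 0.50. Per-record RNG
substreams are derived from (seed, index), so output is bitwise stable and
order-independent.

What the generator does **not** emulate: folded flanks (flanks are emitted
unstructured, whereas real flanking sequence pairs partially), multi-branch
precursors, asymmetric bulges on the miRNA strand, sequence biases of real
miRNAs (e.g. the 5′-U preference), and lineage structure. Consequently,
passing the synthetic recovery tests demonstrates that the pipeline learns
and localizes a planted duplex signal under controlled noise — it does not
certify accuracy on real miRBase data, where published-scale training is
required.

## Problem sizes and thresholds

The parameter-recovery evaluation uses 400 training hairpins at mismatch
rate 0.02 (800 balanced examples) with 10-fold CV, and a disjoint 100-hairpin
held-out set for localization; these sizes run the whole acceptance script
in well under a minute on one core. The acceptance thresholds — CV accuracy
≥ 0.85 and median |Δstart| ≤ 2 nt — were calibrated once by a pilot run
(which gave ≈0.99 and 0) and then frozen. The unit-test corpus is smaller
(60 hairpins, reduced forests) purely to keep the suite fast; the model
defaults are unchanged.

## Known limitations

- The builtin folder is a maximum-weight pairing model; energies are
  surrogates in pseudo-kcal/mol and not comparable to thermodynamic MFEs.
- The vote-fraction score is uncalibrated; threshold 0.5 is a convention.
- Star derivation requires at least one paired candidate position; the
  reflected-interval fallback for fully unpaired candidates is a featurization
  device, not a biological claim.
- Mature-to-hairpin matching from miRBase-layout FASTA is by exact substring
  (the format carries no coordinates); multi-occurrence matures take the
  5′-most hit, and duplicates are collapsed by (hairpin, start, length).
- `fetch-mirbase` is a network convenience and is deliberately outside the
  tested surface.
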