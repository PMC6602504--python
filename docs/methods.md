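# Methods

## Problem and model

Class A G-protein coupled receptors (GPCRs) transduce extracellular signals
by coupling to heterotrimeric G-proteins whose α-subunits fall into four
families (Gs, Gi/o, Gq/11, G12/13).  Quantitative coupling data come from a
chimeric-Gα shedding assay: eleven chimeras, each a GNAQ backbone whose last
six residues are replaced by another Gα's C-terminus, are co-expressed with
a receptor and a dose–response curve yields Emax and EC50 per (receptor, Gα)
pair.  The package turns those endpoints into coupling indices and learns,
per Gα, a binary classifier that predicts coupling from receptor sequence
alone.

**Coupling index.**  For one receptor, the activity ratio Emax/EC50 is
normalised by its maximum over the Gα panel (relative intrinsic activity,
RAi) and log10-transformed:

    LogRAi = log10( (Emax/EC50) / max_g (Emax/EC50) ),  clamped to [-2, 0].

The maximal chimera is exactly 0; the clamp realises a 100-fold linear
dynamic range.  LogRAi ≥ −1.0 (inclusive) calls a coupling.  The clamp
floor is a design choice: the index's stated range is [−2, 0] and values
below are floored rather than discarded.  Replicate records for the same
(receptor, Gα) are averaged on the Emax/EC50 ratio before normalisation.
Ties for the per-receptor maximum are allowed (several chimeras at 0).

**Features.**  The training receptors share one multiple alignment.  For a
given Gα the alignment splits into coupled and not-coupled sub-alignments,
each summarised as a profile HMM (consensus columns at symfrac 0.5,
inclusive).  Features per receptor are:

* *positional* — columns consensus in both profiles where the 20 paired
  residue bit-scores (log2 emission/background) differ by Wilcoxon's
  signed-rank test, p ≤ 0.05.  The pairing unit is the 20 amino-acid
  bit-scores of one column; zero differences are dropped and the exact null
  distribution is used whenever the non-zero |differences| are tie-free.
  Each selected column contributes the query residue's bit-score from
  *both* profiles (two values).
* *indel* — columns consensus in exactly one profile, contributing the
  single available bit-score.
* *loop* — ICL3 and C-terminal length plus 20 per-residue counts per
  region, retained when a two-sided rank-sum test gives p < 0.05 (strict,
  matching the printed inequality; the positional threshold is inclusive).
  Counts are raw; frequencies are available behind a flag.
* *structural* (optional) — per template complex, the permutation Z-score
  of an interface statistical potential (below), included for a Gα only
  when coupled and uncoupled training Z-scores differ (rank-sum p < 0.05).

A query with no residue at a selected column receives the *least conserved*
sentinel — the minimum residue bit-score of that column in each profile.
(The source description of this rule is internally contradictory under the
standard bit-score orientation — "highest bit scores … implying the least
conserved" — we implement the stated intent, least conserved, which is the
minimum.)  Indel features are bit-score-valued when a residue is present,
not binary indicators.

Helix positions are reported in Ballesteros/Weinstein numbering: label
`h.(50 + offset)` relative to each helix's x.50 anchor column, given by a
reference table (helix, start, end, anchor); positions outside the helices
fall back to the raw 1-based column in parentheses.  ICL3 is defined as the
columns between the TM5 and TM6 ranges of that table; the C-terminus is
everything after the last TM7 consensus column.

**Classifier.**  Per Gα, binary L2-penalised logistic regression

    min_{w,c}  (1/2) wᵀw + C Σ_i log(1 + exp(−y_i (x_iᵀw + c))),  y ∈ {−1, 1}

with features min-max scaled to [0, 1] (constant features map to 0;
prediction-time values are clipped into [0, 1]) and classes weighted
inversely to frequency.  C is selected by grid search (10 logarithmic
points in [1e−3, 1e3]) over stratified 5-fold cross-validated ROC AUC; the
whole CV repeats ten times with fold seeds derived from the master seed by
fixed arithmetic, and the reported CV AUC is the mean ± sd over repeats.
Ties in AUC resolve to the smallest C (strongest regularisation).  The
optimiser is scikit-learn's lbfgs with tight tolerance: it leaves the
intercept unpenalised, exactly matching the cost above, and satisfies its
first-order conditions to gradient norm ≤ 1e−6 (verified against a
from-scratch gradient-descent oracle in the tests).  By default the scaler
is fit inside each CV training fold (leak-free); a "global" mode that
scales the whole matrix before CV is available for parity with pipelines
that do so.  Feature relevance is the trained weight vector ranked by
|weight|; a label-randomisation test (class-count-preserving permutations,
full retraining) probes over-fitting.

**Prediction.**  Queries are aligned to a base profile built from the whole
training alignment; sequences scoring below a reporting floor (default 0
bits) are returned as non-family with no probabilities.  Features are
extracted per Gα schema, scaled with the stored bounds and passed through
P = (1 + e^{−(wᵀx+c)})⁻¹; P > 0.5 (strict) calls a coupling.  Per-feature
contributions (weight × scaled value) sum to logit(P) − intercept exactly.
Model artifacts carry a fingerprint (SHA-256 of the canonical schema and
profile serializations) checked at load and predict time.

**Design mode.**  Residues mapping to the positional-feature columns of the
selected Gα models are each substituted into the 19 alternative amino
acids; mutants are re-predicted end to end.  ΔP(coupled) = P(mut) − P(WT)
and ΔP(uncoupled) = −ΔP(coupled); candidates pass when the relevant
difference reaches the threshold (default 0.25) and are ranked by the best
qualifying difference, ties broken by position then residue.  Indel and
loop regions are not scanned: point substitutions cannot express length
changes.  Combinatorial multi-mutation design is out of scope.

## Profile HMM implementation

A reduced plan7 architecture: one match/insert/delete node per consensus
column, all nine inter-state transitions estimated from the alignment with
Laplace pseudocounts (α = 0.1 on emissions and transitions; external HMM
packages use richer Dirichlet-mixture priors, so numeric parity with their
bit-scores is not claimed — only the contract: consensus columns, emission
bit-scores, glocal alignment).  The background is uniform (1/20),
overridable.  Decoding is Viterbi in log2-odds space, glocal: every node is
traversed (match or delete), every query residue matched or inserted;
insert states emit the background and so score 0 bits.  Ties prefer match >
delete > insert, making decoding deterministic.  On profiles small enough
for exhaustive path enumeration the decoder provably attains the optimum
(tested).  Coordinates are 0-based half-open internally; 1-based only in
rendered reports.  Inputs are upper-cased; B/J/Z/X/U/O map to an "unknown"
residue emitting the background.  An adapter seam (any aligner producing
the same `ProfileAlignment` contract) allows substituting an external
implementation.

## Interface statistical potential

The raw score of a receptor/Gα pair against a template complex is the sum
of a 20×20 residue-pair potential over the template's interface contacts
(residue pairs with any heavy-atom pair within 5.0 Å), read through
alignments of the query sequences to the template chains; contacts with an
unaligned or gapped side are skipped.  Significance uses a permutation
null: the receptor's aligned residues are shuffled over its aligned
positions (the Gα side is fixed — chimeras differ only in a short tail;
the scheme is switchable), z = (raw − mean)/max(sd, 1e−9) and
p = (1 + #{null ≥ raw})/(n_perm + 1) with n_perm = 100 by default.  The
shipped potential for tests is a synthetic symmetric log-odds-like table;
externally derived potentials can be supplied as TSV.  When several
templates are suitable for one Gα each contributes its own feature column.

## Synthetic data generator

The generator emulates the training conditions: by default 144 receptors,
the 11-chimera Gα panel, 60 consensus columns in seven helix blocks with a
two-column ICL3 stub, a variable ICL3 (Poisson lengths, class-linked means
28/10 for the GNAS loop effect) and C-terminal tail (Poisson mean 8),
sparse random gap runs (rate 0.02), and two strong determinants
(effect 0.9) for one representative Gα of each family.  Labels are drawn
first (Bernoulli(coupled fraction), deterministic given the seed);
determinant residues are planted conditioned on the label with probability
1/20 + effect·19/20, so the between-class frequency margin is effect·19/20
and vanishes at zero effect.  Non-determinant columns draw from a
class-balanced conserved background (one preferred residue per column,
probability 0.6): conservation anchors profile alignment as in real 7TM
families while introducing no composition difference between classes.
Insert regions are realised as low-occupancy column pools (each receptor's
loop residues occupy a sorted random subset), so the emitted alignment has
*exactly* the configured number of consensus columns at symfrac 0.5.
Simulated assays place coupled pairs at the receptor maximum and uncoupled
pairs exactly dynamic-range-fold (default 100) lower before log-normal
noise (default 0.15 decades), then split the ratio into an EC50
(log-uniform, ~3–300 nM) and matching Emax.

What the generator does **not** emulate: real GPCR phylogeny and
substitution processes, correlated determinants, family-specific loop
compositions, receptor-specific assay ceilings, or partial agonism.
Passing tests therefore demonstrate the machinery's correctness and its
power under idealised signal, not real-data performance.

## Numerical choices and degenerate inputs

* Wilcoxon signed-rank: zero differences dropped; exact distribution only
  when tie-free, else normal approximation.  Zero-variance loop candidates
  are dropped.
* Scaling: constant features map to 0; prediction-time clipping into
  [0, 1].
* Permutation Z: sd floor 1e−9; constant nulls give z = 0, p = 1.
* CV requires each class to have at least as many members as folds; Gα
  violating this are skipped with a report entry, not silently dropped.
* Viterbi tie-break (match > delete > insert) and the design-scan
  tie-break (position, then residue) make all outputs deterministic given
  the seed.
* The acceptance script and the test suite use a scaled-down family
  (120 receptors, 44 columns, 3 determinants for one Gα) for the recovery
  and classifier studies; the generator's defaults remain the full-scale
  conditions.

## Known limitations

* The profile aligner is glocal-only: no multi-domain search, no forward/
  posterior decoding, no E-value calibration.
* Structural features are optional and validated on synthetic fixtures;
  published interface potentials and real template complexes are an ingest,
  not included.
* On cleanly separable synthetic data the smallest-C tie-break yields
  heavily regularised models whose probabilities compress toward 0.5;
  rankings (AUC, design ordering) are unaffected, but absolute ΔP
  thresholds are conservative in that regime.
* B/W anchors are an input table; they are not derived from conservation.
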