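# Methods

`coevdimer` classifies pairs of protein families ("dimers") as
physically interacting or not, using nothing but sequence information:
inter-protein residue covariation summarized into per-dimer scalar
features and fed to a support-vector machine.

## Model and procedure

**Input unit.** A dimer is a pair of multiple sequence alignments, one
per family, with rows matched one-to-one by species and listed in the
same order. Alignment columns at which the query sequence has a gap are
assumed removed upstream, so alignment width equals query length.
Sequences use a fixed 21-letter alphabet: 20 amino acids plus the gap
symbol, which is counted as an ordinary 21st state throughout.
Ambiguity codes (B, Z, X, U, O, J) are folded onto the gap symbol at
parse time — the alphabet is fixed at 21 states and no other rule is
defensible without per-code frequency conventions.

**Exposed-residue restriction.** Interfaces form on protein surfaces,
so covariation is computed only between solvent-exposed columns. Each
query position carries a relative accessible surface area (RSA) in
[0, 1], averaged position-wise over one or more sequence-based
predictor profiles supplied as TSV. A column is exposed at threshold
*t* when RSA > *t*, strictly: at *t* = 0 only positions with RSA
exactly 0 are dropped, and a value equal to the threshold is buried.
The ladder of ten thresholds (0.0, 0.05, 0.15, 0.2, 0.25, 0.35, 0.45,
0.55, 0.65, 0.75) produces ten nested exposed-residue MSA (ER-MSA)
pairs per dimer. RSA is treated as relative, never absolute Å²;
callers must pre-normalize absolute values.

**Covariation scores.** For exposed column *x* of family A and *y* of
family B (over the N matched rows):

- MI(x, y) = H(x) + H(y) − H(x, y), entropies from raw relative
  frequencies over the 21 symbols with logarithms base 21, so all
  quantities live in [0, 1]. No pseudocounts, no sequence weighting.
- Normalized MI (nMI) divides by the joint entropy; 0/0 → 0.
- CLR z-scores each nMI entry against its row distribution and its
  column distribution (mean and *population* standard deviation over
  the full rectangular matrix, no diagonal exclusions — the matrix is
  rectangular and has no meaningful diagonal), clips negatives to zero
  and combines the two by root-sum-square. σ = 0 makes its z-score 0.
- MIp subtracts the average product correction
  APC(a, b) = (row-a mean)(column-b mean)/(overall mean); an all-zero
  matrix maps to zero. MIp is applied to nMI by default so the CLR and
  MIp branches share one input; `mip_on_raw=True` restores the
  original raw-MI formulation. The choice matters little in practice
  because nMI is a monotone per-entry rescaling, but it is recorded in
  every run's configuration.
- Any column with ≥ 80% gap characters is considered signal-free:
  every pair containing it scores exactly 0 in MI and nMI, and those
  zeros propagate into the CLR/MIp inputs.

All 0/0 conventions resolve to 0 ("no signal in, no signal out").
Tiny negative MI values produced by floating-point cancellation are
clamped to zero.

CCMpred (pseudo-likelihood DCA) is consumed, never re-implemented: its
square score matrix over the concatenated ER-MSA is parsed and the
rectangular inter-protein block trimmed out; an asymmetric input is
symmetrized by averaging the block with the transpose of its mirror.

**Feature construction.** Each matrix collapses to its Frobenius norm
√Σ|aᵢⱼ|². Squaring suppresses the many weak indirect couplings
relative to the few strong direct ones, so one scalar summarizes a
dimer at one threshold. Per-pair MI does not depend on which other
columns were retained, so the implementation computes one full-width
MI/nMI matrix per dimer and slices it per threshold; CLR and MIp are
recomputed per threshold because their row/column statistics change
with the retained set. Feature vectors are either a single threshold's
norm or a contiguous group of thresholds ending at 0.75 (0.0–0.75 down
to 0.65–0.75). Norms are left raw here; standardization belongs to the
classifier, fit on training data only.

**Classification protocol.** A stratified 30% of the dimers is held
out. On the remaining 70%, an RBF-kernel SVM
(k(aᵢ, aⱼ) = exp(−‖aᵢ − aⱼ‖²/2σ²)) is tuned by stratified ten-fold
cross-validation repeated over ten rotations of the fold assignment;
the tuned model is refit on the full 70% and evaluated exactly once on
the 30%. The tuning grid puts σ on {0.25, 0.5, 1, 2, 4} times the
median pairwise distance of the standardized training features and the
cost C on {0.1, 1, 10, 100}; both grids are configuration items
recorded in every report, and ties resolve deterministically to the
smaller C, then the smaller σ. Stratification is applied to both the
holdout and the folds to avoid degenerate splits at n = 166.
Evaluation reports the confusion counts and accuracy, sensitivity,
specificity, precision, FPR, NPV, FNR and bookmaker informedness
(BM = sensitivity + specificity − 1); any zero-denominator metric is
reported as NaN and named in an `undefined` list, never silently
zeroed. Norm distributions of the two classes are compared by a
two-sided Mann–Whitney U test flagged at α = 0.05.

## Dataset-construction gates

The filtration operations are reusable stand-alone: per-hit homolog
gates (subject length ≥ 80% of query, identity ≥ 40%, bit score ≥
0.5 × query length, e-value < 1e-4, alignment overlap ≥ 90% of query,
checked in that fixed order with the first failure reported), the
dimer-length gate L = √(l₁l₂) ∈ [90, 550] (removal applies strictly
beyond the boundaries, so both endpoints are kept), the depth gate
N ≥ 50, the N/L
shallowness descriptor, and GO-identity frequencies (fraction of
non-query rows sharing ≥ 1 term with the query per aspect, unusable
when > 15% of organisms are unknown). The relaxed "special cases"
policy (78%, identity 25/30/35%, 0.45×, overlap 70/80/85%) must be
selected explicitly by the caller; nothing triggers it automatically.
The bit-score length is read as the *query* length and overlap is
normalized by the query length; both are conventions, recorded here
because the alternatives (subject length) are equally defensible.
Outlier-row detection is out of scope; `drop_sequences` removes an
externally supplied exclusion list from both families while protecting
the query row.

## Synthetic data generator

The generator emulates the study conditions so the whole chain is
testable without any download: 83 positive + 83 negative dimers,
alignment depths uniform on [50, 950], per-family widths uniform on
[90, 180] (dimer lengths inside the [90, 550] gate; the upper end is
kept moderate so a replicate runs in seconds), per-cell gap rate 0.05
with a gap-free query row, per-column background residue distributions
drawn from a Dirichlet with concentration 0.5 (partially conserved
columns), and RSA values from a buried/exposed beta mixture
(0.35·Beta(2, 8) + 0.65·Beta(4, 2)) that keeps every threshold's
exposed set nonempty and strictly shrinking with high probability.

Positives carry planted covariation through a paired-state
substitution table: 30% of min(l₁, l₂) column pairs are coupled; each
row draws the family-A residue from the column background and, with
probability 0.9 (the coupling strength), the family-B partner is the
image of that residue under a pair-specific permutation of the 20
amino acids, otherwise it is drawn independently. Negatives are fully
independent. Both classes share every other distribution, so
covariation is the only separating signal. Everything is reproducible
from a single integer seed.

What this does *not* emulate: phylogenetic correlation between rows
(real MSAs are not i.i.d. samples), compositional biases, alignment
errors, paralog contamination, correlated conservation between
interacting surfaces, or structurally realistic interfaces. Passing
tests therefore demonstrate that the pipeline recovers planted
covariation under realistic dimensions and noise — not that real
dimers are classified at any particular accuracy.

## Numerical choices

- Entropies are computed from exact integer counts via
  H = (ln N − Σ c ln c / N)/ln 21 with a c ln c lookup table; the
  per-pair joint counting is a compiled (numba) kernel, and agreement
  with direct dictionary-counting references is required to 1e-12 in
  the tests.
- Population (ddof = 0) standard deviation in CLR.
- Matrix slicing per threshold is exact, not an approximation (per-pair
  scores are independent of the retained column set).
- Degenerate inputs: zero exposed columns raise an "empty interface"
  error rather than emitting an empty matrix; single-class label sets
  and fewer per-class samples than CV folds are rejected up front;
  fully tied Mann–Whitney inputs return p = 1.
- All randomness flows from explicit integer seeds (NumPy
  `default_rng`); reruns are bit-identical.

## Problem sizes used in the shipped checks

The test suite and the acceptance script regenerate everything at run
time: the discrimination checks use five seeded replicates of the full
default 83+83 set; the rank-sum null calibration uses 600 draws of
20+20 small dimers (widths 10–14, depth 50–60), sizes at which a
replicate costs milliseconds while the test statistic's null behavior
is unchanged; oracle-equivalence checks run on dimers with N ≤ 30 and
widths ≤ 8 where brute force is feasible.

## Known limitations

- The generator's coupling mechanism plants mutual information
  directly; global methods (CCMpred) are exercised only through the
  block-extraction adapter, not end to end.
- GO semantic similarity, proteome-scale screening, paralog matching
  and structure-based accessibility are out of scope.
- MIp-on-nMI versus MIp-on-raw-MI is an interpretation choice (see
  above); results for the two variants differ slightly.
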