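# Methods

This note documents the model and procedure implemented by `ptaref`, the
parameters that matter, the synthetic data used to exercise it, and the
design choices made where the design was genuinely open.

## Pipeline overview

A Type-I run processes each transcript × miRNA pair in four stages:

1. **Thermodynamic scan** → candidate sites under an energy cutoff;
2. **Refinement and encoding** → a 5-state interaction pattern per site;
3. **Library filter** → keep sites whose pattern lies within an edit
   distance of 0–4 of some experimentally derived library pattern;
4. **SVR scoring** → a signed regression score from the flanking-region
   dinucleotide density profile; positive = target.

## Duplex scanning and the energy model

The hybridization stage is pluggable. When an external hybridizer is
configured, its per-site records (position, energy, gapped duplex strings)
are parsed into `CandidateSite` objects. Otherwise the internal scanner is
used, with a nearest-pair energy model (kcal/mol):

| term | default |
|---|---|
| G:C pair | −3.0 |
| A:U pair | −2.0 |
| G:U wobble | −1.0 |
| mismatch | +1.0 |
| bulge open / extend | +3.0 / +1.0 |

These numbers are *configuration, not biology*: they are chosen so a
near-perfect ~21-nt duplex scores far below the default −10 kcal/mol
cutoff while short or heavily mismatched placements do not, and they are
fully overridable.

The scanner's search space is every **ungapped placement** of the miRNA
along the transcript plus every placement carrying a **single interior
bulge** on either strand. Under the penalties above a second bulge is
essentially never worth its cost, and restricting the space makes the
scanner exactly checkable against naive placement enumeration; it is
implemented with vectorized diagonal prefix sums over the per-column energy
table. A general global duplex aligner (`duplex_dp`, three-state affine DP
with deterministic tie-breaking: pair > bulge-on-target > bulge-on-miRNA)
is provided separately and verified against exhaustive alignment
enumeration. Overlapping candidate sites for the same miRNA are reduced to
the minimum-energy representative (greedy from lowest energy; ties by
start, then end). Site length is capped at 50 nt, the assumed maximum span
of a miRNA:target interaction.

## Pattern encoding and library matching

Each candidate site is re-aligned end-to-end against the reversed miRNA by
Needleman–Wunsch with *complementarity* as the reward: Watson–Crick pair
+5, G:U wobble +5+1, mismatch −4, affine gaps at −15 (first gapped column
of a run) and −5 (each further column). The wobble advantage and gap
penalties are the method's stated values; the pair/mismatch magnitudes are
EDNAFULL-like defaults — only their ordering shapes the trace — and are
configurable. Traceback ties break diagonal > gap-in-target >
gap-in-miRNA, so the alignment is deterministic.

The trace is reduced to one state per column: `M` (Watson–Crick), `W`
(G:U), `X` (mismatch), `T` (gap in the miRNA strand, i.e. a target base
bulges), `O` (gap in the target strand). Pattern similarity is unit-cost
**edit distance** rather than Hamming distance because patterns of
different lengths (extra bulges) must remain comparable; matching is
end-to-end against every library entry, minimum distance wins, ties go to
the earlier library entry, and a site survives the filter iff its minimum
distance is ≤ the user's mismatch level (0–4). Raising the level can only
grow the prediction set (monotone filter).

## Flanking-region features

Up to 75 nt on each side of the site is scanned with 20-nt windows at step
1 (56 windows per side, site-proximal first). Each window yields 16
overlapping-dinucleotide densities (count / 19; each window vector sums
to 1); the flattened layout is upstream block, downstream block,
dinucleotides lexicographic over {A,C,G,U} — 1792 features. Windows that
would run past a transcript end are zero-filled and the vector flagged
truncated, so near-terminal sites are scored rather than dropped. Features
are always recomputed from full-transcript coordinates, never from chunk
sequences, so parallel chunking cannot perturb flank content.

Two variation modes exist. The default `raw` mode uses the site-anchored
positional densities themselves. `delta_from_site` subtracts the density
vector of the site's own leading 20 nt from every window. The subtraction
looks attractive (homogeneous contexts map to exactly zero) but the
reference is estimated from only ~20 dinucleotide observations, giving it
a per-density sampling SD of about 0.05 — the same order as realistic
compositional contrasts — and that noise is injected identically into all
112 windows. Empirically this caps out-of-sample sensitivity at the zero
threshold near 0.84, versus ≈0.98 for the raw positional profile under
identical conditions, so `raw` is the default and `delta_from_site` is
retained for ablation.

Mean-distribution feature selection ranks features by
|mean₊ − mean₋| / pooled SD (zero-SD features last, ties by index) and is
available but not applied by default: on the synthetic signal it did not
improve the operating point.

## SVR scoring

Class labels are encoded as regression targets +1/−1 and an ε-SVR is fit
(ε = 0.1, C = 1 by default); classification is the sign of the regression
output and |score| is the confidence. Three kernels are exposed under their
user-facing names: `linear`, `gaussian` (RBF) and `polynomial` (degree 3).
Gamma defaults to the variance-scaled value 1/(n_features · var(X)) and
the polynomial kernel uses coef0 = 1: the density features have magnitudes
well below 1, and a fixed 1/n_features gamma with coef0 = 0 collapses the
polynomial kernel toward a constant. Scoring evaluates the kernel
expansion directly from the stored support vectors, dual coefficients and
bias, so a model saved to its versioned JSON archive (`ptaref-svr-1`)
scores bit-identically after reload, independently of the training
backend's internals. Training is deterministic for fixed inputs.

## Evaluation

Sn, Sp and Ac are percentages; MCC uses the standard four-factor
denominator and is reported as 0 and flagged undefined when any factor is
zero. The cross-validated ROC pools out-of-fold SVR scores from a seeded
stratified k-fold split (default 10) and integrates AUC by the trapezoid
rule — equal, by construction, to the pairwise Mann–Whitney statistic on
the pooled scores. Region benchmarking counts a prediction as true
positive when it overlaps a validated region on the same transcript by at
least 1 nt (configurable) and reports the percent of regions hit and the
percent of predictions falling outside every region.

One symmetry worth recording: complementing the class labels swaps Sn↔Sp
but leaves MCC invariant (numerator and denominator are both symmetric
under TP↔TN, FP↔FN); MCC is *negated* by inverting the predictions
(TP↔FP, TN↔FN). The tests assert both.

## Concurrency contract

A query sequence is chopped into at most `threads` chunks of ≥ 50 nt
overlapping by ≥ 50 nt. Because the overlap is at least the maximal site
length, every site detectable on the full sequence lies intact in some
chunk. Chunk scans emit *raw* placements (no per-chunk deduplication —
a chunk-local winner could otherwise mask a site whose true overlap
competitor lies in a different chunk); the merge deduplicates exact
coordinates, then applies the single global minimum-energy overlap
reduction. The parallel phase is a pure ordered map over
(transcript × miRNA × chunk) work items with no shared mutable state, so
results are byte-identical for any thread count — the testable replacement
for wall-clock speedup claims.

## Synthetic data: what it emulates and what it does not

`fixtures` generates every input the pipeline consumes.

* **Planted sites**: the reverse complement of a random 21-mer carrying a
  requested number of mismatch (identical-base columns), wobble (G:U/U:G)
  and target-bulge edits, placed with ≥ 3-column spacing away from the
  duplex ends; the generator re-derives the pattern through the refinement
  alignment and re-draws edit positions if the interpretation is ambiguous,
  so the truth sidecar is exact by construction.
* **Compositional signal**: positive-site flanks are drawn AU-rich
  (A/U 0.35, C/G 0.15 each) against a uniform background, standing in for
  the compositional bias of real plant target contexts; negatives are
  plain random windows and near-complementary decoys in uniform flanks.
  This is the one deliberate simplification that matters: real flanking
  bias is weaker, structured and species-dependent, so passing the planted
  recovery test demonstrates that the machinery — scanning, encoding,
  filtering, feature extraction, scoring — is wired correctly and that the
  SVR can exploit a flank-composition signal when one exists; it does not
  certify accuracy on real transcriptomes.
* **Pattern library**: mostly-match patterns with 0–4 deviations anchored
  by the canonical all-match entry, so near-perfect planted duplexes pass
  the ≤ 4-distance filter the way they would against a real experimentally
  derived library. The real 268-pattern library is not public; users
  supply their own via the TSV format.
* **Abstract training sets** (standard-normal features, a planted mean
  shift on a known subset) calibrate the selection and CV machinery, and
  **expression fixtures** draw each gene/miRNA pair from the Gaussian
  model y = ρx + √(1−ρ²)ε, so the population correlation is exactly ρ.

All generators are pure functions of seed and parameters.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; writers emit 1-based
  inclusive. Ambiguity codes are rejected at parse time (densities and
  duplex scoring have no semantics for N).
* Sites shorter than 20 nt use their full length for the delta-mode
  reference density. A transcript shorter than the miRNA yields an empty
  candidate list, not an error.
* MCC with a zero denominator factor → 0, flagged; all-zero confusion
  counts → error. Pearson correlation requires ≥ 3 conditions and nonzero
  variance. Pairs with IDs absent from the expression matrix are reported
  as data-unavailable, never dropped silently.
* Problem sizes in the test and reproduction runs — 150 training instances
  per class, 50-transcript batches, 300-nt transcripts, 10-fold CV on 200
  instances — are chosen so the full cycle completes in seconds while
  every statistical check retains power.

## Known limitations

* The internal energy model is a stand-in for a true hybridization
  backend; its energies are not thermodynamically calibrated and no
  statistical (extreme-value) significance is attached to sites.
* No intramolecular structure or accessibility modeling, by design — the
  method positions flank composition against structure-based features.
* Library matching is end-to-end; local (sub-pattern) matching could admit
  partial-duplex evidence and is noted as an extension.
* Shipped/synthetic models and libraries are labeled synthetic; real-data
  performance requires user-supplied validated instances.
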