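# Methods

`seedfold` implements a structural-statistical pipeline for asking whether an
RNA-binding-protein (RBP) motif concentrates among the miRNA target sites
that are *hardest to open* in 3'-UTR secondary structure, and whether
expression data supports cooperative repression by the miRNA and the RBP.
This note records the models, parameter choices, numerical conventions, and
the limits of what the synthetic benchmark can establish.

## Seed-match sites and target windows

A miRNA family is represented by its 7-nt seed (miRNA positions 2–8,
5'→3').  Three canonical site types are predicted in a UTR: the 7mer-m8
(reverse complement of the full seed), the 7mer-A1 (reverse complement of
seed positions 2–7 followed by an A opposite miRNA position 1), and the 8mer
(both).  When an 8mer is present, the 7mer matches it contains are not
reported separately: one locus, strongest type.  Conservation filtering is
out of scope; callers may supply pre-filtered site tables.

Around every site a window of `2*flank + site_length` nt is cut
(`flank = 70`, giving the canonical 147-nt window for 7-nt sites) with the
site centered.  Sites closer than `flank` to a UTR end are dropped (logged),
never padded, so all windows have uniform length downstream.  Overlap within
a UTR is thinned by a maximum independent set on the interval graph whose
edges join windows with starts closer than `min_start_distance = 100`
(distance exactly 100 is allowed).  On interval graphs the greedy
left-to-right scan is provably optimal; ties at equal starts break by
window id.

## Accessibility model

For each window S:

* `dG_all(S)` — minimum free energy of the unconstrained window;
* `dG_masked(S)` — MFE with the 25 nt centered on the site midpoint forced
  unpaired (midpoint rounded down for 8-nt sites).  Masking is realized by
  N-substitution so every folding backend behaves identically;
* `dG_open(S) = dG_all − dG_masked` — the energy cost of opening the site;
* `GA(S) = 2*dG_all − dG_masked` — the global accessibility score.

Windows are ranked ascending by GA: the most negative (least accessible)
first.  Ranking ties break by window id.

Folding is pluggable behind a single `fold(sequence, unpairable)` contract.
The default `internal` engine is a Nussinov-style dynamic program maximizing
pair weights G–C = 3, A–U = 2, G–U = 1 with a minimum hairpin loop of 3;
energies are the negated weight in pseudo-kcal/mol.  It is deterministic,
has exact constraint semantics (`dG_open ≤ 1e-6` holds identically), and
needs no native dependencies, which keeps every statistic in the pipeline
reproducible bit-for-bit.  The `external` engine wraps ViennaRNA's MFE
folder when its Python bindings are installed; for a Turner-model engine the
N-substitution tolerance is documented as 0.5 kcal/mol.  Requesting an
unavailable backend raises a configuration error naming the internal
fallback.  The pipeline's statistics are invariant to the engine choice in
design: the engine only produces the ranking and the mask.

## The mHG statistic

Given a ranked list with binary labels λ (N entries, B ones), the
hypergeometric tail `HGT(b; N, B, n)` is the probability of b or more ones
among the top n under uniform placement.  The mHG score is
`min over 1 ≤ n < N` of `HGT(b_n; N, B, n)` — a data-driven cutoff, so the
score itself is not a p-value.  The exact correction is computed by dynamic
programming over the (n, b) lattice: cells whose tail is at most the
observed score are zeroed and surviving label paths are counted with exact
integer arithmetic, giving `p = 1 − surviving/C(N, B)`.  The only
floating-point step is the HGT cell comparison, guarded by a relative
tolerance of 1e-12; tails themselves come from `scipy`'s log-stable survival
function, and a rational-arithmetic tail is provided for small N (the test
oracle uses it).  `B = 0` degenerates to score 1 without error, and the
smallest minimizing prefix is reported on ties.  A Bonferroni-style
`N*score` bound is exposed as a cross-check field only.

## Motif discovery

Before searching, each window is masked: the seed site and every position
paired with it in the window's MFE structure are replaced by N, so neither
the site nor its structural complement can surface as a "motif".  Discovery
enumerates every exact k-mer (`k = 9`) occurring in at least `min_support`
windows (default 5 — a floor on the candidate set, configurable; degenerate
or shorter motifs are out of scope by design).  Each candidate's label
vector is presence/absence (counts are kept for reporting); hits must reach
mHG score ≤ 1e-4 and are sorted by exact p-value.  No additional correction
across k-mers is applied beyond the per-motif exact p — the score threshold
is the selection rule — but a Bonferroni column over the number of tested
k-mers is emitted for transparency.

## Motif clustering

The i-level distance between equal-length motifs is i plus the Hamming
mismatches between the first k−i characters of one and the last k−i of the
other; the motif distance minimizes over all i.  The raw definition is
asymmetric (prefix of s against suffix of t), so it is symmetrized by taking
the minimum over both argument orders — clustering needs a symmetric
dissimilarity.  Clusters grow by average-linkage nearest-neighbour
agglomeration and stop when the closest pair exceeds the `diameter`
parameter (default 3 for 9-mers; no canonical value exists, so it is
reported in output metadata).  Equally close pairs merge in lexicographic
member order.  Instead of a multiple alignment the consensus is a
position-frequency matrix over members aligned at their stored best shifts,
with overhangs ignored.

## Control battery

* **Multiplicity**: the relaxed site count accepts G-U wobble pairs and at
  most one position failing both Watson-Crick and wobble pairing (wobble is
  a pair, not a mismatch), counting overlapping 7-nt windows.  Pearson
  correlation is taken against integer rank positions 1..L, least accessible
  first; zero-variance inputs are reported as undefined (NaN) rather than
  raising.
* **Consensus-pattern enrichment** accepts IUPAC degenerate patterns and any
  ranked sequence list, covering the folding-energy and GC-content ranking
  controls; a resampling mode repeats the test over random same-size subsets
  and reports the best p across repeats, with a caller-supplied ranking key.
* **Validated-set enrichment** labels a target positive only if its gene is
  in the validated set *and* the window contains a consensus match that
  overlaps neither the seed site nor any occurrence of the site's reverse
  complement ("its complement" is read as the reverse complement of the site
  sequence searched within the window).

## Expression-based cooperation test

Samples are points (x, y) = (miRNA, RBP expression).  A 2D kd-tree with
alternating median splits (x at even depths, y at odd; the first ⌈m/2⌉
coordinate-sorted points go left, residual ties by sample id) is scanned
left to right to give a joint ordering from joint-low to joint-high.
Nested configurations take the k highest samples as A_k and the k lowest as
B_k for every k up to ⌊N/2⌋ (no k is excluded).

Per target, differential repression is the TNoM score: the minimum over
expression thresholds of misclassified samples under the one-sided rule
"A below the threshold, B above" — thresholds are placed only between
distinct pooled values, so ties can never be split.  Its exact p-value is
the permutation-null probability of a score at least as small, computed by
counting label arrangements with integer lattice-path DP (enumeration-exact,
verified against brute force for |A|+|B| ≤ 10).  Targets are ranked by this
p (ties by gene id) and the mHG enrichment of the least-accessible set Φ
(top 20% of the accessibility ranking) at the head of that ranking is the
figure of merit; the configuration minimizing it wins.  Single-regulator
comparisons reuse the same machinery with samples ordered by one coordinate.

The empirical null redraws Φ-sized disjoint random target subsets and
repeats the full best-configuration search.  Because (N, B) are identical
across draws, the exact p is a strictly monotone function of the mHG score,
so draws are compared to Φ by score — an exact shortcut, not an
approximation.  Expression matrices are used as provided; normalization is
the caller's concern.

## Synthetic world

The generator emulates the statistical structure the pipeline detects, with
all randomness flowing from one root seed through named substreams (window
sequences, motif placement, expression), so each part regenerates
independently and FASTA/TSV output is byte-identical across runs.

| parameter | default | rationale |
|---|---|---|
| `n_windows` | 200 | a realistic per-family target-list size (the motivating datasets run to a few hundred) |
| `gc_background` | 0.5 | neutral base composition |
| `structured_fraction` | 0.5 | equal planted/background split maximizes ranking contrast |
| `stem_length` | 21 | a stem spanning the 7-nt site plus flanks, long enough to dominate background pairing |
| `motif_prob_top` / `motif_prob_rest` | 0.9 / 0.05 | strong planting odds in low-accessibility windows |
| `n_samples` | 40 | a small cell-line-panel scale |
| `effect_size` | 2.0 SD | clearly detectable but noise-limited repression |
| `noise_sd` | 1.0 | unit residual scale |

Structured windows receive a stem whose left arm covers the site and whose
right arm is its reverse complement placed downstream, locking the site in a
helix; which windows are structured is a seeded random subset of the index
range so ground truth never correlates with gene-id order (deterministic
tie-breaks downstream would otherwise be confounded).  The motif is planted
clear of the site and stem.  Expression panels split samples into even
quarters — joint-high, joint-low, miRNA-only-high, RBP-only-high — and
repress Φ rows by `effect_size * noise_sd` only in joint-high samples.  The
mixed quarters are essential: they are what makes single-regulator sample
orderings genuinely underperform the joint ordering.

A note on "unstructured" background: any random 4-letter RNA of 147 nt
pairs substantially by chance, so background windows have negative dG_open
under the internal engine too; the generator's guarantee is a strong *mean*
GA separation between structured and background windows, not zero background
structure.  Setting `background_alphabet="AC"` (with a {G,U} seed) gives a
provably pairing-free background for which every unstructured window has
exactly `dG_open = 0`; this configuration exists to pin the engine contract
in tests.

What the generator does **not** emulate: Turner-model thermodynamics, human
UTR composition and length variation, conservation structure, dependence
between sites of different families, and measurement noise models of real
expression panels.  A green synthetic test therefore establishes that the
statistics recover planted signal at the stated odds and effect sizes under
an idealized folding model — not that the biological findings reproduce.

## Numerical conventions and degenerate inputs

* Coordinates 0-based half-open everywhere; TSV site files use the same.
* mHG cell comparisons: relative tolerance 1e-12; path counts exact ints.
* All-zero label vectors score 1 (no error); `score = 1` gives `p = 1`.
* Zero-variance multiplicity vectors: NaN, logged.
* Greedy MIS ties, ranking ties, TNoM ranking ties, cluster-merge ties:
  lexicographic (window id / gene id / member pair), for determinism.
* Empirical-null resolution: an observed 0 of n draws is reported as 0 and
  should be read as "< 1/n_draws".

## Known limitations

* The internal engine's pseudo-energies are not calibrated to kcal/mol;
  only orderings and differences are meaningful.
* Exact k-mer discovery cannot find degenerate motifs; the IUPAC matcher in
  the control battery handles fixed consensus patterns only.
* The TNoM null assumes distinct pooled expression values; heavy ties make
  the exact p conservative.
* `mhg_pvalue` is O(N*B) with big-integer arithmetic — fine to N ~ 10^4,
  slow far beyond.
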