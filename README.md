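# seedfold

Some miRNA binding sites sit in tightly folded 3'-UTR structure that the
RISC machinery should struggle to open.  If such low-accessibility targets
are nonetheless repressed, an RNA-binding protein (RBP) may be helping.
`seedfold` is a library for detecting that signature: it ranks predicted
miRNA target sites by the energetic cost of opening their local structure,
searches for RBP motifs enriched among the least accessible targets with an
exact rank statistic, and tests for cooperative miRNA/RBP repression in
expression panels.  It is aimed at regulatory-genomics researchers who want
the full statistical machinery — with exact p-values and a ground-truth
synthetic benchmark — without external data dependencies.

## What it computes

**Accessibility.**  For a 147-nt window S with the seed-match site centered,
two MFE foldings give ΔG_all(S) (free) and ΔG_masked(S) (25 nt around the
site forced unpaired via N-substitution).  Then

    ΔG_open(S) = ΔG_all(S) − ΔG_masked(S)          (site-opening cost)
    GA(S)      = 2·ΔG_all(S) − ΔG_masked(S)        (global accessibility)

Targets are ranked ascending by GA: least accessible first.  Folding is
pluggable (built-in Nussinov-style engine by default; ViennaRNA optional).

**Rank enrichment (mHG).**  For a binary label vector λ over the ranked
list (N entries, B ones), the minimum-hypergeometric score is

    mHG(λ) = min over 1 ≤ n < N of HGT(b_n; N, B, n),   b_n = Σ_{i≤n} λ_i

where HGT is the hypergeometric tail P(X ≥ b).  Because the cutoff n is
optimized, the score is corrected by the exact dynamic-programming p-value
P(mHG ≤ s) under the uniform-permutation null (integer path counting, no
Monte Carlo).  Motif discovery enumerates all 9-mers, labels windows by
presence, and keeps motifs with mHG score ≤ 10⁻⁴; binding sites and their
predicted pairing partners are masked out first.

**Cooperation (TNoM + kd ordering).**  Samples are ordered by joint
(miRNA, RBP) expression via a 2D kd-tree; nested high/low sample
configurations are scored by each target's threshold-number-of-
misclassifications (TNoM) p-value; the enrichment of the least-accessible
target set Φ (top 20%) among the most repressed targets is the figure of
merit, compared against single-regulator orderings and a random-subset
empirical null.

## Worked example

`examples/03_motif_discovery.py` generates the default synthetic benchmark
(200 windows, a 9-mer planted in 90% of structured vs 5% of background
windows, seed 1), ranks by accessibility, masks, and searches:

```
    motif  k  n_star  b_star    mhg_score      p_value   bonferroni  gc_content
UGUAUAUAU  9     105      92 1.739941e-33 1.232468e-32 3.943899e-31    0.111111
GUAUAUAUA  9     104      26 7.409662e-09 7.104009e-08 2.273283e-06    0.111111
...
```

Read: of 200 ranked windows, 92 of the top 105 contain `UGUAUAUAU`; the best
hypergeometric tail over all prefixes is 1.7×10⁻³³ and its exact corrected
p-value 1.2×10⁻³². The planted Pumilio-like motif (GC content 1/9 = 11.1%)
dominates; the trailing hits are its shifted copies, which the clustering
step (example 04) folds into one cluster at shift-distance 1.

`examples/06_cooperation_test.py` runs the expression test on the same
world (40 samples, 2-SD repression of Φ only when both regulators are high):

```
joint  ordering: best k=11  enrichment p=2.00e-41
mirna  ordering: best k=18  enrichment p=2.72e-28
rbp    ordering: best k=20  enrichment p=3.57e-30
random-subset empirical p = 0.000 (resolution 1/200)
```

The joint ordering's Φ-enrichment beats either single-regulator ordering by
many orders of magnitude — the signature of cooperative repression — and no
random target subset of 200 matches Φ.

The other examples cover site prediction and window extraction (01),
accessibility scoring (02), motif clustering (04), and the control battery
(05).  `seedfold.pipeline.run_discovery` / `run_cooperation` chain the
stages end to end from a `PipelineConfig` and write TSV reports plus a run
manifest.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch through the library, the exact mHG p-value for a
ranked list of 388 targets containing 14 validated positives all within the
top 251 ranks (minimum attained at prefix 251) and writes it as JSON.

## Layout

```
src/seedfold/        sequence_sites, accessibility, folding, mhg,
                     motif_discovery, motif_clustering, enrichment,
                     expression, synthetic, pipeline, io
examples/            one short narrative script per capability
tests/               pytest suite with brute-force oracles
docs/methods.md      models, parameter rationale, numerical conventions
```
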