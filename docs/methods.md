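# Methods

This note documents the models and procedures implemented in `ptmcross`,
the conventions chosen where the underlying methods literature leaves the
details open, and what the synthetic benchmarks do and do not establish.

## Group-based peptide scoring

A tyrosine's context is the peptide `PY(m, n)`: m upstream and n downstream
residues, padded with `*` beyond the protein termini. A candidate `c` is
scored against the positive (known-site) peptides `p` as

    S(c) = mean_p max(0, Σ_i w_i · M[c_i, p_i])

* `M` — a symmetric 22-letter substitution matrix (20 residues, `X` for
  ambiguity, `*` for padding). The base matrix is BLOSUM62 with the `*`
  row/column pinned to 0, so padding is inert by construction. `X` keeps its
  BLOSUM62 row.
* `w` — non-negative per-position weights, initially all 1.
* The per-pair clamp at 0 stops strongly dissimilar training peptides from
  dominating the mean with large negative sums.

**Leave-one-out discipline.** Every positive is scored with itself removed
from the positive set; negatives are scored against all positives. Negative
examples are the non-modified tyrosines of proteins that carry at least one
known site of the PTM class in question — the natural background, since
only experimentally studied substrates can contribute verified negatives.

**Training.** Three stages, in order:

1. *Motif length selection* — grid search over (m, n), keeping the window
   that maximises the leave-one-out AROC with unit weights (ties prefer the
   smaller window, then the smaller m). Deterministic, so it takes no seed.
2. *Weight training* — per iteration, one position weight is multiplied by
   a factor drawn from the log-symmetric grid {0.5, 0.8, 1.25, 2.0}; the
   step is kept only if the leave-one-out AROC strictly improves.
3. *Matrix mutation* — per iteration, one symmetric entry pair among the
   20 standard residues is shifted by ±1 under the same strict-improvement
   rule, so the matrix stays symmetric and `*` stays inert.

The strict-improvement rule makes "training never degrades the model" a
theorem rather than an observation; the test suite audits it anyway. The
default schedule (100 iterations per stage, single seed driving both
stages) is deliberately short: on the standard benchmark it moves the
leave-one-out AROC from 0.890 to 0.918, and longer schedules trade run time
for increasingly marginal, increasingly overfit gains on 200 positives.
The hill-climbing step sizes and schedule are this package's conventions —
the broader family of group-based predictors does not standardise them.

**ROC and AROC.** Thresholds sweep the distinct observed scores (plus +∞);
tied scores collapse to one threshold; the area is the trapezoid rule. This
makes AROC exactly the normalized Mann–Whitney U statistic (ties counted
half), an identity the tests assert to 1e-12.

**Threshold calibration.** For each level the cutoff is the smallest
observed score whose empirical specificity (fraction of negatives scoring
below it) meets the target: low 0.85, medium 0.90, high 0.95. Higher
targets give higher cutoffs, so prediction sets nest (high ⊆ medium ⊆ low).
If no observed score reaches the target, the cutoff is placed just above
the maximum score and a warning is attached.

## Redundancy clearing

Training sets are clustered at 40% global identity (longest-first greedy
assignment to the first representative meeting the threshold). Identity is
Needleman–Wunsch global alignment (BLOSUM62, gap open −11, extend −1, end
gaps penalized) with matches divided by *alignment columns* — gaps count in
the denominator, which is stricter than the shorter-sequence convention
some clustering tools use; users can rescale if they need to match those.
Within a cluster, a member's site is dropped when its aligned column on the
representative already carries a kept site of the same PTM class. The
original curation additionally applied a manual inspection step; no
automated equivalent is attempted.

## Enrichment statistics

All co-occurrence and enrichment questions reduce to (N, K, n, k):
N background elements, K background successes, n drawn, k drawn successes.

* **E-ratio** = (k/K)/(n/N), or generally (k₁/n₁)/(k₂/n₂). A zero reference
  proportion is reported as ∞ (flagged, never raised); a zero numerator
  gives 0.
* **Hypergeometric tail** — pmf in log space via log-gamma (stable to
  N ~ 10⁶), tails as exact sums over the support. The tail direction is not
  standardised in the enrichment literature; the package's convention is
  over-representation tail P(X ≥ k) when E ≥ 1, under-representation tail
  P(X ≤ k) otherwise, which matches how such tables are narrated
  ("enriched" vs "under-represented"). Tests verify the tails against
  exact rational enumeration for all N ≤ 60 and against an independent
  library implementation at N = 10⁶.
* **Yates' χ²** for 2×2 tables uses the continuity-corrected statistic with
  one degree of freedom; a zero margin yields NaN (undefined, flagged).
* **Term enrichment** treats each annotation term as its own quadruple and
  sorts by p. P-values are reported unadjusted (fixed-cutoff practice);
  an optional Benjamini–Hochberg q-value column is off by default.
* Report tables round E-ratios half-up to two decimals.

Two printed reference ratios are arithmetically inconsistent with their own
published counts (the sulfation–nitration overlap row and one
cancer-variant nitration row); the package reproduces the values implied by
the counts and documents the discrepancy rather than matching the typo.

## Conservation (RCS_Y)

Ortholog groups are human-anchored stars: a group exists for each human
protein with at least one reciprocal-best-hit partner (best = highest
bitscore, ties by lower e-value, then lexicographic subject id). Alignments
are consumed, not computed — aligned FASTA per group, one row per species.

For a tyrosine column:

* `N_Y` — number of member sequences with Y in the column;
* MBL pair — the two tyrosine-bearing species at maximum patristic
  distance on the species tree;
* `N` — number of member species inside the smallest tree clade containing
  the MBL pair;
* `RCS_Y = N_Y / N`, conserved iff `RCS_Y ≥ threshold` (default 1.0).

The published description of this score names the quantities but not the
exact denominator; binding N to "member species inside the MBL clade"
reproduces the score's stated behaviors (threshold range 5/8..1 meaningful
with eight species, RCS_Y = 1 meaning full retention across the span) using
only named quantities. Two consequences are surfaced rather than hidden:
a column whose only tyrosine is the human one degenerates to N = N_Y = 1,
RCS_Y = 1 (flagged `degenerate=True`), and on adversarial branch lengths a
tyrosine-bearing species can fall outside the MBL clade, making RCS_Y > 1
arithmetically possible — impossible on the shipped vertebrate tree, and
left unclamped so it would be visible if a user's tree triggered it.
Raising the threshold can only shrink the conserved set (tested), which is
the sensitivity analysis the score is designed for.

Class-versus-class conservation uses the same E-ratio + hypergeometric
machinery (N = both classes, K = all conserved, n = class A, k = conserved
in A); the choice of the hypergeometric here is the package's own, for
consistency with every other statistic it reports.

## Sequence/structure preferences and variants

* Terminal thirds: boundaries at ⌈L/3⌉ and ⌈2L/3⌉; position ≤ first bound →
  N-terminal, ≤ second → Middle, else C-terminal. For L = 10 position 4 is
  N-terminal — a pinned regression case for the ceiling convention.
* Secondary structure = argmax of (helix, strand, coil) probabilities; exact
  ties prefer coil, then strand. Exposure: exposed iff RSA ≥ 0.25
  (inclusive at the boundary — the source convention does not say, so
  inclusive is pinned here). Disorder: disordered iff score ≥ 0.5.
  Structure predictors are never run in-package; their outputs arrive via a
  documented TSV, which keeps results deterministic and the package
  self-contained.
* Per-category preference: 2×2 table (modified vs background × in-category
  vs not) → two-proportion E-ratio + Yates' χ². Swapping the two site sets
  inverts the ratio and preserves the statistic (tested).
* Variant mapping: a site is hit iff a variant shares its
  (protein, position) and the variant's reference residue is the tyrosine;
  multiple variants on a site count once. Rare means allele frequency
  strictly below 1%; records without a frequency land in an unclassified
  bucket excluded from fraction denominators.

## The synthetic benchmarks

The generators are pure functions of a `SyntheticSpec` (seed included);
identical bytes across runs and platforms, ground truth in a sidecar JSON.

* **Motif dataset.** Positive windows follow the sulfation profile:
  aspartate/glutamate enriched across −5..+5 and dominating at −1 (D 0.35,
  E 0.28), tyrosine over-represented at +1/+2 (0.20 each) and weakly
  upstream, mild G/Q enrichment near the center; sulfated tyrosines sit in
  acidic stretches, and these rates encode that. Background, linkers, and
  dedicated negative flanks exclude tyrosine so the derived negative count
  is exact; incidental tyrosines inside positive flanks become (hard)
  negatives and are counted toward the total. Defaults echo the
  non-redundant training-set shape (200/1,027/116); the standard benchmark
  pins 200 positives / 1,000 negatives at seed 42. On it the base model
  scores leave-one-out AROC 0.890 and the trained model 0.918, with k-fold
  estimates within 0.003 of leave-one-out.
* **Ortholog set.** Eight vertebrates on a fixed tree (human, mouse, rat,
  dog, cow, pig, chicken, zebrafish). The planted per-class "conservation
  rate" is the probability a site's column is *fully* retained: a conserved
  draw keeps Y in all eight species (RCS_Y = 1 exactly); a non-conserved
  draw keeps Y in human and zebrafish — so the MBL clade spans the root and
  N = 8 — and substitutes it in 1–3 internal species, forcing RCS_Y ≤ 7/8.
  Retention of a column is therefore a Bernoulli draw of the planted rate,
  and the recovery tests are exact binomial checks (defaults 0.8 modified
  vs 0.5 unmodified, 500 sites per class, implying a conservation E-ratio
  of 1.6). Non-tyrosine columns mutate at a rate proportional to distance
  from human, with sparse gaps in non-human rows only.
* **Annotations / variants / structure.** One planted term covering all
  foreground proteins versus 10% of the background; variant hit rate 5% on
  2,000 sites with a 90/10 rare/common allele-frequency mixture (rare
  log-uniform on [10⁻⁴, 10⁻²), common uniform on [10⁻², 0.5], so the
  analytic rare fraction is the mixture weight); coil rates 0.60 vs 0.30
  planting a structural E-ratio of 2.

What passing these benchmarks shows: the pipelines recover known effect
sizes from data in the exact input formats, at realistic dataset shapes,
deterministically. What it does not show: performance on real substrates —
real sulfation motifs are weaker and dirtier than the planted profile, real
negatives are contaminated by undiscovered sites, real alignments have
insertions relative to human and alignment error, and real variant tables
have coordinate-mapping noise. Benchmark AROCs are properties of the
generator's signal strength, not estimates of real-data accuracy.

## Numerical choices

* Probabilities accumulate in log space (log-gamma + log-sum-exp); tails
  are clipped to ≤ 1 against rounding.
* E-ratio report rounding is half-up at two decimals.
* All stochastic steps (fold dealing, hill-climbing proposals, generators)
  take explicit integer seeds; there is no global RNG state. Weight
  training and matrix mutation derive their seeds from the single training
  seed (seed, seed + 1).
* Score ties in ROC sweeps are grouped; candidate thresholds for
  calibration come from the observed score set.
* Cluster membership ties resolve to the first (longest, then lexicographic
  id) representative; RBH ties resolve by e-value then subject id; MBL-pair
  ties resolve to the first pair in lexicographic species order.

## Known limitations

* The predictor scores against all training positives; scoring against
  cluster representatives only (an open alternative) is not implemented.
* The hill-climbing schedules are conventions; the score surface is flat
  over long stretches and different schedules give slightly different
  weight profiles with near-identical AROC.
* `RCS_Y` treats the alignment as correct; column mis-assignment in real
  alignments propagates directly into the score.
* The variant machinery consumes per-variant allele-frequency summaries;
  genotype-level or genome-coordinate data must be lifted to protein
  coordinates upstream.
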