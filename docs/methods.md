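# Methods

## The convergence model

Two arrayed screens measure the same phenotype under complementary
perturbations: overexpression of `M` miRNA mimics and knockdown of genes by
siRNA pools. The premise is that a gene truly central to the phenotype
should surface twice — as an siRNA hit, and as a preferential target of the
miRNAs that most strongly shift the phenotype. The pipeline formalizes that
as a set-overlap statistic per gene, with the screened miRNA universe as the
exchangeable background.

### Tail selection

Candidates are the extreme `floor(f·M)` entities per tail of the composite
score (default `f = 0.01`). Floor rounding is deliberate: it is the only
rule under which a 2555-entity screen at 1% per tail yields exactly 50
candidates. Ties are broken by (score, entity id) under a stable sort, so
selection is a pure function of table contents: permutation-invariant, and
monotone in `f` (growing the tail never drops a previous selection). The
composite score is taken as given; plate normalization and per-channel
combination are upstream concerns and out of scope.

### Consensus prediction

Individual target-prediction algorithms have high false-positive rates with
poorly overlapping errors, so a (miRNA, gene) pair is retained only when at
least `min_algorithms` (default 4) distinct algorithms call it. "At least
four algorithms" is interpreted as *per-pair support counting*, not as the
intersection of whole per-algorithm target lists — the standard consensus
practice, and the only reading under which a gene-level funnel is
computable. The predictions themselves are an input table; no algorithm is
re-implemented or queried. The threshold is antitone by construction
(raising it can only remove pairs), and a `binder_mode="union"` escape hatch
(support ≥ 1) exists because published analyses do not always state which
convention they used.

### Drawing-lots enrichment

For a convergent gene `g` with consensus binder set `B_g` (restricted to the
screened universe) and candidate set `C` (`|C| = n`), the observed statistic
is `k_obs = |B_g ∩ C|`. The null resamples *candidate sets*: `N` lots of `n`
miRNAs drawn uniformly **without replacement** from the `M` screened (a lot
is a set of distinct miRNAs). One shared lot stream scores all genes — the
lot does not depend on the gene, sharing it is both faithful to the
procedure and vectorizable. The empirical p uses the add-one estimator

    p_emp = (#{|B_g ∩ L| ≥ k_obs} + 1) / (N + 1)

which is never zero, has floor `1/(N+1)`, and is super-uniform under the
null (a valid p-value at any `N`). The test is one-sided for enrichment;
that is the only direction the convergence question asks.

Because a uniform lot without replacement makes `|B_g ∩ L|` exactly
`Hypergeometric(M, |B_g|, n)`, the closed-form tail `P(X ≥ k_obs)`
(`hypergeom_tail`, via `scipy.stats.hypergeom.sf`) is attached to every
record as an independent oracle. The test suite checks agreement over a
grid of `(M, b, n, k)` within three binomial standard errors plus `1/N`.

Multiplicity is handled by Bonferroni (adjusted `p = min(1, p·G)`, per-test
threshold `α/G`), delegated to `statsmodels.multipletests`; with `G = 180`
genes at `α = 0.05` the threshold is `0.05/180 ≈ 2.78 × 10⁻⁴`. No FDR
procedure is offered: family-wise control is the convention for a short
confirmatory gene list. Null calibration is verified empirically: on 200
replicates of fully null binder sets, the fraction of runs flagging any of
180 genes stays at or below nominal.

Implementation: lots are drawn by ranking i.i.d. `float32` uniforms per row
(partial `argpartition`), in chunks of 4096 draws to bound memory; per-gene
overlaps reduce a boolean membership gather. `10⁶` draws × 180 genes × 41
candidates runs in well under a minute on one CPU.

### Generic over-representation

`pathway_ora` applies the same hypergeometric tail to a query set against
named annotation sets over a user-supplied background, with Bonferroni
across sets. Annotation databases are inputs, not dependencies; published
pathway p-values depend on database versions and are not reproduction
targets.

## Seed-site scanning

Canonical grammar only: the 6mer core is the reverse complement of miRNA
positions 2–7 on the UTR read 5'→3'; a Watson–Crick match to position 8 on
the 5' flank and/or an `A` opposite position 1 on the 3' flank upgrade the
class (8mer > 7mer-m8 > 7mer-A1 > 6mer; one class per core locus). G:U
wobble is excluded, as canonical-site definitions require. DNA input is
normalized to RNA on the sense strand; coordinates are 1-based and the
reported start includes the position-8 match when present. Every reported
hit is re-verified base-by-base before being returned. No thermodynamic or
context scoring is attempted.

Allele comparison scans both haplotype sequences (which must differ at
exactly one position), matches hits by (miRNA, start, class), and labels
the remainder `ref_only`/`alt_only`; hits whose window spans the variant
are summarized as variant-created or variant-destroyed. This captures the
mechanism where a 3'UTR risk allele creates an 8mer site and makes
repression allele-specific.

## Quantification arithmetic

**Comparative Ct.** `ΔCt = Ct_target − Ct_normalizer` per sample,
`ΔΔCt = ΔCt − mean(ΔCt | reference group)`, `RQ = 2^−ΔΔCt`. The calibrator
is the reference-group *mean* (not a paired sample) — the common choice for
unpaired case/control designs; consequently the reference group's RQ has
geometric mean exactly 1, an identity the tests assert.

**±3 MAD filter.** Values strictly outside `center ± k·d` are excluded in a
single pass, where `d` is the *mean* absolute deviation about the mean
(default) or the *median* absolute deviation about the median
(`center_mode="median"`). Both modes exist because "MAD" is used for either
statistic in practice; the mode is recorded in the result. No 1.4826
robust-scale constant is applied and the pass is not iterated — the filter
is the literal `±3·MAD` band. Zero dispersion (constant input) keeps all
values and warns.

## Puncta connectivity

Each postsynaptic centroid is assigned to its nearest presynaptic centroid
iff that Euclidean distance is ≤ `d_max` (default 1 µm, boundary
inclusive); a presynaptic punctum may collect several posts, and no
exclusive bipartite matching is attempted — the readout is defined on
assignment counts, not matchings. Distance ties resolve to the
lexicographically smallest presynaptic id, making the result deterministic.
The readout is `100 · #{pre with 0 assignments} / n_pre`. Distances are
centroid-to-centroid; segmented volumes are carried through but unused.
The implementation is a full distance-matrix argmin (exact by
construction); the test suite cross-checks it against an independent
KD-tree comparator on random instances.

## Synthetic data

The generators reproduce the *structure* of the study inputs, not their
biology:

* **screen scores** — standard-normal background with planted mean shifts
  (default +10 SD) for designated tail hits; the real screen's score
  distribution is unpublished, so the normal background is an explicit
  stand-in. Defaults: 2555 miRNAs, 25 planted per tail.
* **prediction calls** — planted genes get exactly `b` consensus binders of
  which exactly `k` are candidates; each planted binder is called by
  `consensus_min + Binomial(K − consensus_min, agreement)` algorithms.
  Background calls are independent Bernoulli(`base_call_prob`) per
  (pair, algorithm) over non-planted genes only, so planted counts stay
  exact. Binder sets are sampled without replacement uniformly outside the
  forced overlap, matching the exchangeability the permutation null
  assumes. The i-th planted gene is anchored to the (i mod n)-th candidate
  so ≥ n planted genes jointly cover all n candidates.
* **siRNA hits** — planted convergent genes plus a uniform filler to the
  configured list size (default 832 of the gene universe).
* **variant UTRs** — uniform-random background with an 8mer written in so
  that its seed core spans the variant on the carrier allele; the other
  allele differs at that single position, which necessarily destroys the
  core. Draws where the random background blurs the planted truth (e.g. a
  coincidental nearby site) are rejected and redrawn.
* **puncta** — uniform presynaptic points in a box (default 50×50×10 µm);
  `round(fraction·n_pre)` get partner posts at Gaussian offset (default
  0.1 µm/axis); distractors uniform. Puncta are ideal points: no imaging
  noise, PSF, or intensity model, so recovery tests speak to the assignment
  arithmetic, not to segmentation robustness.
* **Ct tables** — case-group target Ct shifted by −log2-fold cycles,
  normalizer unshifted, i.i.d. Gaussian cycle noise on every measurement.

One integer seed drives a per-generator `(seed, stream-id)` derivation:
outputs are byte-identical under a fixed seed and independent across
generators. What passing recovery tests show is that each stage inverts its
generator's planted truth at the stated sampling error — not that the
pipeline is robust to real-data pathologies (batch effects, correlated
prediction errors across algorithms, segmentation artifacts), which the
generators deliberately do not model.

## Problem sizes and numerical choices

* The acceptance script (`scripts/acceptance.py`) runs the full pipeline at
  2555 miRNAs × 4000 genes (background call probability 0.01) with 10⁶
  drawing lots — the gene universe is kept below the full siRNA panel size
  to keep the generated call table and runtime desk-scale; the statistic's
  null depends only on the miRNA universe, which is full-size.
* Its demo planting uses 180 convergent genes (binder counts 30–120,
  overlaps mostly 1–2) with one strongly convergent gene (4 of 12 binders
  among the candidates), whose exact tail (≈ 2.6 × 10⁻⁵) sits below the
  Bonferroni threshold — a realistic "top gene" rather than a degenerate
  all-candidate binder.
* Permutation tests in the test suite use 10⁴–10⁵ draws; the add-one floor
  `1/(N+1)` then still sits 1–2 orders of magnitude below the `0.05/180`
  threshold, so scaled-down runs are conclusive.
* `float32` uniforms are used for lot drawing (ranking only needs order
  statistics); all p-value arithmetic is `float64`.

## Known limitations

* The consensus interpretation ("≥4 algorithms call the pair") and the use
  of consensus (not union) binder sets in the enrichment are documented
  choices where published descriptions are ambiguous; both knobs are
  exposed.
* `pathway_ora` treats annotation sets as given and independent; no
  between-set overlap correction.
* The seed scanner implements canonical sites only — no wobble, bulge,
  3'-supplementary pairing, or context scores — so it under-calls relative
  to thermodynamic predictors by design.
* Connectivity assumes already-segmented centroids in a common coordinate
  frame; no registration or segmentation quality control.
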