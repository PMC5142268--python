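# Methods

## Model

The package scores the hypothesis that a candidate gene causes a query
phenotype by testing for *phenotype consensus* in its mechanistic
neighborhood. The underlying assumption is that genes acting in the same
molecular mechanism, when perturbed, produce diseases with similar trait
profiles. The pipeline has four stages:

1. **Mechanism sampling.** Related genes are taken from a directed, scored
   interaction network (all, upstream-only, or downstream-only neighbors at a
   confidence threshold, default ≥ 0.5 on the unit scale) or from pathway
   gene sets; custom lists are accepted wherever a pathway member set is. The
   candidate itself is always excluded from its related set.
2. **Annotation.** Every gene known to cause Mendelian disease inherits the
   union of the phenotype terms of its diseases. Terms live in an `is_a` DAG
   restricted to the phenotypic-abnormality branch; alternate identifiers are
   resolved, obsolete terms dropped, out-of-branch terms discarded with a
   logged count (annotation builds always contain drift, so drop-and-count is
   preferred to failing). Gene-disease links are filtered to pathogenic
   clinical significance and germline-type origins (germline, de novo,
   inherited, maternal, paternal, biparental, uniparental) by default; both
   filters are configurable.
3. **Similarity.** Term specificity is `IC = -ln(|p|/|Ω|)` in nats, with
   propagated gene counts; term-term similarity is the IC of the most
   informative common ancestor; set-set similarity is the symmetric
   best-match average. Ancestor closures are reflexive, so a term's MICA with
   itself is itself. Terms annotated by no gene carry no IC and are skipped
   as MICA candidates; a query term with no annotated descendants still gets
   a defined similarity through its nearest IC-bearing ancestor (the branch
   root, IC 0, guarantees termination).
4. **Consensus test.** Each universe gene's symmetric similarity to the query
   is computed; a one-sided Mann-Whitney U test compares related-gene scores
   against all remaining disease-annotated genes. When the candidate belongs
   to several pathways, the most significant pathway is reported along with
   how many were tested — deliberately without multiple-testing correction,
   since the count itself is reported and the validation metrics are computed
   on the same convention.

## Conventions and numerical choices

* **Candidate exclusion.** The candidate's score is removed from both groups
  by default: in validation its annotations are masked anyway, and in
  exploratory use a known association would otherwise confirm itself. Its
  score is still reported for display, and a flag restores inclusion.
* **Not-computable is an outcome, not an error.** A related set with no
  annotated member yields a result with undefined p; the validation
  *potential* metric is precisely the fraction of associations avoiding this
  outcome.
* **Mann-Whitney branches.** Pooled samples of size ≤ 12 are tested by exact
  enumeration of all group assignments over shared mid-ranks (ties handled
  exactly). Larger tie-free samples up to pooled size 40 use the exact
  rank-sum distribution (dynamic programming); beyond that, or with ties, the
  tie-corrected normal approximation with continuity correction. The plain
  normal approximation is not used near the enumeration boundary because its
  absolute error there reaches ~0.06 for very unbalanced splits (about half
  the mode probability of the discrete null even for balanced ones), which
  would make the reported p jump discontinuously across the branch switch;
  with the exact tie-free distribution the two branches agree to machine
  precision. In realistic corpora the background contains thousands of genes
  with tied zero scores, so the asymptotic path is the one normally taken.
* **Quantiles.** Background quantiles (50/75/95% by default) use linear
  interpolation between order statistics (numpy's default convention).
* **Rank percentile.** The candidate's p is mid-ranked among itself plus its
  computable negatives and divided by the list length; the batch summary
  reports the *median* of these percentiles (the robust choice between the
  two plausible location summaries) and a *pooled* AUC over all candidate and
  negative p-values (score = -p, half credit for ties), the simplest
  construction that uses every record at once.
* **Leave-one-out masking.** Only the true candidate's annotations are
  removed; negatives are sampled from the remaining annotated universe,
  excluding genes linked to the query disease, and are not themselves masked
  (a negative is excluded from both test groups regardless, so its own
  annotations cannot self-confirm). IC is recomputed on the masked corpus by
  default so |Ω| stays consistent; `recompute_ic=False` reuses a global table
  as a labelled fast approximation.
* **Reproducibility.** Each association's random stream is
  `default_rng([master_seed, crc32(gene\tdisease)])`, so record tables are
  byte-identical across runs and evaluation orders.
* **Min-p combination.** Across two resources, the candidate's and each
  negative's p is the minimum of the computable values; a combined value is
  not-computable only if both are, so combined potential can never fall below
  either input's.

## Synthetic benchmarks

The generators emulate the statistical structure the method assumes, at desk
scale:

* a complete rooted tree ontology (default depth 5, branching 3 → 364 terms,
  243 leaves; optional random downward edges create diamonds while keeping
  the DAG),
* a corpus of `n_genes` (default 200) genes, one disease each, with 3-6 leaf
  terms per disease: module genes' diseases draw a fraction `effect` of their
  terms from one designated subtree (the most specific subtree that can
  supply a full term set), background diseases draw uniformly from all
  leaves,
* a directed two-block network with edge probability `p_within` (default
  0.5) inside the module and `p_between` (default 0.02) elsewhere, scores
  uniform on (0.5, 1.0) so every edge passes the default confidence filter
  and threshold behavior must be probed with crafted edges.

`effect = 0` gives a null corpus — module membership independent of phenotype
— used for calibration; `effect = 0.8` with a 20-of-200-gene module is the
standard strong-signal condition. Defaults were chosen once as a realistic
desk-scale analogue of a Mendelian-disease corpus: a few hundred genes, a
handful of specific terms per disease, and a mechanism module an order of
magnitude smaller than the corpus.

What the fixtures do **not** emulate: multi-disease (pleiotropic) genes,
multiple overlapping modules, term-frequency skew of real annotation builds,
annotation noise/drift, and the scale of real resources (thousands of genes,
hundreds of thousands of edges). Passing the synthetic benchmarks therefore
demonstrates correctness and calibration of the machinery, not performance on
real corpora; published-scale performance numbers additionally depend on
licensed pathway content and historical database builds that cannot be
bundled.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the harness at 200 genes with
20-50 associations and 20-50 negatives per association, 500 random related
sets for the uniformity check, and exhaustive rank-pattern enumeration up to
pooled size 12 for the Mann-Whitney cross-validation — sizes at which every
quantity is recomputed from scratch in seconds while keeping Monte-Carlo
intervals tight enough for the stated tolerances.

## Known limitations

* Only `is_a` ancestry is honored; `part_of` and cross-ontology mappings are
  out of scope.
* A gene's profile is the union over its diseases; a per-disease best-match
  alternative (scoring each disease separately and keeping the maximum) is a
  documented possible extension.
* The pathway selection reports the minimum p over pathways uncorrected;
  interpret it with the reported pathway count.
* Exact-test cost grows combinatorially; the enumeration limit of 12 keeps
  the worst case at 924 assignments.
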