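# Methods

## Enrichment model

For one experiment, the query is an ordered gene list (read directly, or
produced from BED peaks by overlap with promoter-extended transcripts) and
the background is a gene universe containing the query. For each ontology
term the four disjoint cells of a 2×2 table are

- n1 — query genes annotated to the term (after propagation),
- n2 — query genes not annotated,
- n3 — background-minus-query genes annotated,
- n4 — background-minus-query genes not annotated.

The background row is background *minus* query deliberately: an odds ratio
requires disjoint rows, whereas the list-vs-population tables used by many
enrichment servers overlap. The enrichment score is z = log δ / SE(δ) with
δ = (n1·n4)/(n2·n3) and the Woolf standard error
SE = √(1/n1 + 1/n2 + 1/n3 + 1/n4); under no enrichment z is approximately
standard normal, and the two-sided p-value is 2(1 − Φ(|z|)). The 95% CI is
reported on the log-odds scale (log δ ± 1.96·SE); the literal band
z ± 1.96·SE is also emitted for completeness, since some presentations
attach the interval to z itself (the two differ by a factor of SE and only
the log-odds version is a confidence interval in the usual sense).

Zero cells get the Haldane–Anscombe correction (+0.5 on all four cells,
flagged in the output) by default; `zero_correction="skip"` instead marks
the term undefined, excluding it from comparisons — the strict
"non-zero log odds ratios only" policy. Terms with fewer than `min_count`
(default 2) query hits are not scored.

Between experiments, each shared scoreable term gets
z_k = (log δ_i − log δ_j)/√(SE_i² + SE_j²), two-sided normal p-values and,
by default, Benjamini–Hochberg adjustment (statsmodels). The shared
universe is the intersection of the two profiles' defined term sets;
terms scoreable in only one profile are reported separately, never
force-scored with imputed zeros. Ties in |z_k| break lexicographically by
term id so output is stable. The Jaccard coefficient compares the two
term-hit gene sets; the summary `mean_jc` averages over shared terms with
at least one contributing gene, and `pearson_r` correlates the paired
per-experiment z's.

The **overlap baseline** reproduces the practice the comparative score
replaces: each profile is tested per term with a one-sided Fisher exact
test for over-representation (scipy), adjusted within the profile,
thresholded at α, and the significant sets are set-differenced into
both / i-only / j-only / neither.

### Numerical notes and caveats

- p-values are floored at 5·10⁻³²⁴ (normal tail underflow) so downstream
  adjustment, which requires p > 0, is well defined.
- z is *not* strictly monotone in n1 at fixed margins over the whole
  range: as n2 → 0 the SE diverges and z flattens (first non-monotone step
  at n1 = 44 of a 50-gene query in the test fixture). Monotonicity holds —
  and is tested — away from degenerate margins.
- Scaling all four cells by c leaves δ unchanged and shrinks SE by √c, so
  z grows like √c: equal proportions are *not* equal evidence.
- With only one shared term, `pearson_r` is undefined and reported as NaN.

## Ontology engine

OBO 1.2/1.4 is parsed with `obonet`; obsolete terms are dropped
(`replaced_by` not followed) and only `is_a` / `relationship: part_of`
edges are kept — the standard true-path relations; `regulates`-type edges
are ignored. Acyclicity is asserted at construction (a cycle is a hard
error naming a member). Associations come from GAF 2.x (rows whose
qualifier contains `NOT` are skipped; gene identity from the symbol column
by default, the DB-object-ID column by option) or a 2-column TSV.
Propagation adds every gene to all ancestors of its direct terms;
association rows naming terms absent from the ontology are skipped with a
logged count, tolerating ontology/annotation version skew. Gene
identifiers are opaque case-sensitive strings; no aliasing is attempted.

## Peak-to-gene assignment

Coordinates are 0-based half-open throughout (BED native; the transcript
TSV is declared in the same convention, so overlap needs no ±1
adjustment). A peak is assigned to every gene whose transcript span,
extended `upstream` bp (default 5000) on the transcript's 5′ side
(before txStart on `+`, after txEnd on `−`), overlaps it by ≥1 bp; there
is no nearest-gene tie-break, which keeps assignment deterministic and
order-independent. Chromosome names match exactly unless `--strip-chr`
normalizes a leading `chr`. Implementation uses an interval tree; the test
suite checks it against an all-pairs scan.

## Synthetic-data generator

The generator emulates a complete desk-scale study and is the basis of
every statistical claim in the test suite:

- **Ontology** — terms T:0000001..n; term k takes one uniform parent among
  earlier terms plus, with probability 0.2, a second (`part_of`) parent:
  a DAG, acyclic by construction, edge count in [n−1, 2(n−1)].
- **Genome** — 500 genes (default) on 5 chromosomes, non-overlapping 2 kb
  transcripts, 12 kb start-to-start (10 kb gaps), alternating strand.
- **Annotations** — each gene draws Poisson(3) direct terms uniformly.
- **Experiments** — 150 genes (default) sampled without replacement from
  the exponentially tilted subset law P(S) ∝ Π_{g∈S} w(g), with
  w(g) = Π_t OR_t^[g ∈ propagated(t)] over the planted terms. For a single
  planted term this is exactly Fisher's noncentral hypergeometric
  distribution (sampled via scipy), whose realized sample odds ratio
  concentrates at the planted OR — measured mean ≈ 5.1–5.4 for a target
  of 5. Sequential probability-proportional-to-weight draws were
  considered and rejected: they follow the Wallenius law and overshoot
  (≈ 9.6 realized for a target of 5 at these sizes). With several
  overlapping planted terms the tilted law is sampled by a seeded
  Metropolis swap chain (40·n proposals). `peak_mode` additionally emits a
  400 bp BED interval centered 200 bp upstream of each selected gene's 5′
  end, which `assign_genes` recovers.

One global seed drives per-stage substreams, so outputs are byte-identical
for a fixed configuration and earlier stages are unaffected by later-stage
parameter changes.

Two study designs recur in tests and in `scripts/acceptance.py`:

- **Planted differential term** (power): `pick_planted_term` selects the
  host — propagated size nearest 20% of the universe, with every ancestor
  ≥1.6× larger and every descendant ≤1/1.6× the size. The separation
  requirement is an identifiability condition: a term with a near-duplicate
  relative shares essentially all its genes with it, so the planted effect
  would be legitimately attributed to either; such hosts make "the planted
  term ranks first" ill-posed rather than hard. At OR 5 vs 1 the planted
  term attains the top |z_k| in ≥95% of replicates.
- **Replicate pair** (specificity): `plant_shared_enrichment` plants odds
  ratios 2–5 on five mid-size terms *identically in both experiments* —
  null for differential enrichment but rich in true per-experiment signal,
  like repeated experiments on the same factor. This is the regime where
  hard thresholding fails: truly enriched terms straddle the cutoff
  between replicates, so the overlap baseline reports many "specific"
  terms while z_k correctly reports (near) none. A flat null without
  shared enrichment does not produce the straddling artifact — with
  adjusted thresholds both methods then report ~0 terms — so the
  replicate-pair design is the meaningful rendition of the contrast.

What the generator does **not** emulate: realistic genome sequence or peak
shapes, peak-caller noise, correlated annotations (real GO terms co-occur
along gene-function lines), namespace structure, evidence codes, or gene
length/mappability biases. Passing tests therefore demonstrate the
statistical machinery under its stated sampling model, not performance on
a real annotation corpus.

## Multi-experiment classification

Per-term z-scores are assembled into a terms × experiments matrix; the
default `intersect` policy keeps terms scoreable everywhere (no imputed
zeros; `union_zero` is available). PCA treats experiments as points in
term space, mean-centering each term row but not variance-scaling
(z-scores already share a scale). Hierarchical clustering is agglomerative
over experiment columns, Euclidean metric and average linkage by default
(`correlation` = 1 − Pearson and other linkages selectable); trees
serialize to Newick via scikit-bio and round-trip losslessly.

## Problem sizes

Defaults everywhere are the desk-scale study above (500 genes, 100–200
terms, 150-gene queries). The statistical suites use 50 seeds for null
calibration (≈7,500 term tests), 100 replicates for power, 50 for the
baseline contrast; a full test run takes well under a minute beyond
fixture generation, and `scripts/acceptance.py` completes in ≈25 s.

## Known limitations

- The normal approximation for z is anti-conservative for very sparse
  tables; `min_count` and the Haldane correction mitigate but do not
  remove this. Measured null type-I at raw p < 0.05 is ≈ 0.028 — slightly
  conservative overall, reflecting discreteness.
- Propagation makes ancestor scores strongly dependent; per-term p-values
  are marginal and BH is applied without modeling the DAG dependence.
- No evidence-code filtering and no gene-ID aliasing: the association file
  is taken at face value.
- Pairwise comparisons only; k-experiment contrasts are expressed through
  the z-matrix machinery, not a joint test.
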