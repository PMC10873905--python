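# Methods

This note documents the models, estimators and design choices behind
`taxoclass`, the parameters that matter, and what the synthetic-data
experiments do and do not demonstrate.

## Taxonomy model

A fixed seven-rank ladder (root, phylum, class, order, family, genus,
species). Every species must carry a complete lineage through all six
sub-root ranks; loaders reject skipped ranks rather than silently
patching them, because every hierarchical strategy assumes that a
parent's children all sit exactly one rank down. For dumps with "no
rank" intermediates, `taxonomy.fill_missing_ranks` synthesizes
`unranked-fill` placeholder nodes on request. Taxids are opaque positive
integers; names are never used for identity, which sidesteps
nomenclature inconsistencies between databases. Root is an explicit rank
so the lowest common ancestor is always defined.

## Reference curation

Per species, the pipeline is prioritize → ANI → cluster → representative
→ dedup:

* **Prioritization.** Sort by assembly completeness (complete genome >
  chromosome > scaffold > contig), then annotation category (reference >
  representative > NA), then N50 descending, then accession. Above the
  per-species cap (default 10), the worst-ranked assemblies whose strain
  is already represented by a better-ranked assembly are dropped first;
  truncation at the cap is the last resort. Dropping from the
  worst-ranked end is a deterministic choice among several defensible
  orders.
* **ANI estimator.** Alignment-free and self-contained: each assembly is
  cut into 3000 bp fragments; a fragment's identity against the other
  assembly is `100·c^(1/16)` where `c` is the canonical 16-mer
  containment of the fragment — under divergence d a k-mer survives with
  probability (1−d)^k, so `c^(1/k)` inverts back to per-base identity.
  Fragments with containment < 0.1 are treated as non-homologous and
  excluded, mirroring the fragment filtering of mapping-based ANI tools.
  The reported ANI is the mean of both directions. On substitution-only
  fixtures the estimator tracks the closed form within about one ANI
  point, which is the tolerance the tests use.
* **Clustering.** OPTICS (scikit-learn, `metric="precomputed"`,
  xi-steepness extraction, `min_samples=2`, other parameters at their
  defaults — the setting that maximized mean silhouette in parameter
  sweeps on real curation runs). The dissimilarity fed in is
  `(100 − ANI)/100`. Noise points are promoted to singleton clusters: a
  species' only assembly is never discarded. Note that xi extraction is
  scale-free; when validating against a fixed-eps density oracle the
  comparison bounds `max_eps` at the oracle's density scale (0.1),
  because with unbounded reach a uniformly-distant point set looks like
  one dense cluster at its own scale.
* **Representatives and dedup.** Highest-N50 member per cluster
  (accession breaks ties); pooled coding sequences are then collapsed by
  greedy longest-first clustering at 99 % estimated identity (canonical
  10-mer containment of the shorter in the longer, mapped through
  `c^(1/k)`). With k=10 the estimate is ≈ 1 − d for pairwise divergence
  d, so the threshold behaves like true percent identity; canonical
  k-mers make reverse-complement duplicates collapse. All stages are
  deterministic, so byte-identical inputs give byte-identical outputs.

## Classifiers

* **k-mer LCA index** (default k=21). Each canonical k-mer maps to the
  LCA of all species containing it. A read pair is classified to the
  deepest hit node on the max-scoring root-to-leaf path (path score =
  sum of hits on its nodes; ties across paths resolve to the LCA of
  their deepest hit nodes). Confidence = fraction of queried k-mers on
  the chosen root path; the default threshold is 0, with 0.1 as the
  stringent option. k=21 suits the desk-scale curated references this
  toolkit builds (a seed length in the range short-read aligners use);
  production tools indexing hundreds of gigabases use longer k-mers.
  The `lca_storage=False` ablation stores an arbitrary (first-seen)
  containing species instead of the LCA and exists only to measure how
  much the LCA convention suppresses false species calls.
* **Profile classifier** (default k=13, pseudocount 1). A smoothed
  multinomial per label over canonical 13-mer tokens. Prediction scores
  are the **mean** per-token log-likelihood, softmax-normalized over the
  (possibly restricted) label set. The length normalization preserves
  the argmax but keeps the softmax from saturating as a read pair
  contributes hundreds of statistically dependent tokens; without it the
  confidence is 1.0 for essentially every read and a fixed 0.5
  threshold cannot separate reliable from unreliable calls. Tokens never
  seen in training are skipped at prediction time (the alternative — an
  out-of-vocabulary bucket — only adds a label-independent constant
  under additive smoothing). Ties break toward the earlier label in
  model order. This classifier plays the role a trained embedding model
  plays in production ensembles: a multi-class model emitting a
  softmax-scored species call; external model predictions can be
  imported through the parsers instead.
* **Best-hit aligner** (seed length 21). Exact-seed, ungapped extension
  at +1/−1 on both strands; a pair's score against a reference is the
  sum of each mate's best placement. Unique top species wins; an
  unmapped pair or a cross-species score tie is reported as such and the
  ensemble layer falls back. No gaps or quality scores: at
  substitution-only fixture scale, ungapped scoring is exact.

## Hierarchical strategies and ensembles

LCL trains one model per rank and predicts each rank independently
(headline = deepest rank whose softmax clears the 0.5 threshold).
Hierarchy-informed LCL restricts each rank's candidates to children of
the previous prediction, renormalizing the softmax over the restriction
so the threshold keeps its meaning; an empty restriction or
sub-threshold score stops the descent. LCPN routes top-down through
per-parent-node models; under the default `multichild_only` policy,
single-child parents pass through with confidence 1 and need no trained
model (the accounting in `count_models` makes the policy explicit
because published model counts cannot be re-derived without the
underlying taxonomy). The LCL–LCPN hybrid uses rank models through
family and node models below — hierarchy-informed routing confined to
the ranks where upper-level errors cannot yet compound.

The primary+specialist ensembles project the primary classifier's call
to genus and hand the read to that genus's species specialist. A profile
specialist must clear the softmax threshold (default 0.5) or the
primary's own lowest-rank prediction stands; an alignment specialist
must produce a unique best species or the primary stands; an
unclassified primary stays unclassified. The fallback uses the primary's
original, untruncated prediction — it may itself be species-level — since
truncating it to genus would discard information for no benefit.
Specialists are trained with approximately equal read counts per species
(seeded down-sampling) so within-genus priors stay flat. The union
ensemble prefers the primary's species call, then the secondary's, then
the primary's lowest-rank call.

## Evaluation

Truth and predictions are projected to the evaluated rank; predictions
above that rank (or absent) fall into an `unclassified` pseudo-class
with zero true occurrences. MCC follows the confusion-matrix formula
with the 0/0 → 0 degenerate-margin convention; note this convention also
makes a single-class-perfect matrix score 0, so communities evaluated at
ranks where only one taxon exists report 0 by construction. Precision is
correct/classified, recall is correct/total, hence recall = precision ×
classified-fraction as an identity. An `unclassified="drop"` mode
excludes unclassified reads from the matrix instead; the default counts
them, which penalizes non-classification symmetrically with
misclassification. The unseen-taxa false-positive rate selects reads
whose true taxon at a rank lies outside the reference set at that rank
and reports the fraction that nonetheless received a species call.

## Synthetic communities

One random ancestral genome per phylum; every branch applies i.i.d.
substitutions at its rank's divergence (defaults 0.25/0.15/0.10/0.06/
0.04/0.015 from phylum to species, strictly decreasing so sister species
are always more similar than cross-genus pairs). Strain-level assemblies
add 0.2 % further divergence; train and test panels use disjoint
accession namespaces and test assemblies never enter any index or model.
Genomes are cut into CDS-like segments (uniform 300–3000 bp). Reads are
150 bp paired-end with Gaussian insert (350 ± 35 bp) and uniform
per-base substitution errors (default 0.5 %); the error process draws
from its own random stream so fragment coordinates are
seed-reproducible across error rates. Default problem sizes are
desk-scale: 20 kb genomes, 2000 training reads per species — large
enough for every direction-of-effect experiment to be stable across
seeds while the whole validation suite runs in minutes on one CPU.

What the generator does **not** emulate: indels and rearrangements
(keeping ANI and identity oracles closed-form), quality-score error
profiles, PCR duplicates, chimeras, abundance skew, horizontal transfer,
and real genome sizes. Passing tests therefore demonstrate the
*mechanisms* — LCA safety, redundancy-driven index bloat, the
species/genus rank asymmetry under confusable sisters, specialist
rescue, unseen-taxa false-positive suppression — not absolute accuracy
figures on real communities.

## Numerical and degenerate-input conventions

* k-mers containing N are skipped everywhere; canonicalization is the
  lexicographic minimum of a k-mer and its reverse complement.
* All ties (sorting, representative selection, profile argmax, LCA path
  ties, best-hit species ties) break deterministically, by accession,
  label order or smallest taxid.
* Silhouette: noise excluded; singleton clusters contribute 0; an
  all-singleton labelling scores 0; fewer than two clusters is an error.
* A global integer seed fans out to per-stage streams by stable hashing
  of stage names, so any stage can be reproduced in isolation.

## Known limitations

Pure-Python k-mer handling bounds practical reference sizes to the tens
of megabases; the profile classifier is a calibrated stand-in, not a
trained embedding model; SAM import uses the `AS` tag of primary
alignments only; the strict six-rank ladder requires preprocessing for
real taxonomy dumps with irregular ranks.
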