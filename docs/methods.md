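# Methods

## Scope and data flow

The package starts where the external tools stop. BLAST tabular hit files
(12-column outfmt-6 dialect), homology-cluster membership TSVs, Newick
gene trees with `SPECIES|GENE` leaf labels, a species taxonomy TSV and
normalized log2 expression matrices are inputs; running the homology
search, alignment, tree inference or array preprocessing is out of scope.
Two stages consume them: annotation (membership → cluster screening →
family vote → subgroup partition) and expression (contrasts → induction
calls → summaries). A curated annotation table for *T. reesei* is bundled
as the reference summary surface.

## Membership and cluster screening

A protein is a confident CAZyme when its best retained hit has
percent identity ≥ 97 and alignment length strictly greater than 200
amino acids; hits are retained only when E-value < 10⁻¹¹ (strict, so an
E-value of exactly 10⁻¹¹ is discarded). The best hit is the maximal
bitscore; equal bitscores are resolved by lower E-value, then
lexicographically smallest subject id, so the choice is deterministic. An
E-value ordering is available (`best_hit_by_evalue`, selectable in
`RunConfig.best_hit_order`) because published best-hit listings are often
E-value sorted; bitscore is the default.

Cluster screening ("is this homology cluster CAZy-like on average?") uses
a rectangular acceptance boundary: mean best-hit identity ≥ I₀ (default
40) and mean alignment length ≥ L₀ (default 100), means taken over
members that have a hit; a cluster with no hits is rejected. The original
screen was a hand-drawn boundary in the identity × length plane; a
rectangle preserves its monotone "above the line" semantics while being
explicit and configurable, and is the package's own choice of boundary
shape and defaults.

## Family assignment

Each cluster member with a confident hit votes for its best hit's family;
a reference protein listed in several families casts one full vote in
each. The modal family wins. Ties are broken by the larger summed
bitscore of the voting members, then by the lexicographically smallest
family label, with `tie_broken` recorded for audit. Focal-species genes
are excluded from voting by default (the assignment should rest on the
evidence from other species); the `exclude_focal_species` flag reverses
this. A cluster with no voters is `UNASSIGNED`, mirroring curated rows
whose family column shows only the bare class.

## Duplication dating and subgroups

Duplications are inferred by species overlap: an internal node is a
duplication iff at least two of its children have intersecting species
sets. This is the standard tree-only operationalization of "the
duplication predates the ancestor of clade X" and needs no dated species
tree; its known failure mode (deep coalescence or tree error mimicking
overlap) is accepted and documented rather than modelled. A duplication
is ancient iff its descendant species set contains a species outside the
focal clade. Trees are taken as rooted as given (an unrooted trifurcation
is treated as rooted at the trifurcation); midpoint rooting is not
applied silently because subgroup partitions can depend on rooting.
Internal-node labels that parse as numbers are kept as bootstrap
supports; a configurable minimum support for trusting a duplication
exists with default 0 (all nodes trusted), since no threshold was part of
the original analysis.

The subgroup partition is computed structurally: each maximal clade whose
species set stays inside the focal clade contributes one part, the focal
genes under it. This is equivalent to the pairwise rule (two genes share
a part iff their LCA's species set stays inside the clade) and makes the
equivalence property explicit; the test suite checks the equivalence
against a brute-force pairwise-LCA oracle with transitive closure on
random trees. Parts are lettered a, b, c, … (then aa, ab, …) in order of
first appearance in left-to-right leaf order — any deterministic order
would do; leaf order matches how the labels read off a plotted tree.

## Expression model

Contrasts are computed within cultivation batch because each batch had
its own control series and array design; cross-batch normalization is out
of scope. For genes × replicates groups X₁ (induced) and X₂ (control):

* lfc = mean(X₁) − mean(X₂) per gene,
* pooled variance s²_g with d_g = n₁ + n₂ − 2 df,
* prior (d₀, s₀²) fitted across genes by method of moments on
  log variances: with e = log s²_g − ψ(d_g/2) + log(d_g/2), the mean of e
  estimates log s₀² + ψ(d₀/2) − log(d₀/2) and the excess of var(e) over
  ψ′(d_g/2) estimates ψ′(d₀/2), inverted by Newton iteration. A
  non-positive excess is encoded as d₀ = ∞ (complete shrinkage); exactly
  identical variances return s₀² equal to that common value,
* posterior s̃² = (d₀s₀² + d_g s²_g)/(d₀ + d_g),
  t = lfc/(s̃√(1/n₁ + 1/n₂)), two-sided p on d₀ + d_g df (normal reference
  at d₀ = ∞; the plain pooled t at d₀ = 0, offered behind
  `moderation="none"`),
* call = +1 iff p < 0.01 and lfc > 0.4; −1 iff p < 0.01 and lfc < −0.4;
  both inequalities strict.

Moderation is estimated per contrast from that contrast's pooled
variances (not pooled across all conditions per gene); this is a modelling
choice and is the only variance pooling the package does. The raw-p gate
is deliberate: the original thresholds were an uncorrected p < 0.01 plus
the fold-change gate; Benjamini–Hochberg adjusted p-values can be
computed by the caller from the returned p-values but are not applied.
Zero posterior variance (identical values in both groups under d₀ = 0)
yields p = 0 with a warning.

The core induced set requires at least one +1 call on a cellulose-class
substrate, one on a xylan-class substrate, and +1 calls on
⌈0.70 × n_substrates⌉ distinct substrates. The two Avicel concentrations
count as distinct substrates (10 substrates ⇒ threshold 7); the
substrate → class map is configuration (`RunConfig.substrate_classes`)
because the class membership of the complex substrates is a judgement
call. Co-expression branches come from complete-linkage agglomerative
clustering on Euclidean distances of fold-change profiles — the common
default of heatmap tooling — cut into k groups (default 18) and lettered
A, B, … by first member in input order. An optional saturation ceiling is
not implemented; strongly saturated genes (known to distort array fold
changes) should be inspected via the signal matrix directly.

## Synthetic data

The generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`, and emit exactly the file dialects the
readers consume.

* `gen_hit_table`: members draw identity ~ U(97, 100), length
  ~ U(201, 600), E log-uniform in [10⁻⁵⁰, 10⁻¹²]; each non-member
  violates the identity bound, the length bound, or both (recorded), and
  half the non-members additionally carry a non-significant E-value.
* `gen_gene_tree`: n_ancient + 1 lineages split above the focal clade's
  root, each retaining outside-clade witness leaves and one focal-clade
  sister leaf; recent duplications nest inside the focal species. The
  planted partition (n_ancient + 1 parts) is exact by construction.
* `gen_expression_dataset`: baseline log2 signals ~ N(8, 1) per gene,
  Gaussian replicate noise, four replicates per condition, the ten-
  substrate/two-batch/five-time-point design by default; induced genes
  receive +effect_lfc at every non-zero time point.

What the generators do *not* emulate: sequence evolution, probe-level
effects, signal saturation, correlated noise across genes, or
heavy-tailed variance heterogeneity. Passing tests therefore demonstrate
correctness of the inference rules under the stated model, not robustness
to array artefacts.

## Study conditions used in tests and the acceptance script

* Tree oracles: 500 random trees (acceptance suite; 200 in the script's
  agreement metric) of up to 50 leaves over an 11-species panel;
  planted-partition recovery over all feasible (n_ancient, n_recent) with
  up to 10 focal genes (220 configurations).
* Power: planted log2 effect 2.0, replicate sd 0.5, 4 vs 4 replicates,
  1,000 genes × 20 seeds.
* Null calibration: no effect, replicate sd 0.2, 4 vs 4, 2,000 genes ×
  20 seeds. The dual threshold is conservative precisely when the
  fold-change gate binds, i.e. when the standard error of the fold change
  is small against the 0.4 gate (replicate sd ≲ 0.2 at n = 4, a typical
  replicate sd for normalized log2 array data); at sd 0.5 the p-gate
  alone determines the rate and calibration reduces to that of the
  moderated p-values themselves.
* End-to-end: an 8-cluster bundle plus a 400-gene, two-substrate
  expression set. These sizes keep the full suite under a minute on one
  CPU while leaving each check statistically meaningful.

## Known limitations

* The rectangular cluster-acceptance boundary is a stand-in for a curve
  chosen by eye in the original screen; its defaults are conventions, not
  fitted values.
* Species-overlap duplication detection cannot distinguish duplication
  from deep coalescence or tree estimation error, and subgroup partitions
  depend on the rooting of the input tree.
* Moment estimation of (d₀, s₀²) treats the fitted prior as known in the
  reference distribution; the resulting p-values are approximate, which
  is visible as a few-percent relative inflation of tail rates when the
  fold-change gate does not bind.
* The curated table's four letterless subgroup labels are accepted
  verbatim with a warning; no letter is guessed.
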