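# Methods

## Data model

A *peptidoform record* is one quantified observation: (sample group,
replicate, peptide region, modification state, peak area). Modification
states assign exactly one of {unmod, me1, me2, me3, ac} to every modifiable
residue of the region (mutual exclusivity per residue). Trimethylation is
accepted at K9 and K27; K36me3 is accepted but logged as unusual; me3
anywhere else is rejected. Propionylation is a sample-preparation label, not
a biological mark: propionyl tokens (including Skyline-style +56.026 mass
shifts) canonicalize to `unmod`. Site labels always use protein residue
numbering.

Forms absent from a replicate are treated as *not observed* — they are
excluded from that replicate's composition rather than entered as zeros.
This mirrors how detection works in MS (a missing form is below the
detection limit, which is not the same as measured zero) and defers all
zero handling to the statistics layer, where it is explicit and logged.

## Quantification

* **Relative abundance**: area of a form over the total area of its peptide
  in the same (sample, replicate). Every emitted composition or marginal
  profile is checked for closure to 1 within 1e-9; a slice with zero total
  area is reported as unquantifiable rather than silently dropped.
* **Variant proportion**: computed per replicate from the two K27–R40
  peptides, summarized by the **median** over replicates (robust to the
  occasional replicate with poor recovery); per-replicate values are kept
  for box plots and t-tests. The `a:1` ratio string rounds a to one
  decimal, prints whole numbers bare (`3:1`, `2:1`) and the balanced case
  as `1.0:1.0`; it is presentational only and never enters computation.
* **Site marginalization** sums form abundances over co-modification
  states; closure is inherited exactly.
* **Variant combination**: the K9–R17 and K18–R26 peptides are identical in
  H3.1 and H3.3 and never pass through variant weighting (scope `n/a`).
  K27/K36 profiles are combined as `p·H3.1 + (1−p)·H3.3`. The weight p is
  the group-median variant proportion by default (primary output);
  per-replicate weighting is available (`weighting="replicate"`) because
  the choice is not uniquely determined by the quantities being combined —
  both are computed and labelled.
* **Merging groups** (e.g. root and shoot halves of one seedling pool) sums
  areas per (replicate, region, form), pairing replicates by index;
  unpaired replicates are kept with the available areas. Pooling at the
  area level (rather than averaging relative abundances) treats the merged
  sources as parts of one physical sample; the decision is recorded in the
  run manifest.

## Statistics

* **Zero replacement** is multiplicative: zeros become delta, positive
  parts are rescaled by `(1 − z·delta)/sum(positive)`, preserving closure
  and all ratios among positive parts. Delta defaults to 0.65 × the
  smallest positive fraction observed for that feature across the dataset —
  a standard compositional choice placing imputed values just below the
  observed detection floor. Every replacement is logged with its delta.
* **2-part alr**: `log2(x/(1−x))`. Base 2 so that one unit is a two-fold
  change of the odds of the form against all others.
* **t-tests**: Student's pooled-variance by default (Welch behind a flag),
  two-sided, requiring ≥ 2 replicates per group; features failing that are
  skipped with a logged reason. Tiers: *significant* p < 0.05, *trend*
  0.05 ≤ p < 0.1 (the boundary point is assigned to the trend tier; the
  event has measure zero in floating point). Tiers are deliberately
  uncorrected for multiplicity — the intended reading is per-feature — but
  the report carries Benjamini–Hochberg q-values in a separate column so
  both views are visible.
* **Pivot coordinates**: `z_j = sqrt((D−j)/(D−j+1)) · ln(x_(j) /
  gmean(x_(j+1)…x_(D)))`, natural log (the standard definition of this ilr
  basis). Coordinate values depend on the pivot order (default: input
  feature order, alphabetical after canonicalization); Euclidean distances
  between coordinate vectors do not, which is the property clustering
  relies on, verified against a clr-based Aitchison-distance oracle.
* **Clustering**: UPGMA on Euclidean distances between pivot-coordinate
  rows, implemented directly (O(n³) recomputation of cross-pair means) so
  that tie-breaking is pinned: among minimal distances the lexicographically
  lowest cluster-index pair merges first. Heights are monotone (average
  linkage is reducible). The unit is the group-mean composition,
  re-closed after averaging, with features missing in any clustered unit
  dropped matrix-wide and logged; replicate-level clustering is available
  behind a flag. Trees are exported as ultrametric Newick (node height =
  merge height / 2).

## Synthetic-data generator

The generator emulates the study design the analysis assumes: nine groups
(7-day seedlings; 20-day root/shoot calli; NaB- and TSA-treated calli;
1-year calli), six replicates each, five region ids (K27–R40 once per
variant). Per replicate and region:

* total area = `scale · LogNormal(0, sigma)` with `sigma = 0.25` by default
  — run-level intensity variation large enough to make recovery nontrivial;
* form shares = design profile × `LogNormal(0, form_sigma)`, renormalized,
  so composition noise does not leak into totals;
* the H3.1 fraction of the K27–R40 pool is drawn on the log-odds scale with
  sd `split_sigma = 0.06·sigma` (0.015 at default). The two variant
  peptides co-elute from the same run and sample, so their *ratio* is far
  more stable than their absolute intensities; the small split noise
  encodes that. With six replicates the median log-odds then resolves the
  one-decimal ratio rounding windows (the tightest, 3:1, is ±0.017
  log-odds) reliably;
* dropout: `Binomial(n_forms, rate)` forms go missing per region and
  replicate, lowest design abundance first (MS detection realism), with
  elevated rates in root-derived groups (0.12 vs 0.04), mirroring the
  poorer histone recovery from roots.

Group profiles are built as products of independent site marginals, so each
designed marginal is exact. Only a handful of profile entries restate
reported values (the variant proportions; 7ds K27me1 of 27%/13%; cR H3.3
K27me1 of 24%); everything else is a synthetic default chosen to encode the
qualitative contrasts — root/shoot methylation differences, NaB calli
sharing the root-callus profile and TSA calli the shoot-callus profile, a
persistent acetylation imprint in 1-year shoot calli — and is labelled as
such in the preset docstring.

What the generator does **not** emulate: correlated noise across forms of
one peptide (co-eluting isobaric interference), retention-time-dependent
intensity drift, batch effects, non-independent site co-occurrence within a
peptide, and intensity-dependent variance. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to every artefact of real chromatography.

For t-test calibration, features are simulated directly on the alr scale
(baseline means uniform on [−3, 0], replicate sd 0.5, n = 6 per group;
"large effect" = mean shift of 2 alr units), which isolates the test's
behaviour from the quantification stack.

## Problem sizes

The recovery suite uses 200 generator seeds at the default noise level;
t-test calibration uses 1000 null and 500 large-effect features; oracle
equivalence suites use 200 random instances with up to 8 rows or 12 parts.
These sizes give binomial standard errors comfortably below the asserted
tolerances while keeping the full test run around a quarter of a minute.

## Known limitations

* The H3.1:H3.3 proportion is estimated from peak areas without
  ionization-efficiency correction; the two K27–R40 peptides differ by one
  residue (A31/T31), so a small constant bias between variants is possible
  in real data and is not modelled.
* Site marginals for K9–R17 and K18–R26 cannot be assigned to a variant;
  they are reported with scope `n/a` and never variant-weighted.
* No protein-level stoichiometry: abundances are always relative within
  one peptide.
* The preset's non-printed profile entries are plausible but synthetic;
  conclusions about real tissue require real data.
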