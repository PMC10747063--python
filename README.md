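# histoptm

Compositional quantification of histone post-translational modifications
(PTMs) from bottom-up proteomics peak-area tables.

## Who this is for

Labs running propionylation-based bottom-up histone proteomics (e.g. on
*Arabidopsis thaliana* seedlings and calli) quantify short tryptic peptides
of the H3 and H4 N-terminal tails — H3 K9–R17, K18–R26, K27–R40 (once per H3
variant) and H4 G4–R17 — as extracted-ion-chromatogram peak areas per
*peptidoform* (a peptide carrying one specific combination of marks).
`histoptm` takes those exported tables and produces the standard downstream
quantities with a statistically sound compositional treatment.

## What it computes

1. **Form compositions.** The relative abundance of a peptidoform is its
   peak area over the total area of its peptide in the same sample and
   replicate, so each peptide yields a composition closed to 1.
2. **H3 variant proportions.** The K27–R40 peptide differs between variants
   (H3.1 `KSAPATGGVKKPHR` vs H3.3 `KSAPTTGGVKKPHR`), so per replicate
   `p(H3.1) = A(H3.1) / (A(H3.1) + A(H3.3))`; the group value is the
   *median* over replicates, also rendered as the conventional ratio string
   (`3:1`, `1.0:1.0`).
3. **Site-level marks.** Marginal abundances of the mutually exclusive
   states {unmod, me1, me2, me3, ac} at each residue, by summing form
   abundances over co-modification states; K27/K36 marks are additionally
   combined across variants, weighted by the sample's variant proportion.
4. **Acetylation degrees.** Fractions of mono/di/tri/tetra-acetylated forms
   (hyperacetylation readout for H4 G4–R17).
5. **Statistics.** Abundances are compositional, so group comparisons use
   the 2-part additive log-ratio `alr(x) = log2(x / (1 − x))` with
   multiplicative zero replacement, two-sample t-tests (Student's pooled by
   default), a two-tier readout (*significant* p < 0.05, *trend*
   0.05 ≤ p < 0.1) and Benjamini–Hochberg q-values in a separate column.
6. **Clustering.** Sample PTM profiles are mapped to pivot (isometric
   log-ratio) coordinates — where Euclidean distance equals the Aitchison
   distance — and clustered by average linkage (UPGMA), per peptide or over
   all peptides jointly, with Newick export.

A synthetic-data generator (`histoptm.simulate`) reproduces the
seedling/callus study design (9 groups × 6 replicates × 4 peptides,
log-normal intensity noise, abundance-ranked detection dropout), so the full
pipeline is testable without raw MS data.

## Worked example

27% of H3.1 K27–R40 and 13% of H3.3 K27–R40 carry K27me1, and the sample's
H3.1:H3.3 ratio is 3:1 (H3.1 proportion 0.75). The overall K27me1 level,
regardless of variant origin, is the variant-weighted average:

```python
from histoptm import SiteMarkProfile, VariantProportion, combine_variants

h31 = SiteMarkProfile("7ds", 1, "K27", "H3.1", {"me1": 0.27, "unmod": 0.73})
h33 = SiteMarkProfile("7ds", 1, "K27", "H3.3", {"me1": 0.13, "unmod": 0.87})
vp = VariantProportion("7ds", 0.75, {1: 0.75})

print(vp.ratio_text)                          # 3:1
print(combine_variants(h31, h33, vp).marks["me1"])  # 0.235
```

`0.75 × 0.27 + 0.25 × 0.13 = 0.235`: about 23% of all K27 positions carry
monomethylation even though the two variants differ two-fold, because the
more abundant variant dominates the pool.

## Command line

```bash
histoptm simulate --seed 1 --out data.tsv --truth truth.json
histoptm quantify --input data.tsv --outdir out/
histoptm stats --input data.tsv --group-a 7ds --group-b cR --out report.tsv
histoptm cluster --input data.tsv --scope all-peptides --out tree.nwk
histoptm run-all --preset --seed 1 --outdir run/
```

`run-all` writes every report table (TSV), dendrograms (Newick) and a JSON
manifest with versions, seed, config hash and per-file checksums; identical
config and seed give identical checksums.

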