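# Methods

This note records the package's statistical and numerical choices, the
synthetic-data model, and the open design decisions.

## Catalog curation

- **Input dialects.** GWAS Catalog association TSVs report p-values in
  several spellings (`6E-12`, `6 x 10-12`, `6 × 10-12`); the parser accepts
  all three and round-trips them to the same float. Positions and
  chromosomes may be blank or non-numeric; such rows survive parsing with
  `None` fields and are excluded only at stages that need coordinates.
- **Symbol harmonization.** The `MAPPED_GENE` field is split on `", "` and
  `" - "` (padded separators only, so hyphenated symbols such as `IRF1-AS1`
  stay intact). Symbols resolve through the HGNC table in priority order
  approved > alias > previous; when a spelling is both someone's approved
  symbol and another gene's alias, the approved reading wins. Rows with an
  empty `MAPPED_GENE` fall back to `SNP_GENE_IDS` (Ensembl IDs, versions
  stripped).
- **Publication counting.** A gene is counted once per PUBMEDID per trait,
  retaining the best p-value per (publication, gene). Recurrence uses an
  inclusive threshold (≥ 3 publications). Word-cloud weights instead count
  *raw catalog entries* with p strictly below 0.01, because they weight
  evidence volume rather than independent support.

## SNP classification

- Pairs enter with p < 5×10⁻⁸ (strict), chromosome mapped to 1–24
  (X→23, Y→24), and position > 0; duplicate (SNP, gene) pairs collapse to
  the smallest p-value.
- Classes are presence-based over the shared panel: significant in UC only,
  CD only, or both.
- Percentages use decimal half-up rounding to one decimal place (matching
  conventional reporting, where e.g. 10/69 prints as 14.5%), implemented
  with `decimal.Decimal` rather than binary-float `round`.
- Circos tracks are emitted as 0-based half-open BED intervals; the
  oncoprint matrix orders genes by descending burden (alphabetical ties)
  and SNPs by genomic coordinate.

## Overlap statistics

- Background N defaults to 20,000 protein-coding genes; it is a parameter
  everywhere.
- Odds ratio: cross-product with the Haldane–Anscombe 0.5 correction added
  to all cells when any cell is zero; 95% Wald interval on log-OR.
- Two-sided Fisher exact test: point-probability rule. The hypergeometric
  pmf is evaluated in log space (`scipy.stats.hypergeom.logpmf`), the tail
  is summed with `logsumexp`, and tables whose point probability ties the
  observed one within relative tolerance 1e-7 are included, which protects
  symmetric tables against floating-point noise. Degenerate margins give
  p = 1.
- Upper-tail hypergeometric probability P(X ≥ overlap) is computed the same
  way, returning exactly 1.0 when the whole support is included.
- Benjamini–Hochberg is hand-authored (step-up with a reverse cumulative
  minimum, capped at 1) and cross-checked against statsmodels in the test
  suite; p = 0 (underflow of extreme Fisher p-values) is accepted input.
- Both exact tests are validated against exhaustive integer enumeration
  (`math.comb`) for every 2×2 table with N ≤ 60, using the margin
  symmetries to deduplicate.

## Expression aggregation

- The sampling unit is the gene: per-gene mean TPM over the tissues of a
  group (7 gastrointestinal tissues; 13 brain regions). Treating tissues as
  replicates would pseudo-replicate, since tissue columns of the same gene
  are strongly correlated.
- Group comparisons use the two-sided Mann–Whitney U test with the
  asymptotic normal approximation (group sizes here are far beyond the
  small-sample regime); heterogeneity across regions uses one-way ANOVA
  with genes as replicates. Identical tissue vectors short-circuit to
  F = 0, p = 1 rather than 0/0.
- Ranks within a tissue group order tissues by descending mean TPM with
  ties broken by tissue name, so output ordering is deterministic.

## Synthetic-data generator

- **Streams.** Every output file draws from its own generator seeded by
  `SeedSequence([seed, role])`, so adding a file never perturbs another and
  a fixed seed reproduces each file byte for byte.
- **Catalogs.** The plan plants, per gene, the number of distinct
  publications per trait and a set of genome-wide-significant SNPs with
  known classes; the writer guarantees each gene appears in exactly its
  planted number of PUBMEDIDs, renders p-values in all three catalog
  dialects, and exercises the `", "` / `" - "` / alias / Ensembl-only
  spellings of the gene field. Internally inconsistent plans (e.g. a SNP
  planted as UC-significant for a gene with no UC publications) are
  rejected at construction.
- **Expression.** Gene-set genes are log-normal around the planted group
  mean of their tissue's group (defaults 22.54 TPM gastrointestinal, 12.76
  brain), background genes around a lower baseline. Noise decomposes into a
  gene-level factor shared across tissues (σ_log = 0.12) and an independent
  per-cell factor (σ_log = 0.3), both mean-one on the natural scale; the
  shared gene factor reflects that gene identity dominates expression
  variance in real data, and it makes the unpaired group test conservative
  under the null. Brain-region multipliers (σ_log = 0.3) are renormalized
  to mean one per group so planted group means are preserved exactly; with
  all σ = 0 every value equals its planted mean.
- The matrix's leading gene-set rows can be labeled with external
  (Ensembl ID, symbol) pairs to tie it to a simulated catalog bundle;
  identities never affect the sampled values.
- **Scope.** The generator validates pipeline correctness (planted-truth
  recovery), not biological realism: no linkage disequilibrium, no study
  overlap between traits, and independence across genes apart from the
  shared noise factor.

## Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| genome-wide threshold | 5×10⁻⁸ (strict <) | conventional GWAS significance |
| recurrence threshold | ≥ 3 publications | screens out single-study hits while keeping moderately replicated genes |
| word-cloud threshold | p < 0.01 (strict) | nominal evidence volume |
| background N | 20,000 | protein-coding gene count |
| alpha | 0.05 | conventional; BH-adjusted within each call's family |
| Fisher tie tolerance | 1e-7 relative | absorbs float noise in tied tables |

## Open design decisions and limitations

- The Fisher test uses the point-probability two-sided rule (the common
  convention, matching `scipy.stats.fisher_exact`); other two-sided
  definitions (tail-doubling) would give slightly different p-values for
  asymmetric margins.
- The odds-ratio interval is the Wald interval on log-OR; exact conditional
  intervals would be wider for sparse tables.
- The BH family is always exactly the set of tests in one call; no
  across-call correction is attempted.
- Mann–Whitney p-values use the asymptotic approximation; for group sizes
  below ~20 per side the exact method would be preferable (the test suite
  bounds the discrepancy at small n).
- Synthetic catalogs draw publications per trait independently, so the
  UC/CD recurrent-set overlap in the bundle is structural (the planted
  panel), not an emergent property.
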