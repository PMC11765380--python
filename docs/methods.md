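# Methods

## Proteoform counting from Swiss-Prot annotation

A proteoform is one distinct molecular form of a protein: one gene can
yield many through alternative splicing, genomic sequence variation, and
post-translational modification. The package counts, per reviewed
Swiss-Prot entry:

- **AS sequences** — the `Named isoforms=k` count of the entry's
  `CC -!- ALTERNATIVE PRODUCTS` block, counted only when the block's
  `Event` includes alternative splicing. The default convention
  (`all_named`) counts all *k* named isoforms, so a spliced gene
  contributes at least 2; `non_canonical` (k−1) is available as a flag.
  `VAR_SEQ` feature sites are parsed and exposed on the record
  (`splice_features`) as the alternative evidence stream, but are not the
  default AS count: isoform declarations are curated per-gene statements,
  VAR_SEQ lines are per-segment evidence.
- **SAP sequences** — one per `FT VARIANT` feature line.
- **PTM sequences** — one per PTM feature site. Default key set:
  `MOD_RES`, `CARBOHYD`, `LIPID`, `CROSSLNK`. `DISULFID` is excluded by
  default because disulfide bridges are a folding/structural feature rather
  than a chemical proteoform in most treatments; the set is configurable.
  Per-site counting is used because a per-protein count could never exceed
  one PTM sequence per gene, which is inconsistent with observed per-gene
  PTM averages well above 1 in densely annotated species.

Entries map to genes by `(NCBI taxon, gene label)`, with GN-line precedence
`Name > OrderedLocusNames > ORFNames` and the primary accession as
fallback, so unnamed entries form singleton genes rather than silently
deflating N. Counts are summed over a gene's entries. Feature coordinates
stay 1-based inclusive as printed in the flat file; a cross-link's second
coordinate may lie beyond the chain (inter-chain links) and is exempt from
the bounds check.

Parsing delegates per-entry field extraction to `Bio.SwissProt`; the
package only chunks the stream on `//` terminators so that one malformed
entry is skipped with a warning naming its starting line instead of
aborting the file.

## The width models

With N genes, event-class gene counts ASg/SAPg/PTMg and event totals
AS/SAP/PTM, the densities (ASd = ASg/N, …) and per-gene averages
(ASav = AS/ASg, …, defined as 0 when the denominator is 0):

```
Nps1 = N (1 + ASd ASav + SAPd SAPav + PTMd PTMav)
Nps2 = Nps1 + AS (SAPav + PTMav)
Nps3 = Nps2 + N SAPav PTMav + AS SAPav PTMav
```

All evaluation uses `fractions.Fraction` on the integer counts. This is a
correctness choice, not a style one: the densities and averages are exact
ratios, and under rational arithmetic Nps1 telescopes to the integer
identity `Nps1 = N + AS + SAP + PTM`, which floating evaluation would
satisfy only approximately. The zero-denominator convention (`av = 0` when
the gene count is 0) makes the models total and collapses them correctly
for degenerate species: with AS = 0, model 2 equals model 1; with SAP = 0
or PTM = 0, model 3 equals model 2 — the regime of a PTM-only minimal
genome (6 genes, PTMs on 4 of them, 7 PTM sequences → 13 proteoforms under
all three models).

N defaults to the number of distinct gene keys in the parsed file; an
override is accepted because the protein-coding gene count of a species
differs between database releases and tables, while event totals are more
stable.

## Report precision

Per-PCG ratios (Nps/N) are rounded half-up to one decimal and printed with
a trailing `.0` dropped. Coverage percentages use tiered precision —
integer at ≥10%, one decimal at 1–10%, one significant figure below 1% —
also half-up. Published coverage tables mix truncation into roughly a third
of rows (e.g. 32.87% printed as 32, 1.69% as 1.6) and one rodent row uses a
different gene-count input than the same table prints; the package applies
its single convention and *logs* disagreements rather than
reverse-engineering a per-row convention. All 90 published per-PCG ratio
cells reproduce exactly under this convention; 18 of 30 coverage cells do,
and the remaining 12 are exactly the truncated/inconsistent rows.

## Orthogroup overlap

The overlap statistic for target species *t* is the number of orthogroups
with a nonempty intersection between the human column and the mapped
aging-protein set, and a nonempty *t* column. Aging genes enter as symbols
and are joined to protein accessions through an explicit mapping table
(orthogroup tables carry protein ids, not gene symbols); unmapped symbols
are reported, never fatal. Enlarging the aging set can only grow the
counts, and the human-vs-human count equals the number of aging-containing
orthogroups — both properties are tested.

### RBH inferrer (desk-scale stand-in)

For self-contained validation the package infers orthogroups by reciprocal
best hits: global Needleman–Wunsch alignment (BLOSUM62; affine gaps with
open 10, extend 1, i.e. a length-k gap costs 10 + k), best hit per query
per target species with ties broken by lexicographically smallest target
id, reciprocal pairs as edges, and connected components of size ≥2 as
orthogroups (ids assigned after sorting components, so inference is
invariant to input order). This is a classical heuristic chosen for
determinism and testability; it does not replicate OrthoFinder's
DIAMOND+MCL pipeline, and full-scale orthogroup counts over complete
proteomes are explicitly out of scope. Because RBH links at most one best
hit per query and species pair, exact recovery of planted families is
guaranteed only with one member per species per family; with paralogs
present, surplus members become singletons and are dropped from the table.

## Synthetic data

`generate_flatfile` plants structure deterministically: exactly
`round(fraction · n_genes)` genes per event class (membership drawn with
the seed, counts exact), exactly `*_per_gene` events per affected gene, one
entry per gene, sequences uniform over the 20 amino acids. Deterministic
planting rather than Bernoulli sampling is deliberate: the generator's
implied parameter vector is arithmetic, so pipeline recovery is tested for
*exact* equality (a recovery report diffs all 13 fields), not
statistically. Byte-identical output under equal seeds is part of the
contract.

`generate_ortholog_families` derives each family's ancestor from a common
root mutated to the between-family identity level, and each member from its
family ancestor at the within-family level (default 90% within vs 20%
between — comfortably separated for RBH at the default sequence length of
80 aa). A planted fraction of families is marked as aging through their
human members. What this emulates is membership structure at controlled
divergence; it does not emulate real proteome composition, domain
architecture, indels, or realistic PTM-type distributions — so passing
tests demonstrate the counting and inference logic, not database-scale
biology.

Analysis problem sizes (tens of genes per synthetic species, 8 families ×
4 species, 100-spec recovery sweeps, 1,000 random width vectors, 200 random
overlap tables) were chosen as the smallest sizes that exercise every code
path and every degenerate regime; all stages are exact, so scale adds no
statistical power.

## Known limitations

- Whether curators counted named isoforms or VAR_SEQ segments for AS, and
  whether disulfides counted as PTMs, is not recoverable from published
  totals; both choices are exposed as options with the defaults argued
  above.
- The published absolute width totals depend on a full per-species
  parameter table at one specific UniProt release and are not recomputed
  here; only their ratio columns are.
- TrEMBL (unreviewed) entries, UniProt XML, live REST fetching and isoform
  sequence reconstruction are out of scope.
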