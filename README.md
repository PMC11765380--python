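# proteowidth

Estimating the **proteome width** of model organisms — the number of
distinct proteoforms a genome can encode — from expert-reviewed
UniProtKB/Swiss-Prot annotation, together with two companion statistics
used to rank model species for aging research: genome **annotation
coverage** and the **orthogroup overlap** between a human aging-gene list
and each species' proteome.

It is written for comparative proteomics work: given per-species Swiss-Prot
flat files (reviewed entries), an Ensembl gene-count table, an aging-gene
list, and an orthogroups table (OrthoFinder `Orthogroups.tsv` dialect, or
FASTA proteomes for the built-in reciprocal-best-hit inferrer), it produces
the three report tables of such a study.

## The model

Each species is summarized by a 13-parameter vector built from three
annotation layers of its reviewed proteome — alternative splicing (AS),
single-amino-acid polymorphisms (SAP, `FT VARIANT` features), and
post-translational modifications (PTM):

- *N* — protein-coding genes; *ASg*, *SAPg*, *PTMg* — genes with ≥1 event
  of each class;
- *AS*, *SAP*, *PTM* — event-bearing sequence counts;
- densities *ASd* = ASg/N (likewise SAPd, PTMd) and per-gene averages
  *ASav* = AS/ASg (likewise SAPav, PTMav; defined as 0 when the gene count
  is 0).

Three information models turn the vector into a proteoform count *Np(H)*:

```
Nps1 = N · (1 + ASd·ASav + SAPd·SAPav + PTMd·PTMav)
Nps2 = Nps1 + AS · (SAPav + PTMav)
Nps3 = Nps2 + N · SAPav·PTMav + AS · SAPav·PTMav
```

Model 1 puts sequence changes only on canonical sequences, model 2 also on
splice variants, model 3 lets SAPs and PTMs co-occur on any sequence. The
densities are ratios of integers, so the package evaluates the formulas in
exact rational arithmetic; the identity `Nps1 = N + AS + SAP + PTM` holds
exactly, and `Nps3 ≥ Nps2 ≥ Nps1 ≥ N` always.

Annotation coverage is `100 · PCG_SwissProt / genes_Ensembl` (it can exceed
100% for redundantly annotated bacteria). The overlap statistic counts, per
target species, orthogroups containing at least one mapped human aging
protein and at least one protein of that species.

## Worked example

Evaluate the width models on a parameter vector with 10 genes, 2 spliced
genes carrying 4 splice sequences, 5 SAP genes with 10 SAP sequences and 20
PTM sequences on all 10 genes:

```python
>>> from proteowidth import ProteomeParameters, compute_widths
>>> p = ProteomeParameters(N=10, ASg=2, AS=4, SAPg=5, SAP=10, PTMg=10, PTM=20)
>>> w = compute_widths(p)
>>> (w.nps1, w.nps2, w.nps3)
(Fraction(44, 1), Fraction(60, 1), Fraction(116, 1))
>>> w.per_pcg(p.N)
(4.4, 6.0, 11.6)
```

44 = 10 genes + 4 + 10 + 20 event sequences (the model-1 identity); model 2
adds 4·(2+2)=16 variant-borne events; model 3 adds the SAP×PTM
combinations. Or end to end from a synthetic flat file:

```
$ proteowidth simulate --n-genes 20 --as-fraction 0.5 --ptm-fraction 0.5 \
      --seed 3 --out synth.dat
planted N=20 ASg=10 AS=20 SAPg=0 SAP=0 PTMg=10 PTM=10
$ proteowidth extract synth.dat --species synth
species	taxon_id	N	ASg	AS	SAPg	SAP	PTMg	PTM
synth	9606	20	10	20	0	0	10	10
```

The extracted row equals the planted truth exactly — the parser, gene
aggregation and parameter derivation are lossless on well-formed input.
The numbered scripts under `analysis/` run the full study on synthetic
inputs plus the bundled published gene-count tables and write their reports
under `results/` (run them in order; `01` generates what the later ones
consume).

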