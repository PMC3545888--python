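# baculokit

Annotation and comparative analysis of circular baculovirus genomes, built
around the *Helicoverpa armigera* multinucleocapsid nucleopolyhedrovirus
(HearMNPV, GenBank NC_011615) and its closest relative MacoNPV-B.

Baculoviruses carry circular double-stranded DNA genomes of 100-180 kb whose
annotation follows a small set of field conventions: ORFs are
methionine-initiated frames of ≥ 150 nt (50 aa) with minimal mutual overlap,
numbered from the adenine of the polyhedrin ATG; early transcription is
signalled by a TATA box with a CAGT/CATT initiator 20-40 nt downstream and
late transcription by (A/T/G)TAAG, both within 180 nt upstream of the start
codon; homologous regions (*hr*s) — enhancer/origin elements — are tandem
arrays of ~40-bp imperfect palindromes (type A) with 31-bp direct repeats
(type B) at their flanks; and between-genome relationships are read off
identity–gene-parity plots of ordinal gene positions. `baculokit` implements
each of these steps as a tested library module, plus absolute qPCR
quantification (standard curve Ct = m·log₁₀ copies + b, actin
normalisation, phase labelling and doubling arithmetic) for replication
kinetics, and a synthetic-data generator that plants every one of these
structures with recorded ground truth.

## Layout

- `src/baculokit/` — the library: `genome_io` (FASTA/GFF3/annotation-table
  dialect, circular 1-based coordinates), `orf_annotation` (six-frame
  circular ORF calling + minimal-overlap resolution), `promoter_scan`,
  `hr_analysis`, `comparative` (Needleman–Wunsch identity, reciprocal-best-hit
  homologs, parity/collinearity, segmental indels, ITR+TTAA transposon
  signatures), `replication_kinetics`, `genome_stats`, `synthetic_data`,
  and a `click` CLI (`baculokit --help`).
- `src/baculokit/data/hearmnpv_orfs.tsv` — the published HearMNPV annotation
  table (162 ORFs, 4 hrs) with per-virus homolog/identity columns.
- `analysis/01…05_*.py` — numbered analysis drivers; each writes its tables
  under `results/`.
- `tests/` — pytest suite, including brute-force oracle comparisons.

## Worked example

```sh
$ python analysis/01_genome_annotation_report.py
162 ORFs over 154,196 bp (85 forward / 77 reverse)
encoded amino acids: 46,763 (nominal coding 140,775 bp as span-sum, 139,250 bp overlap-collapsed)
largest ORF 3,627 bp (ORF85, helicase); smallest 150 bp (ORF99, ctl)
69 ORFs overlap a neighbour (1525 nt total, max pairwise 245 nt)
promoter classes: {'early_only': 21, 'late_only': 71, 'both': 9, 'none': 61, 'unassigned': 0}
```

The 162 ORFs cover 90% of the 154-kb genome; 21 carry only an early
promoter signature, 71 only a late one, 9 both and 61 neither. Comparison
against the sister genome:

```sh
$ python analysis/03_comparative_parity.py
MacoNPV-B   : 161 shared ORFs, mean identity 98.5%, 1 HearMNPV-unique genes
...
MacoNPV-B collinearity: Spearman rho = 0.9842, adjacency preserved 96.9%
```

HearMNPV shares all but one gene (ORF139) with MacoNPV-B at a mean amino
acid identity of 98.5% and near-perfect collinearity — the two genomes
differ mainly by a five-gene segmental deletion and one relocated gene,
which `comparative.detect_segmental_indels` and the parity plot recover
exactly on synthetic genome pairs. Replication kinetics:

```sh
$ python analysis/04_replication_kinetics.py
phase sequence: decreasing -> latent -> exponential -> stationary
exponential window 12-48 h: 4.49e+08-fold increase = 28.7 doublings (~29), one copy every 1.24 h
```

i.e. during the exponential phase the virus doubles its genome copy number
roughly every 1.24 h, a ~4.5×10⁸-fold increase between 12 and 48 h
post-infection.

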