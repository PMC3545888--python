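# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model

All coordinates are 1-based inclusive. Position 1 is the adenine of the
polyhedrin ATG, the conventional zero point of a baculovirus physical map,
so the packaged HearMNPV table needs no shift (polyhedrin spans 1..741).
A feature crossing the origin of a circular genome is stored with
`start > end` plus a `wraps` flag; its span is `end − start + 1 + L`.
Orientation is stored as the literal table characters `>` (forward,
clockwise with polyhedrin) and `<`. An ORF's inclusive genomic span is
`3·aa + 3` (stop codon included); its *nominal* length, the figure genome
reports quote in "bp", is `3·aa` (stop excluded). Both are used and labelled
explicitly throughout.

## ORF calling

An ORF candidate is a methionine-initiated reading frame of at least
`min_aa` (default 50) amino acids, counting the initiator Met and excluding
the stop, terminating at TAA/TAG/TGA. The 150-nt threshold quoted in the
field therefore corresponds to a 153-nt genomic span. Each stop-to-stop
interval contributes at most one candidate, anchored at its *first* ATG
(the default of the classical ORF-finding tools). Circular genomes are
scanned by walking every stop-to-stop interval around the circle — exact
for any genome length, unlike a doubled-sequence scan, because reading-frame
chains only repeat with period L when L ≡ 0 (mod 3). A candidate containing
an N anywhere in its span is rejected (conservative calling on draft
sequence). Candidates whose span would exceed the genome length are
impossible and dropped.

"Minimal overlap" has no standard quantitative definition; the resolver
admits candidates greedily in decreasing amino-acid length, rejecting any
candidate fully nested in an already-kept ORF or overlapping one by more
than `max_overlap_nt` (default 250 nt, configurable). The default cap was
chosen because the largest retained overlap between neighbouring genes in
the packaged HearMNPV table is 245 nt; a smaller cap would split such real
gene pairs. Ties in the greedy order are broken by start coordinate, then
end, then strand, so the output is independent of input order.

## Promoter classification

The upstream window is `window` nt (default 180) strictly upstream of, and
not including, the A of the ATG, taken on the ORF's coding strand and
wrapping the origin on circular genomes. Motifs must lie entirely inside
the window; a late motif whose tail would overlap the ATG is therefore not
counted. The late signature is (A/T/G)TAAG. The early signature is a TATA
box with a CAGT or CATT initiator whose first base lies 20-40 nt downstream
of the TATA box's first base. Since no canonical TATA-box definition exists
for these screens, the loosest literal `TATA` is the default, configurable
to IUPAC patterns such as `TATAWA`; classification counts (early-only /
late-only / both / none) depend on that choice. Overlapping upstream genes
are not masked — the window is raw sequence — because published screens
give no exclusion rule. The exclusive four-way tally always sums to the
number of ORFs.

The packaged HearMNPV table's promoter column tallies to 21 early-only, 71
late-only, 9 both, 61 none.

## Homologous-region detection

hrs are modelled exactly as the two-domain repeat structure described for
the MacoNPV lineage: near-palindromic type-A units (default 40 nt) and
31-nt type-B direct repeats at the head/end of one or both sides of each
palindrome.

* **Type A.** Every window whose left arm matches the reverse complement of
  its right arm with at most `max_arm_mismatch` (default 3) mismatches.
  Overlapping windows within half a unit length are reduced by non-maximum
  suppression (fewest mismatches wins; ties go to the leftmost window). The
  reported `mismatches` field is the Hamming distance of the unit to its own
  reverse complement (= 2 × arm mismatches).
* **Type B.** The immediate left/right 31-mers of all type-A units
  (de-duplicated by position) are single-linkage clustered at the mismatch
  threshold (default 4); the largest cluster, if it has ≥ 2 members, yields
  a column-majority consensus. A single copy is never called a repeat. Each
  palindrome side is then scanned outward within `search_radius` (100 nt)
  and the *nearest* placement within the threshold is reported, at most one
  per side — nearest-first, rather than best-first, because the repeats sit
  at the head/end of the palindrome and a better-scoring copy further away
  belongs to a neighbouring unit.
* **Regions.** Units are single-linkage clustered with an inter-unit gap cap
  of 500 nt; clusters with ≥ 2 type-A units become regions named hr1, hr2, …
  in genome order. Regions overlapping annotated ORFs by more than half
  their length are dropped (hrs are intergenic). AT-richness is reported per
  region, never used as a gate, since "AT-rich" is qualitative.
* **Architecture diff.** Between two genomes, regions are paired by rank and
  each unit reduced to a (type, orientation) token; an LCS-based minimal
  insertion/deletion script is reported with nucleotide extents from the
  unit coordinates. Substitution-level differences inside units are not part
  of the edit script.

The defaults keep each of the four HearMNPV hrs (724-1,766 bp) a single
cluster. Published percent identities between corresponding hrs of two
genomes depend on an unstated alignment procedure and are not reproduced.

## Comparative analysis

Protein pairs are aligned by global Needleman–Wunsch under unit scoring
(match +1, mismatch 0, gap −1, linear penalty) with a deterministic
diagonal > up > left traceback. Percent identity uses the full alignment
length, gap columns included, as denominator (configurable convention).
Homologs are reciprocal best hits on percent identity, ties broken by
alignment score then lower index; pairs under 15% identity are dropped, a
floor chosen below the lowest identity printed in the packaged table
(16.7%) so no published pair would be lost. Parity data places each shared
gene at its ordinal ranks in the two genomes and each unique gene on an
axis; identity bins default to <30 / 30-50 / 50-70 / ≥70%. Collinearity is
Spearman's rank correlation plus the fraction of consecutive-in-A shared
pairs whose partners are adjacent in B (inversion-tolerant). Segmental
indels are maximal runs of ≥ `min_run` (2) consecutive unpaired genes
flanked by paired ones; a genome end counts as a flank and is marked
`None`. When parity is built from a published homolog table rather than
reciprocal best hits, duplicate partner ids are tolerated (a relocated gene
and its collinear paralog may both point at the same partner ORF), whereas
the RBH path treats duplicates as an integrity error.

Transposon signatures are exact by definition: a `tsd` (default TTAA)
immediately 5′ of the element, an `itr_len`-mer (default 13) opening the
element whose reverse complement closes it, and the `tsd` again immediately
3′; one mismatched ITR base disqualifies. All qualifying (start, end) pairs
within the region and span cap are reported.

## Replication kinetics

Triplicate Ct values are averaged on the Ct scale before any conversion.
The standard curve is an ordinary least-squares fit of mean Ct on log₁₀
copies (≥ 3 dilution points, negative slope required); efficiency is
`10^(−1/slope) − 1`, warned outside [0.8, 1.1]. Quantification inverts the
curve; normalisation reports viral copies per 10⁵ host actin copies and is
invariant under common rescaling. Phase labels are per-interval from the
log₂ growth rate r: decreasing if r < −0.05 log₂/h, exponential if
r ≥ 0.5 log₂/h, otherwise latent before the first exponential interval and
stationary after it. The two thresholds are conventions chosen so that the
canonical four-phase trajectory labels cleanly; they are configurable.
Kinetics over a window report fold change, doublings = log₂(fold),
doubling time = window/doublings, plus the integer-rounded pair (genome
reports quote "about 29 times, 1.24 h"). Fold changes computed from the
published 12-48 h endpoints (452 → 2.02×10¹¹ per 10⁵ actin) give
4.469×10⁸; printed figures truncate, so comparisons use 1% relative
tolerance. A flat window (doublings = 0) reports its doubling time as
absent rather than infinite.

## Genome summary statistics

Two coding totals are reported deliberately — the sum of inclusive spans
and the overlap-collapsed union — because published genome reports rarely
state their convention and the two differ by >1 kb here. Intergenic
sequence is `L − union − hr_total`. GC/AT percentages exclude N. Overlap
statistics run over all ORF pairs with intersecting inclusive spans.

The packaged HearMNPV table is internally consistent row by row (every span
equals 3·aa + 3) but several of the *prose* summary figures published with
it cannot be reconstructed from it: the rows sum to 46,763 aa (prose:
46,677), orientation counts are 85/77 (prose: 86/76 — and the prose's own
percentages contradict its counts), 69 ORFs overlap a neighbour in 40
adjacent pairs totalling 1,525 nt with a 245-nt maximum (prose: 38 ORFs,
1,485 nt, 1-244 bp), and the prose's mean identities for AcMNPV (44.7%) and
HearSNPV-G4 (41.0%) are exactly swapped relative to the table columns. The
table is treated as authoritative throughout; the affected figures agree
with the prose to within 0.2-2%.

## Synthetic data

The generator's defaults are the study conditions the rest of the package
is validated under: 20 ORFs of 60-300 aa on random strands, an equal
early/late/both/none promoter mix, four hr cassettes of 3-7 type-A units
(40 nt, AT bias 0.7) with type-B repeats (31 nt) abutting one or both
sides, 2% per-base unit noise, a partner genome at 5% substitution
divergence carrying one five-gene deletion and optionally one relocated
gene, and a qPCR trajectory anchored at the published values (452 per 10⁵
actin at 12 h, 0.798 log₂/h to 2.02×10¹¹ at 48 h, threefold decrease over
0-4 h, slow stationary rise of 0.047 log₂/h, Ct noise sd 0.3, slope
−3.3219, intercept 40). Genomes come out around 16-20 kb — a deliberate
scale-down from 154 kb that preserves every structure the detectors target
while keeping the suite fast.

Construction guarantees, in order: ORFs are random non-stop codons;
intergenic spacers are stop-dense soup (a forward- or reverse-strand stop
trinucleotide every few bases, drifting through all six frames, with C/G
shims that keep the filler far from self-complementarity); each upstream
window is rebuilt to carry exactly its promoter class (wanted motifs
planted and protected, competing motifs scrubbed, an in-frame TAA abutting
the ATG so the planted ATG is always its interval's first); and after
assembly the generator re-scans its own product with an independent
brute-force scanner, breaking any residual ≥ 50-aa off-target reading frame
or off-target near-palindrome by codon-respecting edits, then re-verifies
every window class, iterating until all three checks pass. Type-A unit
noise is resampled until the unit stays within the near-perfect threshold
(≤ 3 arm mismatches): the structure being planted *is* a near-perfect
palindrome, so noise that destroys palindromy would change the truth, not
perturb it. Divergence is synonymous-biased inside ORFs (75% of
substitution events try a synonymous codon swap), suppressed inside planted
promoter windows and hr units, and free in spacer middles; the relocated
gene is spliced into the middle of a distant spacer so neighbouring ORFs'
realized windows survive. The qPCR latent phase is held flat even though
the in-vivo report describes a ~7× rise over 4-12 h, because a rise of that
size is not "latent" under any rate threshold consistent with the other
phases; the 12-h anchor value is kept.

What the generator does **not** emulate: indel evolution beyond the single
planted deletion, rate heterogeneity, codon-usage bias, overlapping genes,
origin-wrapping ORFs (tested separately by rotation), per-hr B-unit
consensus divergence (one genome-wide B consensus is used, where real
genomes drift per-hr), or amplification-efficiency differences between
qPCR targets. Passing recovery tests therefore demonstrates correctness of
the detection logic under the stated model, not performance on real
sequencing data with those extra complications.

## Problem sizes

The test suite uses 20-ORF genomes, 5 seeds per recovery metric, 1,000
seeded instances per brute-force-oracle comparison (small sequences:
45-400 nt; alignment oracles on ≤ 6-mers where exhaustive enumeration is
feasible), and 200 simulated qPCR experiments for the noisy doubling-count
recovery rate. `scripts/acceptance.py` re-derives its synthetic seeds from
the single `--seed` argument.

## Known limitations

* The promoter tally from raw sequence depends on the configurable TATA
  pattern; only the table-derived tally is asserted exactly.
* Reciprocal-best-hit homology is adequate at desk scale but quadratic in
  proteome size; the published homolog columns can be supplied directly to
  bypass it.
* `find_palindromes` scans the linear sequence; a palindrome straddling the
  origin would be missed (no known hr does).
* The hr architecture diff treats units as tokens; it does not align unit
  sequences internally.
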