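#!/usr/bin/env python
"""Genome-wide annotation summary of the HearMNPV reference table.

Loads the packaged 162-ORF / 4-hr annotation (GenBank NC_011615), computes
the summary statistics (coding totals, orientation, overlaps, extremes,
promoter tally) and writes them to results/genome_summary.tsv.
"""

from pathlib import Path

from baculokit.genome_io import load_reference_annotation
from baculokit.genome_stats import summarize

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ann = load_reference_annotation()
    s = summarize(None, ann)
    OUT.mkdir(exist_ok=True)
    with open(OUT / "genome_summary.tsv", "w") as fh:
        for key, val in s.as_rows():
            fh.write(f"{key}\t{val}\n")
    print(f"{s.n_orfs} ORFs over {s.genome_length:,} bp "
          f"({s.n_forward} forward / {s.n_reverse} reverse)")
    print(f"encoded amino acids: {s.total_aa:,} "
          f"(nominal coding {s.total_coding_nt:,} bp as span-sum, "
          f"{s.union_coding_nt:,} bp overlap-collapsed)")
    print(f"largest ORF {s.largest_orf[1]:,} bp (ORF{s.largest_orf[0]}, "
          f"helicase); smallest {s.smallest_orf[1]} bp "
          f"(ORF{s.smallest_orf[0]}, ctl)")
    print(f"{s.n_overlapping_orfs} ORFs overlap a neighbour "
          f"({s.total_overlap_nt} nt total, "
          f"max pairwise {s.max_overlap_nt} nt)")
    print(f"promoter classes: {s.promoter_tally}")
    print(f"-> {OUT / 'genome_summary.tsv'}")


if __name__ == "__main__":
    main()
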