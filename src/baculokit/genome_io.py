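"""Readers, writers and the circular-coordinate model.

Coordinates are 1-based inclusive throughout, with position 1 anchored at the
adenine of the polyhedrin ATG (the conventional zero point of a baculovirus
physical map).  Features that cross the origin of the circular genome are
stored with ``start > end`` plus a ``wraps`` flag; their nucleotide span is
``end - start + 1 + genome_length``.

The annotation-table dialect mirrors the published HearMNPV ORF table: one row
per ORF with columns ``ORF, Name, Start, Orient, End, Prm, Length_aa`` followed
by repeated ``<virus>_ORF, <virus>_Pct`` homolog pairs, and trailing rows named
``hr*`` carrying only Name/Start/End for the homologous regions.  Orientation
is stored as the literal characters ``>`` (forward, clockwise with polyhedrin)
and ``<`` (reverse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, IntegrityError

NUCLEOTIDES = set("ACGTN")

FORWARD = ">"
REVERSE = "<"

PROMOTER_CLASSES = ("early", "late", "both", "none", "unassigned")

#: Prm-column byte representation of each promoter class.
_PRM_TO_CLASS = {"E": "early", "L": "late", "E,L": "both", "": "none"}
_CLASS_TO_PRM = {"early": "E", "late": "L", "both": "E,L",
                 "none": "", "unassigned": ""}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return str(Seq(seq).reverse_complement())


@dataclass
class CircularGenome:
    """A (by default circular) nucleotide sequence with 1-based coordinates."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise FormatError(
                f"genome {self.id!r}: non-nucleotide characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int, wraps: bool = False) -> str:
        """Sequence of the 1-based inclusive interval, wrapping if asked."""
        if wraps:
            if not self.circular:
                raise IntegrityError("wrapping fetch on a linear genome")
            return self.sequence[start - 1:] + self.sequence[:end]
        return self.sequence[start - 1:end]


@dataclass
class OrfRecord:
    """One annotation-table row: an ORF with coordinates and homology columns.

    ``start`` is always the leftmost genome coordinate and ``end`` the
    rightmost (ATG sits at ``start`` for forward ORFs, at ``end`` for reverse
    ones) unless ``wraps`` is set, in which case ``start > end``.
    """

    index: int
    name: str
    start: int
    end: int
    strand: str
    length_aa: int
    promoter_class: str = "unassigned"
    homologs: dict[str, tuple[str, float]] = field(default_factory=dict)
    wraps: bool = False
    flagged: bool = False

    def span_nt(self, genome_length: int | None = None) -> int:
        """Inclusive genomic span, including the stop codon."""
        if self.wraps:
            if genome_length is None:
                raise IntegrityError("wrapping ORF needs a genome length")
            return self.end - self.start + 1 + genome_length
        return self.end - self.start + 1

    def nominal_bp(self) -> int:
        """ORF length on the 3*aa convention (stop codon excluded)."""
        return 3 * self.length_aa


@dataclass
class AnnotationSet:
    """A genome's ordered ORF records plus its homologous-region intervals."""

    genome_id: str
    genome_length: int
    orfs: list[OrfRecord] = field(default_factory=list)
    hrs: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        starts = [o.start for o in self.orfs]
        if starts != sorted(starts):
            raise IntegrityError("ORFs are not sorted by start")
        idx = [o.index for o in self.orfs]
        if idx != list(range(1, len(idx) + 1)):
            raise IntegrityError("ORF indices not contiguous from 1")
        for o in self.orfs:
            if not (1 <= o.start <= self.genome_length
                    and 1 <= o.end <= self.genome_length):
                raise IntegrityError(f"ORF {o.index}: coordinates outside genome")

    def homolog_viruses(self) -> list[str]:
        seen: list[str] = []
        for o in self.orfs:
            for v in o.homologs:
                if v not in seen:
                    seen.append(v)
        return seen


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, circular: bool = True) -> list[CircularGenome]:
    """Read every record of a FASTA file as a :class:`CircularGenome`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    genomes, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        genomes.append(CircularGenome(rec.id, str(rec.seq), circular=circular))
    return genomes


def write_fasta(genomes: list[CircularGenome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation-table dialect

def read_annotation_table(path) -> AnnotationSet:
    """Parse the tabular ORF/hr annotation dialect into an AnnotationSet.

    Rows whose Name matches ``hr*`` (with an empty ORF column) become hr
    intervals.  A row whose span disagrees with ``3*aa + 3`` is kept but
    flagged with a warning, matching the tolerant reading of published tables.
    """
    genome_id, genome_length = "", None
    header: list[str] | None = None
    orfs: list[OrfRecord] = []
    hrs: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "genome_id":
                    genome_id = parts[1]
                elif parts[0] == "genome_length":
                    genome_length = int(parts[1])
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                continue
            cells += [""] * (len(header) - len(cells))
            cells = [c.strip() for c in cells]
            row = dict(zip(header, cells))
            if not row.get("ORF") and row.get("Name", "").startswith("hr"):
                hrs.append((row["Name"], int(row["Start"]), int(row["End"])))
                continue
            if not row.get("ORF"):
                continue
            homologs: dict[str, tuple[str, float]] = {}
            for col in header:
                if col.endswith("_ORF") and row.get(col):
                    virus = col[:-4]
                    pct = row.get(f"{virus}_Pct", "")
                    homologs[virus] = (row[col], float(pct) if pct else 0.0)
            orf = OrfRecord(
                index=int(row["ORF"]),
                name=row.get("Name", ""),
                start=int(row["Start"]),
                end=int(row["End"]),
                strand=row["Orient"],
                length_aa=int(row["Length_aa"]),
                promoter_class=_PRM_TO_CLASS.get(row.get("Prm", ""), "none"),
                homologs=homologs,
            )
            orfs.append(orf)
    if header is None or (not orfs and not hrs):
        raise FormatError(f"{path}: no records")
    if genome_length is None:
        genome_length = max(max((o.end for o in orfs), default=0),
                            max((e for _, _, e in hrs), default=0))
    ann = AnnotationSet(genome_id, genome_length, orfs, hrs)
    for o in orfs:
        if not (1 <= o.start <= genome_length and 1 <= o.end <= genome_length):
            raise FormatError(
                f"ORF {o.index}: coordinate outside genome length {genome_length}")
        if o.span_nt(genome_length) != 3 * o.length_aa + 3:
            o.flagged = True
            warnings.warn(
                f"ORF {o.index} ({o.name or 'unnamed'}): span "
                f"{o.span_nt(genome_length)} nt inconsistent with "
                f"{o.length_aa} aa", stacklevel=2)
    return ann


def write_annotation_table(ann: AnnotationSet, path,
                           viruses: list[str] | None = None) -> None:
    """Write an AnnotationSet back out in the annotation-table dialect."""
    if viruses is None:
        viruses = ann.homolog_viruses()
    header = ["ORF", "Name", "Start", "Orient", "End", "Prm", "Length_aa"]
    for v in viruses:
        header += [f"{v}_ORF", f"{v}_Pct"]
    lines = [f"# genome_id\t{ann.genome_id}",
             f"# genome_length\t{ann.genome_length}",
             "\t".join(header)]
    for o in ann.orfs:
        row = [str(o.index), o.name, str(o.start), o.strand, str(o.end),
               _CLASS_TO_PRM[o.promoter_class], str(o.length_aa)]
        for v in viruses:
            if v in o.homologs:
                oid, pct = o.homologs[v]
                row += [oid, format(pct, "g")]
            else:
                row += ["", ""]
        lines.append("\t".join(row))
    for name, s, e in ann.hrs:
        lines.append("\t".join(["", name, str(s), "", str(e), "", ""]
                               + [""] * (2 * len(viruses))))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(ann: AnnotationSet, path) -> None:
    """Export ORFs as CDS features and hrs as repeat_region features.

    An origin-wrapping ORF is emitted as two part-lines sharing an ID, per the
    GFF3 convention for discontinuous features on circular molecules.
    """
    seqid = ann.genome_id or "genome"
    lines = ["##gff-version 3",
             f"##sequence-region {seqid} 1 {ann.genome_length}"]
    for o in ann.orfs:
        strand = "+" if o.strand == FORWARD else "-"
        attrs = f"ID=orf{o.index}"
        if o.name:
            attrs += f";Name={o.name}"
        attrs += f";promoter_class={o.promoter_class}"
        parts = ([(o.start, ann.genome_length), (1, o.end)] if o.wraps
                 else [(o.start, o.end)])
        for s, e in parts:
            lines.append("\t".join(
                [seqid, "baculokit", "CDS", str(s), str(e), ".",
                 strand, "0", attrs]))
    for name, s, e in ann.hrs:
        lines.append("\t".join(
            [seqid, "baculokit", "repeat_region", str(s), str(e), ".",
             ".", ".", f"ID={name};Name={name}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> AnnotationSet:
    """Re-import a GFF3 written by :func:`write_gff3` (coordinates only)."""
    seqid, length = "", 0
    cds: dict[str, dict] = {}
    hrs: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, seqid, _, ln = line.split()
                length = int(ln)
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";"))
            s, e = int(cols[3]), int(cols[4])
            if cols[2] == "repeat_region":
                hrs.append((attrs.get("Name", attrs["ID"]), s, e))
                continue
            fid = attrs["ID"]
            entry = cds.setdefault(fid, {
                "name": attrs.get("Name", ""), "strand": cols[6],
                "promoter_class": attrs.get("promoter_class", "unassigned"),
                "parts": []})
            entry["parts"].append((s, e))
    orfs = []
    for fid, entry in cds.items():
        parts = sorted(entry["parts"])
        wraps = len(parts) == 2
        if wraps:
            # parts sorted ascending: (1, end-part) then (start-part, L)
            start, end = parts[1][0], parts[0][1]
        else:
            start, end = parts[0]
        span = (end - start + 1 + length) if wraps else (end - start + 1)
        orfs.append(OrfRecord(
            index=int(fid.replace("orf", "")), name=entry["name"],
            start=start, end=end,
            strand=FORWARD if entry["strand"] == "+" else REVERSE,
            length_aa=(span - 3) // 3,
            promoter_class=entry["promoter_class"], wraps=wraps))
    orfs.sort(key=lambda o: o.start)
    return AnnotationSet(seqid, length, orfs, hrs)


# ---------------------------------------------------------------------------
# GenBank (optional reader, ORIGIN sequence + CDS features only)

def read_genbank(path, circular: bool = True
                 ) -> tuple[CircularGenome, AnnotationSet]:
    rec = SeqIO.read(str(path), "genbank")
    genome = CircularGenome(rec.id, str(rec.seq), circular=circular)
    orfs = []
    n = 0
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        n += 1
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = FORWARD if feat.location.strand != -1 else REVERSE
        span = end - start + 1
        orfs.append(OrfRecord(
            index=n, name=feat.qualifiers.get("gene", [""])[0],
            start=start, end=end, strand=strand,
            length_aa=max((span - 3) // 3, 0)))
    return genome, AnnotationSet(rec.id, len(rec.seq), orfs, [])


# ---------------------------------------------------------------------------
# Packaged reference annotation

def load_reference_annotation() -> AnnotationSet:
    """The packaged HearMNPV ORF/hr table (GenBank accession NC_011615)."""
    from importlib.resources import files
    path = files("baculokit").joinpath("data/hearmnpv_orfs.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return read_annotation_table(str(path))


def reindex(orfs: list[OrfRecord]) -> list[OrfRecord]:
    """Sort ORFs by start and renumber them 1..n."""
    out = sorted(orfs, key=lambda o: (o.start, o.end, o.strand))
    return [replace(o, index=i + 1) for i, o in enumerate(out)]
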