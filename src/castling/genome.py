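"""Genome + ORF annotation model.

All coordinates are 0-based, half-open and genome-forward internally; GFF3
input/output converts from/to the 1-based closed convention of that format.
``stop_codon_start`` is the leftmost genomic coordinate of the three-base
STOP codon interval, regardless of strand (for a minus-strand ORF it equals
``cds_start``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from ._seq import STOP_CODONS, is_dna, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrfRecord:
    """A single protein-coding ORF (terminal exon for spliced genes)."""

    orf_id: str
    chrom: str
    strand: str  # "+" or "-"
    cds_start: int  # 0-based half-open, genome-forward
    cds_end: int
    stop_codon_start: int  # leftmost genomic base of the STOP codon

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def stop_interval(self) -> tuple[int, int]:
        return self.stop_codon_start, self.stop_codon_start + 3


@dataclass
class TerminusWindow:
    """Oriented sequence around an ORF STOP codon with its coordinate map."""

    orf_id: str
    sequence: str  # in ORF orientation
    # local index -> genomic coordinate on the forward strand
    coord_map: list[int]
    chrom: str
    strand: str
    clipped: bool
    # local index of the first STOP-codon base (ORF orientation)
    stop_local: int


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus validated ORF records."""

    chromosomes: dict[str, str]
    orfs: list[OrfRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not is_dna(seq):
                bad = sorted({c for c in seq if c not in "ACGTN"})
                raise ValueError(f"chromosome {name}: invalid characters {bad}")
        for orf in self.orfs:
            self._validate(orf)
        self._index = {o.orf_id: o for o in self.orfs}

    def _validate(self, orf: OrfRecord) -> None:
        if orf.chrom not in self.chromosomes:
            raise ValueError(f"{orf.orf_id}: chromosome {orf.chrom} not in FASTA")
        chrom = self.chromosomes[orf.chrom]
        if not (0 <= orf.cds_start < orf.cds_end <= len(chrom)):
            raise ValueError(f"{orf.orf_id}: CDS outside chromosome bounds")
        length = orf.cds_end - orf.cds_start
        if length % 3 != 0:
            raise ValueError(f"{orf.orf_id}: CDS length {length} not a multiple of 3")
        s, e = orf.stop_interval
        if not (0 <= s and e <= len(chrom)):
            raise ValueError(f"{orf.orf_id}: STOP codon outside chromosome")
        codon = chrom[s:e]
        if orf.strand == "-":
            codon = revcomp(codon)
        if codon not in STOP_CODONS:
            raise ValueError(f"{orf.orf_id}: {codon} is not a STOP codon")

    def orf(self, orf_id: str) -> OrfRecord:
        try:
            return self._index[orf_id]
        except KeyError:
            raise KeyError(f"unknown ORF id: {orf_id}") from None

    @property
    def orf_ids(self) -> list[str]:
        return [o.orf_id for o in self.orfs]


def _orf_from_cds(orf_id: str, chrom: str, strand: str, start: int, end: int) -> OrfRecord:
    """Build an OrfRecord taking the STOP codon as the terminal CDS codon."""
    stop_start = end - 3 if strand == "+" else start
    return OrfRecord(orf_id, chrom, strand, start, end, stop_start)


def load_genome(fasta_path: str | Path, gff_path: str | Path) -> AnnotatedGenome:
    """Load a FASTA + GFF3 pair into a validated :class:`AnnotatedGenome`.

    CDS features are grouped by their ``Parent`` (falling back to ``ID``)
    attribute; for multi-exon ORFs only the STOP-codon location and total CDS
    length are derived from the full set of exons, and the terminal exon
    defines the interval used for terminus windows.  ORFs violating the model
    invariants (length not a multiple of 3, no STOP codon at the annotated
    end, out-of-bounds coordinates) are excluded with a logged reason.
    """
    import gffutils

    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    if not gff_path.exists():
        raise FileNotFoundError(gff_path)

    chromosomes = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }

    groups: dict[str, list] = {}
    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        logger.warning("annotation %s contains no features", gff_path)
    else:
        for feat in db.features_of_type("CDS"):
            parent = feat.attributes.get("Parent", feat.attributes.get("ID", [feat.id]))[0]
            groups.setdefault(parent, []).append(feat)

    shell = AnnotatedGenome(chromosomes, [])  # validates sequences once
    orfs: list[OrfRecord] = []
    for orf_id, feats in sorted(groups.items()):
        chrom = feats[0].seqid
        strand = feats[0].strand
        if chrom not in chromosomes:
            raise ValueError(f"{orf_id}: chromosome {chrom} present in GFF but not FASTA")
        # GFF3 is 1-based closed; convert to 0-based half-open.
        ivals = sorted((f.start - 1, f.end) for f in feats)
        total = sum(e - s for s, e in ivals)
        terminal = ivals[-1] if strand == "+" else ivals[0]
        candidate = OrfRecord(
            orf_id=orf_id,
            chrom=chrom,
            strand=strand,
            cds_start=terminal[0],
            cds_end=terminal[1],
            stop_codon_start=(ivals[-1][1] - 3 if strand == "+" else ivals[0][0]),
        )
        try:
            if total % 3 != 0:
                raise ValueError(f"{orf_id}: total CDS length {total} not a multiple of 3")
            shell._validate(candidate)
        except ValueError as exc:
            logger.warning("excluding ORF %s: %s", orf_id, exc)
            continue
        orfs.append(candidate)

    shell.orfs = orfs
    shell._index = {o.orf_id: o for o in orfs}
    return shell


def write_genome(genome: AnnotatedGenome, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write FASTA + GFF3 that :func:`load_genome` reads back identically."""
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in genome.orfs:
            fh.write(
                "\t".join(
                    [
                        orf.chrom,
                        "castling",
                        "CDS",
                        str(orf.cds_start + 1),
                        str(orf.cds_end),
                        ".",
                        orf.strand,
                        "0",
                        f"ID=cds-{orf.orf_id};Parent={orf.orf_id}",
                    ]
                )
                + "\n"
            )


def terminus_window(genome: AnnotatedGenome, orf_id: str, flank: int = 30) -> TerminusWindow:
    """Sequence around the STOP codon, in ORF orientation.

    Covers ``[stop_codon_start - flank, stop_codon_start + 3 + flank)`` in
    genomic coordinates (symmetric, so orientation does not change the
    extent), clipped at chromosome ends with ``clipped`` flagged.  The
    returned coordinate map gives, for each local position, the forward-strand
    genomic coordinate of that base.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    orf = genome.orf(orf_id)
    chrom = genome.chromosomes[orf.chrom]
    lo = orf.stop_codon_start - flank
    hi = orf.stop_codon_start + 3 + flank
    clipped = lo < 0 or hi > len(chrom)
    lo_c, hi_c = max(lo, 0), min(hi, len(chrom))
    seq = chrom[lo_c:hi_c]
    coord = list(range(lo_c, hi_c))
    if orf.strand == "-":
        seq = revcomp(seq)
        coord = coord[::-1]
    stop_local = coord.index(
        orf.stop_codon_start if orf.strand == "+" else orf.stop_codon_start + 2
    )
    return TerminusWindow(
        orf_id=orf_id,
        sequence=seq,
        coord_map=coord,
        chrom=orf.chrom,
        strand=orf.strand,
        clipped=clipped,
        stop_local=stop_local,
    )
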