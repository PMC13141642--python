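"""Genome and annotation input: FASTA/GFF3 reading, gene models, sequence utilities.

All internal coordinates are 0-based half-open on the plus strand of the
assembly.  GFF3 input/output uses the standard 1-based inclusive convention;
the conversion happens exactly once, at the module boundary
(``internal_start = gff_start - 1``, ``internal_end = gff_end``).

A gene is represented by a single transcript.  When the annotation provides
several mRNAs for one gene, the one with the longest total CDS is kept
(ties broken by lexicographically smallest mRNA ID), because downstream
targetability accounting counts genes, not isoforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Interval = tuple[int, int]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a coding sequence with the standard code ('*' = stop)."""
    return str(Seq(cds).translate())


class GenomeSequences(dict):
    """Mapping of sequence name -> uppercase residue string over {A,C,G,T,N}."""

    def __setitem__(self, name: str, seq: str) -> None:
        if name in self:
            raise ValueError(f"duplicate sequence name {name!r}")
        for i, ch in enumerate(seq):
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"illegal residue {ch!r} in record {name!r} at offset {i}"
                )
        super().__setitem__(name, seq)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.items()}


def read_fasta(path: str | Path) -> GenomeSequences:
    """Load a FASTA file, folding residues to uppercase and validating them.

    Duplicate record names and residues outside {A,C,G,T,N} are hard errors;
    an empty file yields an empty mapping with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences = GenomeSequences()
    for record in SeqIO.parse(str(path), "fasta"):
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        logger.warning("FASTA file %s contains no records", path)
    return sequences


def write_fasta(sequences: GenomeSequences, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(eq=False)
class GeneModel:
    """One gene's coordinates, reduced to a single transcript.

    ``exons`` and ``cds_segments`` are sorted by genomic position regardless
    of strand; transcription order is derived from ``strand`` on access.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds_segments: list[Interval]
    complete: bool = True
    incomplete_reason: str | None = None
    mrna_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds_segments = sorted(tuple(c) for c in self.cds_segments)
        for ivs in (self.exons, self.cds_segments):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if e1 > s2:
                    raise ValueError(
                        f"overlapping intervals in gene {self.gene_id}: "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )

    # ---- derived structure -------------------------------------------------

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def introns_tx_order(self) -> list[Interval]:
        """Introns ordered 5'->3' along the transcript."""
        ivs = self.introns
        return ivs if self.strand == "+" else ivs[::-1]

    @property
    def cds_length_nt(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def start_codon(self) -> Interval:
        """Genomic interval of the first CDS codon (assumes it is unsplit)."""
        if self.strand == "+":
            s = self.cds_segments[0][0]
            return (s, s + 3)
        e = self.cds_segments[-1][1]
        return (e - 3, e)

    # ---- coordinate maps ---------------------------------------------------

    @cached_property
    def _cds_positions(self) -> list[int]:
        """Genomic coordinate of each CDS base, in transcription order."""
        pos: list[int] = []
        if self.strand == "+":
            for s, e in self.cds_segments:
                pos.extend(range(s, e))
        else:
            for s, e in reversed(self.cds_segments):
                pos.extend(range(e - 1, s - 1, -1))
        return pos

    @cached_property
    def _coord_to_cds_offset(self) -> dict[int, int]:
        return {coord: i for i, coord in enumerate(self._cds_positions)}

    def cds_offset_of(self, coord: int) -> int | None:
        """0-based offset of a genomic coordinate within the spliced CDS."""
        return self._coord_to_cds_offset.get(coord)

    def cds_coord_of(self, offset: int) -> int:
        return self._cds_positions[offset]

    def intron_hit(self, coord: int) -> tuple[int, int, int] | None:
        """Locate a genomic coordinate inside an intron.

        Returns ``(intron_index, position, length)`` with the index 1-based in
        transcription order and the position 1-based from the donor (5') end,
        or ``None`` if the coordinate is not intronic.
        """
        for idx, (s, e) in enumerate(self.introns_tx_order, start=1):
            if s <= coord < e:
                pos = coord - s + 1 if self.strand == "+" else e - coord
                return idx, pos, e - s
        return None

    def cds_offset_before_intron(self, intron_index: int) -> int:
        """Number of CDS nucleotides transcribed before the given intron."""
        s, e = self.introns_tx_order[intron_index - 1]
        if self.strand == "+":
            return sum(min(ce, s) - cs for cs, ce in self.cds_segments if cs < s)
        return sum(ce - max(cs, e) for cs, ce in self.cds_segments if ce > e)


def spliced_cds(gene: GeneModel, sequences: GenomeSequences) -> str:
    """Concatenate CDS segments in transcription order (coding-strand text)."""
    chrom_seq = sequences[gene.chrom]
    parts = [chrom_seq[s:e] for s, e in gene.cds_segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = revcomp(cds)
    return cds


def _completeness(gene: GeneModel, sequences: GenomeSequences) -> str | None:
    """Reason the gene model is unusable for codon-level work, or None."""
    chrom_len = len(sequences[gene.chrom])
    if gene.span[0] < 0 or gene.span[1] > chrom_len:
        raise ValueError(
            f"gene {gene.gene_id} extends beyond chromosome {gene.chrom} "
            f"(length {chrom_len})"
        )
    if not gene.cds_segments:
        return "no CDS"
    if gene.cds_length_nt % 3 != 0:
        return "CDS length not a multiple of 3"
    for s, e in gene.introns:
        if e - s < 4:
            return "intron shorter than 4 nt"
    cds = spliced_cds(gene, sequences)
    if "N" in cds:
        return "N residue in CDS"
    if not cds.startswith("ATG"):
        return "CDS does not start with ATG"
    if cds[-3:] not in STOP_CODONS:
        return "CDS does not end with a stop codon"
    aa = translate(cds)
    if "*" in aa[:-1]:
        return "internal stop codon"
    return None


def read_gff(path: str | Path, sequences: GenomeSequences) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    Incomplete CDS models (bad frame, non-ATG start, internal stops, N
    residues, micro-introns) are flagged, not dropped, so callers can decide;
    genome-wide summaries exclude them.  CDS features with no mRNA parent are
    skipped with a warning; features past the chromosome end are hard errors.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    orphans = 0
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype="mRNA"))
        if not parents:
            orphans += 1
    if orphans:
        logger.warning("skipped %d CDS feature(s) without an mRNA parent", orphans)

    genes: list[GeneModel] = []
    excluded = 0
    for gene_feat in db.features_of_type("gene"):
        if gene_feat.seqid not in sequences:
            raise ValueError(f"unknown chromosome {gene_feat.seqid!r} in GFF")
        chrom_len = len(sequences[gene_feat.seqid])
        mrnas = list(db.children(gene_feat, featuretype="mRNA"))
        if not mrnas:
            logger.warning("gene %s has no mRNA; skipped", gene_feat.id)
            continue

        def total_cds(m):  # longest-CDS transcript selection
            return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

        mrna = min(mrnas, key=lambda m: (-total_cds(m), m.id))
        exons = [
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        ]
        cds_segs = [
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
        ]
        if not exons:
            exons = list(cds_segs)
        for s, e in exons + cds_segs:
            if s < 0 or e > chrom_len:
                raise ValueError(
                    f"feature ({s + 1},{e}) of gene {gene_feat.id} lies beyond "
                    f"chromosome {gene_feat.seqid} end ({chrom_len})"
                )
        gene = GeneModel(
            gene_id=gene_feat.id,
            chrom=gene_feat.seqid,
            strand=gene_feat.strand,
            exons=exons,
            cds_segments=cds_segs,
            mrna_id=mrna.id,
        )
        reason = _completeness(gene, sequences)
        if reason is not None:
            gene.complete = False
            gene.incomplete_reason = reason
            excluded += 1
        genes.append(gene)
    if excluded:
        logger.info(
            "%d of %d gene model(s) flagged incomplete and excluded from "
            "codon-level strategies",
            excluded,
            len(genes),
        )
    return genes


def write_gff(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back out as standard GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            tid = g.mrna_id or f"{g.gene_id}.t1"
            s, e = g.span
            fh.write(
                f"{g.chrom}\tbescan\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tbescan\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for xs, xe in g.exons:
                fh.write(
                    f"{g.chrom}\tbescan\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"Parent={tid}\n"
                )
            segs = g.cds_segments if g.strand == "+" else g.cds_segments[::-1]
            phases: dict[Interval, int] = {}
            done = 0
            for seg in segs:  # GFF3 phase: bases to skip to reach a codon start
                phases[seg] = (3 - done % 3) % 3
                done += seg[1] - seg[0]
            for cs, ce in g.cds_segments:
                fh.write(
                    f"{g.chrom}\tbescan\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t"
                    f"{phases[(cs, ce)]}\tID=cds_{tid};Parent={tid}\n"
                )
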