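"""Synthetic test genomes with planted, editor-targetable sites.

Two generators are provided:

* :func:`simulate_genome` builds a seeded random genome (FASTA + GFF3) of
  multi-exon genes on both strands, optionally planting per gene: a CBE
  stop-gain site (a CAG codon in the 5' quarter with a correctly phased NGG
  PAM), an ABE start-loss site (the initiator A at protospacer position 6
  with an NGG PAM inside codon 6), and an ABE splice-donor site (the donor
  T of an intron reachable through a guide on the opposite strand).  Every
  planted site is recorded in a truth manifest so recovery can be checked
  exactly.

* :func:`alba_fixture` builds one pigment-gene-like 5-exon model (a stand-in
  for the *albA* polyketide synthase gene; the real genomic sequence is not
  reproduced) that embeds experimentally used protospacers with valid PAM
  context: two CBE stop-gain guides placed so that codon 55 is TGG and codon
  292 is CGA, an ABE splice-donor guide in intron 2, and an NG-only
  start-codon guide.

Seeded runs are bit-reproducible.  Editing-window geometry throughout
assumes the default window, protospacer positions 4-8.
"""

from __future__ import annotations

import dataclasses
import json
import math
import random
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

from .genome_io import (
    STOP_CODONS,
    GeneModel,
    GenomeSequences,
    _completeness,
    revcomp,
    write_fasta,
    write_gff,
)

SENSE_CODONS = tuple(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)

# protospacers used experimentally against the albA gene (fixture inputs)
ALBA_STOP_GUIDE_W55 = "CGCTGACCAGCATGTTGACT"   # opposite-strand CBE guide, TGG codon
ALBA_STOP_GUIDE_R292 = "ACGACGACTATGCTGGGACA"  # coding-strand CBE guide, CGA codon
ALBA_START_GUIDE_NG = "CAAACATGGAGGGTCCATCT"   # ABE guide over the ATG, NG-only PAM


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted editable site."""

    gene_id: str
    strategy: str  # stop | start | splice
    editor: str
    pam: str
    chrom: str
    position: int  # plus-strand 0-based coordinate of the edited base
    ref: str  # plus-strand
    alt: str
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    subsite: str | None = None


@dataclass
class SyntheticGenomeSpec:
    """Parameters of a simulated genome.

    Planting probabilities are per gene and per strategy; a planted site is
    guaranteed discoverable with the default 4-8 editing window and NGG PAM.
    """

    n_genes: int = 100
    chrom_name: str = "chr_sim"
    gc_fraction: float = 0.5
    codon_count_range: tuple[int, int] = (80, 200)
    exon_count_range: tuple[int, int] = (1, 4)
    intron_length_range: tuple[int, int] = (30, 80)
    intergenic_length_range: tuple[int, int] = (80, 200)
    p_stop: float = 0.6
    p_start: float = 0.5
    p_splice: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.codon_count_range[0] < 60:
            raise ValueError(
                "genes shorter than 60 codons cannot host the planted "
                "protospacer/PAM cassettes"
            )
        if self.intron_length_range[0] < 10:
            raise ValueError("introns shorter than 10 nt cannot host splice plants")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0,1)")


@dataclass
class _GeneBuild:
    seq: str  # gene-local, coding orientation
    exons: list[tuple[int, int]]  # gene-local intervals
    plants: list[dict]  # local-coordinate plant records


def _random_dna(rng: random.Random, n: int, gc: float) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=w, k=n))


def _make_intron(rng: random.Random, length: int, gc: float) -> str:
    return "GT" + _random_dna(rng, length - 4, gc) + "AG"


def _build_gene(rng: random.Random, spec: SyntheticGenomeSpec) -> _GeneBuild:
    n = rng.randint(*spec.codon_count_range)
    codons = (
        ["ATG"]
        + [rng.choice(SENSE_CODONS) for _ in range(n - 2)]
        + [rng.choice(sorted(STOP_CODONS))]
    )
    plants: list[dict] = []

    plant_stop = rng.random() < spec.p_stop
    plant_start = rng.random() < spec.p_start
    plant_splice = rng.random() < spec.p_splice

    # --- start-loss plant: initiator A at protospacer position 6, NGG PAM in
    #     codon 6 (CDS offsets 15-17); protospacer runs 5 nt into the upstream
    #     intergenic sequence
    if plant_start:
        codons[5] = "AGG"
        plants.append(
            {"strategy": "start", "editor": "ABE", "cds_offset": 0,
             "coding_ref": "A", "coding_alt": "G", "codon_index": 1,
             "ref_codon": "ATG", "alt_codon": "GTG"}
        )

    # --- stop-gain plant: CAG codon with its C at protospacer position 6 of a
    #     coding-strand CBE guide; NGG PAM lands in codon cs+5
    cs = None
    if plant_stop:
        cs_hi = math.floor(0.25 * n) - 6
        cs = rng.randint(9, max(9, cs_hi))
        codons[cs - 1] = "CAG"
        for i in range(cs, cs + 4):
            codons[i] = "GCT"
        codons[cs + 4] = "AGG"
        plants.append(
            {"strategy": "stop", "editor": "CBE", "cds_offset": 3 * (cs - 1),
             "coding_ref": "C", "coding_alt": "T", "codon_index": cs,
             "ref_codon": "CAG", "alt_codon": "TAG"}
        )

    cds_len = 3 * n
    k = rng.randint(*spec.exon_count_range)
    if plant_splice and k < 2:
        k = 2

    # zones (CDS-offset intervals) an intron must not interrupt
    forbidden: list[tuple[int, int]] = [(0, 18)]  # start guide span
    if cs is not None:
        forbidden.append((3 * cs - 8, 3 * cs + 16))

    intron_offsets: list[int] = []
    splice_d = None
    if plant_splice:
        lo = (3 * cs + 34) if cs is not None else 37
        cands = [
            d for d in range(lo, cds_len - 20)
            if d % 3 == 1 and (d - 16) // 3 != 5
        ]
        if not cands:
            raise ValueError("gene too short to host a splice plant")
        splice_d = rng.choice(cands)
        # the opposite-strand guide's NGG PAM: CCN codon at offsets d-16..d-14
        codons[(splice_d - 16) // 3] = "CCA"
        intron_offsets.append(splice_d)
        forbidden.append((splice_d - 16, splice_d + 8))

    while len(intron_offsets) < k - 1:
        placed = False
        for _ in range(100):
            d = rng.randint(19, cds_len - 21)
            if any(lo < d <= hi for lo, hi in forbidden):
                continue
            if any(abs(d - o) < 25 for o in intron_offsets):
                continue
            intron_offsets.append(d)
            placed = True
            break
        if not placed:
            break  # fewer introns than asked for; still a valid gene

    intron_offsets.sort()
    introns: dict[int, str] = {}
    for d in intron_offsets:
        length = rng.randint(*spec.intron_length_range)
        iseq = _make_intron(rng, length, spec.gc_fraction)
        if d == splice_d:
            # keep guide positions 4-5 free of extra A targets: intron pos 3-4
            iseq = iseq[:2] + "CA" + iseq[4:]
        introns[d] = iseq

    if splice_d is not None:
        shift = sum(len(introns[d]) for d in intron_offsets if d < splice_d)
        s_local = splice_d + shift  # gene-local intron start
        plants.append(
            {"strategy": "splice", "editor": "ABE", "local": s_local + 1,
             "coding_ref": "T", "coding_alt": "C", "subsite": "donor"}
        )

    # assemble pre-mRNA and gene-local exon intervals
    cds = "".join(codons)
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    prev = 0
    pos = 0
    for d in intron_offsets:
        parts.append(cds[prev:d])
        exons.append((pos, pos + (d - prev)))
        pos += d - prev
        parts.append(introns[d])
        pos += len(introns[d])
        prev = d
    parts.append(cds[prev:])
    exons.append((pos, pos + (cds_len - prev)))
    seq = "".join(parts)

    # finalise plant local coordinates for the CDS-level plants
    for p in plants:
        if "cds_offset" in p:
            off = p.pop("cds_offset")
            p["local"] = off + sum(
                len(introns[d]) for d in intron_offsets if d <= off
            )
    return _GeneBuild(seq=seq, exons=exons, plants=plants)


def simulate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[GenomeSequences, list[GeneModel], list[PlantedSite]]:
    """Generate a genome, its gene models and the planted-truth manifest."""
    spec.validate()
    rng = random.Random(spec.seed)
    chrom_parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    manifest: list[PlantedSite] = []

    for gi in range(spec.n_genes):
        gene_id = f"gene{gi + 1:04d}"
        pad = _random_dna(
            rng, rng.randint(*spec.intergenic_length_range), spec.gc_fraction
        )
        chrom_parts.append(pad)
        cursor += len(pad)

        build = _build_gene(rng, spec)
        strand = rng.choice("+-")
        glen = len(build.seq)
        gene_start = cursor
        if strand == "+":
            block = build.seq
            exons = [(gene_start + s, gene_start + e) for s, e in build.exons]
        else:
            block = revcomp(build.seq)
            exons = sorted(
                (gene_start + glen - e, gene_start + glen - s)
                for s, e in build.exons
            )
        chrom_parts.append(block)
        cursor += glen

        gene = GeneModel(
            gene_id=gene_id,
            chrom=spec.chrom_name,
            strand=strand,
            exons=exons,
            cds_segments=list(exons),
        )
        genes.append(gene)

        for p in build.plants:
            local = p["local"]
            if strand == "+":
                position = gene_start + local
                ref, alt = p["coding_ref"], p["coding_alt"]
            else:
                position = gene_start + glen - 1 - local
                comp = str.maketrans("ACGT", "TGCA")
                ref = p["coding_ref"].translate(comp)
                alt = p["coding_alt"].translate(comp)
            manifest.append(
                PlantedSite(
                    gene_id=gene_id,
                    strategy=p["strategy"],
                    editor=p["editor"],
                    pam="NGG",
                    chrom=spec.chrom_name,
                    position=position,
                    ref=ref,
                    alt=alt,
                    codon_index=p.get("codon_index"),
                    ref_codon=p.get("ref_codon"),
                    alt_codon=p.get("alt_codon"),
                    subsite=p.get("subsite"),
                )
            )

    tail = _random_dna(
        rng, rng.randint(*spec.intergenic_length_range), spec.gc_fraction
    )
    chrom_parts.append(tail)
    sequences = GenomeSequences()
    sequences[spec.chrom_name] = "".join(chrom_parts)

    # build-time self-checks: gene models must be clean, planted refs must match
    for g in genes:
        reason = _completeness(g, sequences)
        if reason is not None:
            raise AssertionError(f"generated gene {g.gene_id} is invalid: {reason}")
    seq = sequences[spec.chrom_name]
    for site in manifest:
        if seq[site.position] != site.ref:
            raise AssertionError(
                f"planted site for {site.gene_id} expects {site.ref} at "
                f"{site.position}, genome has {seq[site.position]}"
            )
    return sequences, genes, manifest


def write_outputs(
    sequences: GenomeSequences,
    genes: list[GeneModel],
    manifest: list[PlantedSite],
    prefix: str | Path,
) -> tuple[Path, Path, Path]:
    """Write FASTA, GFF3 and the JSON truth manifest under a path prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = prefix.with_suffix(".fasta")
    gff = prefix.with_suffix(".gff3")
    mjson = prefix.parent / (prefix.name + "_manifest.json")
    write_fasta(sequences, fasta)
    write_gff(genes, gff)
    mjson.write_text(
        json.dumps([dataclasses.asdict(s) for s in manifest], indent=2) + "\n"
    )
    return fasta, gff, mjson


# ---------------------------------------------------------------------------
# albA-like fixture
# ---------------------------------------------------------------------------

_ALBA_SEED = 1015  # fixed: the fixture must be byte-stable across runs


def alba_fixture() -> tuple[GenomeSequences, list[GeneModel]]:
    """A synthetic 5-exon pigment-gene model embedding real protospacers.

    The 1200-codon coding sequence is random except where constrained:

    * codons 50-57 spell the reverse complement of the W55 stop-gain guide
      so that codon 55 is TGG, with the opposite-strand NGG PAM (plus-strand
      CCA) immediately upstream;
    * codons 290-298 embed the R292 guide on the coding strand so that codon
      292 is CGA with a downstream GGG PAM;
    * intron 2 starts at CDS offset 400 and its donor GT is reachable by an
      opposite-strand ABE guide (plus-strand CCA PAM inside exon 2);
    * the start codon sits at position 6 of an ABE guide whose PAM (TGT) is
      NG but not NGG, so the start is targetable only in relaxed-PAM mode.

    Intron lengths are 60/61/55/62 nt, so retention of intron 2 shifts the
    frame while retention of intron 1 does not.
    """
    rng = random.Random(_ALBA_SEED)
    n = 1200
    codons = (
        ["ATG"] + [rng.choice(SENSE_CODONS) for _ in range(n - 2)] + ["TAA"]
    )

    def set_codons(first_index: int, *vals: str) -> None:
        for i, v in enumerate(vals):
            codons[first_index - 1 + i] = v

    # NG-only start site: guide = upstream "CAAAC" + CDS offsets 0-14; PAM TGT
    set_codons(2, "GAG", "GGT", "CCA", "TCT", "TGT", "CTT")
    # W55 stop-gain site: revcomp(guide) occupies CDS offsets 151-170
    set_codons(50, "TCC", "AAG", "TCA", "ACA", "TGC", "TGG", "TCA", "GCG")
    # R292 stop-gain site: guide occupies CDS offsets 869-888, PAM GGG after
    set_codons(290, "GCA", "CGA", "CGA", "CTA", "TGC", "TGG", "GAC", "AGG", "GGT")
    # splice-donor guide PAM for intron 2 (inserted at CDS offset 400)
    set_codons(129, "CCA")

    cds = "".join(codons)
    assert cds[151:171] == revcomp(ALBA_STOP_GUIDE_W55)
    assert cds[869:889] == ALBA_STOP_GUIDE_R292

    intron_plan = [(120, 60), (400, 61), (1500, 55), (2500, 62)]
    parts: list[str] = []
    prev = 0
    for d, length in intron_plan:
        parts.append(cds[prev:d])
        iseq = _make_intron(rng, length, 0.5)
        if d == 400:  # keep ABE guide positions 4-5 free of extra targets
            iseq = iseq[:2] + "CA" + iseq[4:]
        parts.append(iseq)
        prev = d
    parts.append(cds[prev:])

    gene_seq = "".join(parts)
    exons = []
    pos = 0
    prev = 0
    for d, length in intron_plan:
        exons.append((pos, pos + (d - prev)))
        pos += (d - prev) + length
        prev = d
    exons.append((pos, pos + (len(cds) - prev)))

    upstream = _random_dna(rng, 115, 0.5) + "TAT" * 10 + "CAAAC"
    downstream = _random_dna(rng, 150, 0.5)
    gene_start = len(upstream)

    sequences = GenomeSequences()
    sequences["alba_chr"] = upstream + gene_seq + downstream
    gene = GeneModel(
        gene_id="albA_like",
        chrom="alba_chr",
        strand="+",
        exons=[(gene_start + s, gene_start + e) for s, e in exons],
        cds_segments=[(gene_start + s, gene_start + e) for s, e in exons],
    )
    reason = _completeness(gene, sequences)
    if reason is not None:
        raise AssertionError(f"albA fixture inconsistent: {reason}")
    for s, e in gene.introns:
        chrom = sequences["alba_chr"]
        assert chrom[s : s + 2] == "GT" and chrom[e - 2 : e] == "AG"
    return sequences, [gene]
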