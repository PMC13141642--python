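"""Classify window edits into gene-inactivation strategies.

Three strategies are modelled:

* ``premature_stop`` — a single edit turns a sense codon into TAA/TAG/TGA.
  Stops landing in the 5' quarter of the coding sequence (codon index <=
  ceil(quarter * n_codons), quarter configurable) are marked as reliably
  inactivating; the final (natural stop-adjacent) codon is never counted.
* ``start_loss`` — an edit in codon 1 destroys the ATG initiator
  (ABE: ATG>GTG or ATG>ACG; CBE: ATG>ATA through an opposite-strand guide).
* ``splice_disruption`` — an edit inside an intron.  Hits on the terminal
  donor GT / acceptor AG dinucleotides are tier 1; putative branch-region
  adenines (within a configurable window at the intron 3' end, default 50
  nt) and other intronic positions are tier 2, reflecting how unreliably
  interior intronic edits abolish splicing in practice.

Consequences are predicted structurally: nonsense truncation length,
start-loss with the next in-frame ATG, or intron retention simulated by
re-inserting the intron into the mature transcript and translating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .edit_chemistry import BaseEdit
from .genome_io import STOP_CODONS, GeneModel, GenomeSequences, revcomp, spliced_cds, translate

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

STRATEGIES = ("premature_stop", "start_loss", "splice_disruption")


@dataclass(frozen=True)
class Consequence:
    kind: str  # nonsense | start_loss | intron_retention
    ptc_codon_index: int | None = None  # 1-based codon of the first stop
    truncated_length_aa: int | None = None
    frameshift: bool = False
    retained_intron: int | None = None
    next_inframe_atg: int | None = None  # informational, start_loss only

    def summary(self) -> str:
        if self.kind == "nonsense":
            return f"nonsense:PTC@{self.ptc_codon_index};{self.truncated_length_aa}aa"
        if self.kind == "start_loss":
            nxt = self.next_inframe_atg if self.next_inframe_atg else "none"
            return f"start_loss:next_ATG@{nxt}"
        fs = "frameshift" if self.frameshift else "in-frame"
        ptc = f";PTC@{self.ptc_codon_index}" if self.ptc_codon_index else ""
        return f"intron_retention:I{self.retained_intron};{fs}{ptc}"


@dataclass(frozen=True)
class DisruptionCandidate:
    gene_id: str
    guide_id: str
    edit: BaseEdit
    strategy: str
    codon_index: int | None = None  # 1-based, CDS strategies only
    ref_codon: str | None = None
    alt_codon: str | None = None
    intron_index: int | None = None  # 1-based in transcription order
    splice_subsite: str | None = None  # donor | acceptor | branch_region | other_intronic
    tier: int | None = None
    within_5prime_quarter: bool | None = None
    consequence: Consequence | None = None


def _coding_base(base: str, gene_strand: str) -> str:
    return base if gene_strand == "+" else _COMP[base]


def _codon_change(
    gene: GeneModel, cds: str, edit: BaseEdit
) -> tuple[int, str, str] | None:
    """(codon_index, ref_codon, alt_codon) for an edit in the spliced CDS."""
    off = gene.cds_offset_of(edit.position)
    if off is None:
        return None
    ref_base = _coding_base(edit.ref, gene.strand)
    alt_base = _coding_base(edit.alt, gene.strand)
    if cds[off] != ref_base:
        raise ValueError(
            f"CDS/genome inconsistency for {gene.gene_id} at offset {off}: "
            f"CDS has {cds[off]!r}, edit ref is {ref_base!r}"
        )
    k = off // 3
    ref_codon = cds[3 * k : 3 * k + 3]
    j = off % 3
    alt_codon = ref_codon[:j] + alt_base + ref_codon[j + 1 :]
    return k + 1, ref_codon, alt_codon


def quarter_boundary(n_codons: int, quarter: float = 0.25) -> int:
    """Last codon index still counted as the 5' quarter of the CDS."""
    return math.ceil(quarter * n_codons)


def stop_candidates(
    gene: GeneModel,
    edits: Iterable[BaseEdit],
    sequences: GenomeSequences,
    quarter: float = 0.25,
    cds: str | None = None,
) -> list[DisruptionCandidate]:
    """Edits that convert a sense codon of the gene into a stop codon."""
    if not gene.complete:
        return []
    cds = cds if cds is not None else spliced_cds(gene, sequences)
    n_codons = len(cds) // 3
    boundary = quarter_boundary(n_codons, quarter)
    out = []
    for edit in edits:
        if edit.out_of_window:
            continue
        change = _codon_change(gene, cds, edit)
        if change is None:
            continue
        codon_index, ref_codon, alt_codon = change
        if ref_codon in STOP_CODONS or alt_codon not in STOP_CODONS:
            continue
        if codon_index >= n_codons:  # final codon: no truncation achieved
            continue
        out.append(
            DisruptionCandidate(
                gene_id=gene.gene_id,
                guide_id=edit.guide_id,
                edit=edit,
                strategy="premature_stop",
                codon_index=codon_index,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                within_5prime_quarter=codon_index <= boundary,
            )
        )
    return out


def start_candidates(
    gene: GeneModel,
    edits: Iterable[BaseEdit],
    sequences: GenomeSequences,
    cds: str | None = None,
) -> list[DisruptionCandidate]:
    """Edits that destroy the ATG initiator codon."""
    if not gene.complete:
        return []
    cds = cds if cds is not None else spliced_cds(gene, sequences)
    out = []
    for edit in edits:
        if edit.out_of_window:
            continue
        change = _codon_change(gene, cds, edit)
        if change is None or change[0] != 1:
            continue
        _, ref_codon, alt_codon = change
        if ref_codon == "ATG" and alt_codon != "ATG":
            out.append(
                DisruptionCandidate(
                    gene_id=gene.gene_id,
                    guide_id=edit.guide_id,
                    edit=edit,
                    strategy="start_loss",
                    codon_index=1,
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                )
            )
    return out


def splice_candidates(
    gene: GeneModel,
    edits: Iterable[BaseEdit],
    sequences: GenomeSequences,
    branch_window: int = 50,
) -> list[DisruptionCandidate]:
    """Edits falling inside introns, classified by splice subsite."""
    if not gene.introns:
        return []
    out = []
    for edit in edits:
        if edit.out_of_window:
            continue
        hit = gene.intron_hit(edit.position)
        if hit is None:
            continue
        idx, pos, length = hit
        coding_ref = _coding_base(edit.ref, gene.strand)
        if pos <= 2:
            subsite = "donor"
        elif pos >= length - 1:
            subsite = "acceptor"
        elif pos > length - branch_window and coding_ref == "A":
            subsite = "branch_region"
        else:
            subsite = "other_intronic"
        out.append(
            DisruptionCandidate(
                gene_id=gene.gene_id,
                guide_id=edit.guide_id,
                edit=edit,
                strategy="splice_disruption",
                intron_index=idx,
                splice_subsite=subsite,
                tier=1 if subsite in ("donor", "acceptor") else 2,
            )
        )
    return out


def simulate_intron_retention(
    gene: GeneModel, intron_index: int, sequences: GenomeSequences
) -> Consequence:
    """Consequence of retaining one intron in the mature transcript.

    The intron (coding-strand orientation) is re-inserted into the spliced
    CDS at its transcript position and the result translated from the start
    codon.  A retained intron whose length is not a multiple of 3 shifts the
    downstream reading frame.  Introns lying entirely outside the CDS (UTR
    introns) are reported as retained with no coding consequence.
    """
    introns = gene.introns_tx_order
    if not 1 <= intron_index <= len(introns):
        raise IndexError(
            f"gene {gene.gene_id} has {len(introns)} intron(s); "
            f"index {intron_index} out of range"
        )
    s, e = introns[intron_index - 1]
    intron_seq = sequences[gene.chrom][s:e]
    if gene.strand == "-":
        intron_seq = revcomp(intron_seq)
    frameshift = (e - s) % 3 != 0
    cds = spliced_cds(gene, sequences)
    off = gene.cds_offset_before_intron(intron_index)
    if off == 0 or off == len(cds):
        return Consequence(
            kind="intron_retention", retained_intron=intron_index, frameshift=False
        )
    mutant = cds[:off] + intron_seq + cds[off:]
    aa = translate(mutant[: len(mutant) - len(mutant) % 3])
    stop_at = aa.find("*")
    return Consequence(
        kind="intron_retention",
        retained_intron=intron_index,
        frameshift=frameshift,
        ptc_codon_index=stop_at + 1 if stop_at >= 0 else None,
        truncated_length_aa=stop_at if stop_at >= 0 else None,
    )


def predict_consequence(
    gene: GeneModel,
    candidate: DisruptionCandidate,
    sequences: GenomeSequences,
    cds: str | None = None,
) -> Consequence:
    """Transcript/protein consequence of one disruption candidate."""
    if candidate.strategy == "premature_stop":
        return Consequence(
            kind="nonsense",
            ptc_codon_index=candidate.codon_index,
            truncated_length_aa=candidate.codon_index - 1,
        )
    if candidate.strategy == "start_loss":
        cds = cds if cds is not None else spliced_cds(gene, sequences)
        nxt = None
        for k in range(1, len(cds) // 3):
            if cds[3 * k : 3 * k + 3] == "ATG":
                nxt = k + 1
                break
        return Consequence(kind="start_loss", next_inframe_atg=nxt)
    if candidate.strategy == "splice_disruption":
        return simulate_intron_retention(gene, candidate.intron_index, sequences)
    raise ValueError(f"unknown strategy {candidate.strategy!r}")


def annotate_consequences(
    gene: GeneModel,
    candidates: Sequence[DisruptionCandidate],
    sequences: GenomeSequences,
) -> list[DisruptionCandidate]:
    """Attach predicted consequences to a gene's candidates."""
    cds = spliced_cds(gene, sequences) if gene.complete else None
    out = []
    for c in candidates:
        cons = predict_consequence(gene, c, sequences, cds=cds)
        out.append(replace(c, consequence=cons))
    return out


def candidates_to_frame(candidates: Iterable[DisruptionCandidate]) -> pd.DataFrame:
    """Tabular view of candidates (VCF-style 1-based POS column)."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "gene": c.gene_id,
                "guide": c.guide_id,
                "strategy": c.strategy,
                "subsite": c.splice_subsite or ".",
                "codon_index": c.codon_index if c.codon_index is not None else ".",
                "ref_codon": c.ref_codon or ".",
                "alt_codon": c.alt_codon or ".",
                "intron_index": c.intron_index if c.intron_index is not None else ".",
                "within_quarter": (
                    c.within_5prime_quarter
                    if c.within_5prime_quarter is not None
                    else "."
                ),
                "tier": c.tier if c.tier is not None else ".",
                "consequence": c.consequence.summary() if c.consequence else ".",
                "editor": c.edit.editor,
                "chrom": c.edit.chrom,
                "pos": c.edit.position + 1,
                "ref": c.edit.ref,
                "alt": c.edit.alt,
            }
        )
    columns = [
        "gene", "guide", "strategy", "subsite", "codon_index", "ref_codon",
        "alt_codon", "intron_index", "within_quarter", "tier", "consequence",
        "editor", "chrom", "pos", "ref", "alt",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values(["gene", "chrom", "pos", "strategy", "guide"]).reset_index(
        drop=True
    )


def write_candidates_tsv(
    candidates: Iterable[DisruptionCandidate], path: str | Path
) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)
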