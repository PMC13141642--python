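"""Base-editor chemistries and enumeration of window edits.

A cytosine base editor (CBE) deaminates C->T on the guide strand; an adenine
base editor (ABE) converts A->G.  On the plus strand of the assembly this is
recorded as C>T / A>G for a '+' strand guide and G>A / T>C for a '-' strand
guide.  Editing is modelled inside a protospacer-position window (default
4-8, 1-based from the PAM-distal end); bases outside the window can be
enumerated too, flagged ``out_of_window``, mirroring the occasional
non-canonical on-target edits seen in sequencing data.

``stop_gain_routes`` derives, by exhaustive enumeration, which sense codons a
single editor-induced change can convert to a stop.  For CBE these are
CAA>TAA, CAG>TAG, CGA>TGA (direct C>T) and TGG>TAG / TGG>TGA (G>A through a
guide on the opposite strand).  No single A>G or T>C change creates a stop,
so the ABE map is empty: ABE cannot introduce premature stop codons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple

from .genome_io import STOP_CODONS, GenomeSequences
from .guide_scanner import GuideSite, map_protospacer_pos

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class Editor:
    """An editor chemistry: the guide-strand base it converts and to what."""

    label: str
    source: str  # guide-strand base recognised by the deaminase
    product: str

    @property
    def coding_changes(self) -> tuple[tuple[str, str], ...]:
        """Single-base changes achievable on a coding strand (either guide strand)."""
        return (
            (self.source, self.product),
            (_COMP[self.source], _COMP[self.product]),
        )


CBE = Editor("CBE", "C", "T")
ABE = Editor("ABE", "A", "G")

EDITORS = {"CBE": CBE, "ABE": ABE}


@dataclass(frozen=True)
class BaseEdit:
    """A single editor-induced substitution in guide and genomic coordinates."""

    guide_id: str
    chrom: str
    guide_strand: str
    protospacer_pos: int  # 1-20
    guide_ref: str
    guide_alt: str
    position: int  # plus-strand genomic coordinate, 0-based
    ref: str  # plus-strand
    alt: str  # plus-strand
    editor: str
    out_of_window: bool = False


class StopGainRoute(NamedTuple):
    codon_pos: int  # 1-3 within the codon
    change: str  # coding-strand sense, e.g. "C>T" or "G>A"
    stop_codon: str


def enumerate_window_edits(
    guide: GuideSite,
    editor: Editor,
    window: tuple[int, int] | None = None,
    extended: bool = False,
) -> list[BaseEdit]:
    """All editable bases of a guide, one :class:`BaseEdit` per position.

    With ``extended=True`` every target base along the protospacer is
    emitted and those outside the window carry ``out_of_window=True``.
    """
    lo, hi = window if window is not None else guide.window
    if not (1 <= lo <= hi <= 20):
        raise ValueError(f"invalid window ({lo},{hi})")
    positions = range(1, 21) if extended else range(lo, hi + 1)
    edits = []
    for p in positions:
        base = guide.protospacer[p - 1]
        if base != editor.source:
            continue
        coord = map_protospacer_pos(guide, p)
        if guide.strand == "+":
            ref, alt = editor.source, editor.product
        else:
            ref, alt = _COMP[editor.source], _COMP[editor.product]
        edits.append(
            BaseEdit(
                guide_id=guide.guide_id,
                chrom=guide.chrom,
                guide_strand=guide.strand,
                protospacer_pos=p,
                guide_ref=editor.source,
                guide_alt=editor.product,
                position=coord,
                ref=ref,
                alt=alt,
                editor=editor.label,
                out_of_window=not (lo <= p <= hi),
            )
        )
    return edits


def stop_gain_routes(editor: Editor) -> dict[str, list[StopGainRoute]]:
    """Codon -> single-edit routes to a stop codon, by exhaustive enumeration."""
    routes: dict[str, list[StopGainRoute]] = {}
    for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
        if codon in STOP_CODONS:
            continue
        found = []
        for i in range(3):
            for src, dst in editor.coding_changes:
                if codon[i] != src:
                    continue
                mutant = codon[:i] + dst + codon[i + 1 :]
                if mutant in STOP_CODONS:
                    found.append(StopGainRoute(i + 1, f"{src}>{dst}", mutant))
        if found:
            routes[codon] = found
    return routes


def apply_edit(sequences: GenomeSequences, edit: BaseEdit) -> GenomeSequences:
    """Return a copy of the genome with one edit applied.

    The plus-strand reference base must match the genome at the edited
    coordinate; a mismatch means a coordinate-mapping bug upstream and is a
    hard error.
    """
    seq = sequences[edit.chrom]
    actual = seq[edit.position]
    if actual != edit.ref:
        raise ValueError(
            f"ref mismatch at {edit.chrom}:{edit.position}: genome has "
            f"{actual!r}, edit expects {edit.ref!r}"
        )
    out = GenomeSequences()
    for name, s in sequences.items():
        if name == edit.chrom:
            s = s[: edit.position] + edit.alt + s[edit.position + 1 :]
        dict.__setitem__(out, name, s)
    return out


def revert(edit: BaseEdit) -> BaseEdit:
    """The inverse substitution (useful for round-trip checks)."""
    return replace(
        edit,
        ref=edit.alt,
        alt=edit.ref,
        guide_ref=edit.guide_alt,
        guide_alt=edit.guide_ref,
    )


def write_vcf(
    edits: Iterable[BaseEdit], sequences: GenomeSequences, path: str | Path
) -> None:
    """Write edits as VCF 4.2 (1-based, plus-strand REF/ALT)."""
    rows = sorted(edits, key=lambda e: (e.chrom, e.position, e.alt, e.guide_id))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=GUIDE,Number=1,Type=String,Description="Guide id">\n')
        fh.write(
            '##INFO=<ID=PSPOS,Number=1,Type=Integer,'
            'Description="Protospacer position 1-20">\n'
        )
        fh.write('##INFO=<ID=EDITOR,Number=1,Type=String,Description="CBE or ABE">\n')
        fh.write(
            '##INFO=<ID=OOW,Number=0,Type=Flag,'
            'Description="Outside the canonical editing window">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for e in rows:
            info = f"GUIDE={e.guide_id};PSPOS={e.protospacer_pos};EDITOR={e.editor}"
            if e.out_of_window:
                info += ";OOW"
            fh.write(
                f"{e.chrom}\t{e.position + 1}\t.\t{e.ref}\t{e.alt}\t.\t.\t{info}\n"
            )
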