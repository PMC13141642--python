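"""Protospacer/PAM scanning on both strands under NGG or NG PAM modes.

Protospacer positions are numbered 1-20 with position 1 at the PAM-distal
(5') end of the guide strand and the PAM immediately 3' of position 20.
The relaxed NG mode is treated as a 2-nt functional PAM (any base, then G);
because every NGG site also satisfies NG, the NG guide set is a strict
superset of the NGG set on any input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .genome_io import GenomeSequences, revcomp

PROTOSPACER_LEN = 20
DEFAULT_WINDOW = (4, 8)


@dataclass(frozen=True)
class PamMode:
    """A PAM recognition mode: its label and the PAM length it consumes."""

    label: str
    length: int

    def matches(self, bases: str) -> bool:
        return pam_match(bases, self)


NGG = PamMode("NGG", 3)
NG = PamMode("NG", 2)

PAM_MODES = {"NGG": NGG, "NG": NG}

# regex per mode for the forward strand; lookahead so overlapping sites are all
# reported; N anywhere in protospacer or PAM disqualifies the site
_FWD_RE = {
    "NGG": re.compile(r"(?=[ACGT]{20}[ACGT]GG)"),
    "NG": re.compile(r"(?=[ACGT]{20}[ACGT]G)"),
}


@dataclass(frozen=True)
class GuideSite:
    """One protospacer+PAM occurrence.

    ``start``/``end`` delimit the protospacer on plus-strand coordinates
    (0-based half-open).  For a '-' strand guide the protospacer is the
    reverse complement of the genome slice and the PAM lies at
    ``[start - len(pam), start)`` on the plus strand.
    """

    chrom: str
    strand: str
    protospacer: str
    pam: str
    start: int
    end: int
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be exactly 20 nt")
        w_lo, w_hi = self.window
        if not (1 <= w_lo <= w_hi <= PROTOSPACER_LEN):
            raise ValueError(f"invalid editing window {self.window}")

    @property
    def guide_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


def pam_match(bases: str, mode: PamMode) -> bool:
    """True if ``bases`` (read 5'->3' on the guide strand) satisfy the mode."""
    if len(bases) < 2:
        raise ValueError("PAM must be at least 2 nt")
    if mode.label == "NGG":
        return len(bases) >= 3 and bases[1] == "G" and bases[2] == "G"
    if mode.label == "NG":
        return bases[1] == "G"
    raise ValueError(f"unknown PAM mode {mode.label!r}")


def _scan_forward(seq: str, mode: PamMode) -> Iterable[tuple[int, str, str]]:
    """Yield (start, protospacer, pam) for guides on the given strand text."""
    plen = mode.length
    for m in _FWD_RE[mode.label].finditer(seq):
        i = m.start()
        yield i, seq[i : i + 20], seq[i + 20 : i + 20 + plen]


def find_guides(
    sequences: GenomeSequences,
    region: tuple[str, int, int] | None = None,
    mode: PamMode = NGG,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[GuideSite]:
    """Enumerate every protospacer/PAM occurrence on both strands.

    ``region`` = (chrom, start, end) restricts the scan to sites whose
    protospacer and PAM both lie inside the interval.  Output order is
    deterministic: chromosome, then plus-strand start, then strand
    ('+' before '-').
    """
    guides: list[GuideSite] = []
    if region is not None:
        chrom, rs, re_ = region
        if chrom not in sequences:
            raise KeyError(chrom)
        if not (0 <= rs <= re_ <= len(sequences[chrom])):
            raise ValueError(f"region {region} out of bounds")
        targets = [(chrom, sequences[chrom][rs:re_], rs)]
    else:
        targets = [(name, seq, 0) for name, seq in sequences.items()]

    for chrom, seq, offset in targets:
        length = len(seq)
        for i, proto, pam in _scan_forward(seq, mode):
            guides.append(
                GuideSite(chrom, "+", proto, pam, offset + i, offset + i + 20, window)
            )
        rc = revcomp(seq)
        for i, proto, pam in _scan_forward(rc, mode):
            start = length - (i + 20)
            guides.append(
                GuideSite(chrom, "-", proto, pam, offset + start,
                          offset + start + 20, window)
            )
    guides.sort(key=lambda g: (g.chrom, g.start, g.strand))
    return guides


def map_protospacer_pos(guide: GuideSite, p: int) -> int:
    """Plus-strand genomic coordinate of protospacer position ``p`` (1-20)."""
    if not 1 <= p <= PROTOSPACER_LEN:
        raise ValueError(f"protospacer position {p} out of range 1-20")
    if guide.strand == "+":
        return guide.start + (p - 1)
    return guide.end - p


def write_bed(guides: Iterable[GuideSite], path: str | Path) -> None:
    """BED6 of protospacer intervals (0-based half-open; score column unused)."""
    with open(path, "w") as fh:
        for g in guides:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.guide_id}\t0\t{g.strand}\n"
            )
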