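"""Genome-wide targetability accounting.

Aggregates disruption candidates into per-gene boolean flags and a summary
table of genes targetable per (editor x strategy x PAM).  The accounting
rules follow the published convention for this kind of table:

* counts are gene-level — a gene counts once no matter how many candidate
  guides it has;
* a premature-stop flag requires the stop to land within the 5' quarter of
  the coding sequence;
* "any disruption" is the per-gene union of start-loss and premature-stop
  (never their sum), and the "Either" editor row is the per-gene union over
  CBE and ABE;
* splice-disruption candidates are reported separately and excluded from
  the table;
* percentages are relative to the number of complete gene models, rounded
  half-up to one decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .disruption import (
    DisruptionCandidate,
    splice_candidates,
    start_candidates,
    stop_candidates,
)
from .edit_chemistry import EDITORS, Editor, enumerate_window_edits
from .genome_io import GeneModel, GenomeSequences, spliced_cds
from .guide_scanner import DEFAULT_WINDOW, PAM_MODES, GuideSite, find_guides

EDITOR_ROWS = ("CBE", "ABE", "Either")
STRATEGY_COLS = ("start", "stop", "any")
PAM_COLS = ("NGG", "NG")

_STRATEGY_OF = {"premature_stop": "stop", "start_loss": "start"}


def percentage(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def relative_increase(count_ngg: int, count_ng: int) -> int | None:
    """Percent gain from NGG to NG counts, rounded half-up to an integer.

    Returns ``None`` (not applicable) when the NGG count is zero.
    """
    if count_ngg < 0 or count_ng < 0:
        raise ValueError("counts must be non-negative")
    if count_ngg == 0:
        return None
    return int(
        (Decimal(count_ng - count_ngg) * 100 / Decimal(count_ngg)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class TargetabilitySummary:
    """Gene counts per (editor x strategy x PAM) plus run metadata."""

    total_genes: int
    counts: dict[tuple[str, str, str], int]
    splice_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def count(self, editor: str, strategy: str, pam: str) -> int:
        return self.counts[(editor, strategy, pam)]

    def pct(self, editor: str, strategy: str, pam: str) -> float:
        return percentage(self.count(editor, strategy, pam), self.total_genes)

    def validate(self) -> None:
        c = self.counts
        for ed in EDITOR_ROWS:
            for st in STRATEGY_COLS:
                if not c[(ed, st, "NG")] >= c[(ed, st, "NGG")]:
                    raise AssertionError(f"NG < NGG for {ed}/{st}")
            for pam in PAM_COLS:
                lo = max(c[(ed, "start", pam)], c[(ed, "stop", pam)])
                hi = c[(ed, "start", pam)] + c[(ed, "stop", pam)]
                if not lo <= c[(ed, "any", pam)] <= hi:
                    raise AssertionError(f"union bounds violated for {ed}/{pam}")
        for st in STRATEGY_COLS:
            for pam in PAM_COLS:
                lo = max(c[("CBE", st, pam)], c[("ABE", st, pam)])
                hi = c[("CBE", st, pam)] + c[("ABE", st, pam)]
                if not lo <= c[("Either", st, pam)] <= hi:
                    raise AssertionError(f"Either bounds violated for {st}/{pam}")
        for pam in PAM_COLS:
            if c[("ABE", "stop", pam)] != 0:
                raise AssertionError("ABE cannot introduce premature stops")
            if c[("Either", "stop", pam)] != c[("CBE", "stop", pam)]:
                raise AssertionError("Either stop must equal CBE stop")

    # ---- serialisation -----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "counts": {
                ed: {
                    st: {
                        pam: {
                            "count": self.count(ed, st, pam),
                            "pct": self.pct(ed, st, pam),
                        }
                        for pam in PAM_COLS
                    }
                    for st in STRATEGY_COLS
                }
                for ed in EDITOR_ROWS
            },
            "splice_gene_counts": {
                f"{ed}|{pam}": n for (ed, pam), n in sorted(self.splice_counts.items())
            },
            "metadata": self.metadata,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TargetabilitySummary":
        counts = {
            (ed, st, pam): cell["count"]
            for ed, block in d["counts"].items()
            for st, sub in block.items()
            for pam, cell in sub.items()
        }
        splice = {
            tuple(k.split("|")): v for k, v in d.get("splice_gene_counts", {}).items()
        }
        return cls(
            total_genes=d["total_genes"],
            counts=counts,
            splice_counts=splice,
            metadata=d.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def _gene_tree(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        s, e = g.span
        trees.setdefault(g.chrom, IntervalTree()).addi(s, e, i)
    return trees


def collect_candidates(
    sequences: GenomeSequences,
    genes: Sequence[GeneModel],
    editor: Editor,
    pam: str = "NGG",
    window: tuple[int, int] = DEFAULT_WINDOW,
    quarter: float = 0.25,
    branch_window: int = 50,
    strategies: Iterable[str] = ("stop", "start", "splice"),
    guides: Sequence[GuideSite] | None = None,
    extended_window: bool = False,
) -> list[DisruptionCandidate]:
    """Run scan -> window edits -> strategy classification for one editor/PAM."""
    strategies = set(strategies)
    if guides is None:
        guides = find_guides(sequences, mode=PAM_MODES[pam], window=window)
    trees = _gene_tree(genes)
    per_gene: dict[int, list] = {}
    for guide in guides:
        tree = trees.get(guide.chrom)
        if tree is None:
            continue
        for edit in enumerate_window_edits(
            guide, editor, window=window, extended=extended_window
        ):
            for iv in tree.at(edit.position):
                per_gene.setdefault(iv.data, []).append(edit)

    out: list[DisruptionCandidate] = []
    for gi, edits in sorted(per_gene.items()):
        gene = genes[gi]
        cds = spliced_cds(gene, sequences) if gene.complete else None
        if "stop" in strategies and gene.complete:
            out.extend(stop_candidates(gene, edits, sequences, quarter, cds=cds))
        if "start" in strategies and gene.complete:
            out.extend(start_candidates(gene, edits, sequences, cds=cds))
        if "splice" in strategies:
            out.extend(splice_candidates(gene, edits, sequences, branch_window))
    return out


def gene_targetability(
    gene: GeneModel,
    candidates_by_mode: dict[tuple[str, str], Sequence[DisruptionCandidate]],
) -> dict[tuple[str, str, str], bool]:
    """Per-gene boolean flags over (editor, strategy in {start, stop}, PAM).

    ``candidates_by_mode`` maps (editor, pam) to that gene's candidates.  The
    stop flag requires the candidate stop to lie within the 5' quarter;
    splice candidates are ignored here (they are not part of the table).
    """
    flags: dict[tuple[str, str, str], bool] = {}
    for (editor, pam), cands in candidates_by_mode.items():
        for st in ("start", "stop"):
            key = (editor, st, pam)
            flags.setdefault(key, False)
        for c in cands:
            if c.gene_id != gene.gene_id:
                continue
            st = _STRATEGY_OF.get(c.strategy)
            if st is None:
                continue
            if st == "stop" and not c.within_5prime_quarter:
                continue
            flags[(editor, st, pam)] = True
    return flags


def summarize_genome(
    sequences: GenomeSequences,
    genes: Sequence[GeneModel],
    window: tuple[int, int] = DEFAULT_WINDOW,
    quarter: float = 0.25,
    branch_window: int = 50,
    annotation_source: str = "unspecified",
) -> TargetabilitySummary:
    """Full pipeline: scan, enumerate edits, classify, count genes.

    Deterministic for fixed inputs and parameters.  Incomplete gene models
    are excluded from both the denominator and the flags.
    """
    complete = [g for g in genes if g.complete]
    if not complete:
        raise ValueError("no complete gene models to summarise")

    # flags[gene_id][(editor, strategy, pam)]
    flags: dict[str, dict[tuple[str, str, str], bool]] = {
        g.gene_id: {} for g in complete
    }
    splice_flag: dict[tuple[str, str], set[str]] = {}
    for pam in PAM_COLS:
        guides = find_guides(sequences, mode=PAM_MODES[pam], window=window)
        for editor_label, editor in EDITORS.items():
            cands = collect_candidates(
                sequences,
                complete,
                editor,
                pam=pam,
                window=window,
                quarter=quarter,
                branch_window=branch_window,
                guides=guides,
            )
            by_gene: dict[str, list[DisruptionCandidate]] = {}
            for c in cands:
                by_gene.setdefault(c.gene_id, []).append(c)
            for g in complete:
                gflags = gene_targetability(
                    g, {(editor_label, pam): by_gene.get(g.gene_id, [])}
                )
                flags[g.gene_id].update(gflags)
            splice_flag[(editor_label, pam)] = {
                c.gene_id for c in cands if c.strategy == "splice_disruption"
            }

    counts: dict[tuple[str, str, str], int] = {}
    for pam in PAM_COLS:
        for g in complete:
            f = flags[g.gene_id]
            for ed in ("CBE", "ABE"):
                f[(ed, "any", pam)] = f[(ed, "start", pam)] or f[(ed, "stop", pam)]
            for st in STRATEGY_COLS:
                f[("Either", st, pam)] = f[("CBE", st, pam)] or f[("ABE", st, pam)]
        for ed in EDITOR_ROWS:
            for st in STRATEGY_COLS:
                counts[(ed, st, pam)] = sum(
                    1 for g in complete if flags[g.gene_id][(ed, st, pam)]
                )

    summary = TargetabilitySummary(
        total_genes=len(complete),
        counts=counts,
        splice_counts={k: len(v) for k, v in splice_flag.items()},
        metadata={
            "window": list(window),
            "quarter_fraction": quarter,
            "branch_window_nt": branch_window,
            "pam_dialect": "NG = 2-nt functional PAM (any base then G), superset of NGG",
            "annotation_source": annotation_source,
            "genes_total_annotated": len(genes),
            "genes_excluded_incomplete": len(genes) - len(complete),
        },
    )
    summary.validate()
    # keep per-gene flags available to callers (genes.tsv) without widening the API
    summary._flags = flags  # type: ignore[attr-defined]
    return summary


def gene_flags_frame(summary: TargetabilitySummary) -> pd.DataFrame:
    """Wide per-gene flag table (one row per gene, one column per cell)."""
    flags: dict[str, dict] = getattr(summary, "_flags", {})
    rows = []
    for gene_id in sorted(flags):
        row = {"gene": gene_id}
        for ed in EDITOR_ROWS:
            for st in STRATEGY_COLS:
                for pam in PAM_COLS:
                    row[f"{ed}_{st}_{pam}"] = flags[gene_id][(ed, st, pam)]
        rows.append(row)
    return pd.DataFrame(rows)


def render_table(summary: TargetabilitySummary) -> tuple[str, dict]:
    """TSV and JSON renderings of the summary (ABE stop cells printed '-')."""
    lines = [
        "editor\tstart_NGG\tstart_NG\tstop_NGG\tstop_NG\tany_NGG\tany_NG",
    ]
    for ed in EDITOR_ROWS:
        cells = [ed]
        for st in ("start", "stop"):
            for pam in PAM_COLS:
                if ed == "ABE" and st == "stop":
                    cells.append("-")
                else:
                    cells.append(str(summary.count(ed, st, pam)))
        for pam in PAM_COLS:
            cells.append(
                f"{summary.count(ed, 'any', pam)} ({summary.pct(ed, 'any', pam)}%)"
            )
        lines.append("\t".join(cells))
    lines.append("")
    lines.append(f"# total_genes\t{summary.total_genes}")
    for k, v in summary.metadata.items():
        lines.append(f"# {k}\t{v}")
    return "\n".join(lines) + "\n", summary.to_json_dict()


def write_summary(
    summary: TargetabilitySummary, prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write summary.tsv, summary.json and genes.tsv under a path prefix."""
    prefix = Path(prefix)
    tsv, js = render_table(summary)
    tsv_path = prefix.with_suffix(".tsv")
    json_path = prefix.with_suffix(".json")
    genes_path = prefix.parent / (prefix.name + "_genes.tsv")
    tsv_path.write_text(tsv)
    json_path.write_text(json.dumps(js, indent=2, sort_keys=True) + "\n")
    gene_flags_frame(summary).to_csv(genes_path, sep="\t", index=False)
    return tsv_path, json_path, genes_path
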