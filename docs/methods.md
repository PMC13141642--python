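# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open on the plus strand of the
assembly; GFF3 input/output and VCF output use their standard 1-based
conventions, converted exactly once at the module boundary. Protospacer
positions are 1–20 with position 1 at the PAM-distal (5′) end and the PAM
immediately 3′ of position 20. When a gene has several annotated mRNAs the
transcript with the longest total CDS is kept (ties broken by
lexicographically smallest mRNA ID): targetability is counted per gene, not
per isoform. Gene models that are structurally unusable for codon-level work
— CDS length not a multiple of 3, non-ATG start, missing terminal stop,
internal stop, N residues in the CDS, or introns shorter than 4 nt — are
flagged rather than dropped, excluded from summaries, and counted in the
summary metadata.

## PAM modes

NGG requires G at PAM positions 2 and 3; the relaxed mode is implemented as
a 2-nt functional PAM (any base, then G) immediately 3′ of the protospacer,
because relaxed-PAM Cas9 variants are characterised by the NG dinucleotide
requirement and nothing in the scanned context constrains a third base. By
construction every NGG site is also an NG site, so NG guide sets, candidate
sets and gene counts are supersets of their NGG counterparts; the relaxed
columns of a summary therefore mean "NG including NGG". Protospacers or PAM
bases containing N are skipped. Overlapping guides are all reported;
deduplication is left to consumers.

## Editing model

CBE converts C→T and ABE converts A→G on the guide strand; for a guide on
the minus strand the genomic record is the complementary change (G→A,
T→C). The default editing window is protospacer positions 4–8 for both
editors. Real deaminase windows vary by architecture (APOBEC3A-based CBEs in
particular can edit more widely), so the window is configurable per run and
echoed into every output; it is the single largest determinant of
genome-wide counts. Positions outside the window can be enumerated with
`--extended-window` and are flagged `out_of_window`, mirroring the
occasional non-canonical on-target edits seen in Sanger traces; they never
enter summaries. Each candidate is a single-base edit: when several window
bases are editable, each is reported separately and gene-level counting
makes the multiplicity irrelevant. No sequence-context efficiency model
(e.g. the TC preference of some deaminases) is applied.

Stop-gain chemistry is derived, not hard-coded: for each editor the code
enumerates every sense codon × position × strand-sense change and keeps the
conversions that produce TAA/TAG/TGA. For CBE this yields exactly CAA→TAA,
CAG→TAG, CGA→TGA (direct C→T) and TGG→TAG, TGG→TGA (G→A via an
opposite-strand guide); for ABE the set is empty, which the test suite also
verifies against an independent brute force.

## Disruption strategies and consequences

* **Premature stop.** For every window edit inside the spliced CDS the
  affected codon is recomputed on the coding strand; a candidate is emitted
  iff the single edit converts a sense codon to a stop. Stops at the final
  codon are excluded (no truncation is achieved). A stop counts toward
  summaries only within the 5′ quarter of the CDS: codon index ≤
  ceil(quarter × n_codons) with quarter = 0.25 by default. The rule is
  applied in codon units with ceiling rounding; the fraction is
  configurable.
* **Start loss.** Edits in codon 1 that change ATG: ABE gives GTG (position
  1) or ACG (position 2 via the opposite strand), CBE gives ATA (position 3
  via the opposite strand). Near-cognate initiation at ACG/GTG is not
  modelled; the predicted consequence reports the next in-frame ATG as
  context. All codon-1 changes count as start loss.
* **Splice disruption.** Every window edit inside an intron is a candidate.
  Subsites: donor (intron positions 1–2), acceptor (last 2 positions),
  branch region (adenines within the last 50 nt, configurable), otherwise
  other-intronic. Donor/acceptor hits are tier 1; everything else tier 2,
  encoding the empirical unreliability of interior intronic edits — there is
  no motif model for fungal branch points here, only a positional adenine
  heuristic, and no splicing-strength scoring. CBE splice hits (GT→AT,
  AG→AA) are classified like ABE ones but, like all splice candidates, are
  excluded from the start/stop summary table and reported separately.

Intron retention is simulated structurally: the intron sequence (coding
orientation) is re-inserted into the spliced CDS at its transcript position
and the result translated from the original start; the consequence records
the first stop codon index, the truncated length, and a frameshift flag
(intron length mod 3 ≠ 0). Introns outside the CDS span are reported as
retained with no coding consequence.

An edit spanning decisions: a candidate is attributed by the single edited
base's location (exon vs intron), never by the guide's footprint.

## Summary accounting

Counts are gene-level booleans aggregated per (editor × strategy × PAM).
"Any disruption" is the per-gene union of start loss and quarter-gated
premature stop; the "Either" row is the per-gene union over CBE and ABE.
Invariants asserted on every run: NG ≥ NGG per cell; union cells bounded by
max and sum of their parts; ABE stop ≡ 0 and Either stop ≡ CBE stop.
Percentages are 100 × count / complete-genes, rounded half-up to one
decimal; relative NGG→NG increases are rounded half-up to an integer.
Half-up rounding (not banker's) matches how such tables are conventionally
printed. Every summary embeds its window, quarter fraction, branch window,
PAM dialect and annotation source, since genome-scale counts are
meaningless without them.

## Synthetic data

`simulate_genome` emulates a compact fungal genome: intergenic spacers of
80–200 nt at a configurable GC fraction, genes of 80–200 codons on both
strands with 1–4 exons and GT…AG introns of 30–80 nt. Coding sequence is
drawn uniformly from sense codons, so codon usage, intron consensus beyond
the terminal dinucleotides, UTRs and alternative isoforms of real genomes
are *not* modelled — passing tests demonstrate the correctness of
coordinate arithmetic, chemistry and accounting, not performance on real
annotation quirks. Per gene, with default probabilities 0.6/0.5/0.5, three
kinds of ground-truth sites are planted with correctly phased NGG PAMs for
the default 4–8 window: a CAG codon in the 5′ quarter reachable by a
coding-strand CBE guide, the initiator A at protospacer position 6 of an
ABE guide, and an intron donor T reachable by an opposite-strand ABE guide.
Every plant is recorded in a JSON truth manifest (gene, strategy, editor,
PAM, coordinate, expected codon change), generation is bit-reproducible for
a fixed seed, and generated models are self-checked (clean translation,
splice motifs, planted reference bases) before being returned.

The *albA*-like fixture is a synthetic 1200-codon, 5-exon gene — the real
genomic sequence of the pigment gene is not reproduced — constrained to
embed experimentally used protospacers with valid PAM context: the
opposite-strand CBE guide over codon 55 (TGG), the coding-strand CBE guide
over codon 292 (CGA), an opposite-strand ABE guide over the donor GT of
intron 2, and an ABE guide over the start codon whose PAM (TGT) satisfies
NG but not NGG. Intron lengths 60/61/55/62 nt make intron-1 retention
in-frame and the others frameshifting. One known side effect of embedding
the real guide sequences: the codon-292 guide contains a second CGA
(codon 291) that an incidental neighbouring guide can also reach; tests and
the acceptance script therefore identify the two headline sites by their
guide sequence.

## Problem sizes and numerical choices

The test suite and acceptance script run on a 100-gene planted genome
(~65 kb, recovery checks), a 25-gene genome (whole-pipeline property
checks: strand symmetry, NG ⊇ NGG, window-widening monotonicity) and the
fixture gene; these sizes give full coverage of the combinatorics while
keeping a complete run in seconds. Scanning is regex-based with overlap
lookahead and scales linearly; a 35-Mb genome is a matter of minutes.
Guide ordering is deterministic (chromosome, plus-strand start, then
strand) and all CLI outputs are byte-stable across reruns.

## Known limitations

No on/off-target scoring, no gRNA secondary-structure checks, no editing
efficiency model, no multi-base (tandem) conversion accounting in
summaries, no splicing-strength prediction, no GTF/fuzzy-coordinate/
trans-splicing support, and no modelling of which tier-2 intronic edits
actually abolish splicing. Published genome-wide counts for a real
annotation additionally depend on an editing-window choice that is not
stated with them, so reproduction on a downloaded genome should be treated
as best-effort and interpreted via the metadata block.
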