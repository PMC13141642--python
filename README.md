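# bescan

Base-editor guide design for gene disruption in filamentous fungi.

Cytosine base editors (CBEs) convert C·G→T·A and adenine base editors (ABEs)
convert A·T→G·C inside a narrow window of the protospacer, without
double-strand breaks. In fungi such as *Aspergillus niger* this chemistry
supports three gene-inactivation strategies: introducing a premature stop
codon, destroying the ATG start codon, and disrupting splice signals (donor
GT, acceptor AG, branch-region adenines) so that an intron is retained and
the transcript acquires a premature termination codon or frameshift.
`bescan` finds and classifies such sites genome-wide:

* **scan** both strands for 20-nt protospacers under the strict NGG PAM of
  SpCas9 or the relaxed NG PAM of SpCas9-NG variants (positions numbered
  1–20 from the PAM-distal end, PAM 3′ of position 20);
* **enumerate** editor-reachable bases inside a configurable editing window
  (default positions 4–8);
* **classify** each edit: stop-gain (CBE only — by exhaustive codon
  enumeration, the single-edit routes are CAA→TAA, CAG→TAG, CGA→TGA and
  TGG→TAG/TGA via the opposite strand; no single A→G or T→C edit creates a
  stop, so ABE contributes none), start-codon loss (ATG→GTG/ACG via ABE,
  ATG→ATA via CBE), and intronic splice-signal hits tiered by subsite;
* **predict** consequences: nonsense truncation length, next in-frame ATG
  after start loss, and intron-retention simulation (re-insert the intron
  into the mature transcript, translate, report PTC and frameshift);
* **summarise** per-gene targetability counts per (editor × strategy × PAM),
  where a premature stop only counts inside the 5′ quarter of the CDS,
  "any disruption" is the per-gene union of start and stop, and percentages
  are relative to the complete gene models.

It is aimed at people building base-editing toolkits for fungal (or other
intron-containing, haploid-friendly) genomes who want candidate gRNAs and
honest genome-wide targetability estimates before cloning anything.

## Worked example

```sh
# build the albA-like fixture (a synthetic 5-exon, 1200-codon pigment gene
# embedding experimentally used protospacers)
python -c "
from bescan import alba_fixture, write_fasta, write_gff
s, g = alba_fixture()
write_fasta(s, 'alba.fasta'); write_gff(g, 'alba.gff3')"

bescan design alba.fasta alba.gff3 --editor cbe --pam ngg -o alba
# 534 guides, 57 disruption candidates -> alba_*
```

`alba_candidates.tsv` then contains, among others:

```text
gene       guide                 strategy        ... codon_index ref alt within_quarter consequence
albA_like  alba_chr:361-381:-    premature_stop      55          TGG TAG True           nonsense:PTC@55;54aa
albA_like  alba_chr:361-381:-    premature_stop      55          TGG TGA True           nonsense:PTC@55;54aa
albA_like  alba_chr:1139-1159:+  premature_stop      292         CGA TGA True           nonsense:PTC@292;291aa
```

i.e. one opposite-strand CBE guide converts the tryptophan codon 55 (TGG)
to TAG or TGA through G→A edits, and a coding-strand guide converts the
arginine codon 292 (CGA) to TGA, truncating the protein after 54 or 291
amino acids respectively. A genome-wide summary of a 40-gene simulated
genome:

```sh
bescan simulate --n-genes 40 --seed 11 -o sim
bescan summarize sim.fasta sim.gff3 -o summary
cat summary.tsv
```

```text
editor  start_NGG  start_NG  stop_NGG  stop_NG  any_NGG     any_NG
CBE     11         31        29        38       32 (80.0%)  39 (97.5%)
ABE     32         38        -         -        32 (80.0%)  38 (95.0%)
Either  33         39        29        38       38 (95.0%)  40 (100.0%)
```

Rows are editors (plus their union), columns the number of genes targetable
per strategy under each PAM; relaxing NGG to NG never loses a gene, ABE
never gains a stop-codon column, and "any" cells carry the percentage of
complete genes. Splice-disruption genes are reported separately
(`summary.json`) because the table counts only start ∪ stop.

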