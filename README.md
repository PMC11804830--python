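# phosbase

Phosphosite-centric base-editor guide design and pooled-screen analysis.

Mass-spectrometry phosphoproteomics can quantify tens of thousands of
phosphorylation sites, but almost none of them have a known function.
CRISPR base editors make it possible to mutate individual
serine/threonine/tyrosine residues at scale — an adenine base editor such
as ABE8e converts A→G in a fixed window of the protospacer, turning e.g. a
tyrosine codon `TAC` into cysteine `TGC`, or (editing the antisense strand
of) a serine codon `TCA` into proline `CCA` — and a pooled screen over such
a library links each phosphosite to a phenotype.

`phosbase` implements the design and analysis layer of that workflow for
people building phosphosite-mutant screening libraries:

- **reference_model** — FASTA/GTF loading and exact bidirectional mapping
  between 1-based protein residues and genomic codon coordinates, including
  codons split across exon junctions and genes on either strand.
- **editing_engine** — base-editor chemistries (built-ins `ABE8e` A→G and
  `BE4` C→T; window 4–8 of a 20-nt protospacer, position 1 PAM-distal, NGG
  PAM at 21–23) and deterministic edit-outcome prediction: every source
  base in the window is edited, affected codons are rebuilt and translated,
  and the consequence at the target site is classified as
  `missense_at_site`, `silent_at_site` or `site_unchanged`, with bystander,
  non-coding and splice-site edits tracked separately.
- **guide_design** — protospacer enumeration per phosphosite on both
  strands and the library exclusion filters: cloning-enzyme sites
  (BsmBI/Esp3I `CGTCTC`) in the assembled oligo, poly-T runs (`TTTT`, the
  Pol III terminator), more than five perfect genomic matches, and
  silent-at-site guides that carry bystander edits. Sites below 90%
  localization confidence are dropped (inclusive cutoff).
- **library_builder** — the four control classes (non-targeting,
  intergenic, essential-gene and TCR-gene splice disruptors; 250 each by
  default), protospacer deduplication, and Golden-Gate-ready oligos
  (`CACCG` + protospacer / `AAAC` + reverse-complement + 3′ `C`).
- **screen_sim** — a deterministic synthetic mini-genome with planted
  design cases and an answer key produced by an independent exhaustive
  scanner, plus a negative-binomial pooled-screen count simulator with
  planted log2 fold-change effects.
- **screen_analysis** — control-based median-of-ratios size factors,
  per-guide log2FC, site-level aggregation with a control-permutation null
  and BH correction, essential-depletion QC, and per-position editing
  quantification from amplicon reads. This is a small, explicit stand-in
  for MAGeCK-style tools, not a reimplementation.

## Worked example

The whole pipeline runs offline on the synthetic fixture:

```sh
phosbase simulate --seed 11 --out demo
phosbase design --genome demo/genome.fa --gtf demo/annotation.gtf \
    --sites demo/phosphosites.tsv --editor ABE8e --out demo/guides.tsv
phosbase assemble --guides demo/guides.tsv --genome demo/genome.fa \
    --gtf demo/annotation.gtf --essential-genes demo/essential_genes.txt \
    --tcr-genes demo/tcr_genes.txt --controls-nt 250 \
    --controls-intergenic 250 --seed 17 --out-dir demo/library
phosbase analyze --counts demo/sim_counts.tsv --library demo/sim_library.tsv \
    --compare post:pre --seed 11 --out-dir demo/analysis
```

`design` prints

```
designed 29 guides (24 retained) for 11 sites; 4 sites skipped
```

meaning 11 usable phosphosites produced 29 candidate placements of which 24
survive the filters; 4 input sites were skipped (below the confidence
cutoff, residue/annotation mismatch, or unmappable) — reasons are logged.
The guide table lists each placement with its predicted consequence, e.g.

```
protospacer           pam  strand  target      site_class        aa_changes  filter_flags
GGTCTACGATCTGGTGGCGG  TGG  +       GENE_A:Y5   missense_at_site  Y5C
GTCTACGATCTGGTGGCGGT  GGG  +       GENE_A:Y5   missense_at_site  Y5C;D6G
```

(the second guide makes the same Y→C edit plus a D6G bystander). `assemble`
reports the per-class library composition — exactly 250 non-targeting and
250 intergenic controls retained from larger pools — and `analyze` prints

```
60 sites tested, 8 at FDR<0.05; depletion QC: PASS
```

the 8 significant sites being exactly the simulation's planted −2 log2FC
phosphosites, with the essential-splice class strongly depleted
(median log2FC ≈ −2.2, rank-sum p ≈ 2e-62 in `analysis/qc.json`), as a
working base-editing screen should show.

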