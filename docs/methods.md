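# Methods

## Coordinate model

All internal coordinates are 0-based half-open; GTF input is converted on
load (1-based inclusive, CDS features with frame validated against the
cumulative CDS length). A transcript's CDS segments are stored 5′→3′ in
transcript orientation, so a minus-strand gene's first segment has the
highest genomic coordinates. `protein_to_codon` resolves residue *i* to CDS
bases 3(i−1)…3i−1 and maps each through the per-transcript position index,
which makes codons split across exon junctions first-class: their three
genomic positions are simply non-contiguous. The stop codon is inside the
CDS but excluded from `protein_length`, so phosphosites can never address
it. When a phosphosite names no transcript isoform, the longest CDS of the
gene is selected and a warning is logged; this is a documented policy
choice, since site tables frequently omit isoform information.

`translate` uses the standard genetic code (via Biopython's codon table)
with stops rendered `*`. Any codon containing a non-ACGT character yields
`X`, even when the ambiguity would resolve (e.g. `GGN`): guide design must
never silently design against an uncertain base.

## Editing model

A `BaseEditorSpec` is a conversion chemistry (source→product base), an
editing window in 1-based protospacer coordinates with position 1 the most
PAM-distal base, a PAM pattern, and a protospacer length. Built-ins:
`ABE8e` (A→G) and `BE4` (C→T), both with window 4–8, NGG, 20 nt. Only one
window is configured because only one is commonly characterized for this
design style; both editors share it, and other geometries (including NG
PAMs) are reachable through the editor config file but not validated here.

Outcome prediction is deterministic: **every** source base inside the
window is edited. This matches how such libraries are designed — the
designer must assume complete co-editing, because partial editing cannot be
controlled — and makes outcomes a pure function of sequence. Edited window
positions are projected to genomic coordinates (a position is editable iff
its guide-strand base equals the source base), affected codons are rebuilt
from the transcript's coordinate map and translated, and the target residue
is classified `missense_at_site` / `silent_at_site` / `site_unchanged`.
`aa_changes` records every codon whose nucleotides changed, including
synonymous changes, so "silent at the site but carrying a bystander" is
expressible; window edits outside the CDS are recorded as
`noncoding_edits`, never as amino-acid changes. A splice site counts as
disrupted when an edit hits the first two or last two bases of an annotated
intron (the donor GT / acceptor AG dinucleotides in transcript
orientation); this base-level definition is our own, as knockouts via
"splice disruption" are usually described only operationally.

`enumerate_codon_outcomes` brute-forces all synonymous codons × both guide
strands × every contiguous window coverage of the codon and reports the
reachable substitutions. For the phospho-residues this gives
Y × ABE8e → {C, H, silent}, S × ABE8e → {P, G, silent},
T × ABE8e → {A, silent}, and Y × BE4 → {silent} (a C→T editor cannot touch
either tyrosine codon's sense strand usefully, and the antisense strand
offers no C in the right places). The enumeration is also the test oracle
for `predict_outcome`: the two routes share no edit logic.

## Guide enumeration and filters

For each site, both strands are scanned over every anchor that can place
the editing window on an editable base of the target codon; candidates
require a PAM match on the guide strand. Placements truncated by a contig
end are skipped. Filters, each recorded as a flag on the rejected guide:

- `cloning_site` — BsmBI/Esp3I `CGTCTC` on either strand of either
  assembled oligo (adapters + protospacer, not the bare protospacer: the
  adapter junction `CACCG`+`TCTC…` itself creates a site). Enzyme list
  configurable.
- `polyT` — `TTTT` in the protospacer (U6 Pol III terminator); run length
  configurable.
- `multimatch` — more than 5 perfect, PAM-agnostic, both-strand genomic
  matches (overlapping occurrences counted). PAM-agnostic counting is the
  conservative choice when the matching convention is unspecified.
- `silent_with_bystander` — silent at the site but with bystander
  amino-acid changes or non-coding window edits; such guides are useless as
  controls and confounded as perturbations.

The localization-confidence cutoff is inclusive (conf ≥ 0.90 passes).
Identical protospacers arising from different sites are emitted once with
concatenated target annotations; all passing placements are kept rather
than picking one per site, since any prioritization would be arbitrary.

## Library assembly

Controls: non-targeting guides are seeded random 20-mers with zero perfect
and zero single-mismatch genomic matches; intergenic controls are real
placements whose protospacer and window lie wholly outside annotated gene
spans but still contain an editable base (editing happens, inertly);
splice disruptors edit a donor/acceptor base of genes from user-supplied
essential/TCR lists. Intergenic and splice controls additionally avoid
poly-T and cloning-site sequences so every control is clonable with the
standard adapters (a package choice; only non-targeting controls strictly
require it). Class caps default to 250, sampled without replacement with a
seed. Protospacer collisions across classes resolve to the phosphosite
class and are logged. Oligos follow the Golden-Gate scheme exactly:
`CACCG`+protospacer forward and `AAAC`+revcomp+`C` reverse, with no 5′-G
deduplication — the prefix G is appended regardless of the protospacer's
first base, which users should know when counting spacer lengths.

## Synthetic fixture

The mini-genome (two chromosomes, ≈ 6 kb) carries four hand-designed genes:
a plus-strand two-exon gene with the Tyr-missense, Thr→Ala, clean-silent,
silent-with-bystander, poly-T, cloning-site and multimatch cassettes; a
minus-strand gene with the antisense Ser→Pro case; a three-exon essential
gene whose target codon spans an exon junction and whose introns support
donor and acceptor disruptors; and a minus-strand TCR gene. The seeded RNG
shapes only intergenic background, so the planted geometry is fixed;
`make_fixture` raises if any planted case is not recoverable. The site
table spans confidence values (0.60–0.99 with both sides of the 0.90
boundary), a residue-mismatch record and an out-of-range record.

The answer key is generated at build time by `scan_guides_exhaustive`,
which edits the genome string directly and re-translates the entire CDS —
deliberately sharing no logic with the design modules — so "design output
equals answer key" is a two-route consistency check, not a tautology.

What the fixture does **not** emulate: real exon/intron length
distributions, chromatin or editing-efficiency heterogeneity, near-match
off-target landscapes beyond exact counting, and isoform complexity.
Passing tests demonstrate coordinate and filter correctness, not biological
performance on a real genome.

## Screen simulation and analysis

Counts are negative binomial per guide × sample: baseline abundances are
log-normal (σ = 1), a sample's expected fraction applies the planted log2
fold-changes (essential-splice and planted phosphosites: −2 in the
post-editing sample; reporter-bin effects ±half the bin log2FC), and
counts are drawn with mean m and variance m + φm², φ = 0.1 — standard
overdispersion for pooled screens. Default problem sizes: 60 sites × 3
guides (8 planted), 250 + 250 controls, 120 essential-splice guides, 10⁶
reads per sample. Sorting bins are effect-shifted abundance draws, not an
explicit cell-sorting model; that suffices to exercise the analysis stage.

Analysis follows the control-based normalization principle: size factors
are median-of-ratios over intergenic + non-targeting controls only, so a
globally shifted phosphosite distribution (e.g. widespread depletion)
cannot masquerade as normalization error. Guide log2FC uses a pseudocount
of 1 on normalized counts. Site scores are the median guide log2FC; the
null draws size-matched sets from control guides (10⁴ permutations,
two-sided p = (1 + #{|null| ≥ |obs|})/(n_perm + 1), so p is bounded below
by 1/(n_perm+1)), with BH correction across sites. The essential-depletion
QC is a one-sided Mann-Whitney test of the essential-splice class against
the pooled controls.

One statistical subtlety, found while validating: every site is tested
against the *same* permutation null, so sampling noise of a finite control
pool correlates all site p-values, and a null simulation's p-value
histogram can deviate from uniform conditional on one control draw. This is
inherent to control-permutation designs, not a bug; the dedicated
uniformity check therefore simulates a 2 000-guide control pool (verified
across 30 seeds), while the screening simulation keeps the realistic
250 + 250 condition.

`quantify_editing` reports, per window position carrying the source base in
the reference, the fraction of covering reads with the product base —
a read-count analogue of chromatogram-based editing quantification.
Positions with N are excluded from coverage.

## Known limitations

- No editing-efficiency or mismatch-tolerant off-target scoring; the
  specificity filter is exact-match counting only.
- One transcript per protein; no isoform-aware design.
- The analysis stage is intentionally minimal — it is a transparent
  permutation stand-in, and hit lists will differ from MAGeCK-class tools
  on the same counts.
- Alternative genetic codes and selenocysteine are out of scope.
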