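"""Base-editor chemistries and deterministic edit-outcome prediction.

A base editor converts one base to another (ABE8e: A->G, BE4: C->T) within a
fixed window of the protospacer.  Following the deterministic co-editing
model used for library design, *every* source base inside the window is
considered edited; there is no partial-editing model.  Window positions are
1-based with position 1 the most PAM-distal protospacer base and the PAM at
positions 21-23.

`predict_outcome` projects window edits onto genomic coordinates, rebuilds
every affected codon (including neighbours of the target and codons split
across exon junctions), translates, and classifies the consequence at the
targeted phosphosite.  `enumerate_codon_outcomes` brute-forces all reachable
amino-acid substitutions for a residue class and doubles as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import yaml

from .reference_model import (
    CodonLocus,
    Genome,
    TranscriptModel,
    complement,
    translate,
)


@dataclass(frozen=True)
class BaseEditorSpec:
    """Conversion chemistry, editing window and PAM of one base editor."""

    name: str
    source_base: str
    product_base: str
    window_start: int = 4
    window_end: int = 8
    pam_pattern: str = "NGG"
    protospacer_len: int = 20

    def __post_init__(self) -> None:
        if self.source_base == self.product_base:
            raise ValueError("source and product base must differ")
        if self.source_base not in "ACGT" or self.product_base not in "ACGT":
            raise ValueError("source/product must be A, C, G or T")
        if not 1 <= self.window_start <= self.window_end <= self.protospacer_len:
            raise ValueError(
                f"invalid window {self.window_start}-{self.window_end} for "
                f"{self.protospacer_len}-nt protospacer"
            )

    @property
    def window_offsets(self) -> range:
        """0-based protospacer offsets of the editing window."""
        return range(self.window_start - 1, self.window_end)


#: Editors as configured for phosphosite library design: 20-nt protospacer,
#: NGG PAM, editing window 4-8 for both chemistries.
ABE8E = BaseEditorSpec("ABE8e", "A", "G")
BE4 = BaseEditorSpec("BE4", "C", "T")
BUILTIN_EDITORS = {"ABE8e": ABE8E, "BE4": BE4}


def get_editor(name: str) -> BaseEditorSpec:
    try:
        return BUILTIN_EDITORS[name]
    except KeyError:
        raise KeyError(
            f"unknown editor {name!r}; built-ins: {sorted(BUILTIN_EDITORS)}"
        ) from None


def load_editor_config(path) -> BaseEditorSpec:
    """Load a BaseEditorSpec from a small YAML/JSON mapping.

    Keys: name, source_base, product_base, and optionally window_start,
    window_end, pam_pattern, protospacer_len.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return BaseEditorSpec(**cfg)


def pam_matches(pam_seq: str, pattern: str) -> bool:
    """Match a PAM against an IUPAC-free pattern where N is a wildcard."""
    if len(pam_seq) != len(pattern):
        return False
    return all(p == "N" or p == b for p, b in zip(pattern, pam_seq))


def apply_window_edit(protospacer: str, editor: BaseEditorSpec) -> str:
    """Edit every source base in the window of a guide-strand 20-mer."""
    if len(protospacer) != editor.protospacer_len:
        raise ValueError(
            f"protospacer length {len(protospacer)} != {editor.protospacer_len}"
        )
    seq = list(protospacer)
    for i in editor.window_offsets:
        if seq[i] == editor.source_base:
            seq[i] = editor.product_base
    return "".join(seq)


@dataclass
class EditOutcome:
    """Codon/protein-level consequence of one guide's window edits.

    ``aa_changes`` holds one ``(protein_pos, ref_aa, alt_aa)`` entry for every
    codon whose nucleotides were edited, including synonymous outcomes
    (ref_aa == alt_aa); ``site_class`` is derived solely from entries at the
    target residue.  Edited window positions outside the CDS are recorded in
    ``noncoding_edits``, never as amino-acid changes.
    """

    edited_genomic_positions: list[int] = field(default_factory=list)
    aa_changes: list[tuple[int, str, str]] = field(default_factory=list)
    site_class: str = "site_unchanged"
    bystander_changes: list[tuple[int, str, str]] = field(default_factory=list)
    noncoding_edits: list[int] = field(default_factory=list)
    splice_disrupted: bool = False

    @staticmethod
    def classify(at_site: Iterable[tuple[int, str, str]]) -> str:
        changes = list(at_site)
        if not changes:
            return "site_unchanged"
        if any(ref != alt for _, ref, alt in changes):
            return "missense_at_site"
        return "silent_at_site"


def edited_positions_on_genome(
    guide, genome: Genome, editor: BaseEditorSpec
) -> dict[int, str]:
    """Genomic positions the guide edits, mapped to their new plus-strand base.

    ``guide`` needs attributes ``chrom``, ``strand`` and
    ``window_genomic_positions`` (window positions in guide 5'->3' order).
    A position is edited iff its guide-strand base equals the editor's source.
    """
    seq = genome[guide.chrom].seq
    edits: dict[int, str] = {}
    for pos in guide.window_genomic_positions:
        base = seq[pos] if guide.strand == "+" else complement(seq[pos])
        if base == editor.source_base:
            new = editor.product_base
            edits[pos] = new if guide.strand == "+" else complement(new)
    return edits


def predict_outcome(
    guide,
    transcript: TranscriptModel,
    target: CodonLocus,
    editor: BaseEditorSpec,
    genome: Genome,
) -> EditOutcome:
    """Simulate all window edits of a guide and classify the consequence.

    Rebuilds only the codons whose bases were edited (via the transcript's
    genomic-position index), so codons adjacent to the target and codons
    split across exon junctions are handled; an exhaustive re-translation
    oracle cross-checks this logic in the test-suite.
    """
    if guide.chrom != transcript.chrom:
        raise ValueError(
            f"guide on {guide.chrom} but transcript {transcript.transcript_id} "
            f"on {transcript.chrom}"
        )
    edits = edited_positions_on_genome(guide, genome, editor)
    outcome = EditOutcome(edited_genomic_positions=sorted(edits))

    pos_index = transcript.position_index()
    cds_positions = transcript.cds_positions()
    seq = genome[transcript.chrom].seq

    affected: set[int] = set()  # 0-based codon indices
    for pos in edits:
        if pos in pos_index:
            affected.add(pos_index[pos] // 3)
        else:
            outcome.noncoding_edits.append(pos)
    outcome.noncoding_edits.sort()

    for codon_idx in sorted(affected):
        triplet = cds_positions[3 * codon_idx : 3 * codon_idx + 3]
        ref_bases, alt_bases = [], []
        for p in triplet:
            ref = seq[p]
            alt = edits.get(p, ref)
            if transcript.strand == "-":
                ref, alt = complement(ref), complement(alt)
            ref_bases.append(ref)
            alt_bases.append(alt)
        ref_codon, alt_codon = "".join(ref_bases), "".join(alt_bases)
        if ref_codon == alt_codon:
            continue
        entry = (codon_idx + 1, translate(ref_codon), translate(alt_codon))
        outcome.aa_changes.append(entry)
        if codon_idx + 1 != target.protein_pos:
            outcome.bystander_changes.append(entry)

    outcome.site_class = EditOutcome.classify(
        c for c in outcome.aa_changes if c[0] == target.protein_pos
    )
    splice = transcript.splice_site_positions()
    outcome.splice_disrupted = any(p in splice for p in edits)
    return outcome


# --- brute-force outcome enumeration (also the predict_outcome oracle) ------

_CODON_TABLES: dict[str, list[str]] = {}


def _codons_for_residue(residue: str) -> list[str]:
    if not _CODON_TABLES:
        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    codon = b1 + b2 + b3
                    _CODON_TABLES.setdefault(translate(codon), []).append(codon)
    return _CODON_TABLES[residue]


def edit_codon_subset(
    codon: str, covered: Iterable[int], guide_strand: str, editor: BaseEditorSpec
) -> str:
    """Edit the covered codon offsets as a guide on the given strand would.

    ``guide_strand`` is relative to the coding strand: ``+`` edits source
    bases directly, ``-`` edits positions whose antisense base is the source
    (i.e. coding bases complementary to it).
    """
    src = (
        editor.source_base
        if guide_strand == "+"
        else complement(editor.source_base)
    )
    dst = (
        editor.product_base
        if guide_strand == "+"
        else complement(editor.product_base)
    )
    out = list(codon)
    for i in covered:
        if out[i] == src:
            out[i] = dst
    return "".join(out)


#: Contiguous codon-offset subsets a 3+ nt editing window can cover.
_WINDOW_COVERAGES = [(0,), (1,), (2,), (0, 1), (1, 2), (0, 1, 2)]


def enumerate_codon_outcomes(residue: str, editor: BaseEditorSpec) -> set[str]:
    """All amino-acid outcomes reachable for a residue class with one editor.

    Brute force over every synonymous codon x both guide strands x every
    contiguous window placement over the codon, editing all source bases the
    window covers.  Synonymous (codon-changing, residue-preserving) outcomes
    are reported as ``"silent"``; placements that change no base are ignored.
    """
    outcomes: set[str] = set()
    for codon in _codons_for_residue(residue):
        for strand in "+-":
            for covered in _WINDOW_COVERAGES:
                edited = edit_codon_subset(codon, covered, strand, editor)
                if edited == codon:
                    continue
                aa = translate(edited)
                outcomes.add("silent" if aa == residue else aa)
    return outcomes
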