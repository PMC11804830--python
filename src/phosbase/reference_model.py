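"""Genome/annotation loading and protein<->genome codon coordinate mapping.

Base-editor guide design needs to know, for a phosphorylated residue reported
in protein coordinates, exactly which three genomic bases encode it.  This
module loads a reference genome (FASTA) and CDS annotation (GTF, 1-based
inclusive with frame) and provides exact bidirectional mapping between
1-based protein residue positions and genomic codon coordinates, including
codons split across exon junctions and genes on the reverse strand.

All internal coordinates are 0-based half-open; file I/O honours each
format's native convention (GTF is converted on load).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def complement(base: str) -> str:
    """Complement of a single base (N-safe)."""
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class GenomeSequence:
    """One reference sequence: uppercase DNA over {A,C,G,T,N}."""

    chrom: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for {self.chrom!r}")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.chrom!r}: non-ACGTN characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


#: A loaded genome: mapping chrom name -> GenomeSequence.
Genome = dict


@dataclass(frozen=True)
class CdsSegment:
    """One CDS interval, 0-based half-open, with its GTF frame."""

    start: int
    end: int
    frame: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Strand-aware CDS model of one transcript.

    ``cds_segments`` are ordered 5'->3' in transcript orientation (for minus
    strand transcripts that is descending genomic order).  The stop codon is
    part of the CDS but excluded from ``protein_length``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[CdsSegment]
    protein_length: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        total = sum(len(s) for s in self.cds_segments)
        if total == 0 or total % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {total} not divisible by 3"
            )
        self.protein_length = total // 3 - 1

    @property
    def cds_length(self) -> int:
        return sum(len(s) for s in self.cds_segments)

    def genomic_span(self) -> tuple[int, int]:
        """(min, max) genomic extent of the CDS, 0-based half-open."""
        return (
            min(s.start for s in self.cds_segments),
            max(s.end for s in self.cds_segments),
        )

    def cds_positions(self) -> list[int]:
        """Genomic position of every CDS base, in coding (5'->3') order."""
        out: list[int] = []
        for seg in self.cds_segments:
            if self.strand == "+":
                out.extend(range(seg.start, seg.end))
            else:
                out.extend(range(seg.end - 1, seg.start - 1, -1))
        return out

    def position_index(self) -> dict[int, int]:
        """Mapping genomic position -> 0-based index within the CDS."""
        return {g: i for i, g in enumerate(self.cds_positions())}

    def extract_cds(self, genome: Genome) -> str:
        """Coding-strand CDS sequence assembled from the genome."""
        seq = genome[self.chrom].seq
        parts = []
        for seg in self.cds_segments:
            chunk = seq[seg.start : seg.end]
            parts.append(chunk if self.strand == "+" else reverse_complement(chunk))
        return "".join(parts)

    def protein_sequence(self, genome: Genome) -> str:
        """Translated protein, stop stripped."""
        aa = translate(self.extract_cds(genome))
        return aa[:-1] if aa.endswith("*") else aa

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive CDS segments (ascending)."""
        segs = sorted(self.cds_segments, key=lambda s: s.start)
        return [(a.end, b.start) for a, b in zip(segs, segs[1:])]

    def splice_site_positions(self) -> set[int]:
        """Genomic positions of donor/acceptor dinucleotides of each intron.

        For every intron this is the first two and last two intronic bases
        (GT donor / AG acceptor in transcript orientation, whichever strand).
        """
        out: set[int] = set()
        for gs, ge in self.introns():
            out.update((gs, gs + 1, ge - 2, ge - 1))
        return out


@dataclass(frozen=True)
class CodonLocus:
    """The three genomic bases encoding one protein residue."""

    transcript_id: str
    protein_pos: int
    genomic_positions: tuple[int, int, int]
    ref_codon: str
    ref_aa: str
    chrom: str
    strand: str


def translate(seq: str) -> str:
    """Translate a coding-strand DNA string with the standard genetic code.

    Stops render as ``*``.  Any codon containing a character outside ACGT
    (e.g. N) yields ``X``, even where the ambiguity would resolve to a single
    residue; callers needing IUPAC resolution should use Biopython directly.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"length {len(seq)} not divisible by 3")
    seq = seq.upper()
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def load_genome(path) -> Genome:
    """Load a FASTA into {chrom: GenomeSequence}, uppercasing sequence.

    Rejects empty files, duplicate record names and non-ACGTN characters.
    """
    genome: Genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def _expected_frame(cum_len: int) -> int:
    # GTF frame: bases to skip at segment start to reach the next codon start.
    return (3 - cum_len % 3) % 3


def load_annotation(path, genome: Genome) -> dict[str, TranscriptModel]:
    """Load CDS features from a GTF into {transcript_id: TranscriptModel}.

    Coordinates are converted from GTF 1-based inclusive to 0-based half-open.
    Frames are validated against cumulative CDS length; segments must not
    extend past the chromosome end.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        tid = feat.attributes["transcript_id"][0]
        grouped.setdefault(tid, []).append(feat)

    transcripts: dict[str, TranscriptModel] = {}
    for tid, feats in grouped.items():
        strand = feats[0].strand
        chrom = feats[0].seqid
        gene_id = feats[0].attributes.get("gene_id", [tid])[0]
        if chrom not in genome:
            raise ValueError(f"{tid}: chromosome {chrom!r} not in genome")
        if any(f.strand != strand or f.seqid != chrom for f in feats):
            raise ValueError(f"{tid}: inconsistent strand/chrom across CDS")
        feats = sorted(feats, key=lambda f: f.start, reverse=(strand == "-"))
        segs = []
        for f in feats:
            start, end = f.start - 1, f.end  # to 0-based half-open
            if end > len(genome[chrom]) or start < 0:
                raise ValueError(
                    f"{tid}: CDS segment {start}-{end} beyond end of {chrom}"
                )
            segs.append(CdsSegment(start, end, int(f.frame)))
        cum = 0
        for seg in segs:
            if seg.frame != _expected_frame(cum):
                raise ValueError(
                    f"{tid}: frame {seg.frame} at {seg.start} inconsistent "
                    f"with cumulative CDS length {cum}"
                )
            cum += len(seg)
        model = TranscriptModel(tid, gene_id, chrom, strand, segs)
        cds = model.extract_cds(genome)
        if translate(cds[-3:]) != "*":
            logger.warning("%s: CDS does not end in a stop codon", tid)
        transcripts[tid] = model
    return transcripts


def protein_to_codon(
    transcript: TranscriptModel, protein_pos: int, genome: Genome
) -> CodonLocus:
    """Genomic codon coordinates of a 1-based protein residue position.

    Works across exon junctions; for reverse-strand transcripts the returned
    ``ref_codon`` is the coding-strand (reverse-complemented) genome slice.
    The stop codon is not addressable.
    """
    if not 1 <= protein_pos <= transcript.protein_length:
        raise ValueError(
            f"{transcript.transcript_id}: protein position {protein_pos} out "
            f"of range 1..{transcript.protein_length}"
        )
    positions = transcript.cds_positions()
    triplet = tuple(positions[3 * (protein_pos - 1) : 3 * protein_pos])
    seq = genome[transcript.chrom].seq
    bases = [seq[p] for p in triplet]
    if transcript.strand == "-":
        bases = [complement(b) for b in bases]
    codon = "".join(bases)
    return CodonLocus(
        transcript_id=transcript.transcript_id,
        protein_pos=protein_pos,
        genomic_positions=triplet,
        ref_codon=codon,
        ref_aa=translate(codon),
        chrom=transcript.chrom,
        strand=transcript.strand,
    )


def select_transcript_for_gene(
    transcripts: dict[str, TranscriptModel], gene_id: str
) -> TranscriptModel:
    """Longest-CDS transcript of a gene (used when a site names no isoform)."""
    cands = [t for t in transcripts.values() if t.gene_id == gene_id]
    if not cands:
        raise KeyError(f"no transcript for gene {gene_id!r}")
    cands.sort(key=lambda t: (-t.cds_length, t.transcript_id))
    if len(cands) > 1:
        logger.warning(
            "gene %s has %d transcripts; using longest CDS %s",
            gene_id,
            len(cands),
            cands[0].transcript_id,
        )
    return cands[0]
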