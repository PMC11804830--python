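"""Candidate protospacer enumeration and library exclusion filters.

For each phosphosite this module scans both genomic strands around the
encoding codon for 20-mer + NGG protospacer placements whose editing window
covers at least one editable base of the codon, predicts the edit outcome of
each placement, and applies the exclusion filters used for screening
libraries: cloning-enzyme sites in the assembled oligo, poly-T stretches
(Pol III terminator), promiscuous protospacers with more than five perfect
genomic matches, and silent-at-site guides carrying bystander edits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import reverse_complement

from . import editing_engine as ee
from .reference_model import (
    CodonLocus,
    Genome,
    TranscriptModel,
    protein_to_codon,
    select_transcript_for_gene,
)

logger = logging.getLogger(__name__)

PHOSPHO_RESIDUES = frozenset("STY")


@dataclass(frozen=True)
class Phosphosite:
    """One observed phosphorylation site in protein coordinates."""

    protein_id: str
    residue: str
    protein_pos: int
    localization_conf: float
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be S/T/Y, got {self.residue!r}")
        if not 0.0 <= self.localization_conf <= 1.0:
            raise ValueError("localization_conf must lie in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.protein_id}:{self.residue}{self.protein_pos}"


@dataclass
class GuideCandidate:
    """A protospacer placement with its predicted edit outcome and flags."""

    protospacer: str
    pam: str
    chrom: str
    strand: str
    start: int  # genomic span of the protospacer, 0-based half-open
    end: int
    window_genomic_positions: list[int]  # in guide 5'->3' order
    site: Phosphosite | None = None
    target: CodonLocus | None = None
    outcome: ee.EditOutcome | None = None
    filter_flags: set[str] = field(default_factory=set)

    @property
    def retained(self) -> bool:
        return not self.filter_flags


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the exclusion filters.

    ``enzyme_sites`` is checked on the assembled cloning oligos (adapters +
    protospacer) on both strands; default BsmBI/Esp3I, the enzyme the
    destination vector is digested with.  ``polyt_run`` is the Pol III
    terminator run length; ``max_matches`` the maximum tolerated number of
    perfect genomic matches.
    """

    enzyme_sites: tuple[str, ...] = ("CGTCTC",)
    polyt_run: int = 4
    max_matches: int = 5


def guide_strand_base(genome: Genome, chrom: str, pos: int, strand: str) -> str:
    from .reference_model import complement

    base = genome[chrom].seq[pos]
    return base if strand == "+" else complement(base)


def _window_positions(start: int, strand: str, editor: ee.BaseEditorSpec) -> list[int]:
    # Guide 5'->3' order: ascending genomic for '+', descending for '-'.
    plen = editor.protospacer_len
    if strand == "+":
        return [start + off for off in editor.window_offsets]
    return [start + plen - 1 - off for off in editor.window_offsets]


def _placement_at(
    genome: Genome, chrom: str, start: int, strand: str, editor: ee.BaseEditorSpec
) -> GuideCandidate | None:
    """Build the candidate anchored at ``start`` if its PAM matches."""
    seq = genome[chrom].seq
    plen, pam_len = editor.protospacer_len, len(editor.pam_pattern)
    if strand == "+":
        if start < 0 or start + plen + pam_len > len(seq):
            return None
        proto = seq[start : start + plen]
        pam = seq[start + plen : start + plen + pam_len]
    else:
        if start - pam_len < 0 or start + plen > len(seq):
            return None
        proto = reverse_complement(seq[start : start + plen])
        pam = reverse_complement(seq[start - pam_len : start])
    if "N" in proto or not ee.pam_matches(pam, editor.pam_pattern):
        return None
    return GuideCandidate(
        protospacer=proto,
        pam=pam,
        chrom=chrom,
        strand=strand,
        start=start,
        end=start + plen,
        window_genomic_positions=_window_positions(start, strand, editor),
    )


def placements_covering(
    genome: Genome,
    chrom: str,
    target_positions: set[int],
    editor: ee.BaseEditorSpec,
) -> list[GuideCandidate]:
    """All placements whose window covers >=1 editable target position.

    A target position counts as editable when its guide-strand base equals
    the editor's source base.  Both strands are scanned exhaustively over
    every anchor that could place the window on a target position.
    """
    lo, hi = min(target_positions), max(target_positions)
    plen = editor.protospacer_len
    out = []
    for strand in "+-":
        for start in range(lo - plen - 3, hi + plen + 4):
            cand = _placement_at(genome, chrom, start, strand, editor)
            if cand is None:
                continue
            editable = [
                p
                for p in cand.window_genomic_positions
                if p in target_positions
                and guide_strand_base(genome, chrom, p, strand)
                == editor.source_base
            ]
            if editable:
                out.append(cand)
    out.sort(key=lambda c: (c.start, c.strand))
    return out


def find_pam_placements(
    genome: Genome,
    codon: CodonLocus,
    editor: ee.BaseEditorSpec,
    transcript: TranscriptModel | None = None,
    site: Phosphosite | None = None,
) -> list[GuideCandidate]:
    """Unfiltered candidate guides for a target codon, with outcomes.

    Placements truncated by a contig end are skipped.  When the transcript is
    given, every candidate carries its predicted EditOutcome.
    """
    cands = placements_covering(
        genome, codon.chrom, set(codon.genomic_positions), editor
    )
    for cand in cands:
        cand.site = site
        cand.target = codon
        if transcript is not None:
            cand.outcome = ee.predict_outcome(
                cand, transcript, codon, editor, genome
            )
    return cands


def count_perfect_matches(protospacer: str, genome: Genome) -> int:
    """Exact occurrences of a protospacer on both strands of the genome.

    PAM-agnostic; overlapping occurrences count.  A reverse-complement
    palindromic protospacer at one locus counts once per strand.
    """
    rc = reverse_complement(protospacer)
    n = 0
    for rec in genome.values():
        for probe in (protospacer, rc):
            n += len(re.findall(f"(?={re.escape(probe)})", rec.seq))
    return n


def oligo_pair(protospacer: str) -> tuple[str, str]:
    """Cloning oligos: CACCG + protospacer / AAAC + revcomp + 3' C."""
    return "CACCG" + protospacer, "AAAC" + reverse_complement(protospacer) + "C"


def compute_filter_flags(
    cand: GuideCandidate, genome: Genome, config: FilterConfig
) -> set[str]:
    flags: set[str] = set()
    fwd, rev = oligo_pair(cand.protospacer)
    for site in config.enzyme_sites:
        if any(
            site in oligo or site in reverse_complement(oligo)
            for oligo in (fwd, rev)
        ):
            flags.add("cloning_site")
    if "T" * config.polyt_run in cand.protospacer:
        flags.add("polyT")
    if count_perfect_matches(cand.protospacer, genome) > config.max_matches:
        flags.add("multimatch")
    if cand.outcome is not None and cand.outcome.site_class == "silent_at_site":
        if cand.outcome.bystander_changes or cand.outcome.noncoding_edits:
            flags.add("silent_with_bystander")
    return flags


def apply_filters(
    candidates: list[GuideCandidate],
    genome: Genome,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[GuideCandidate], list[GuideCandidate]]:
    """Split candidates into (retained, rejected); rejections carry flags."""
    retained, rejected = [], []
    for cand in candidates:
        cand.filter_flags = compute_filter_flags(cand, genome, config)
        (retained if cand.retained else rejected).append(cand)
    return retained, rejected


def format_aa_changes(changes: list[tuple[int, str, str]]) -> str:
    return ";".join(f"{ref}{pos}{alt}" for pos, ref, alt in changes)


@dataclass
class DesignResult:
    """Output of design_for_sites: per-guide table, per-site counts, skips."""

    guides: pd.DataFrame
    per_site: pd.DataFrame
    skipped: list[tuple[str, str]]

    def retained(self) -> pd.DataFrame:
        return self.guides[self.guides["filter_flags"] == ""]


_GUIDE_COLUMNS = [
    "protospacer",
    "pam",
    "chrom",
    "strand",
    "start",
    "end",
    "target",
    "site_class",
    "aa_changes",
    "bystanders",
    "noncoding_edits",
    "splice_disrupted",
    "filter_flags",
]


def design_for_sites(
    sites: list[Phosphosite],
    genome: Genome,
    transcripts: dict[str, TranscriptModel],
    editor: ee.BaseEditorSpec,
    min_conf: float = 0.90,
    config: FilterConfig = FilterConfig(),
) -> DesignResult:
    """Design guides for a phosphosite list end to end.

    Sites below ``min_conf`` (inclusive cutoff: conf >= min_conf passes) are
    dropped; each surviving site is mapped to its codon, validated against
    the translated residue, and every placement is enumerated and filtered.
    Identical protospacers arising from several sites are emitted once with
    the target annotations concatenated.  Unmappable sites are logged and
    reported in ``skipped``, never fatal.
    """
    rows: list[dict] = []
    skipped: list[tuple[str, str]] = []
    per_site_counts: dict[str, tuple[int, int]] = {}

    for site in sites:
        if site.localization_conf < min_conf:
            skipped.append((site.label, "low_confidence"))
            continue
        try:
            if site.transcript_id is not None:
                tx = transcripts[site.transcript_id]
            else:
                tx = select_transcript_for_gene(transcripts, site.protein_id)
            codon = protein_to_codon(tx, site.protein_pos, genome)
        except (KeyError, ValueError) as exc:
            logger.warning("site %s unmappable: %s", site.label, exc)
            skipped.append((site.label, "unmappable"))
            continue
        if codon.ref_aa != site.residue:
            logger.warning(
                "site %s: annotated residue %s but transcript encodes %s",
                site.label,
                site.residue,
                codon.ref_aa,
            )
            skipped.append((site.label, "residue_mismatch"))
            continue
        cands = find_pam_placements(genome, codon, editor, tx, site)
        retained, rejected = apply_filters(cands, genome, config)
        per_site_counts[site.label] = (len(retained), len(rejected))
        for cand in retained + rejected:
            rows.append(
                {
                    "protospacer": cand.protospacer,
                    "pam": cand.pam,
                    "chrom": cand.chrom,
                    "strand": cand.strand,
                    "start": cand.start,
                    "end": cand.end,
                    "target": site.label,
                    "site_class": cand.outcome.site_class,
                    "aa_changes": format_aa_changes(cand.outcome.aa_changes),
                    "bystanders": format_aa_changes(
                        cand.outcome.bystander_changes
                    ),
                    "noncoding_edits": len(cand.outcome.noncoding_edits),
                    "splice_disrupted": cand.outcome.splice_disrupted,
                    "filter_flags": ",".join(sorted(cand.filter_flags)),
                }
            )

    guides = pd.DataFrame(rows, columns=_GUIDE_COLUMNS)
    if not guides.empty:
        guides = (
            guides.groupby(
                [c for c in _GUIDE_COLUMNS if c != "target"], as_index=False
            )
            .agg(target=("target", lambda s: ";".join(sorted(set(s)))))
            .loc[:, _GUIDE_COLUMNS]
            .sort_values(["chrom", "start", "strand", "target"])
            .reset_index(drop=True)
        )
    per_site = pd.DataFrame(
        [
            {"site": label, "n_retained": r, "n_rejected": x}
            for label, (r, x) in sorted(per_site_counts.items())
        ],
        columns=["site", "n_retained", "n_rejected"],
    )
    return DesignResult(guides=guides, per_site=per_site, skipped=skipped)


def read_phosphosite_table(path) -> list[Phosphosite]:
    """Read the tab-delimited phosphosite input table.

    Columns: protein_id, transcript_id (may be empty), residue, position,
    localization_conf.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": "string"})
    required = {"protein_id", "residue", "position", "localization_conf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phosphosite table missing columns {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        tid = getattr(row, "transcript_id", None)
        if pd.isna(tid) or tid == "":
            tid = None
        sites.append(
            Phosphosite(
                protein_id=row.protein_id,
                transcript_id=tid,
                residue=row.residue,
                protein_pos=int(row.position),
                localization_conf=float(row.localization_conf),
            )
        )
    return sites
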