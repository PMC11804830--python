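"""Control-guide generation, library assembly, and cloning oligos.

A screening library combines phosphosite-targeting guides with four control
classes: non-targeting (no genomic match, controls for editor expression),
intergenic (real but inert edits, controls for editing activity),
essential-gene splice disruptors (positive depletion controls) and
TCR-gene splice disruptors.  Every entry receives Golden-Gate-ready oligos:
``CACCG`` + protospacer forward, ``AAAC`` + reverse-complement + 3' ``C``
reverse.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from . import editing_engine as ee
from . import guide_design as gd
from .reference_model import Genome, TranscriptModel

logger = logging.getLogger(__name__)

CONTROL_CLASSES = ("non_targeting", "intergenic", "essential_splice", "tcr_splice")
LIBRARY_CLASSES = ("phosphosite",) + CONTROL_CLASSES

_CLASS_PREFIX = {
    "phosphosite": "PH",
    "non_targeting": "NT",
    "intergenic": "IG",
    "essential_splice": "ES",
    "tcr_splice": "TS",
}


@dataclass
class LibraryEntry:
    """One guide of the final library with class label and cloning oligos."""

    guide_id: str
    protospacer: str
    guide_class: str
    target: str = "none"
    oligo_forward: str = field(init=False)
    oligo_reverse: str = field(init=False)

    def __post_init__(self) -> None:
        if self.guide_class not in LIBRARY_CLASSES:
            raise ValueError(f"unknown class {self.guide_class!r}")
        self.oligo_forward, self.oligo_reverse = gd.oligo_pair(self.protospacer)


def _genome_kmers(genome: Genome, k: int) -> set[str]:
    kmers: set[str] = set()
    for rec in genome.values():
        seq = rec.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            kmers.add(kmer)
            kmers.add(reverse_complement(kmer))
    return kmers


def _one_mismatch_neighbours(seq: str):
    for i, base in enumerate(seq):
        for alt in "ACGT":
            if alt != base:
                yield seq[:i] + alt + seq[i + 1 :]


def make_non_targeting(
    genome: Genome,
    n: int,
    seed: int,
    config: gd.FilterConfig = gd.FilterConfig(),
    max_attempts_per_guide: int = 2000,
) -> list[LibraryEntry]:
    """Seeded random 20-mers absent from the genome even at one mismatch.

    Each returned protospacer has zero perfect and zero single-mismatch
    genomic matches, no poly-T run and no cloning-enzyme site.
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    kmers = _genome_kmers(genome, 20)
    picked: list[str] = []
    seen: set[str] = set()
    attempts = 0
    budget = n * max_attempts_per_guide
    while len(picked) < n:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"could not find {n} non-targeting guides in {budget} attempts"
            )
        proto = "".join(rng.choice(list("ACGT"), size=20))
        if proto in seen:
            continue
        seen.add(proto)
        if "T" * config.polyt_run in proto:
            continue
        fwd, rev = gd.oligo_pair(proto)
        if any(
            site in oligo or site in reverse_complement(oligo)
            for site in config.enzyme_sites
            for oligo in (fwd, rev)
        ):
            continue
        if proto in kmers:
            continue
        if any(nb in kmers for nb in _one_mismatch_neighbours(proto)):
            continue
        picked.append(proto)
    return [
        LibraryEntry(f"{_CLASS_PREFIX['non_targeting']}_{i + 1:04d}", p, "non_targeting")
        for i, p in enumerate(picked)
    ]


def gene_spans(transcripts: dict[str, TranscriptModel]) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome genomic spans covered by annotated genes (CDS extent)."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for tx in transcripts.values():
        spans.setdefault(tx.chrom, []).append(tx.genomic_span())
    return spans


def _outside_all(lo: int, hi: int, spans: list[tuple[int, int]]) -> bool:
    return all(hi <= s or lo >= e for s, e in spans)


def make_intergenic(
    genome: Genome,
    transcripts: dict[str, TranscriptModel],
    editor: ee.BaseEditorSpec,
    n: int,
    seed: int,
    config: gd.FilterConfig = gd.FilterConfig(),
) -> list[LibraryEntry]:
    """Seeded sample of guides editing real but gene-free loci.

    Protospacer and window lie wholly outside annotated gene spans and the
    window contains at least one editable source base, so editing occurs but
    is phenotypically inert.  Poly-T and cloning-site protospacers are
    excluded so every control is clonable with the standard adapters.
    """
    if n == 0:
        return []
    spans = gene_spans(transcripts)
    pool: list[str] = []
    seen: set[str] = set()
    for chrom, rec in genome.items():
        chrom_spans = spans.get(chrom, [])
        for strand in "+-":
            for start in range(len(rec.seq)):
                cand = gd._placement_at(genome, chrom, start, strand, editor)
                if cand is None:
                    continue
                win = cand.window_genomic_positions
                lo = min(cand.start, min(win))
                hi = max(cand.end, max(win) + 1)
                if not _outside_all(lo, hi, chrom_spans):
                    continue
                if not any(
                    gd.guide_strand_base(genome, chrom, p, strand)
                    == editor.source_base
                    for p in win
                ):
                    continue
                if "T" * config.polyt_run in cand.protospacer:
                    continue
                fwd, rev = gd.oligo_pair(cand.protospacer)
                if any(
                    site in o or site in reverse_complement(o)
                    for site in config.enzyme_sites
                    for o in (fwd, rev)
                ):
                    continue
                if cand.protospacer in seen:
                    continue
                seen.add(cand.protospacer)
                pool.append(cand.protospacer)
    if len(pool) < n:
        raise RuntimeError(
            f"only {len(pool)} intergenic placements available, need {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(pool), size=n, replace=False))
    return [
        LibraryEntry(
            f"{_CLASS_PREFIX['intergenic']}_{i + 1:04d}", pool[j], "intergenic"
        )
        for i, j in enumerate(chosen)
    ]


def make_splice_disruptors(
    genome: Genome,
    transcripts: dict[str, TranscriptModel],
    gene_list: list[str],
    editor: ee.BaseEditorSpec,
    n_per_class: int,
    guide_class: str = "essential_splice",
) -> list[LibraryEntry]:
    """Guides whose window edits a donor GT / acceptor AG dinucleotide.

    For every multi-exonic gene in ``gene_list`` all placements editing a
    splice dinucleotide base are collected (deterministic order) and the
    result is capped at ``n_per_class``.  Single-exon genes are skipped with
    a warning.
    """
    entries: list[LibraryEntry] = []
    seen: set[str] = set()
    for gene in gene_list:
        gene_txs = sorted(
            (t for t in transcripts.values() if t.gene_id == gene),
            key=lambda t: t.transcript_id,
        )
        if not gene_txs:
            logger.warning("splice-control gene %s not in annotation", gene)
            continue
        for tx in gene_txs:
            splice = tx.splice_site_positions()
            if not splice:
                logger.warning(
                    "gene %s transcript %s is single-exon; no splice controls",
                    gene,
                    tx.transcript_id,
                )
                continue
            for cand in gd.placements_covering(genome, tx.chrom, splice, editor):
                edits = ee.edited_positions_on_genome(cand, genome, editor)
                if not any(p in splice for p in edits):
                    continue
                if cand.protospacer in seen:
                    continue
                seen.add(cand.protospacer)
                entries.append(
                    LibraryEntry(
                        f"{_CLASS_PREFIX[guide_class]}_{len(entries) + 1:04d}",
                        cand.protospacer,
                        guide_class,
                        target=gene,
                    )
                )
    return entries[:n_per_class]


@dataclass(frozen=True)
class LibraryCaps:
    """Per-class entry caps; control classes default to 250 each."""

    non_targeting: int = 250
    intergenic: int = 250
    essential_splice: int = 250
    tcr_splice: int = 250

    def for_class(self, guide_class: str) -> int:
        return getattr(self, guide_class)


@dataclass
class AssembledLibrary:
    table: pd.DataFrame
    summary: dict


def assemble_library(
    phospho_guides: pd.DataFrame,
    non_targeting: list[LibraryEntry] | None = None,
    intergenic: list[LibraryEntry] | None = None,
    essential_splice: list[LibraryEntry] | None = None,
    tcr_splice: list[LibraryEntry] | None = None,
    caps: LibraryCaps = LibraryCaps(),
    seed: int = 0,
) -> AssembledLibrary:
    """Deduplicate, cap, label and oligo-annotate the final library.

    ``phospho_guides`` is the retained-guide table from design_for_sites.
    Protospacers colliding across classes resolve to the phosphosite class
    (collision logged); control classes are down-sampled to their caps
    without replacement using ``seed``; guide ids are stable for identical
    inputs + seed.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    used: set[str] = set()

    phospho = phospho_guides.sort_values(["chrom", "start", "strand"]).reset_index(
        drop=True
    )
    for i, row in enumerate(phospho.itertuples(index=False)):
        if row.protospacer in used:
            continue
        used.add(row.protospacer)
        fwd, rev = gd.oligo_pair(row.protospacer)
        rows.append(
            {
                "guide_id": f"PH_{i + 1:05d}",
                "protospacer": row.protospacer,
                "class": "phosphosite",
                "target": row.target,
                "oligo_forward": fwd,
                "oligo_reverse": rev,
            }
        )

    pools = {
        "non_targeting": non_targeting or [],
        "intergenic": intergenic or [],
        "essential_splice": essential_splice or [],
        "tcr_splice": tcr_splice or [],
    }
    for cls in CONTROL_CLASSES:
        pool = [e for e in pools[cls] if e.guide_class == cls]
        kept = []
        for entry in pool:
            if entry.protospacer in used:
                logger.info(
                    "protospacer collision: %s control %s already in library",
                    cls,
                    entry.protospacer,
                )
                continue
            kept.append(entry)
        cap = caps.for_class(cls)
        if len(kept) > cap:
            idx = sorted(rng.choice(len(kept), size=cap, replace=False))
            kept = [kept[i] for i in idx]
        for i, entry in enumerate(kept):
            used.add(entry.protospacer)
            rows.append(
                {
                    "guide_id": f"{_CLASS_PREFIX[cls]}_{i + 1:04d}",
                    "protospacer": entry.protospacer,
                    "class": cls,
                    "target": entry.target,
                    "oligo_forward": entry.oligo_forward,
                    "oligo_reverse": entry.oligo_reverse,
                }
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "guide_id",
            "protospacer",
            "class",
            "target",
            "oligo_forward",
            "oligo_reverse",
        ],
    )
    n_sites = 0
    if not phospho.empty and "target" in phospho.columns:
        site_set: set[str] = set()
        for t in table.loc[table["class"] == "phosphosite", "target"]:
            site_set.update(t.split(";"))
        n_sites = len(site_set)
    summary = {
        "guides_per_class": table["class"].value_counts().to_dict(),
        "n_guides": int(len(table)),
        "n_sites_with_guide": n_sites,
    }
    return AssembledLibrary(table=table, summary=summary)


def write_library(lib: AssembledLibrary, tsv_path, fasta_path=None, summary_path=None):
    """Write the library TSV and optionally oligo FASTA and JSON summary."""
    lib.table.to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for row in lib.table.itertuples(index=False):
                fh.write(f">{row.guide_id}_F\n{row.oligo_forward}\n")
                fh.write(f">{row.guide_id}_R\n{row.oligo_reverse}\n")
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(lib.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
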