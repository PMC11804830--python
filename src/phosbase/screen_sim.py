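"""Synthetic fixture generator and pooled-screen count simulator.

Everything downstream of raw data is testable offline against this module:
it emits a deterministic mini-genome (FASTA + GTF) with multi-exon CDS on
both strands, a phosphosite table spanning localization-confidence values,
and an answer key listing every guide the design stage should produce.

The planted cassettes cover each codon-outcome class the design logic must
handle (Tyr missense, Ser->Pro via the antisense strand, Thr->Ala, a clean
silent edit, a silent edit with a bystander) and each exclusion filter
(poly-T, cloning site, >5 perfect matches).  Cassette sequences are fixed by
hand; the seed drives only the intergenic background, so planted geometry is
reproducible byte-for-byte.

The answer key is produced by :func:`scan_guides_exhaustive`, a deliberately
naive scanner that edits the genome string directly and re-translates the
whole CDS.  It shares no prediction logic with the design modules, so
answer-key equality is a genuine two-route consistency check.

`simulate_counts` draws negative-binomial sequencing counts for a guide
library with planted log2 fold-change effects, emulating a pooled screen
with pre/post-editing samples and reporter sorting bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .guide_design import Phosphosite, oligo_pair
from .reference_model import Genome, TranscriptModel, load_annotation, load_genome, translate

PROTOSPACER_LEN = 20
PAM_LEN = 3


class FixtureError(RuntimeError):
    """Raised when a fixture spec cannot produce its planted cases."""


# --------------------------------------------------------------------------
# gene cassettes (coding-strand codon lists; see module docstring)
# --------------------------------------------------------------------------

_GENE_A_EXON1 = (
    "ATG GAT CTG GTC TAC GAT CTG GTG GCG GTG "  # Y5: TAC, A at window pos 6
    "GGC CTG ACT GGC GTG CTG GCC CGG GAC CTG"    # T13: ACT, A at window pos 6
).split()
_GENE_A_INTRON1 = "GT" + "CAGGCACCTGG" + "CC" + "GCACGC" + "AG"  # 23 nt
_GENE_A_EXON2 = (
    "GCC TAT GGC GCC TCA AGC CTG CTG GAC CTG "  # Y22 silent; S25 silent+bystander
    "AGG TTT TAC GGC GAC CTG GCC GAC GGC CGT "  # Y33 guide starts TTTT
    "CTC ACT GAC CTG GCC CTG GCC GTC TAC GGC "  # T42 guide spans CGTCTC; Y49 multimatch
    "GAC CTG GCC CTG GGC TGA"
).split()

_GENE_B_EXON1 = "ATG GCC CAC CCC CTG GAC GTG GCC GAC TCA GCC GTG".split()  # S10: TCA
_GENE_B_INTRON1 = "GT" + "GCACCTGCACCGGCACC" + "AG"  # 21 nt
_GENE_B_EXON2 = "GAC AGC CTG GGC GGT GAC CTG TAA".split()  # S14

_GENE_C_EXON1_CODONS = "ATG CCC CTG GAC GGC GGC".split()  # + "TA" of split Y7
_GENE_C_INTRON1 = "GT" + "CACCTGCCCACCG" + "GG" + "CTGC" + "G" + "AG"  # 24 nt
_GENE_C_EXON2_TAIL = "GAC CTG GGC GAC CTG GGC GCC GTG GAC CTG GCC GAC".split()
_GENE_C_INTRON2 = "GTC" + "ACCGGCATCCACGCCTG" + "GC" + "AG"  # 24 nt
_GENE_C_EXON3 = "GAC ACC GTG CTG CTG GGC GAC TGA".split()  # T21: ACC (no guide)

_GENE_D_EXON1_CODONS = "ATG CCA CTG GTC GGA GCC".split()  # + "TA" of split Y7
_GENE_D_INTRON1 = "GT" + "CAGGCTGCCACCG" + "GG" + "GTGC" + "G" + "AG"  # 24 nt
_GENE_D_EXON2_TAIL = "GAC AGC CTG GCG GTC GAC GGA GCC TAA".split()  # S9: AGC


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of the synthetic mini-genome.

    The planted cassettes are fixed; the seed shapes only intergenic
    background.  ``multimatch_copies`` extra copies of one retained-looking
    protospacer are planted on chr2 so that guide exceeds the 5-perfect-match
    specificity threshold.
    """

    seed: int = 0
    intergenic_lengths: tuple[int, ...] = (650, 700, 750, 650, 600)
    chr2_length: int = 2400
    multimatch_copies: int = 5
    essential_genes: tuple[str, ...] = ("GENE_C",)
    tcr_genes: tuple[str, ...] = ("GENE_D",)


@dataclass
class FixturePaths:
    genome_fasta: Path
    annotation_gtf: Path
    phosphosites_tsv: Path
    answer_key_json: Path
    essential_genes_txt: Path
    tcr_genes_txt: Path


def _spliced(exons: list[str], introns: list[str]) -> str:
    parts = [exons[0]]
    for intron, exon in zip(introns, exons[1:]):
        parts.extend((intron, exon))
    return "".join(parts)


def _gene_block(
    gene_id: str,
    tid: str,
    chrom: str,
    exons: list[str],
    introns: list[str],
    strand: str,
    offset: int,
):
    """Genomic sequence block + GTF CDS records for one gene."""
    premrna = _spliced(exons, introns)
    # exon intervals within the pre-mRNA, transcript order
    tx_intervals, pos = [], 0
    for i, exon in enumerate(exons):
        tx_intervals.append((pos, pos + len(exon)))
        pos += len(exon)
        if i < len(introns):
            pos += len(introns[i])
    block = premrna if strand == "+" else reverse_complement(premrna)
    records = []
    cum = 0
    for a, b in tx_intervals:
        frame = (3 - cum % 3) % 3
        cum += b - a
        if strand == "+":
            g0, g1 = offset + a, offset + b
        else:
            g0, g1 = offset + len(premrna) - b, offset + len(premrna) - a
        records.append(
            f"{chrom}\tphosbase\tCDS\t{g0 + 1}\t{g1}\t.\t{strand}\t{frame}\t"
            f'gene_id "{gene_id}"; transcript_id "{tid}";'
        )
    return block, records


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


_SITE_ROWS = [
    # protein_id, transcript_id, residue, position, conf
    ("GENE_A", "TX_A", "Y", 5, 0.99),
    ("GENE_A", "TX_A", "T", 13, 0.95),
    ("GENE_A", "TX_A", "Y", 22, 0.96),
    ("GENE_A", "TX_A", "S", 25, 0.93),
    ("GENE_A", "TX_A", "Y", 33, 0.92),
    ("GENE_A", "TX_A", "T", 42, 0.94),
    ("GENE_A", "TX_A", "Y", 49, 0.98),
    ("GENE_A", "TX_A", "S", 3, 0.95),  # residue mismatch: codon 3 encodes L
    ("GENE_B", "TX_B", "S", 10, 0.91),
    ("GENE_B", "TX_B", "S", 14, 0.89),  # below the >=0.90 localization cutoff
    ("GENE_B", "TX_B", "S", 99, 0.95),  # beyond protein length: unmappable
    ("GENE_C", "TX_C", "Y", 7, 0.90),  # cutoff boundary, codon split 2|1
    ("GENE_C", "TX_C", "T", 21, 0.97),  # no PAM-compatible placement
    ("GENE_D", "TX_D", "Y", 7, 0.99),
    ("GENE_D", "TX_D", "S", 9, 0.60),  # below cutoff
]


def make_fixture(spec: FixtureSpec, out_dir) -> FixturePaths:
    """Write the fixture genome, annotation, site table and answer key.

    Deterministic for a seed.  Raises :class:`FixtureError` if any planted
    design case is not recoverable from the generated files (which would
    indicate an infeasible spec, e.g. intergenic spans too short).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ig = spec.intergenic_lengths
    if len(ig) != 5 or min(ig) < 100:
        raise FixtureError("need five intergenic spans of >=100 bp on chr1")

    genes = [
        ("GENE_A", "TX_A", [" ".join(_GENE_A_EXON1).replace(" ", ""),
                            " ".join(_GENE_A_EXON2).replace(" ", "")],
         [_GENE_A_INTRON1], "+"),
        ("GENE_B", "TX_B", ["".join(_GENE_B_EXON1), "".join(_GENE_B_EXON2)],
         [_GENE_B_INTRON1], "-"),
        ("GENE_C", "TX_C", ["".join(_GENE_C_EXON1_CODONS) + "TA",
                            "T" + "".join(_GENE_C_EXON2_TAIL),
                            "".join(_GENE_C_EXON3)],
         [_GENE_C_INTRON1, _GENE_C_INTRON2], "+"),
        ("GENE_D", "TX_D", ["".join(_GENE_D_EXON1_CODONS) + "TA",
                            "T" + "".join(_GENE_D_EXON2_TAIL)],
         [_GENE_D_INTRON1], "-"),
    ]

    chr1_parts, gtf_lines = [], []
    offset = 0
    for spacer_len, gene in zip(ig, genes + [None]):
        spacer = _random_dna(rng, spacer_len)
        chr1_parts.append(spacer)
        offset += spacer_len
        if gene is None:
            break
        gene_id, tid, exons, introns, strand = gene
        block, records = _gene_block(gene_id, tid, "chr1", exons, introns, strand, offset)
        chr1_parts.append(block)
        gtf_lines.extend(records)
        if gene_id == "GENE_A":
            gene_a_offset = offset
        offset += len(block)
    chr1 = "".join(chr1_parts)

    # The GENE_A Y49 guide protospacer, planted multimatch_copies more times
    # on chr2 so its total perfect-match count exceeds the threshold.
    multimatch_proto = chr1[gene_a_offset + 163 : gene_a_offset + 183]
    chr2_seq = list(_random_dna(rng, spec.chr2_length))
    step = spec.chr2_length // (spec.multimatch_copies + 1)
    if step < PROTOSPACER_LEN + 10:
        raise FixtureError("chr2 too short for requested multimatch copies")
    for i in range(spec.multimatch_copies):
        insert = multimatch_proto if i % 2 == 0 else reverse_complement(multimatch_proto)
        at = step * (i + 1)
        chr2_seq[at : at + PROTOSPACER_LEN] = insert
    chr2 = "".join(chr2_seq)

    paths = FixturePaths(
        genome_fasta=out / "genome.fa",
        annotation_gtf=out / "annotation.gtf",
        phosphosites_tsv=out / "phosphosites.tsv",
        answer_key_json=out / "answer_key.json",
        essential_genes_txt=out / "essential_genes.txt",
        tcr_genes_txt=out / "tcr_genes.txt",
    )
    with open(paths.genome_fasta, "w") as fh:
        for name, seq in (("chr1", chr1), ("chr2", chr2)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths.annotation_gtf, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")
    sites_df = pd.DataFrame(
        _SITE_ROWS,
        columns=["protein_id", "transcript_id", "residue", "position", "localization_conf"],
    )
    sites_df.to_csv(paths.phosphosites_tsv, sep="\t", index=False)
    paths.essential_genes_txt.write_text("\n".join(spec.essential_genes) + "\n")
    paths.tcr_genes_txt.write_text("\n".join(spec.tcr_genes) + "\n")

    _write_answer_key(paths, min_conf=0.90)
    return paths


# --------------------------------------------------------------------------
# exhaustive reference scanner (answer-key oracle)
# --------------------------------------------------------------------------


def _naive_match_count(protospacer: str, genome: Genome) -> int:
    rc = reverse_complement(protospacer)
    n = 0
    for rec in genome.values():
        seq = rec.seq
        for i in range(len(seq) - len(protospacer) + 1):
            window = seq[i : i + len(protospacer)]
            if window == protospacer:
                n += 1
            if window == rc:
                n += 1
    return n


def _oracle_flags(
    protospacer: str,
    genome: Genome,
    site_class: str,
    n_bystander: int,
    n_noncoding: int,
) -> list[str]:
    flags = []
    fwd, rev = oligo_pair(protospacer)
    for oligo in (fwd, rev):
        if "CGTCTC" in oligo or "CGTCTC" in reverse_complement(oligo):
            flags.append("cloning_site")
            break
    if "TTTT" in protospacer:
        flags.append("polyT")
    if _naive_match_count(protospacer, genome) > 5:
        flags.append("multimatch")
    if site_class == "silent_at_site" and (n_bystander or n_noncoding):
        flags.append("silent_with_bystander")
    return sorted(flags)


def scan_guides_exhaustive(
    genome: Genome,
    transcript: TranscriptModel,
    protein_pos: int,
    source_base: str = "A",
    product_base: str = "G",
) -> list[dict]:
    """Every guide for a residue, found by brute force over the chromosome.

    Edits the genome string directly, re-extracts and re-translates the full
    CDS, and diffs codons — no shared logic with the prediction engine.
    Window 4-8 of a 20-nt protospacer, NGG PAM.
    """
    seq = genome[transcript.chrom].seq
    cds_positions = transcript.cds_positions()
    codon_positions = set(cds_positions[3 * (protein_pos - 1) : 3 * protein_pos])
    ref_cds = transcript.extract_cds(genome)
    splice: set[int] = set()
    segs = sorted(transcript.cds_segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        splice.update((a.end, a.end + 1, b.start - 2, b.start - 1))

    results = []
    for strand in "+-":
        for s in range(len(seq)):
            if strand == "+":
                if s + PROTOSPACER_LEN + PAM_LEN > len(seq):
                    break
                proto = seq[s : s + PROTOSPACER_LEN]
                pam = seq[s + PROTOSPACER_LEN : s + PROTOSPACER_LEN + PAM_LEN]
                window = [s + i for i in range(3, 8)]
            else:
                if s < PAM_LEN or s + PROTOSPACER_LEN > len(seq):
                    continue
                proto = reverse_complement(seq[s : s + PROTOSPACER_LEN])
                pam = reverse_complement(seq[s - PAM_LEN : s])
                window = [s + PROTOSPACER_LEN - 1 - i for i in range(3, 8)]
            if pam[1:] != "GG":
                continue
            edited = {
                p
                for p in window
                if (seq[p] if strand == "+" else reverse_complement(seq[p]))
                == source_base
            }
            if not edited & codon_positions:
                continue
            mut = list(seq)
            for p in edited:
                mut[p] = (
                    product_base
                    if strand == "+"
                    else reverse_complement(product_base)
                )
            mut_genome = dict(genome)
            mut_genome[transcript.chrom] = type(genome[transcript.chrom])(
                transcript.chrom, "".join(mut)
            )
            alt_cds = transcript.extract_cds(mut_genome)
            aa_changes = []
            for i in range(len(ref_cds) // 3):
                rc_, ac_ = ref_cds[3 * i : 3 * i + 3], alt_cds[3 * i : 3 * i + 3]
                if rc_ != ac_:
                    aa_changes.append((i + 1, translate(rc_), translate(ac_)))
            noncoding = sorted(p for p in edited if p not in set(cds_positions))
            at_site = [c for c in aa_changes if c[0] == protein_pos]
            bystanders = [c for c in aa_changes if c[0] != protein_pos]
            if not at_site:
                site_class = "site_unchanged"
            elif any(r != a for _, r, a in at_site):
                site_class = "missense_at_site"
            else:
                site_class = "silent_at_site"
            results.append(
                {
                    "protospacer": proto,
                    "pam": pam,
                    "chrom": transcript.chrom,
                    "strand": strand,
                    "start": s,
                    "site_class": site_class,
                    "aa_changes": ";".join(f"{r}{p}{a}" for p, r, a in aa_changes),
                    "bystanders": ";".join(f"{r}{p}{a}" for p, r, a in bystanders),
                    "noncoding_edits": len(noncoding),
                    "splice_disrupted": bool(edited & splice),
                    "filter_flags": ",".join(
                        _oracle_flags(
                            proto, genome, site_class, len(bystanders), len(noncoding)
                        )
                    ),
                }
            )
    results.sort(key=lambda r: (r["start"], r["strand"]))
    return results


_PLANTED_EXPECTATIONS = [
    # (site label, predicate description, predicate)
    ("GENE_A:Y5", "retained Y5C missense",
     lambda g: g["aa_changes"] == "Y5C" and g["filter_flags"] == ""),
    ("GENE_A:T13", "retained T13A missense",
     lambda g: g["aa_changes"] == "T13A" and g["filter_flags"] == ""),
    ("GENE_A:Y22", "retained clean silent edit",
     lambda g: g["site_class"] == "silent_at_site" and g["filter_flags"] == ""),
    ("GENE_A:S25", "silent_with_bystander exclusion",
     lambda g: "silent_with_bystander" in g["filter_flags"]),
    ("GENE_A:Y33", "polyT exclusion",
     lambda g: "polyT" in g["filter_flags"]),
    ("GENE_A:T42", "cloning_site exclusion",
     lambda g: "cloning_site" in g["filter_flags"]),
    ("GENE_A:Y49", "multimatch exclusion",
     lambda g: "multimatch" in g["filter_flags"]),
    ("GENE_B:S10", "retained S10P via antisense guide",
     lambda g: g["aa_changes"] == "S10P" and g["filter_flags"] == ""),
    ("GENE_C:Y7", "retained Y7C across the exon junction",
     lambda g: g["aa_changes"] == "Y7C" and g["filter_flags"] == ""),
    ("GENE_D:Y7", "retained Y7 missense on the minus-strand gene",
     lambda g: g["site_class"] == "missense_at_site" and g["filter_flags"] == ""),
]


def _write_answer_key(paths: FixturePaths, min_conf: float) -> None:
    genome = load_genome(paths.genome_fasta)
    transcripts = load_annotation(paths.annotation_gtf, genome)
    sites_df = pd.read_csv(paths.phosphosites_tsv, sep="\t")

    key: dict = {"editor": "ABE8e", "min_conf": min_conf, "sites": {}}
    for row in sites_df.itertuples(index=False):
        if row.localization_conf < min_conf:
            continue
        tx = transcripts[row.transcript_id]
        if not 1 <= row.position <= tx.protein_length:
            continue
        protein = tx.protein_sequence(genome)
        if protein[row.position - 1] != row.residue:
            continue
        label = f"{row.protein_id}:{row.residue}{row.position}"
        key["sites"][label] = scan_guides_exhaustive(genome, tx, int(row.position))

    for label, desc, pred in _PLANTED_EXPECTATIONS:
        guides = key["sites"].get(label, [])
        if not any(pred(g) for g in guides):
            raise FixtureError(f"planted case missing: {label} ({desc})")
    if key["sites"].get("GENE_C:T21"):
        # planted as a PAM-less codon: any guide here means broken geometry
        raise FixtureError("GENE_C:T21 unexpectedly gained guides")

    with open(paths.answer_key_json, "w") as fh:
        json.dump(key, fh, indent=1, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# pooled-screen count simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSimSpec:
    """Conditions of the simulated pooled screen.

    Baseline guide abundances are log-normal; counts per guide x sample are
    negative binomial with dispersion ``dispersion`` (var = m + phi * m^2).
    ``planted_log2fc`` is applied to the essential-splice class and to
    ``n_planted_sites`` phosphosites in the post-editing sample; sorting
    bins receive +/- ``bin_log2fc`` for ``n_bin_sites`` sites.
    """

    seed: int = 0
    n_phospho_sites: int = 60
    guides_per_site: int = 3
    n_planted_sites: int = 8
    planted_log2fc: float = -2.0
    n_bin_sites: int = 6
    bin_log2fc: float = 1.5
    n_non_targeting: int = 250
    n_intergenic: int = 250
    n_essential_splice: int = 120
    dispersion: float = 0.1
    reads_per_sample: int = 1_000_000
    baseline_sigma: float = 1.0
    samples: tuple[str, ...] = ("pre", "post", "bin_high", "bin_low")


def make_screen_library(spec: ScreenSimSpec) -> pd.DataFrame:
    """Label-only guide library for count simulation.

    Columns: guide_id, class, site (phosphosite id or 'none'), planted
    (true log2FC in the post sample), bin_effect (log2FC in bin_low).
    """
    rows = []
    for s in range(spec.n_phospho_sites):
        site = f"SITE_{s + 1:03d}"
        effect = spec.planted_log2fc if s < spec.n_planted_sites else 0.0
        bin_eff = (
            spec.bin_log2fc
            if spec.n_planted_sites <= s < spec.n_planted_sites + spec.n_bin_sites
            else 0.0
        )
        for g in range(spec.guides_per_site):
            rows.append((f"PH_{s + 1:03d}_{g + 1}", "phosphosite", site, effect, bin_eff))
    for cls, n, prefix in (
        ("non_targeting", spec.n_non_targeting, "NT"),
        ("intergenic", spec.n_intergenic, "IG"),
    ):
        for i in range(n):
            rows.append((f"{prefix}_{i + 1:04d}", cls, "none", 0.0, 0.0))
    for i in range(spec.n_essential_splice):
        rows.append(
            (f"ES_{i + 1:04d}", "essential_splice", "none", spec.planted_log2fc, 0.0)
        )
    return pd.DataFrame(
        rows, columns=["guide_id", "class", "site", "planted", "bin_effect"]
    )


def simulate_counts(spec: ScreenSimSpec, library: pd.DataFrame) -> pd.DataFrame:
    """Negative-binomial count matrix (guides x samples) with planted effects.

    ``library`` needs columns guide_id, planted and bin_effect (as produced
    by :func:`make_screen_library`).  Baseline abundances are drawn once;
    the ``post`` sample applies ``planted``, the sorting bins apply
    ``bin_effect`` with opposite signs.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(library)
    base = rng.lognormal(mean=0.0, sigma=spec.baseline_sigma, size=n)
    effects = {
        "pre": np.zeros(n),
        "post": library["planted"].to_numpy(float),
        "bin_high": -0.5 * library["bin_effect"].to_numpy(float),
        "bin_low": 0.5 * library["bin_effect"].to_numpy(float),
    }
    counts = {}
    nb_n = 1.0 / spec.dispersion
    for sample in spec.samples:
        w = base * np.power(2.0, effects[sample])
        mean = spec.reads_per_sample * w / w.sum()
        p = nb_n / (nb_n + mean)
        counts[sample] = rng.negative_binomial(nb_n, p)
    return pd.DataFrame(counts, index=pd.Index(library["guide_id"], name="guide_id"))
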