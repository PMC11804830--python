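"""Protospacer enumeration, exact-match counting and exclusion filters."""

import pandas as pd
import pytest
from Bio.Seq import reverse_complement

from phosbase.editing_engine import pam_matches
from phosbase.guide_design import (
    FilterConfig,
    GuideCandidate,
    Phosphosite,
    apply_filters,
    count_perfect_matches,
    design_for_sites,
    find_pam_placements,
    oligo_pair,
)
from phosbase.reference_model import (
    CdsSegment,
    GenomeSequence,
    TranscriptModel,
    protein_to_codon,
)

from conftest import FIXTURE_SEED
from phosbase.screen_sim import FixtureSpec, make_fixture


def _mini_genome(seq: str):
    return {"chr1": GenomeSequence("chr1", seq)}


def _bare_candidate(protospacer: str) -> GuideCandidate:
    return GuideCandidate(
        protospacer=protospacer,
        pam="AGG",
        chrom="chr1",
        strand="+",
        start=0,
        end=20,
        window_genomic_positions=list(range(3, 8)),
    )


class TestPhosphosite:
    def test_residue_validated(self):
        with pytest.raises(ValueError):
            Phosphosite("P1", "A", 10, 0.95)

    def test_confidence_range(self):
        with pytest.raises(ValueError):
            Phosphosite("P1", "S", 10, 1.5)


class TestFindPamPlacements:
    def test_all_pams_match_ngg(self, genome, transcripts, abe8e):
        tx = transcripts["TX_A"]
        codon = protein_to_codon(tx, 5, genome)
        cands = find_pam_placements(genome, codon, abe8e, tx)
        assert cands
        for c in cands:
            assert pam_matches(c.pam, "NGG")

    def test_no_pam_compatible_placement_gives_empty(
        self, genome, transcripts, abe8e
    ):
        # GENE_C T21 (ACC) has no NGG-compatible placement in the fixture
        tx = transcripts["TX_C"]
        codon = protein_to_codon(tx, 21, genome)
        assert find_pam_placements(genome, codon, abe8e, tx) == []

    def test_codon_without_editable_base_gives_empty(self, tmp_path, abe8e):
        # CCC codon, no A on either strand within any window placement
        seq = "G" * 30 + "ATGCCCGGCTAA" + "G" * 30
        genome = _mini_genome(seq)
        tx = TranscriptModel("t", "g", "chr1", "+", [CdsSegment(30, 42, 0)])
        codon = protein_to_codon(tx, 2, genome)
        assert find_pam_placements(genome, codon, abe8e, tx) == []


class TestCountPerfectMatches:
    PROTO = "ACGTACGGATCCTAGCTAGC"

    def test_planted_copies_counted_both_strands(self):
        spacer = "C" * 30
        seq = spacer + self.PROTO + spacer + self.PROTO + spacer
        seq += reverse_complement(self.PROTO) + spacer
        assert count_perfect_matches(self.PROTO, _mini_genome(seq)) == 3

    def test_absent_protospacer(self):
        assert count_perfect_matches(self.PROTO, _mini_genome("G" * 100)) == 0

    def test_overlapping_occurrences_counted(self):
        proto = "AT" * 10
        seq = "C" * 10 + "AT" * 12 + "C" * 10
        # forward overlaps: 3; reverse complement of (AT)n matches too
        n_naive = 0
        rc = reverse_complement(proto)
        for i in range(len(seq) - 19):
            n_naive += seq[i : i + 20] == proto
            n_naive += seq[i : i + 20] == rc
        assert count_perfect_matches(proto, _mini_genome(seq)) == n_naive

    def test_sliding_window_oracle_equivalence(self, genome, answer_key):
        from phosbase.screen_sim import _naive_match_count

        protos = {
            g["protospacer"]
            for guides in answer_key["sites"].values()
            for g in guides
        }
        for proto in sorted(protos)[:10]:
            assert count_perfect_matches(proto, genome) == _naive_match_count(
                proto, genome
            )


class TestApplyFilters:
    def test_polyt_rejected(self, genome):
        cand = _bare_candidate("ACGTTTTACGGATCCTAGCA")
        _, rejected = apply_filters([cand], genome)
        assert rejected and rejected[0].filter_flags == {"polyT"}

    def test_cloning_site_formed_at_adapter_junction(self, genome):
        # CACCG + TCTC... assembles the Esp3I site CGTCTC across the junction
        cand = _bare_candidate("TCTCAAGGATCCGGATCAGA")
        _, rejected = apply_filters([cand], genome)
        assert rejected and "cloning_site" in rejected[0].filter_flags

    def test_match_threshold_five_vs_six(self):
        proto = "ACGTACGGATCCTAGCTAGC"
        spacer = "G" * 25
        five = _mini_genome(spacer + (proto + spacer) * 5)
        six = _mini_genome(spacer + (proto + spacer) * 6)
        retained, _ = apply_filters([_bare_candidate(proto)], five)
        assert retained
        _, rejected = apply_filters([_bare_candidate(proto)], six)
        assert rejected and "multimatch" in rejected[0].filter_flags

    def test_silent_with_bystander_rejected(self, design_result):
        table = design_result.guides
        s25 = table[table["target"].str.contains("GENE_A:S25")]
        assert (s25["filter_flags"] == "silent_with_bystander").any()

    def test_clean_silent_retained(self, design_result):
        table = design_result.guides
        y22 = table[table["target"].str.contains("GENE_A:Y22")]
        silents = y22[y22["site_class"] == "silent_at_site"]
        assert (silents["filter_flags"] == "").any()

    def test_filter_monotonicity(self, phosphosites, genome, transcripts, abe8e):
        loose = design_for_sites(
            phosphosites, genome, transcripts, abe8e,
            config=FilterConfig(max_matches=5),
        )
        tight = design_for_sites(
            phosphosites, genome, transcripts, abe8e,
            config=FilterConfig(max_matches=1),
        )
        keep = lambda r: set(r.retained()["protospacer"])
        assert keep(tight) <= keep(loose)

    def test_retained_rejected_partition(self, genome, transcripts, abe8e):
        tx = transcripts["TX_A"]
        codon = protein_to_codon(tx, 49, genome)
        cands = find_pam_placements(genome, codon, abe8e, tx)
        retained, rejected = apply_filters(cands, genome)
        assert len(retained) + len(rejected) == len(cands)
        assert all(not c.filter_flags for c in retained)
        assert all(c.filter_flags for c in rejected)
        assert rejected, "fixture plants a multimatch rejection at Y49"


class TestDesignForSites:
    def test_confidence_cutoff_inclusive(self, design_result):
        # 0.89 excluded, boundary 0.90 included
        skipped = dict(design_result.skipped)
        assert skipped.get("GENE_B:S14") == "low_confidence"
        assert "GENE_C:Y7" in set(design_result.per_site["site"])

    def test_mismatched_residue_skipped(self, design_result):
        assert ("GENE_A:S3", "residue_mismatch") in design_result.skipped

    def test_unmappable_site_skipped_not_fatal(self, design_result):
        assert ("GENE_B:S99", "unmappable") in design_result.skipped

    def test_empty_site_list(self, genome, transcripts, abe8e):
        result = design_for_sites([], genome, transcripts, abe8e)
        assert result.guides.empty
        assert result.per_site.empty

    def test_reverse_complement_symmetry(self, tmp_path, abe8e):
        """The guide set is invariant under reverse-complementing the genome."""
        import json

        fwd = make_fixture(FixtureSpec(seed=FIXTURE_SEED), tmp_path / "fwd")
        from phosbase.guide_design import read_phosphosite_table
        from phosbase.reference_model import load_annotation, load_genome

        genome = load_genome(fwd.genome_fasta)
        transcripts = load_annotation(fwd.annotation_gtf, genome)
        sites = read_phosphosite_table(fwd.phosphosites_tsv)

        mirror_genome = {
            c: GenomeSequence(c, reverse_complement(rec.seq))
            for c, rec in genome.items()
        }
        mirror_tx = {}
        for tid, tx in transcripts.items():
            length = len(genome[tx.chrom])
            segs = [
                CdsSegment(length - s.end, length - s.start, s.frame)
                for s in tx.cds_segments
            ]
            mirror_tx[tid] = TranscriptModel(
                tid, tx.gene_id, tx.chrom,
                "-" if tx.strand == "+" else "+", segs,
            )
        res_f = design_for_sites(sites, genome, transcripts, abe8e)
        res_m = design_for_sites(sites, mirror_genome, mirror_tx, abe8e)

        def keyset(res):
            return {
                (r.protospacer, r.pam, r.target, r.site_class, r.aa_changes,
                 r.filter_flags)
                for r in res.guides.itertuples(index=False)
            }

        assert keyset(res_f) == keyset(res_m)


def test_oligo_pair_equations():
    fwd, rev = oligo_pair("ACGTACGGATCCTAGCTAGC")
    assert fwd == "CACCGACGTACGGATCCTAGCTAGC"
    assert rev == "AAAC" + reverse_complement("ACGTACGGATCCTAGCTAGC") + "C"
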