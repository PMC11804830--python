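"""Shared fixtures: the synthetic mini-genome is built once per session."""

from __future__ import annotations

import json

import pytest

from phosbase.editing_engine import get_editor
from phosbase.guide_design import design_for_sites, read_phosphosite_table
from phosbase.reference_model import load_annotation, load_genome
from phosbase.screen_sim import FixtureSpec, make_fixture

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return make_fixture(FixtureSpec(seed=FIXTURE_SEED), out)


@pytest.fixture(scope="session")
def genome(fixture_paths):
    return load_genome(fixture_paths.genome_fasta)


@pytest.fixture(scope="session")
def transcripts(fixture_paths, genome):
    return load_annotation(fixture_paths.annotation_gtf, genome)


@pytest.fixture(scope="session")
def phosphosites(fixture_paths):
    return read_phosphosite_table(fixture_paths.phosphosites_tsv)


@pytest.fixture(scope="session")
def answer_key(fixture_paths):
    with open(fixture_paths.answer_key_json) as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def abe8e():
    return get_editor("ABE8e")


@pytest.fixture(scope="session")
def design_result(phosphosites, genome, transcripts, abe8e):
    return design_for_sites(phosphosites, genome, transcripts, abe8e)


def write_fasta(path, records: dict[str, str]) -> str:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)


def write_gtf(path, rows) -> str:
    """rows: (chrom, start1, end1, strand, frame, gene_id, transcript_id)."""
    with open(path, "w") as fh:
        for chrom, start, end, strand, frame, gene, tid in rows:
            fh.write(
                f"{chrom}\ttest\tCDS\t{start}\t{end}\t.\t{strand}\t{frame}\t"
                f'gene_id "{gene}"; transcript_id "{tid}";\n'
            )
    return str(path)
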