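"""FASTA parsing, normalization, reverse complement and site serialization."""

from __future__ import annotations

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtarp.errors import FastaFormatError
from mirtarp.pipeline import TargetSite
from mirtarp.sequence_io import (
    MiRNARecord, NucSequence, normalize_residues, read_fasta, read_sites_tsv,
    reverse_complement, write_fasta, write_gff3, write_sites_tsv,
)

rna = st.text(alphabet="ACGUN", min_size=1, max_size=60)


def test_read_fasta_normalizes_dna_to_rna(tmp_path):
    p = tmp_path / "in.fa"
    p.write_text(">m1\nacgt\n")
    (rec,) = read_fasta(p)
    assert rec.id == "m1"
    assert rec.residues == "ACGU"


def test_duplicate_ids_get_numeric_suffix(tmp_path, caplog):
    p = tmp_path / "in.fa"
    p.write_text(">x\nACGU\n>x\nGGCC\n")
    with caplog.at_level(logging.WARNING):
        recs = read_fasta(p)
    assert [r.id for r in recs] == ["x", "x_2"]
    assert any("duplicate id" in m for m in caplog.messages)


def test_invalid_record_dropped_with_warning(tmp_path, caplog):
    p = tmp_path / "in.fa"
    p.write_text(">bad\nACGX\n>good\nACGU\n")
    with caplog.at_level(logging.WARNING):
        recs = read_fasta(p)
    assert [r.id for r in recs] == ["good"]
    assert sum("dropping record" in m for m in caplog.messages) == 1


def test_missing_and_unparseable_files_raise(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_fasta(tmp_path / "absent.fa")
    p = tmp_path / "junk.fa"
    p.write_text(">only_bad\nZZZZ\n")
    with pytest.raises(FastaFormatError):
        read_fasta(p)


def test_fasta_round_trip(tmp_path):
    recs = [
        NucSequence("a", "ACGU" * 30, "first record"),
        NucSequence("b", "GGNCCUA"),
    ]
    p = tmp_path / "out.fa"
    write_fasta(recs, p)
    assert read_fasta(p) == recs


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGU", "ACGU"), ("AAGG", "CCUU"), ("NAU", "AUN")],
)
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


@settings(max_examples=200, deadline=None)
@given(rna)
def test_reverse_complement_involution_and_length(s):
    rc = reverse_complement(s)
    assert len(rc) == len(s)
    assert reverse_complement(rc) == s


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="acgtuACGTUN", min_size=1, max_size=60))
def test_normalization_is_idempotent(s):
    once = normalize_residues(s)
    assert normalize_residues(once) == once
    assert "T" not in once and once == once.upper()


def test_mirna_record_length_policy(caplog):
    with pytest.raises(ValueError):
        MiRNARecord("tiny", "host", NucSequence("tiny", "ACGUACGU"))
    with caplog.at_level(logging.WARNING):
        MiRNARecord("short", "host", NucSequence("short", "ACGUACGUACGU"))
    assert any("unusual" in m for m in caplog.messages)
    with pytest.raises(ValueError):
        MiRNARecord("m", "plant", NucSequence("m", "ACGUACGUACGUACGUACGUA"))


def _site(**kw) -> TargetSite:
    base = dict(
        mirna_id="mir-1", mirna_origin="host", target_id="t1", strand="+",
        site_start=5, site_end=27, seed_length=8, duplex_mfe=-27.5,
        local_fold_mfe=-3.25, mirna_aln="ACGU", pair_aln="||||", target_aln="UGCA",
    )
    base.update(kw)
    return TargetSite(**base)


def test_sites_tsv_empty_is_header_only(tmp_path):
    p = tmp_path / "sites.tsv"
    write_sites_tsv([], p)
    lines = p.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("mirna_id\t")


def test_sites_tsv_round_trip_and_sorting(tmp_path):
    sites = [
        _site(target_id="t2", site_start=50, site_end=72),
        _site(site_start=5, site_end=27),
        _site(mirna_id="mir-0", site_start=5, site_end=27, local_fold_mfe=None),
    ]
    p = tmp_path / "sites.tsv"
    write_sites_tsv(sites, p)
    rows = read_sites_tsv(p)
    assert [r["mirna_id"] for r in rows] == ["mir-0", "mir-1", "mir-1"]
    assert rows[1]["site_start"] == 5 and rows[1]["site_end"] == 27
    assert rows[1]["duplex_mfe_kcal_mol"] == -27.5
    assert rows[0]["local_fold_mfe_kcal_mol"] is None
    assert p.read_text().splitlines()[1].split("\t")[4:6] == ["5", "27"]


def test_gff3_uses_one_based_inclusive_coordinates(tmp_path):
    p = tmp_path / "sites.gff3"
    write_gff3([_site(site_start=5, site_end=27)], p)
    lines = p.read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    cols = lines[1].split("\t")
    assert cols[2] == "miRNA_target_site"
    assert (cols[3], cols[4]) == ("6", "27")
    assert cols[5] == "-27.50"
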