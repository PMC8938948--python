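"""Directory scanning, format routing, record IO and output-bundle layout."""

import gzip
import zipfile

import pandas as pd
import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioRecord

from seqstab.fixtures import hotspot_free_sequence
from seqstab.hotspot_detection import find_ssr_sites
from seqstab.sequence_io import (
    FASTA,
    GENBANK,
    OutputBundle,
    SequenceRecord,
    read_records,
    scan_input_directory,
    sequence_identicon,
    sites_to_table,
    write_output_bundle,
)


def _write_fasta(path, entries):
    with open(path, "w") as handle:
        for name, seq in entries:
            handle.write(f">{name}\n{seq}\n")


class TestScanDirectory:
    def test_routes_by_extension_and_skips_rest(self, tmp_path):
        _write_fasta(tmp_path / "a.fasta", [("x", "ACGT")])
        with gzip.open(tmp_path / "b.gb.gz", "wt") as handle:
            handle.write("LOCUS placeholder\n")
        (tmp_path / "notes.txt").write_text("not dna")
        found = dict(scan_input_directory(tmp_path))
        assert found[str(tmp_path / "a.fasta")] == FASTA
        assert found[str(tmp_path / "b.gb.gz")] == GENBANK
        assert len(found) == 2

    def test_empty_directory_is_an_error(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="no input sequences"):
            scan_input_directory(tmp_path)

    def test_nested_files_found_with_relative_paths(self, tmp_path):
        (tmp_path / "sub").mkdir()
        _write_fasta(tmp_path / "sub" / "c.fa", [("y", "ACGTACGT")])
        found = scan_input_directory(tmp_path)
        assert [f for f, _ in found] == [str(tmp_path / "sub" / "c.fa")]

    def test_zip_members_expanded(self, tmp_path):
        with zipfile.ZipFile(tmp_path / "arch.zip", "w") as archive:
            archive.writestr("inner.fasta", ">z\nACGTAC\n")
            archive.writestr("readme.md", "skip me")
        found = scan_input_directory(tmp_path)
        assert found == [(f"{tmp_path / 'arch.zip'}!inner.fasta", FASTA)]
        records = read_records(found[0][0], FASTA)
        assert records[0].sequence == "ACGTAC"

    def test_extensionless_file_sniffed_by_content(self, tmp_path):
        (tmp_path / "mystery").write_text(">m\nACGT\n")
        assert scan_input_directory(tmp_path) == [(str(tmp_path / "mystery"), FASTA)]


class TestReadRecords:
    def test_multi_record_fasta_numbered_in_order(self, tmp_path):
        path = tmp_path / "two.fasta"
        _write_fasta(path, [("first", "acgt"), ("second", "GGCC")])
        records = read_records(str(path), FASTA)
        assert [(r.id, r.seq_num, r.sequence) for r in records] == [
            ("first", 1, "ACGT"),
            ("second", 2, "GGCC"),
        ]

    def test_rna_u_converted_to_t(self, tmp_path):
        path = tmp_path / "rna.fasta"
        _write_fasta(path, [("r", "ACGU")])
        assert read_records(str(path), FASTA)[0].sequence == "ACGT"

    def test_ambiguity_codes_beyond_n_rejected(self, tmp_path):
        path = tmp_path / "amb.fasta"
        _write_fasta(path, [("r", "ACGRT")])
        with pytest.raises(ValueError, match="ambiguity"):
            read_records(str(path), FASTA)

    def test_genbank_features_carried_through(self, tmp_path):
        from Bio.SeqFeature import FeatureLocation, SeqFeature

        rec = BioRecord(Seq("ACGT" * 40), id="gb1", annotations={"molecule_type": "DNA"})
        rec.features.append(SeqFeature(FeatureLocation(9, 120), type="CDS"))
        path = tmp_path / "one.gb"
        SeqIO.write([rec], path, "genbank")
        records = read_records(str(path), GENBANK)
        assert ("CDS", 9, 120) in records[0].features

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "z.fasta.gz"
        with gzip.open(path, "wt") as handle:
            handle.write(">g\nACGTACGT\n")
        assert read_records(str(path), FASTA)[0].sequence == "ACGTACGT"


class TestIdenticon:
    def test_equal_sequences_equal_tokens(self):
        assert sequence_identicon("ACGT") == sequence_identicon("acgt")

    def test_single_base_change_flips_token(self):
        assert sequence_identicon("ACGT") != sequence_identicon("ACGA")

    def test_token_is_stable_across_runs(self):
        # frozen regression vector; guards hash choice and formatting
        assert sequence_identicon("ACGT") == "1dff-3e84-fe78"


def _bundle(tmp_path, sequence, site_tables=None):
    record = SequenceRecord(id="s1", sequence=sequence, source_path="in/a.fasta", seq_num=1)
    return OutputBundle(
        input_path="a.fasta",
        records=[record],
        optimized_records=[record],
        site_tables=site_tables or {},
        change_summary=[(1, 5, "A", "G", "gc_content")],
        identicon_before={1: sequence_identicon(sequence)},
        identicon_after={1: sequence_identicon(sequence)},
    )


class TestWriteBundle:
    def test_folder_layout_and_roundtrip(self, tmp_path):
        seq = hotspot_free_sequence(300, seed=31)
        record = SequenceRecord(id="s1", sequence=seq, source_path="x", seq_num=1)
        tables = {"ssr": sites_to_table(record, "ssr", find_ssr_sites(seq))}
        written = write_output_bundle(_bundle(tmp_path, seq, tables), tmp_path, {FASTA, GENBANK})
        folder = tmp_path / "a"
        for name in ("sites_ssr.csv", "sites_rmd.csv", "sites_motif.csv", "optimized.fasta", "optimized.gb", "summary.txt"):
            assert (folder / name).exists()
        assert (tmp_path / "a_optimized.fasta").exists()
        # round-trip both formats byte-for-byte on the sequence
        for path, fmt in [(folder / "optimized.fasta", FASTA), (folder / "optimized.gb", GENBANK)]:
            back = read_records(str(path), fmt)
            assert back[0].id == "s1" and back[0].sequence == seq

    def test_empty_site_lists_write_header_only(self, tmp_path):
        write_output_bundle(_bundle(tmp_path, "ACGTACGTAA"), tmp_path, {FASTA})
        table = pd.read_csv(tmp_path / "a" / "sites_rmd.csv", comment="#")
        assert list(table.columns)[:3] == ["seq_id", "seq_num", "type"]
        assert table.empty

    def test_collision_gets_versioned_suffix(self, tmp_path):
        bundle = _bundle(tmp_path, "ACGTACGTAA")
        write_output_bundle(bundle, tmp_path, {FASTA})
        write_output_bundle(bundle, tmp_path, {FASTA})
        assert (tmp_path / "a").exists() and (tmp_path / "a.v1").exists()

    def test_site_table_coordinates_are_one_based_inclusive(self):
        seq = "CC" + "AT" * 4 + "GG"
        record = SequenceRecord(id="s", sequence=seq, source_path="x", seq_num=1)
        table = sites_to_table(record, "ssr", find_ssr_sites(seq))
        row = table.iloc[0]
        assert (row.start_1based, row.end_1based_inclusive, row.length) == (3, 10, 8)
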