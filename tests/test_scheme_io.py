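import pytest
import yaml

from mlstkit import (AlleleDatabase, AllelicProfile, ProfileTable,
                     read_locus_fasta, read_profiles_tsv, read_scheme,
                     write_profiles_tsv)
from mlstkit.errors import FormatError
from mlstkit.io import (read_allele_fasta, read_st_definitions_tsv,
                        write_allele_fasta, write_locus_fasta, write_scheme,
                        write_st_definitions_tsv)


class TestBundledScheme:
    def test_locus_order_is_alphabetical(self, default_scheme):
        assert default_scheme.locus_names == (
            "carB", "groEL", "murC", "pheS", "pyrG", "recA", "rpoB", "uvrC")

    def test_amplicon_sizes(self, default_scheme):
        assert default_scheme.locus("pyrG").amplicon_length == 598
        assert default_scheme.locus("groEL").amplicon_length == 892
        assert default_scheme.locus("recA").amplicon_length == 550

    def test_amplicon_lengths_sum(self, default_scheme):
        assert sum(l.amplicon_length for l in default_scheme.loci) == 5325

    def test_primers_uppercase_iupac(self, default_scheme):
        for locus in default_scheme.loci:
            for primer in (locus.forward_primer, locus.reverse_primer):
                assert primer == primer.upper()
                assert set(primer) <= set("ACGT")


class TestSchemeConfig:
    def _write(self, tmp_path, doc):
        path = tmp_path / "scheme.yaml"
        path.write_text(yaml.safe_dump(doc))
        return path

    def test_round_trip(self, tmp_path, default_scheme):
        path = tmp_path / "out.yaml"
        write_scheme(default_scheme, path)
        assert read_scheme(path) == default_scheme

    def test_single_locus_rejected(self, tmp_path):
        doc = {"name": "x", "loci": [
            {"name": "a", "forward_primer": "ACGT",
             "reverse_primer": "ACGT", "amplicon_length": 100}]}
        with pytest.raises(FormatError, match="at least 2"):
            read_scheme(self._write(tmp_path, doc))

    def test_duplicate_locus_name_rejected(self, tmp_path):
        block = {"name": "recA", "forward_primer": "ACGT",
                 "reverse_primer": "ACGT", "amplicon_length": 100}
        doc = {"name": "x", "loci": [block, dict(block)]}
        with pytest.raises(FormatError, match="recA"):
            read_scheme(self._write(tmp_path, doc))

    @pytest.mark.parametrize("field", ["forward_primer", "reverse_primer",
                                       "amplicon_length"])
    def test_missing_field_names_locus(self, tmp_path, field):
        block = {"name": "locA", "forward_primer": "ACGT",
                 "reverse_primer": "ACGT", "amplicon_length": 100}
        del block[field]
        doc = {"name": "x", "loci": [block, {
            "name": "locB", "forward_primer": "ACGT",
            "reverse_primer": "ACGT", "amplicon_length": 100}]}
        with pytest.raises(FormatError, match="locA"):
            read_scheme(self._write(tmp_path, doc))

    def test_non_iupac_primer_rejected(self, tmp_path):
        doc = {"name": "x", "loci": [
            {"name": "locA", "forward_primer": "ACXT",
             "reverse_primer": "ACGT", "amplicon_length": 100},
            {"name": "locB", "forward_primer": "ACGT",
             "reverse_primer": "ACGT", "amplicon_length": 100}]}
        with pytest.raises(FormatError, match="locA"):
            read_scheme(self._write(tmp_path, doc))


class TestLocusFasta:
    def test_read_normalizes_and_preserves_order(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">iso2 extra tokens\nacgu\n>iso1\nACGT\n")
        records = read_locus_fasta(path)
        assert records == [("iso2", "ACGT"), ("iso1", "ACGT")]

    def test_many_records(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text("".join(f">iso{i}\nACGT\n" for i in range(50)))
        assert len(read_locus_fasta(path)) == 50

    def test_invalid_character_names_record(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">good\nACGT\n>bad\nACXT\n")
        with pytest.raises(FormatError, match="bad"):
            read_locus_fasta(path)

    def test_ambiguity_codes_warn(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">iso1\nACNT\n")
        with pytest.warns(UserWarning, match="ambiguity"):
            read_locus_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text("")
        with pytest.raises(FormatError, match="empty"):
            read_locus_fasta(path)


def _example_table():
    return ProfileTable(
        locus_names=("a", "b", "c"),
        profiles=[
            AllelicProfile("iso1", (1, 2, 1), st=1, region="north",
                           source="yogurt"),
            AllelicProfile("iso2", (1, 2, 1), st=1, region="south",
                           source="kurut"),
            AllelicProfile("iso3", (2, 2, 2), st=2),
        ],
        st_definitions={(1, 2, 1): 1, (2, 2, 2): 2})


class TestProfilesTsv:
    def test_round_trip_identity(self, tmp_path):
        table = _example_table()
        path = tmp_path / "profiles.tsv"
        write_profiles_tsv(table, path)
        again = read_profiles_tsv(path)
        assert again.locus_names == table.locus_names
        assert again.st_definitions == table.st_definitions
        assert [(p.isolate_id, p.alleles, p.st, p.region, p.source)
                for p in again.profiles] == \
               [(p.isolate_id, p.alleles, p.st, p.region, p.source)
                for p in table.profiles]
        # byte-identical on a second write
        path2 = tmp_path / "profiles2.tsv"
        write_profiles_tsv(again, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_wrong_locus_order_vs_scheme(self, tmp_path, default_scheme):
        names = list(default_scheme.locus_names)
        names[0], names[1] = names[1], names[0]
        path = tmp_path / "profiles.tsv"
        path.write_text("isolate\t" + "\t".join(names) + "\tST\n"
                        "iso1\t1\t1\t1\t1\t1\t1\t1\t1\t1\n")
        with pytest.raises(FormatError, match="order"):
            read_profiles_tsv(path, scheme=default_scheme)

    def test_non_integer_allele_reports_line(self, tmp_path):
        path = tmp_path / "profiles.tsv"
        path.write_text("isolate\ta\tb\tST\niso1\t1\tx\t1\n")
        with pytest.raises(FormatError, match=":2"):
            read_profiles_tsv(path)

    def test_conflicting_st_definition_rejected(self, tmp_path):
        path = tmp_path / "profiles.tsv"
        path.write_text("isolate\ta\tb\tST\n"
                        "iso1\t1\t1\t1\niso2\t1\t1\t2\n")
        with pytest.raises(FormatError, match="ST 1"):
            read_profiles_tsv(path)

    def test_st_definitions_round_trip(self, tmp_path):
        table = _example_table()
        path = tmp_path / "defs.tsv"
        write_st_definitions_tsv(table.locus_names, table.st_definitions,
                                 path)
        names, defs = read_st_definitions_tsv(path)
        assert names == table.locus_names
        assert defs == table.st_definitions


class TestAlleleDatabase:
    def test_fasta_round_trip_preserves_numbers(self, tmp_path):
        db = AlleleDatabase(("recA",))
        db.add("recA", "ACGTAA")
        db.add("recA", "ACGTAT")
        path = tmp_path / "recA.fasta"
        write_allele_fasta(db, "recA", path)
        db2 = read_allele_fasta(path, "recA", AlleleDatabase(("recA",)))
        assert db2.alleles("recA") == db.alleles("recA")

    def test_numbers_from_file_are_authoritative(self, tmp_path):
        path = tmp_path / "recA.fasta"
        write_locus_fasta([("recA_2", "ACGTAT"), ("recA_1", "ACGTAA")], path)
        db = read_allele_fasta(path, "recA", AlleleDatabase(("recA",)))
        assert db.sequence("recA", 1) == "ACGTAA"
        assert db.sequence("recA", 2) == "ACGTAT"

    def test_gap_in_numbering_rejected(self, tmp_path):
        path = tmp_path / "recA.fasta"
        write_locus_fasta([("recA_1", "ACGTAA"), ("recA_3", "ACGTAT")], path)
        with pytest.raises(FormatError, match="1..2"):
            read_allele_fasta(path, "recA", AlleleDatabase(("recA",)))

    def test_duplicate_sequence_rejected(self):
        db = AlleleDatabase(("recA",))
        db.add("recA", "ACGTAA")
        with pytest.raises(FormatError, match="duplicate"):
            db.add("recA", "ACGTAA")

    def test_length_conflict_rejected(self):
        db = AlleleDatabase(("recA",))
        db.add("recA", "ACGTAA")
        with pytest.raises(FormatError, match="length"):
            db.add("recA", "ACGTAAA")
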