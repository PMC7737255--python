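import json

import pytest

from fireladder.ladder_detect import FireLadderPattern
from fireladder.rrf_io import (
    AtomRecord,
    RelRecord,
    RRFParseError,
    SourceConfig,
    build_name_index,
    format_mrconso_row,
    format_mrrel_row,
    read_mrconso,
    read_mrrel,
    write_patterns,
)

CFG = SourceConfig(included_sabs=["HPO", "NCI"], excluded_sabs=["LNC"])


def conso_line(cui, lat, sab, code, name, suppress="N", tty="PT"):
    return format_mrconso_row(AtomRecord(
        cui=cui, lat=lat, sab=sab, tty=tty, code=code,
        str_name=name, suppress=suppress,
    ))


def rel_line(cui1, cui2, sab, rel="PAR", rela="inverse_isa", suppress="N"):
    return format_mrrel_row(RelRecord(
        cui1=cui1, cui2=cui2, sab=sab, rel=rel, rela=rela, suppress=suppress,
    ))


class TestReadMrconso:
    def test_language_and_sab_filters(self, tmp_path):
        p = tmp_path / "MRCONSO.RRF"
        p.write_text("\n".join([
            conso_line("C0000001", "ENG", "HPO", "HP:1", "kept"),
            conso_line("C0000002", "FRE", "HPO", "HP:2", "french"),
            conso_line("C0000003", "ENG", "LNC", "L1", "excluded sab"),
        ]) + "\n")
        atoms = read_mrconso(p, CFG)
        assert [a.cui for a in atoms] == ["C0000001"]
        assert atoms[0].str_name == "kept"

    def test_fig3_row(self, tmp_path):
        p = tmp_path / "MRCONSO.RRF"
        p.write_text(conso_line(
            "C9900001", "ENG", "HPO", "HP:0011100", "Intestinal atresia",
        ) + "\n")
        (atom,) = read_mrconso(p, CFG)
        assert atom.sab == "HPO"
        assert atom.code == "HP:0011100"
        assert atom.str_name == "Intestinal atresia"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "MRCONSO.RRF"
        p.write_text("")
        assert read_mrconso(p, CFG) == []

    def test_suppressed_dropped_by_default(self, tmp_path):
        p = tmp_path / "MRCONSO.RRF"
        p.write_text("\n".join([
            conso_line("C0000001", "ENG", "HPO", "HP:1", "kept"),
            conso_line("C0000001", "ENG", "HPO", "HP:1x", "hidden", suppress="O"),
        ]) + "\n")
        assert len(read_mrconso(p, CFG)) == 1
        keep = SourceConfig(included_sabs=["HPO"], drop_suppressed=False)
        assert len(read_mrconso(p, keep)) == 2

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "MRCONSO.RRF"
        p.write_text(
            conso_line("C0000001", "ENG", "HPO", "HP:1", "ok") + "\n"
            + "C0000002|ENG|HPO|\n"
        )
        with pytest.raises(RRFParseError, match=":2:"):
            read_mrconso(p, CFG)

    def test_canonical_order(self, tmp_path):
        p = tmp_path / "MRCONSO.RRF"
        p.write_text("\n".join([
            conso_line("C0000009", "ENG", "HPO", "HP:9", "z"),
            conso_line("C0000001", "ENG", "NCI", "N1", "b"),
            conso_line("C0000001", "ENG", "HPO", "HP:1", "a"),
        ]) + "\n")
        atoms = read_mrconso(p, CFG)
        assert [(a.cui, a.sab) for a in atoms] == [
            ("C0000001", "HPO"), ("C0000001", "NCI"), ("C0000009", "HPO"),
        ]


class TestReadMrrel:
    def test_rel_rela_filter(self, tmp_path):
        p = tmp_path / "MRREL.RRF"
        p.write_text("\n".join([
            rel_line("C0000001", "C0000002", "HPO"),
            rel_line("C0000001", "C0000002", "HPO", rel="PAR", rela=""),
            rel_line("C0000001", "C0000002", "HPO", rel="RB", rela=""),
        ]) + "\n")
        rels = read_mrrel(p, CFG)
        assert len(rels) == 1
        assert (rels[0].rel, rels[0].rela) == ("PAR", "inverse_isa")

    def test_sab_filter(self, tmp_path):
        p = tmp_path / "MRREL.RRF"
        p.write_text(rel_line("C0000001", "C0000002", "MSH") + "\n")
        assert read_mrrel(p, CFG) == []

    def test_empty_file(self, tmp_path):
        p = tmp_path / "MRREL.RRF"
        p.write_text("")
        assert read_mrrel(p, CFG) == []

    def test_malformed_row(self, tmp_path):
        p = tmp_path / "MRREL.RRF"
        p.write_text("C0000001|PAR|\n")
        with pytest.raises(RRFParseError, match=":1:"):
            read_mrrel(p, CFG)


class TestRoundTrip:
    def test_records_survive_write_read(self, tmp_path):
        atoms = [
            AtomRecord(cui="C0000001", sab="HPO", code="HP:1",
                       str_name="alpha"),
            AtomRecord(cui="C0000002", sab="NCI", code="N2",
                       str_name="beta"),
        ]
        rels = [RelRecord(cui1="C0000002", cui2="C0000001", sab="NCI")]
        (tmp_path / "MRCONSO.RRF").write_text(
            "\n".join(format_mrconso_row(a) for a in atoms) + "\n")
        (tmp_path / "MRREL.RRF").write_text(
            "\n".join(format_mrrel_row(r) for r in rels) + "\n")
        assert read_mrconso(tmp_path / "MRCONSO.RRF", CFG) == sorted(
            atoms, key=lambda a: (a.cui, a.sab, a.code))
        assert read_mrrel(tmp_path / "MRREL.RRF", CFG) == rels


PATTERNS = [
    FireLadderPattern("HPO", "NCI", "SNOMEDCT_US",
                      "C9900001", "C0345203", "C9900002"),
    FireLadderPattern("ATC", "GO", "FMA",
                      "C9000001", "C9000002", "C9000003"),
]


class TestWritePatterns:
    def test_empty_gives_header_only(self, tmp_path):
        out = tmp_path / "patterns.tsv"
        write_patterns([], out)
        assert out.read_text().startswith("target_sab\tupper_sab")
        assert len(out.read_text().splitlines()) == 1

    def test_fig3_pattern_row(self, tmp_path):
        out = tmp_path / "patterns.tsv"
        names = {("C0345203", "NCI"): "Large Intestine Atresia"}
        write_patterns([PATTERNS[0]], out, names=names)
        header, row = out.read_text().splitlines()
        fields = row.split("\t")
        assert fields[0] == "HPO"
        assert fields[6] == "Large Intestine Atresia"

    def test_shuffled_input_identical_bytes(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_patterns(PATTERNS, a)
        write_patterns(list(reversed(PATTERNS)), b)
        assert a.read_bytes() == b.read_bytes()

    def test_json_format(self, tmp_path):
        out = tmp_path / "patterns.json"
        write_patterns(PATTERNS, out, format="json")
        data = json.loads(out.read_text())
        assert len(data) == 2
        assert data[0]["target_sab"] == "ATC"  # canonical sort

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_patterns([], tmp_path / "x", format="csv")


class TestValidation:
    def test_bad_cui_rejected(self):
        with pytest.raises(ValueError, match="CUI"):
            AtomRecord(cui="X123", sab="HPO", code="1", str_name="x")
        with pytest.raises(ValueError, match="CUI"):
            RelRecord(cui1="C0000001", cui2="C1", sab="HPO")

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SourceConfig(included_sabs=[])
        with pytest.raises(ValueError):
            SourceConfig(included_sabs=["A", "A", "B"])
        with pytest.raises(ValueError):
            SourceConfig(included_sabs=["A", "B"], excluded_sabs=["B"])

    def test_name_index_prefers_lexicographic_first(self):
        atoms = [
            AtomRecord(cui="C0000001", sab="HPO", code="1", str_name="zeta"),
            AtomRecord(cui="C0000001", sab="HPO", code="2", str_name="alpha"),
        ]
        assert build_name_index(atoms)[("C0000001", "HPO")] == "alpha"
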