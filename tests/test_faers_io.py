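import datetime

import pytest
from hypothesis import given, settings, strategies as st

from pvdispro.faers_io import (
    AgeUnit,
    DatePrecision,
    DrugLexicon,
    MissingColumnError,
    RoleCode,
    Sex,
    TableKind,
    age_in_years,
    normalize_name,
    parse_date,
    read_lexicon,
    read_soc_mapping,
    read_table,
    write_table,
)


class TestParseDate:
    @pytest.mark.parametrize(
        "text,precision",
        [
            ("20230101", DatePrecision.DAY),
            ("202302", DatePrecision.MONTH),
            ("2023", DatePrecision.YEAR),
            ("20230230", DatePrecision.INVALID),  # Feb 30 is not a date
            ("20231301", DatePrecision.INVALID),
            ("202313", DatePrecision.INVALID),
            ("", DatePrecision.MISSING),
            ("   ", DatePrecision.MISSING),
            ("2023010", DatePrecision.INVALID),
            ("abc", DatePrecision.INVALID),
            (None, DatePrecision.MISSING),
        ],
    )
    def test_precision_classification(self, text, precision):
        assert parse_date(text).precision is precision

    def test_full_date_value(self):
        d = parse_date("20230101")
        assert d.value == datetime.date(2023, 1, 1)
        assert (d.year, d.month) == (2023, 1)

    def test_exhaustive_six_digit_sweep(self):
        """Every 6-digit string agrees with a calendar-validity oracle."""
        for year in (1999, 2004, 2024):
            for month in range(0, 100):
                text = f"{year}{month:02d}"
                expected = (
                    DatePrecision.MONTH if 1 <= month <= 12 else DatePrecision.INVALID
                )
                assert parse_date(text).precision is expected, text

    @given(
        st.integers(1900, 2100),
        st.integers(0, 13),
        st.integers(0, 32),
    )
    @settings(max_examples=300, derandomize=True)
    def test_eight_digit_agrees_with_calendar_oracle(self, y, m, d):
        text = f"{y:04d}{m:02d}{d:02d}"
        try:
            value = datetime.date(y, m, d)
        except ValueError:
            value = None
        parsed = parse_date(text)
        if value is None:
            assert parsed.precision is DatePrecision.INVALID
        else:
            assert parsed.precision is DatePrecision.DAY
            assert parsed.value == value


def _write(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="latin-1")
    return path


class TestReadTable:
    def test_demo_fixture(self, tmp_path):
        p = _write(tmp_path / "demo.txt", [
            "primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$occp_cod$occr_country$wt",
            "1001$100$20230101$20221230$F$45$YR$MD$US$70.5",
            "1002$101$20230102$$M$6$MON$CN$FR$",
            "1003$102$20230103$202211$$$$$GB$",
        ])
        records = read_table(p, TableKind.DEMO)
        assert len(records) == 3
        assert records[0].sex is Sex.F and records[0].age_value == 45
        assert records[1].age_unit is AgeUnit.MONTHS
        assert records[1].age_years == pytest.approx(0.5)
        assert records[2].event_dt.precision is DatePrecision.MONTH
        # order-preserving
        assert [r.primaryid for r in records] == ["1001", "1002", "1003"]

    def test_role_codes_parsed(self, tmp_path):
        p = _write(tmp_path / "drug.txt", [
            "primaryid$drugname$prod_ai$role_cod$route$start_dt",
            "1$AMOXICILLIN$AMOXICILLIN$PS$Oral$20230101",
            "2$X$X$SS$$",
            "3$Y$Y$C$$",
            "4$Z$Z$??$$",
        ])
        roles = [r.role_code for r in read_table(p, "DRUG")]
        assert roles == [RoleCode.PS, RoleCode.SS, RoleCode.C, RoleCode.UNKNOWN]

    def test_header_only_gives_empty_list(self, tmp_path):
        p = _write(tmp_path / "reac.txt", ["primaryid$pt"])
        assert read_table(p, TableKind.REAC) == []

    def test_column_binding_by_name_not_position(self, tmp_path):
        p = _write(tmp_path / "demo.txt", [
            "CASEID$extra$PRIMARYID$FDA_DT",
            "100$junk$1001$20230101",
        ])
        (rec,) = read_table(p, TableKind.DEMO)
        assert rec.primaryid == "1001" and rec.caseid == "100"

    def test_missing_mandatory_column_raises(self, tmp_path):
        p = _write(tmp_path / "demo.txt", ["primaryid$fda_dt", "1$20230101"])
        with pytest.raises(MissingColumnError, match="caseid"):
            read_table(p, TableKind.DEMO)

    @pytest.mark.parametrize(
        "kind,lines",
        [
            (TableKind.DEMO, [
                "primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$occp_cod$occr_country$wt",
                "1001$100$20230101$20221230$F$45$YR$MD$US$70.5",
                "1002$101$20230102$$M$$$CN$FR$",
            ]),
            (TableKind.DRUG, [
                "primaryid$drugname$prod_ai$role_cod$route$start_dt",
                "1001$AMOXICILLIN$AMOXICILLIN$PS$Oral$20230101",
                "1002$X$$SS$$202301",
            ]),
            (TableKind.REAC, ["primaryid$pt", "1001$Urticaria", "1001$Rash"]),
            (TableKind.OUTC, ["primaryid$outc_cod", "1001$HO"]),
            (TableKind.DELETED, ["caseid", "100", "101"]),
        ],
    )
    def test_roundtrip(self, tmp_path, kind, lines):
        records = read_table(_write(tmp_path / "in.txt", lines), kind)
        out = write_table(records, tmp_path / "out.txt", kind)
        assert read_table(out, kind) == records


class TestLexiconAndSocMap:
    def test_lexicon_sections_and_exclusions(self, tmp_path):
        p = tmp_path / "amox.lex"
        p.write_text(
            "[target] amoxicillin\n[synonyms]\nAMOXICILLIN\nAmoxil\n"
            "[exclusions]\namoxicillin and clavulanate potassium\n",
            encoding="utf-8",
        )
        lex = read_lexicon(p)
        assert lex.target_label == "amoxicillin"
        assert lex.matches("amoxicillin")
        assert lex.matches("AMOXIL ")
        assert not lex.matches("Amoxicillin and Clavulanate Potassium")
        assert not lex.matches("cefalexin")

    def test_exclusion_wins_on_either_field(self):
        lex = DrugLexicon("amoxicillin", {"amoxicillin"},
                          {"amoxicillin clavulanate"})
        assert not lex.matches("something", "amoxicillin/clavulanate")

    def test_synonym_exclusion_overlap_rejected(self):
        with pytest.raises(ValueError, match="both"):
            DrugLexicon("x", {"a"}, {"A "})

    def test_normalize_name(self):
        assert normalize_name("  Amoxicillin/Clavulanate  ") == "amoxicillin clavulanate"

    def test_soc_mapping_merges_and_normalizes(self, tmp_path):
        p = tmp_path / "soc.tsv"
        p.write_text(
            "Urticaria\tSkin and subcutaneous tissue disorders\n"
            "Anaphylactic shock\tImmune system disorders\n"
            "Anaphylactic shock\tCardiac disorders\n",
            encoding="utf-8",
        )
        soc = read_soc_mapping(p)
        assert soc.lookup("URTICARIA ") == {"Skin and subcutaneous tissue disorders"}
        assert soc.lookup("Anaphylactic shock") == {
            "Immune system disorders", "Cardiac disorders",
        }

    def test_unmapped_lookup_is_empty_not_error(self, tmp_path):
        p = tmp_path / "soc.tsv"
        p.write_text("Urticaria\tSkin\n", encoding="utf-8")
        assert read_soc_mapping(p).lookup("Pyrexia") == frozenset()

    def test_empty_soc_is_hard_error(self, tmp_path):
        p = tmp_path / "soc.tsv"
        p.write_text("Urticaria\t\n", encoding="utf-8")
        with pytest.raises(ValueError, match="empty SOC"):
            read_soc_mapping(p)


def test_age_normalization_factors():
    assert age_in_years(5, AgeUnit.DECADES) == 50
    assert age_in_years(24, AgeUnit.MONTHS) == pytest.approx(2.0)
    assert age_in_years(52, AgeUnit.WEEKS) == pytest.approx(1.0)
    assert age_in_years(365.25, AgeUnit.DAYS) == pytest.approx(1.0)
    assert age_in_years(40, AgeUnit.UNKNOWN) is None
    assert age_in_years(None, AgeUnit.YEARS) is None
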