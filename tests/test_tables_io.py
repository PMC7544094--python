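"""Parsing, validation and round-trip behaviour of the table readers/writers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telburden import datasets
from telburden.tables_io import (
    BurdenEstimate,
    DiseaseAssociation,
    LDMatrix,
    SNPRecord,
    TableFormatError,
    ValidationError,
    read_burden_table,
    read_ld_matrix,
    read_or_table,
    read_snp_table,
    round_display,
    write_burden_table,
    write_ld_matrix,
    write_or_table,
    write_snp_table,
)


class TestOrTable:
    def test_combined_or_ci_cell_with_en_dash(self, tmp_path):
        p = tmp_path / "or.csv"
        p.write_text(
            "disease_name,or_ci,direction\n"
            'Glioma,"5.27 (3.15–8.81)",per_sd_longer\n'
        )
        (rec,) = read_or_table(p)
        assert rec.or_per_sd == 5.27
        assert (rec.ci_lower, rec.ci_upper) == (3.15, 8.81)
        assert rec.significant  # default

    def test_hyphen_separator_accepted(self, tmp_path):
        p = tmp_path / "or.csv"
        p.write_text(
            "disease_name,or_ci,direction\n"
            'CHD,"1.28 (1.11-1.49)",per_sd_shorter\n'
        )
        assert read_or_table(p)[0].ci_upper == 1.49

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "or.csv"
        p.write_text("disease_name,or_per_sd,direction\n")
        assert read_or_table(p) == []

    def test_malformed_or_cell_names_row(self, tmp_path):
        p = tmp_path / "or.csv"
        p.write_text(
            "disease_name,or_ci,direction\nBad,not-an-or,per_sd_longer\n"
        )
        with pytest.raises(TableFormatError, match="row 2"):
            read_or_table(p)

    def test_inverted_ci_is_validation_error(self, tmp_path):
        p = tmp_path / "or.csv"
        p.write_text(
            "disease_name,or_per_sd,ci_lower,ci_upper,direction\n"
            "Bad,1.5,2.0,1.1,per_sd_longer\n"
        )
        with pytest.raises(ValidationError, match="inverted"):
            read_or_table(p)

    @settings(deadline=None, max_examples=25)
    @given(
        ors=st.lists(
            st.floats(min_value=0.05, max_value=20, allow_nan=False),
            min_size=1,
            max_size=8,
        ),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_identity(self, tmp_path_factory, ors, seed):
        rng = np.random.default_rng(seed)
        recs = [
            DiseaseAssociation(
                disease_name=f"d{i}",
                or_per_sd=o,
                ci_lower=o * 0.8,
                ci_upper=o * 1.2,
                direction="per_sd_longer" if rng.random() < 0.5 else "per_sd_shorter",
                source="s",
                significant=bool(rng.random() < 0.8),
            )
            for i, o in enumerate(ors)
        ]
        p = tmp_path_factory.mktemp("rt") / "or.csv"
        write_or_table(recs, p)
        assert read_or_table(p) == recs


class TestBurdenTable:
    def test_simple_dialect_with_thousands_separator(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text(
            "cause_name,measure,value,ci_lower,ci_upper\n"
            'CHD,incidence,190.81,171.96,211.00\n'
            'CHD,daly,"2,106.22","2,060.06","2,167.79"\n'
        )
        inc, daly = read_burden_table(p)
        assert inc.value == 190.81 and (inc.ci_lower, inc.ci_upper) == (171.96, 211.00)
        assert daly.value == 2106.22

    def test_na_produces_missing(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("cause_name,measure,value\nAortic aneurysm,incidence,NA\n")
        (rec,) = read_burden_table(p)
        assert rec.value is None and rec.ci_lower is None

    def test_gbd_results_dialect(self, tmp_path):
        p = tmp_path / "gbd.csv"
        p.write_text(
            "measure,location,sex,age,cause,metric,year,val,upper,lower\n"
            "DALYs (Disability-Adjusted Life Years),Europe,Both,Age-standardized,"
            'Ischemic heart disease,Rate,2017,"2,106.22","2,167.79","2,060.06"\n'
        )
        (rec,) = read_burden_table(p, dialect="gbd_results")
        assert rec.measure == "daly"
        assert rec.value == 2106.22
        assert rec.population == "Europe" and rec.year == 2017

    def test_unknown_measure_and_negative_rate_rejected(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("cause_name,measure,value\nX,prevalence,3\n")
        with pytest.raises(TableFormatError, match="measure"):
            read_burden_table(p)
        p.write_text("cause_name,measure,value\nX,incidence,-3\n")
        with pytest.raises(ValidationError, match="negative"):
            read_burden_table(p)

    def test_round_trip(self, tmp_path):
        recs = [
            BurdenEstimate("A", "incidence", 12.345678, 10.0, 15.0, "Europe", 2017),
            BurdenEstimate("B", "daly", None, None, None, "Europe", 2017),
        ]
        p = tmp_path / "b.csv"
        write_burden_table(recs, p)
        assert read_burden_table(p) == recs


class TestLDMatrix:
    def test_singleton(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("RS_number\trsX\nrsX\t1\n")
        m = read_ld_matrix(p)
        assert m.n == 1 and m.r2[0, 0] == 1.0

    def test_triangular_mirroring_equals_full(self, tmp_path):
        tri = tmp_path / "tri.tsv"
        tri.write_text(
            "RS_number\trs11125529\trs11890390\n"
            "rs11125529\t1\n"
            "rs11890390\t0.951\t1\n"
        )
        full = tmp_path / "full.tsv"
        full.write_text(
            "RS_number\trs11125529\trs11890390\n"
            "rs11125529\t1\t0.951\n"
            "rs11890390\t0.951\t1\n"
        )
        a, b = read_ld_matrix(tri), read_ld_matrix(full)
        assert a.rsids == b.rsids
        np.testing.assert_array_equal(a.r2, b.r2)
        assert a.r2[0, 1] == 0.951

    def test_all_na_row_stays_missing(self):
        chr8 = next(m for m in datasets.load_ld_matrices() if m.chromosome == "8")
        i = chr8.rsids.index("rs28365964")
        assert np.all(np.isnan(chr8.r2[i]))
        assert np.all(np.isnan(chr8.r2[:, i]))

    def test_nonsquare_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("RS_number\trsA\trsB\nrsA\t1\n")
        with pytest.raises(TableFormatError, match="non-square"):
            read_ld_matrix(p)

    def test_out_of_range_and_asymmetric_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            LDMatrix("x", ["a", "b"], np.array([[1.0, 1.2], [1.2, 1.0]]))
        with pytest.raises(ValidationError, match="asymmetric"):
            LDMatrix("x", ["a", "b"], np.array([[1.0, 0.2], [0.5, 1.0]]))

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        n = 4
        r2 = rng.uniform(0, 1, (n, n))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        r2[0, 3] = r2[3, 0] = np.nan
        m = LDMatrix("7", [f"rs{i}" for i in range(n)], r2)
        p = tmp_path / "m.tsv"
        write_ld_matrix(m, p)
        back = read_ld_matrix(p, chromosome="7")
        np.testing.assert_array_equal(back.r2, m.r2)
        assert back.rsids == m.rsids


class TestSnpTable:
    def test_valid_record(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "rsid,chromosome,position,short_allele,long_allele,short_allele_freq\n"
            "rs621559,1,43179740,G,A,0.908\n"
        )
        (rec,) = read_snp_table(p)
        assert rec.position == 43179740 and rec.short_allele_freq == 0.908

    def test_frequency_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "rsid,chromosome,position,short_allele_freq\nrsX,1,100,1.2\n"
        )
        with pytest.raises(ValidationError, match="frequency"):
            read_snp_table(p)

    def test_duplicate_rsid_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "rsid,chromosome,position\nrsX,1,100\nrsX,1,200\n"
        )
        with pytest.raises(ValidationError, match="rsX"):
            read_snp_table(p)

    def test_round_trip_preserves_all_fields(self, tmp_path):
        recs = [
            SNPRecord("rsA", "2", 123, "C", "T", 0.25, "yes", 1000, True, "European"),
            SNPRecord("rsB", "X", 99, None, None, None, "unknown", None, False, ""),
        ]
        p = tmp_path / "s.csv"
        write_snp_table(recs, p)
        assert read_snp_table(p) == recs


def test_display_rounding_is_half_even():
    assert round_display(35.825) == "35.82"  # ties to even
    assert round_display(35.835) == "35.84"
    assert round_display(None) == "NA"
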