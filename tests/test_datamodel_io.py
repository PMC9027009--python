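import numpy as np
import pytest

from sexmark.datamodel_io import (
    ABSENT,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    PRESENT,
    Dataset,
    FormatError,
    Individual,
    Sex,
    SiteGenotypes,
    TagLocus,
    read_blast_tabular,
    read_genotype_table,
    read_marker_report,
    read_sex_map,
    read_vcf,
    write_confirmed_bed,
    write_genotype_table,
    write_marker_report,
    write_presence_matrix,
    write_sex_map,
)
from sexmark.detectors import DetectionRecord, MarkerCatalog
from sexmark.synthetic_data import SimulationConfig, simulate_dataset

from conftest import site_dataset


class TestDomainTypes:
    def test_duplicate_individual_ids_rejected(self):
        inds = [Individual("a", Sex.MALE), Individual("a", Sex.FEMALE)]
        with pytest.raises(ValueError, match="duplicate"):
            Dataset(inds, [])

    def test_site_offsets_must_increase(self):
        calls = np.zeros(2, dtype=np.int8)
        sites = [
            SiteGenotypes("t", 5, "A", "G", calls),
            SiteGenotypes("t", 5, "C", "T", calls),
        ]
        with pytest.raises(ValueError, match="strictly increasing"):
            TagLocus("t", sites=sites)

    def test_site_outside_sequence_rejected(self):
        site = SiteGenotypes("t", 50, "A", "G", np.zeros(1, dtype=np.int8))
        with pytest.raises(ValueError, match="outside sequence"):
            TagLocus("t", sites=[site], sequence="ACGT" * 10)

    def test_non_nucleotide_allele_rejected(self):
        with pytest.raises(ValueError, match="single"):
            SiteGenotypes("t", 0, "AT", "G", np.zeros(1, dtype=np.int8))

    def test_derived_presence_from_calls(self):
        ds = site_dataset([HOM_REF, MISSING], [HET, MISSING])
        assert list(ds.tags[0].presence) == [PRESENT, ABSENT, PRESENT, ABSENT]

    def test_require_both_sexes(self):
        ds = site_dataset([HOM_REF], [])
        with pytest.raises(ValueError, match="male"):
            ds.require_both_sexes()


class TestSexMap:
    def test_case_insensitive_tokens(self, tmp_path):
        p = tmp_path / "sex.tsv"
        p.write_text("a\tm\nb\tF\nc\tu\n")
        m = read_sex_map(p)
        assert m == {"a": Sex.MALE, "b": Sex.FEMALE, "c": Sex.UNKNOWN}

    def test_unknown_token_is_error_not_unknown(self, tmp_path):
        p = tmp_path / "sex.tsv"
        p.write_text("a\tmale\n")
        with pytest.raises(FormatError, match="not in M/F/U"):
            read_sex_map(p)

    def test_empty_map_rejected(self, tmp_path):
        p = tmp_path / "sex.tsv"
        p.write_text("")
        with pytest.raises(FormatError, match="empty"):
            read_sex_map(p)


class TestGenotypeTable:
    def test_toy_table_shape(self, toy_table):
        ds = read_genotype_table(*toy_table)
        assert len(ds.tags) == 2
        assert ds.n_individuals == 4
        assert [t.tag_id for t in ds.tags] == ["tagA", "tagB"]
        assert len(ds.tags[0].sites) == 2

    def test_sample_missing_from_sex_map_becomes_unknown(self, toy_table, caplog):
        table, _ = toy_table
        sexmap = table.parent / "partial.tsv"
        sexmap.write_text("s1\tF\ns2\tF\ns3\tM\n")
        with caplog.at_level("WARNING"):
            ds = read_genotype_table(table, sexmap)
        assert ds.individuals[3].phenotype is Sex.UNKNOWN
        assert "not in sex map" in caplog.text

    def test_triallelic_row_skipped_and_counted(self, tmp_path):
        # expected skip count from an independent line scan of the raw file
        table = tmp_path / "geno.tsv"
        lines = [
            "tag_id\tsite\tref\talt\ts1\ts2",
            "t1\t0\tA\tG\t0/0\t0/1",
            "t1\t5\tA\tG,T\t0/0\t0/1",  # multiallelic
            "t2\t0\tAC\tG\t0/0\t0/1",  # indel-like ref
            "t2\t7\tC\tT\t1/1\t./.",
        ]
        table.write_text("\n".join(lines) + "\n")
        sexmap = tmp_path / "sex.tsv"
        sexmap.write_text("s1\tF\ns2\tM\n")

        expected_skips = sum(
            1
            for ln in lines[1:]
            if not (
                len(ln.split("\t")[2]) == 1
                and len(ln.split("\t")[3]) == 1
                and ln.split("\t")[2] in "ACGT"
                and ln.split("\t")[3] in "ACGT"
            )
        )
        ds = read_genotype_table(table, sexmap)
        assert ds.notes["skipped_rows"] == expected_skips == 2
        assert sum(len(t.sites) for t in ds.tags) == 2

    def test_bad_genotype_token_rejected(self, tmp_path):
        table = tmp_path / "geno.tsv"
        table.write_text("tag_id\tsite\tref\talt\ts1\nt1\t0\tA\tG\t0|1\n")
        sexmap = tmp_path / "sex.tsv"
        sexmap.write_text("s1\tF\n")
        with pytest.raises(FormatError, match="dialect"):
            read_genotype_table(table, sexmap)

    def test_duplicate_sample_columns_rejected(self, tmp_path):
        table = tmp_path / "geno.tsv"
        table.write_text("tag_id\tsite\tref\talt\ts1\ts1\nt1\t0\tA\tG\t0/0\t0/0\n")
        sexmap = tmp_path / "sex.tsv"
        sexmap.write_text("s1\tF\n")
        with pytest.raises(FormatError, match="duplicated sample"):
            read_genotype_table(table, sexmap)

    def test_empty_file_rejected(self, tmp_path):
        table = tmp_path / "geno.tsv"
        table.write_text("")
        sexmap = tmp_path / "sex.tsv"
        sexmap.write_text("s1\tF\n")
        with pytest.raises(FormatError, match="empty"):
            read_genotype_table(table, sexmap)

    def test_presence_matrix_override(self, toy_table, tmp_path):
        table, sexmap = toy_table
        pres = tmp_path / "presence.tsv"
        pres.write_text(
            "tag_id\ts1\ts2\ts3\ts4\n"
            "tagA\t1\t0\tNA\t1\n"
            "tagY\t0\t0\t1\t1\n"  # presence-only tag, no SNPs
        )
        ds = read_genotype_table(table, sexmap, presence_path=pres)
        assert list(ds.tag("tagA").presence) == [1, 0, -1, 1]
        assert ds.tag("tagY").sites == []
        assert list(ds.tag("tagY").presence) == [0, 0, 1, 1]
        # tagB keeps derived presence
        assert list(ds.tag("tagB").presence) == [1, 1, 1, 1]


class TestRoundTrip:
    def test_write_read_identical_calls_and_phenotypes(self, tmp_path):
        ds, _ = simulate_dataset(
            SimulationConfig(
                n_males=6, n_females=5, n_autosomal_sites=30, n_sexlinked_sites=10,
                n_limited_tags=0, genotyping_error=0.1, missing_rate=0.1, seed=7,
            )
        )
        geno, sexmap = tmp_path / "g.tsv", tmp_path / "s.tsv"
        write_genotype_table(ds, geno)
        write_sex_map(ds, sexmap)
        back = read_genotype_table(geno, sexmap)
        assert [i.id for i in back.individuals] == [i.id for i in ds.individuals]
        assert [i.phenotype for i in back.individuals] == [i.phenotype for i in ds.individuals]
        for t1, t2 in zip(ds.tags, back.tags):
            assert t1.tag_id == t2.tag_id
            for s1, s2 in zip(t1.sites, t2.sites):
                assert (s1.calls == s2.calls).all()
                assert (s1.site_index, s1.ref_allele, s1.alt_allele) == (
                    s2.site_index, s2.ref_allele, s2.alt_allele,
                )

    def test_reader_never_invents_calls(self, tmp_path):
        ds, _ = simulate_dataset(
            SimulationConfig(n_males=5, n_females=5, n_autosomal_sites=40,
                             n_sexlinked_sites=0, n_limited_tags=0,
                             missing_rate=0.3, seed=3)
        )
        geno, sexmap = tmp_path / "g.tsv", tmp_path / "s.tsv"
        write_genotype_table(ds, geno)
        write_sex_map(ds, sexmap)
        back = read_genotype_table(geno, sexmap)
        n_called = sum(int((s.calls != MISSING).sum()) for t in back.tags for s in t.sites)
        # independent token scan of the raw file
        tokens = [
            tok
            for ln in geno.read_text().splitlines()[1:]
            for tok in ln.split("\t")[4:]
        ]
        assert n_called == sum(1 for tok in tokens if tok != "./.")

    def test_presence_matrix_roundtrip(self, tmp_path):
        ds, _ = simulate_dataset(
            SimulationConfig(n_males=4, n_females=4, n_autosomal_sites=0,
                             n_sexlinked_sites=0, n_limited_tags=6,
                             missing_rate=0.2, seed=11)
        )
        geno, sexmap, pres = tmp_path / "g.tsv", tmp_path / "s.tsv", tmp_path / "p.tsv"
        write_genotype_table(ds, geno)
        write_sex_map(ds, sexmap)
        write_presence_matrix(ds, pres)
        back = read_genotype_table(geno, sexmap, presence_path=pres)
        for tag in ds.tags:
            assert (back.tag(tag.tag_id).presence == tag.presence).all()


def _write_vcf(path, records, samples=("s1", "s2", "s3")):
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + "".join(r + "\n" for r in records))


class TestVCF:
    @pytest.fixture
    def sexmap3(self, tmp_path):
        p = tmp_path / "sex.tsv"
        p.write_text("s1\tF\ns2\tM\ns3\tM\n")
        return p

    def test_biallelic_filter(self, tmp_path, sexmap3):
        vcf = tmp_path / "toy.vcf"
        _write_vcf(
            vcf,
            [
                "tag1\t11\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
                "tag1\t30\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",  # triallelic
                "tag2\t5\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0",
                "tag2\t9\t.\tT\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1",
            ],
        )
        ds = read_vcf(vcf, sexmap3)
        assert sum(len(t.sites) for t in ds.tags) == 3
        assert ds.notes["skipped_rows"] == 1
        # POS converted to 0-based
        assert ds.tags[0].sites[0].site_index == 10

    def test_all_missing_column_retained(self, tmp_path, sexmap3):
        vcf = tmp_path / "toy.vcf"
        _write_vcf(vcf, ["tag1\t1\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0"])
        ds = read_vcf(vcf, sexmap3)
        assert ds.n_individuals == 3
        assert ds.tags[0].sites[0].calls[0] == MISSING

    def test_half_called_treated_as_missing(self, tmp_path, sexmap3):
        vcf = tmp_path / "toy.vcf"
        _write_vcf(vcf, ["tag1\t1\t.\tA\tG\t.\tPASS\t.\tGT\t./1\t0/1\t1/1"])
        ds = read_vcf(vcf, sexmap3)
        # manual parse of the toy VCF: tokens ./1, 0/1, 1/1
        expected = [MISSING, HET, HOM_ALT]
        assert list(ds.tags[0].sites[0].calls) == expected

    def test_no_sample_overlap_rejected(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        _write_vcf(vcf, ["tag1\t1\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0"])
        other = tmp_path / "other.tsv"
        other.write_text("x1\tF\n")
        with pytest.raises(FormatError, match="no overlap"):
            read_vcf(vcf, other)


class TestBlastTabular:
    LINE = "{q}\tsubj{i}\t98.5\t95\t1\t0\t1\t95\t{s}\t{e}\t{ev}\t{bs}"

    def test_hits_ordered_by_evalue(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            self.LINE.format(q="q1", i=1, s=100, e=194, ev="1e-10", bs=90) + "\n"
            + self.LINE.format(q="q1", i=2, s=500, e=594, ev="1e-30", bs=180) + "\n"
        )
        hits = read_blast_tabular(p)
        assert [h.evalue for h in hits] == [1e-30, 1e-10]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert read_blast_tabular(p) == []

    def test_zero_evalue_sorts_first(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            self.LINE.format(q="q1", i=1, s=1, e=94, ev="1e-50", bs=100) + "\n"
            + self.LINE.format(q="q1", i=2, s=1, e=94, ev="0.0", bs=200) + "\n"
        )
        hits = read_blast_tabular(p)
        assert hits[0].evalue == 0.0

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\tsubj\t98.5\n")
        with pytest.raises(FormatError, match="12 columns"):
            read_blast_tabular(p)

    def test_unparseable_evalue_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.LINE.format(q="q1", i=1, s=1, e=94, ev="abc", bs=100) + "\n")
        with pytest.raises(FormatError):
            read_blast_tabular(p)


class TestMarkerReport:
    def _catalog(self):
        from sexmark.sexstats import SiteSexStats

        st = SiteSexStats("tagB", 4, 5, 5, 10, 5, 0, 5, 5, 0, True)
        return MarkerCatalog(
            [
                DetectionRecord("tagB", 4, "het_diff", "XY", st),
                DetectionRecord("tagA", None, "sex_limited", "XY", None),
                DetectionRecord("tagA", 1, "freq_diff", "XY", None),
            ]
        )

    def test_empty_catalog_header_only(self, tmp_path):
        p = tmp_path / "report.tsv"
        write_marker_report(MarkerCatalog([]), p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("tag_id\tsite")

    def test_rows_sorted(self, tmp_path):
        p = tmp_path / "report.tsv"
        write_marker_report(self._catalog(), p)
        rows = [ln.split("\t")[:2] for ln in p.read_text().splitlines()[1:]]
        assert rows == [["tagA", "tag"], ["tagA", "2"], ["tagB", "5"]]

    def test_deterministic_output(self, tmp_path):
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        write_marker_report(self._catalog(), p1)
        write_marker_report(self._catalog(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_report_roundtrip(self, tmp_path):
        p = tmp_path / "report.tsv"
        cat = self._catalog()
        write_marker_report(cat, p)
        back = read_marker_report(p)
        assert {(r.tag_id, r.site_index, r.approach, r.pattern) for r in back.records} == {
            (r.tag_id, r.site_index, r.approach, r.pattern) for r in cat.records
        }


class TestBed:
    def test_confirmed_bed_half_open_and_strand(self, tmp_path):
        from sexmark.confirmation import AlignmentHit, ConfirmationRecord

        fwd = AlignmentHit("t1", "chr1", 99.0, 90, 0, 0, 1, 90, 101, 190, 1e-40, 160.0)
        rev = AlignmentHit("t2", "chr1", 99.0, 90, 0, 0, 1, 90, 290, 201, 1e-40, 160.0)
        recs = [
            ConfirmationRecord("t1", True, "top_hit_e", fwd),
            ConfirmationRecord("t2", True, "top_hit_e", rev),
            ConfirmationRecord("t3", False, "top_hit_e", None),
        ]
        p = tmp_path / "out.bed"
        write_confirmed_bed(recs, p)
        lines = [ln.split("\t") for ln in p.read_text().splitlines()]
        assert len(lines) == 2
        assert lines[0][:4] == ["chr1", "100", "190", "t1"] and lines[0][5] == "+"
        assert lines[1][:4] == ["chr1", "200", "290", "t2"] and lines[1][5] == "-"
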