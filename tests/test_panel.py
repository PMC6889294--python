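"""Variant ingestion, pathogenicity/quality filters and dichotomization."""

import textwrap

import pytest
from hypothesis import given, settings, strategies as st

from ecsubtype.panel import (FilterPolicy, GenePanel, VariantRecord,
                             apply_quality_filters, classify_pathogenicity,
                             dichotomize_genes, mutational_load,
                             protein_residue, read_variant_table,
                             VariantTableError)


def _v(**kw):
    base = dict(sample_id="S1", gene="PTEN", chrom="chr10", pos=89620000,
                ref="A", alt="T", protein_change="p.R130Q",
                consequence="missense", depth=800, vaf=0.3,
                clinvar_class="pathogenic")
    base.update(kw)
    return VariantRecord(**base)


class TestGenePanel:
    def test_default_panel_and_rf_subset(self):
        panel = GenePanel()
        assert len(panel.genes) == 13
        assert len(panel.rf_genes) == 12
        assert "POLE" not in panel.rf_genes

    def test_rejects_wrong_size(self):
        with pytest.raises(ValueError):
            GenePanel(genes=("PTEN", "TP53"))


class TestPathogenicity:
    @pytest.mark.parametrize("kw, expected", [
        # ClinVar precedence over predictors, both directions
        (dict(clinvar_class="pathogenic", polyphen_call="benign",
              sift_call="tolerated"), "retain"),
        (dict(clinvar_class="likely_benign", polyphen_call="damaging"), "discard"),
        (dict(clinvar_class="benign", sift_call="deleterious"), "discard"),
        (dict(clinvar_class="vus"), "retain"),
        (dict(clinvar_class="likely_pathogenic"), "retain"),
        # unreported: either predictor can rescue
        (dict(clinvar_class="unreported", sift_call="deleterious"), "retain"),
        (dict(clinvar_class="unreported", polyphen_call="damaging",
              sift_call="tolerated"), "retain"),
        (dict(clinvar_class="unreported", polyphen_call="benign",
              sift_call="tolerated"), "discard"),
        # unreported + both predictors unknown: consequence tie-break
        (dict(clinvar_class="unreported", polyphen_call="unknown",
              sift_call="unknown", consequence="frameshift"), "retain"),
        (dict(clinvar_class="unreported", polyphen_call="unknown",
              sift_call="unknown", consequence="synonymous"), "discard"),
        (dict(clinvar_class="unreported", polyphen_call="unknown",
              sift_call="unknown", consequence="intronic"), "discard"),
    ])
    def test_retention_rules(self, kw, expected):
        assert classify_pathogenicity(_v(**kw)) == expected


class TestQualityFilters:
    @pytest.mark.parametrize("depth, vaf, clinvar, kept", [
        (599, 0.40, "pathogenic", False),   # below coverage floor
        (600, 0.05, "vus", True),           # inclusive boundaries
        (5000, 0.04, "pathogenic", False),  # below VAF floor
        (600, 0.05, "benign", False),
    ])
    def test_boundaries(self, depth, vaf, clinvar, kept):
        out = apply_quality_filters([_v(depth=depth, vaf=vaf, clinvar_class=clinvar)])
        assert bool(out) == kept

    @given(st.lists(st.tuples(st.integers(0, 2000),
                              st.floats(0, 1, allow_nan=False),
                              st.sampled_from(["pathogenic", "vus", "benign",
                                               "unreported"])), max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_monotone(self, rows):
        variants = [_v(depth=d, vaf=round(f, 4), clinvar_class=c)
                    for d, f, c in rows]
        once = apply_quality_filters(variants)
        assert apply_quality_filters(once) == once
        # raising either threshold never enlarges the retained set
        stricter = apply_quality_filters(
            variants, FilterPolicy(min_depth=900, min_vaf=0.10))
        assert set((v.pos, v.depth, v.vaf) for v in stricter) <= set(
            (v.pos, v.depth, v.vaf) for v in once)


class TestDichotomization:
    def test_indicator_semantics(self):
        variants = [
            _v(gene="PTEN", pos=1), _v(gene="PTEN", pos=2), _v(gene="PTEN", pos=3),
            _v(gene="TP53", chrom="chr17", pos=4),
        ]
        prof = dichotomize_genes(variants)["S1"]
        assert prof.gene_status["PTEN"] == 1
        assert prof.gene_status["TP53"] == 1
        assert sum(prof.gene_status.values()) == 2
        assert prof.retained_variant_count == 4

    def test_filtered_to_zero_sample_keeps_all_zero_profile(self):
        profs = dichotomize_genes([], raw_counts={"S9": 5})
        assert profs["S9"].gene_status == {g: 0 for g in GenePanel().genes}
        assert profs["S9"].raw_variant_count == 5
        assert profs["S9"].retained_variant_count == 0

    def test_order_and_duplication_invariance(self):
        variants = [_v(gene="PTEN", pos=1), _v(gene="KRAS", chrom="chr12", pos=2)]
        a = dichotomize_genes(variants)["S1"].gene_status
        b = dichotomize_genes(variants[::-1])["S1"].gene_status
        c = dichotomize_genes(variants + variants)["S1"].gene_status
        assert a == b == c

    def test_off_panel_genes_ignored(self):
        prof = dichotomize_genes([_v(gene="BRCA1", chrom="chr17", pos=1)])["S1"]
        assert sum(prof.gene_status.values()) == 0


class TestMutationalLoad:
    def test_four_point_median(self):
        profs = [
            dichotomize_genes([_v(sample_id=s, pos=i) for i in range(k)])[s]
            for s, k in (("A", 2), ("B", 9), ("C", 10), ("D", 64))
        ]
        out = mutational_load(profs, by="retained")
        assert out["median"] == 9.5
        assert out["range"] == (2, 64)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            mutational_load([])


class TestHgvsParsing:
    @pytest.mark.parametrize("s, res", [
        ("p.P286R", 286), ("p.V411L", 411), ("p.(Ser297Phe)", 297),
        ("p.Ala456Pro", 456), ("", None), ("c.100A>T", None),
    ])
    def test_residue_extraction(self, s, res):
        assert protein_residue(s) == res


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        body = textwrap.dedent("""\
        sample_id\tgene\tchrom\tpos\tref\talt\thgvs_p\tconsequence\tdepth\tvaf\tclinvar\tpolyphen\tsift
        S1\tPTEN\tchr10\t89620001\tA\tT\tp.R130Q\tmissense\t600\t0.05\tpathogenic\tdamaging\tdeleterious
        S1\tTP53\tchr17\t7570001\tG\tC\tp.R175H\tmissense\t900\t0.31\tvus\tunknown\tunknown
        S2\tKRAS\tchr12\t25360001\tC\tA\tp.G12D\tmissense\t1200\t0.12\tunreported\tdamaging\ttolerated
        """)
        p = tmp_path / "v.tsv"
        p.write_text(body)
        records = read_variant_table(p, dialect="tsv")
        assert len(records) == 3
        assert records[0].depth == 600 and records[0].vaf == 0.05
        assert records[1].clinvar_class == "vus"
        assert records[2].sample_id == "S2"

    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("sample_id\tgene\tchrom\n")
        with pytest.raises(VariantTableError, match="pos"):
            read_variant_table(p)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "sample_id\tgene\tchrom\tpos\tref\talt\thgvs_p\tconsequence\tdepth"
            "\tvaf\tclinvar\tpolyphen\tsift\n"
            "S1\tPTEN\tchr10\tnot_a_number\tA\tT\t\tmissense\t600\t0.1\tvus\t\t\n")
        with pytest.raises(VariantTableError, match=":2"):
            read_variant_table(p)

    def test_vcf_multiallelic_split(self, tmp_path):
        vcf = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##INFO=<ID=GENE,Number=A,Type=String,Description="gene">
        ##INFO=<ID=HGVSP,Number=A,Type=String,Description="p.">
        ##INFO=<ID=CSQ,Number=A,Type=String,Description="consequence">
        ##INFO=<ID=CLNSIG,Number=A,Type=String,Description="clinvar">
        ##INFO=<ID=POLYPHEN,Number=A,Type=String,Description="pp2">
        ##INFO=<ID=SIFT,Number=A,Type=String,Description="sift">
        ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">
        ##FORMAT=<ID=AF,Number=A,Type=Float,Description="vaf">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
        chr10\t89620001\t.\tA\tT,G\t.\tPASS\tGENE=PTEN,PTEN;HGVSP=p.R130Q,p.R130G;CSQ=missense,missense;CLNSIG=pathogenic,vus;POLYPHEN=damaging,damaging;SIFT=deleterious,deleterious\tDP:AF\t850:0.31,0.12
        """)
        p = tmp_path / "v.vcf"
        p.write_text(vcf)
        pytest.importorskip("cyvcf2")
        records = read_variant_table(p, dialect="vcf")
        assert len(records) == 2
        assert records[0].pos == records[1].pos == 89620001
        assert {r.alt for r in records} == {"T", "G"}
        assert records[0].vaf == pytest.approx(0.31, abs=1e-6)
        assert records[1].vaf == pytest.approx(0.12, abs=1e-6)
        assert records[1].clinvar_class == "vus"
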