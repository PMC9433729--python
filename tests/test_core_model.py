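"""Domain types and I/O round trips for the table formats."""

import numpy as np
import pytest

from germcsg.core_model import (
    AnnotatedVariant,
    CohortTable,
    Consequence,
    GeneModel,
    ImpactTier,
    Panel,
    ParseError,
    Participant,
    Role,
    SVCall,
    SvType,
    ValidationError,
    Zygosity,
    load_packaged_panel,
    read_gene_panel,
    read_minimal_vcf,
    read_variant_table,
    write_gene_panel,
    write_minimal_vcf,
    write_variant_table,
)
from conftest import random_variant


class TestGenePanel:
    def test_packaged_panel_has_121_genes_18_rcc(self):
        genes = load_packaged_panel()
        assert len(genes) == 121
        assert sum(g.panel is Panel.RCC_CSG for g in genes) == 18
        assert len({g.gene_symbol for g in genes}) == 121

    def test_empty_file_with_header_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("gene_symbol\tchrom\tgene_start\tgene_end\t"
                     "exon_starts\texon_ends\tpanel\ttranscript_id\n")
        assert read_gene_panel(p) == []

    def test_overlapping_exons_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "gene_symbol\tchrom\tgene_start\tgene_end\texon_starts\texon_ends\tpanel\ttranscript_id\n"
            "G1\t1\t100\t900\t100,200\t150,250\tRCC_CSG\tT1\n"
            "G2\t1\t100\t900\t100,140\t150,250\tRCC_CSG\tT2\n"  # exon 2 overlaps exon 1
            "G3\t1\t100\t900\t100\t150\tOTHER_CSG\tT3\n")
        with pytest.raises(ParseError, match=r":3:"):
            read_gene_panel(p)

    def test_start_after_end_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "gene_symbol\tchrom\tgene_start\tgene_end\texon_starts\texon_ends\tpanel\ttranscript_id\n"
            "G1\t1\t900\t100\t\t\tRCC_CSG\tT1\n")
        with pytest.raises(ParseError, match="start"):
            read_gene_panel(p)

    def test_duplicate_symbol_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        row = "G1\t1\t100\t900\t100\t150\tRCC_CSG\tT1\n"
        p.write_text(
            "gene_symbol\tchrom\tgene_start\tgene_end\texon_starts\texon_ends\tpanel\ttranscript_id\n"
            + row + row)
        with pytest.raises(ParseError, match="duplicate"):
            read_gene_panel(p)

    def test_unknown_panel_tag_rejected(self, tmp_path):
        p = tmp_path / "tag.tsv"
        p.write_text(
            "gene_symbol\tchrom\tgene_start\tgene_end\texon_starts\texon_ends\tpanel\ttranscript_id\n"
            "G1\t1\t100\t900\t100\t150\tMYSTERY\tT1\n")
        with pytest.raises(ParseError, match="MYSTERY"):
            read_gene_panel(p)

    def test_round_trip(self, tmp_path, panel):
        out = tmp_path / "roundtrip.tsv"
        write_gene_panel(panel, out)
        assert read_gene_panel(out) == panel


class TestVariantTable:
    def test_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(11)
        variants = [random_variant(rng, ["CHEK2", "VHL", "ATM"]) for _ in range(5)]
        p1, p2 = tmp_path / "v1.tsv", tmp_path / "v2.tsv"
        write_variant_table(variants, p1)
        reread = read_variant_table(p1)
        assert reread == variants
        write_variant_table(reread, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_sentinel_cadd_reads_as_absent(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "participant_id\tgene_symbol\thgvs_c\thgvs_p\tconsequence\timpact\t"
            "af_nfe\tsift\tpolyphen\tcadd_phred\tzygosity\n"
            "P1\tVHL\tc.1A>G\t.\tmissense\tMODERATE\t0.001\tdeleterious\tbenign\t.\thet\n")
        (v,) = read_variant_table(p)
        assert v.cadd_phred is None and v.hgvs_p is None

    def test_out_of_range_frequency_rejected(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "participant_id\tgene_symbol\thgvs_c\thgvs_p\tconsequence\timpact\t"
            "af_nfe\tsift\tpolyphen\tcadd_phred\tzygosity\n"
            "P1\tVHL\tc.1A>G\t.\tmissense\tMODERATE\t1.5\tdeleterious\tbenign\t25\thet\n")
        with pytest.raises(ParseError, match="1.5"):
            read_variant_table(p)

    def test_unknown_consequence_names_offending_value(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "participant_id\tgene_symbol\thgvs_c\thgvs_p\tconsequence\timpact\t"
            "af_nfe\tsift\tpolyphen\tcadd_phred\tzygosity\n"
            "P1\tVHL\tc.1A>G\t.\texplosive\tMODERATE\t0.1\tdeleterious\tbenign\t25\thet\n")
        with pytest.raises(ParseError, match="explosive"):
            read_variant_table(p)


class TestMinimalVcf:
    def _one_sample_variants(self, n=3):
        rng = np.random.default_rng(5)
        out = []
        for _ in range(n):
            v = random_variant(rng, ["CHEK2", "VHL"])
            out.append(AnnotatedVariant(
                "S1", v.gene_symbol, v.hgvs_c, v.consequence, v.impact_tier,
                v.af_by_population, v.zygosity, v.hgvs_p, v.sift, v.polyphen, v.cadd_phred))
        return out

    def test_vcf_and_tsv_readers_agree(self, tmp_path):
        variants = self._one_sample_variants()
        vcf, tsv = tmp_path / "x.vcf", tmp_path / "x.tsv"
        write_minimal_vcf(variants, vcf)
        write_variant_table(variants, tsv)
        from_vcf = read_minimal_vcf(vcf)
        from_tsv = read_variant_table(tsv)
        # floats survive at the VCF writer's text precision (~6 significant digits)
        for a, b in zip(from_vcf, from_tsv):
            assert (a.participant_id, a.gene_symbol, a.hgvs_c, a.hgvs_p,
                    a.consequence, a.impact_tier, a.sift, a.polyphen, a.zygosity) == \
                   (b.participant_id, b.gene_symbol, b.hgvs_c, b.hgvs_p,
                    b.consequence, b.impact_tier, b.sift, b.polyphen, b.zygosity)
            assert (a.cadd_phred is None) == (b.cadd_phred is None)
            if a.cadd_phred is not None:
                assert a.cadd_phred == pytest.approx(b.cadd_phred, rel=1e-5)
            assert set(a.af_by_population) == set(b.af_by_population)
            for pop in a.af_by_population:
                assert a.af_by_population[pop] == pytest.approx(
                    b.af_by_population[pop], rel=1e-5, abs=1e-8)

    def test_uncalled_genotype_skipped(self, tmp_path):
        variants = self._one_sample_variants(2)
        vcf = tmp_path / "x.vcf"
        write_minimal_vcf(variants, vcf)
        text = vcf.read_text().splitlines()
        text[-1] = text[-1].rsplit("\t", 1)[0] + "\t./."
        vcf.write_text("\n".join(text) + "\n")
        assert len(read_minimal_vcf(vcf)) == 1

    def test_missing_required_info_key_names_key(self, tmp_path):
        variants = self._one_sample_variants(1)
        vcf = tmp_path / "x.vcf"
        write_minimal_vcf(variants, vcf)
        lines = vcf.read_text().splitlines()
        fields = lines[-1].split("\t")
        fields[7] = ";".join(kv for kv in fields[7].split(";") if not kv.startswith("GENE="))
        lines[-1] = "\t".join(fields)
        vcf.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="GENE"):
            read_minimal_vcf(vcf)

    def test_header_only_vcf_is_empty(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        write_minimal_vcf(self._one_sample_variants(1), vcf)
        lines = [l for l in vcf.read_text().splitlines() if l.startswith("#")]
        vcf.write_text("\n".join(lines) + "\n")
        assert read_minimal_vcf(vcf) == []


class TestInvariants:
    def test_impact_must_match_consequence(self):
        with pytest.raises(ValidationError):
            AnnotatedVariant("P1", "VHL", "c.1del", Consequence.frameshift,
                             ImpactTier.MODERATE, {}, Zygosity.het)
        with pytest.raises(ValidationError):
            AnnotatedVariant("P1", "VHL", "c.1A>G", Consequence.missense,
                             ImpactTier.HIGH, {}, Zygosity.het)

    def test_control_with_tumour_fields_rejected(self):
        with pytest.raises(ValidationError):
            Participant("K1", Role.control, "female", age_at_diagnosis=50.0)

    def test_cohort_rejects_orphan_variant(self):
        v = AnnotatedVariant("GHOST", "VHL", "c.1A>G", Consequence.missense,
                             ImpactTier.MODERATE, {}, Zygosity.het)
        with pytest.raises(ValidationError, match="GHOST"):
            CohortTable([Participant("P1", Role.case, "male", age_at_diagnosis=60.0,
                                     n_rcc_tumours=1)], [v])

    def test_sv_breakpoints_must_be_ordered_on_one_chromosome(self):
        with pytest.raises(ValidationError):
            SVCall("P1", SvType.deletion, ("1", 500), ("2", 100))
        with pytest.raises(ValidationError):
            SVCall("P1", SvType.deletion, ("1", 500), ("1", 100))
        SVCall("P1", SvType.translocation, ("1", 500), ("2", 100))  # allowed
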