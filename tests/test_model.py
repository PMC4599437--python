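"""Domain-notation parsing, formatting, table IO and gene validation."""

import pytest
from hypothesis import given, settings, strategies as st

from bgcphylo.model import (
    DomainParseError,
    SchemaError,
    FINDING_SINGLE_DOMAIN,
    FINDING_UNUSUAL_ORDER,
    format_domain_string,
    load_cluster_table,
    parse_domain_notation,
    parse_domain_string,
    validate_gene,
)


class TestParse:
    def test_basic_module_string(self):
        tokens = parse_domain_string("C/A_asp/T-TE")
        assert [t.kind for t in tokens] == ["C", "A", "T", "TE"]
        a = tokens[1]
        assert a.substrate == "aspartate"
        assert a.substrate_confidence == "firm"
        # "-" group boundaries are hints, not tokens
        assert tokens[3].group_start and not tokens[2].group_start

    def test_single_domain(self):
        tokens = parse_domain_string("ACP")
        assert len(tokens) == 1 and tokens[0].kind == "ACP"

    def test_ambiguous_extender_set(self):
        tokens = parse_domain_string("KS/AT_e(m)/DH/KR/ACP")
        at = tokens[1]
        assert at.substrate == "ethylmalonyl"
        assert at.substrate_confidence == "ambiguous-set"
        assert set(at.ambiguous_set) == {"ethylmalonyl", "methylmalonyl"}

    def test_unordered_ambiguous_set_and_tentative(self):
        at = parse_domain_string("KS/AT_(m,e)/ACP")[1]
        assert at.substrate is None
        assert at.ambiguous_set == ("methylmalonyl", "ethylmalonyl")
        lys = parse_domain_string("C/A_(lys)/T")[1]
        assert lys.substrate == "lysine"
        assert lys.substrate_confidence == "tentative"

    def test_unknown_substrate_and_tentative_kind(self):
        at = parse_domain_string("KS/AT_?/DH/ACP")[1]
        assert at.substrate == "unknown"
        ks = parse_domain_string("(KS)/AT/ACP")[0]
        assert ks.kind == "KS" and ks.tentative_kind

    def test_truncation_marks_set_gene_flags(self):
        tokens, p_start, p_end = parse_domain_notation("...ACP-KS/AT...")
        assert p_start and p_end
        assert [t.kind for t in tokens] == ["ACP", "KS", "AT"]

    @pytest.mark.parametrize("bad", ["", "   ", "C//T", "QQ/T", "C/A_xyz/T"])
    def test_parse_errors(self, bad):
        with pytest.raises(DomainParseError):
            parse_domain_string(bad)

    def test_error_names_offending_symbol(self):
        with pytest.raises(DomainParseError, match="QQ"):
            parse_domain_string("C/QQ/T")

    def test_token_conservation(self):
        text = "A/MT/T-C/A_ser/T-C/A_orn/MT/T-C/A/T-C/A_ser/T-C/A/T/E"
        n_symbols = sum(len(g.split("/")) for g in text.split("-"))
        assert len(parse_domain_string(text)) == n_symbols


class TestFormat:
    def test_round_trip_simple(self):
        tokens = parse_domain_string("C/A_gly/T")
        assert format_domain_string(tokens) == "C/A_gly/T"

    def test_empty_input(self):
        with pytest.raises(ValueError):
            format_domain_string([])

    def test_round_trip_all_fixture_rows(self, inventories):
        for inv in inventories:
            for cluster in inv.clusters:
                for gene in cluster.genes:
                    text = gene.domain_string
                    tokens, ps, pe = parse_domain_notation(text)
                    assert tokens == gene.tokens
                    assert (ps, pe) == (gene.partial_start, gene.partial_end)
                    assert format_domain_string(tokens, ps, pe) == text


_domain_symbol = st.one_of(
    st.sampled_from(["C", "T", "E", "MT", "CoL", "KS", "DH", "ER", "KR",
                     "ACP", "TE", "(KS)"]),
    st.sampled_from(["A", "A_ser", "A_gly", "A_(lys)", "A_orn"]),
    st.sampled_from(["AT", "AT_m", "AT_e", "AT_?", "AT_(m)", "AT_e(m)",
                     "AT_(m,e)"]),
)


class TestRoundTripProperty:
    @settings(max_examples=200, derandomize=True)
    @given(
        groups=st.lists(st.lists(_domain_symbol, min_size=1, max_size=6),
                        min_size=1, max_size=6),
        p_start=st.booleans(),
        p_end=st.booleans(),
    )
    def test_parse_format_parse_identity(self, groups, p_start, p_end):
        text = "-".join("/".join(g) for g in groups)
        if p_start:
            text = "..." + text
        if p_end:
            text = text + "..."
        tokens, ps, pe = parse_domain_notation(text)
        assert (ps, pe) == (p_start, p_end)
        assert sum(len(g) for g in groups) == len(tokens)
        rendered = format_domain_string(tokens, ps, pe)
        tokens2, ps2, pe2 = parse_domain_notation(rendered)
        assert tokens2 == tokens and (ps2, pe2) == (ps, pe)


class TestTable:
    def test_fixture_loads_five_strains(self, inventories):
        assert len(inventories) == 5
        assert {inv.strain_id for inv in inventories} == {
            "H_cretacea", "H_mongoliensis", "H_yilanensis", "H_daliensis",
            "H_sakaeratensis",
        }

    def test_pks6_has_twelve_genes(self, by_strain):
        assert len(by_strain["H_cretacea"].cluster("pks-6").genes) == 12

    def test_substrate_vocabulary_is_closed(self, inventories):
        # every fixture annotation parses into the controlled vocabulary
        total = sum(len(c.genes) for inv in inventories for c in inv.clusters)
        assert total > 100

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(
            "strain\tcluster_id\torf_id\tlength_aa\tdomains\t"
            "homolog_accession\tidentity\tsimilarity\tflags\n"
        )
        assert load_cluster_table(p) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("strain\tcluster_id\n")
        with pytest.raises(SchemaError, match="missing"):
            load_cluster_table(p)

    def test_row_error_reports_row_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "strain\tcluster_id\torf_id\tlength_aa\tdomains\t"
            "homolog_accession\tidentity\tsimilarity\tflags\n"
            "s1\tc1\to1\t100\tC/WHAT/T\tACC1\t50\t60\t\n"
        )
        with pytest.raises(DomainParseError, match="row 2"):
            load_cluster_table(p)

    def test_partial_and_locus_flags(self, by_strain):
        pks11 = by_strain["H_sakaeratensis"].cluster("pks-11")
        orf1 = next(g for g in pks11.genes if g.orf_id == "s22-orf1")
        assert orf1.partial_end and orf1.length_is_lower_bound
        nrps2 = by_strain["H_cretacea"].cluster("nrps-2")
        assert nrps2.genes[0].outside_main_locus
        assert not nrps2.genes[1].outside_main_locus


class TestValidate:
    def test_findings(self, by_strain):
        gene = by_strain["H_sakaeratensis"].cluster("pks/nrps-4").genes[0]
        assert FINDING_SINGLE_DOMAIN in validate_gene(gene)  # lone ...ACP
        ct = by_strain["H_cretacea"].cluster("nrps-6").genes[0]  # C/T
        assert FINDING_SINGLE_DOMAIN not in validate_gene(ct)
        act = by_strain["H_sakaeratensis"].cluster("nrps-15").genes[0]
        assert FINDING_UNUSUAL_ORDER in validate_gene(act)  # A-C-T start

    def test_cluster_classes(self, by_strain):
        assert by_strain["H_cretacea"].cluster("nrps-1").cluster_class == "NRPS"
        assert by_strain["H_cretacea"].cluster("pks-6").cluster_class == "PKS"
        for strain, cid in [("H_cretacea", "pks/nrps-1"),
                            ("H_mongoliensis", "pks/nrps-2"),
                            ("H_sakaeratensis", "pks/nrps-4")]:
            assert by_strain[strain].cluster(cid).cluster_class == "hybrid"

    def test_table1_class_tallies(self, by_strain):
        expected = {
            "H_cretacea": (9, 1, 5), "H_mongoliensis": (9, 2, 6),
            "H_yilanensis": (9, 2, 4), "H_daliensis": (10, 1, 4),
            "H_sakaeratensis": (12, 2, 4),
        }
        for strain, (nrps, hybrid, pks) in expected.items():
            classes = [c.cluster_class for c in by_strain[strain].clusters]
            assert (classes.count("NRPS"), classes.count("hybrid"),
                    classes.count("PKS")) == (nrps, hybrid, pks)
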