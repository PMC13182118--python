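import pytest

from milkvar.errors import IntegrityError, RangeError
from milkvar.gene_models import GeneModel
from milkvar.haplotype_em import SiteInfo
from milkvar.protein_variants import (
    Catalog,
    Substitution,
    assign_name,
    format_substitutions,
    haplotype_to_substitutions,
    kappa_region,
    match_catalog,
    name_variants,
    parse_substitutions,
)


@pytest.fixture
def pepgene():
    """Forward single-exon gene, 8 codons, 2-residue signal peptide.

    CDS: ATG GCT GAT CCA AAA TTT GGG TAC -> MADPKFGY (mature DPKFGY).
    """
    cds = "ATGGCTGATCCAAAATTTGGGTAC"
    return GeneModel(
        name="PEP",
        chrom="1",
        start=1001,
        end=1024,
        strand="+",
        exons=[(1001, 1024)],
        cds_start=1001,
        cds_end=1024,
        signal_peptide_len=2,
        cds_sequence=cds,
        flank=100,
        reference_variant_name="A",
    )


def site(model, cds_offset, alt):
    pos = model.cds_to_genomic(cds_offset)
    return SiteInfo(model.chrom, pos, model.cds_sequence[cds_offset - 1], alt, cds_offset)


class TestHaplotypeToSubstitutions:
    def test_all_reference_haplotype_is_empty(self, pepgene):
        sites = [site(pepgene, 4, "C"), site(pepgene, 7, "A")]
        assert haplotype_to_substitutions(pepgene, "00", sites) == frozenset()

    def test_signal_peptide_changes_have_no_effect(self, pepgene):
        # codon 2 (GCT->CCT, Ala->Pro) is within the 2-residue signal peptide
        sites = [site(pepgene, 4, "C")]
        assert haplotype_to_substitutions(pepgene, "1", sites) == frozenset()

    def test_mature_position_arithmetic(self, pepgene):
        # codon 5 (AAA->GAA, Lys->Glu): precursor 5, mature 5-2=3
        sites = [site(pepgene, 13, "G")]
        subs = haplotype_to_substitutions(pepgene, "1", sites)
        assert subs == frozenset({Substitution(3, "K", "E")})

    def test_synonymous_alleles_excluded(self, pepgene):
        # codon 6 TTT->TTC both Phe
        sites = [site(pepgene, 18, "C")]
        assert haplotype_to_substitutions(pepgene, "1", sites) == frozenset()

    def test_two_snvs_in_one_codon_translated_jointly(self, pepgene):
        # codon 5 AAA: offset 13 A->T and offset 15 A->T jointly give TAT (Tyr);
        # singly they give Ser (TCA? no: TAA stop / AAT Asn) — joint result differs
        sites = [site(pepgene, 13, "T"), site(pepgene, 15, "T")]
        subs = haplotype_to_substitutions(pepgene, "11", sites)
        assert subs == frozenset({Substitution(3, "K", "Y")})

    def test_reference_mismatch_raises(self, pepgene):
        bad = SiteInfo("1", pepgene.cds_to_genomic(13), "C", "G", 13)
        with pytest.raises(IntegrityError):
            haplotype_to_substitutions(pepgene, "1", [bad])

    def test_reverse_strand_alleles_complemented(self, pepgene):
        rev = GeneModel(
            name="PEPR",
            chrom="1",
            start=1001,
            end=1024,
            strand="-",
            exons=[(1001, 1024)],
            cds_start=1001,
            cds_end=1024,
            signal_peptide_len=2,
            cds_sequence=pepgene.cds_sequence,
            flank=100,
            reference_variant_name="A",
        )
        off = 13  # AAA codon start; genomic base is complement 'T'
        pos = rev.cds_to_genomic(off)
        s = SiteInfo("1", pos, "T", "C", off)  # genomic T>C == transcribed A>G
        subs = haplotype_to_substitutions(rev, "1", [s])
        assert subs == frozenset({Substitution(3, "K", "E")})


def S(text):
    return parse_substitutions(text)


@pytest.fixture
def catalog():
    cat = Catalog()
    cat.add_gene("CSN3", "B")
    cat.add("CSN3", "A", S("136:T>I;148:A>D"))
    cat.add("CSN3", "A1", S("136:T>I"))
    cat.validate()
    return cat


class TestCatalogMatching:
    def test_empty_set_matches_reference(self, catalog):
        assert match_catalog(frozenset(), catalog, "CSN3") == ("B", "known")

    def test_exact_match(self, catalog):
        assert match_catalog(S("136:T>I"), catalog, "CSN3") == ("A1", "known")

    def test_no_match_is_novel(self, catalog):
        assert match_catalog(S("10:Q>R"), catalog, "CSN3") == (None, "novel")

    def test_tsv_round_trip_is_canonical(self, catalog, tmp_path):
        p1, p2 = tmp_path / "c1.tsv", tmp_path / "c2.tsv"
        catalog.to_tsv(p1)
        back = Catalog.from_tsv(p1)
        back.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert back.entries == catalog.entries


class TestHierarchicalNaming:
    def test_first_child_of_base(self, catalog):
        name = assign_name(S("136:T>I;97:R>H"), catalog, "CSN3")
        assert name == "A1.1"

    def test_second_child_increments(self, catalog):
        assign_name(S("136:T>I;97:R>H"), catalog, "CSN3")
        name = assign_name(S("136:T>I;155:S>G"), catalog, "CSN3")
        assert name == "A1.2"

    def test_layers_nest(self, catalog):
        assign_name(S("136:T>I;97:R>H"), catalog, "CSN3")  # -> A1.1
        name = assign_name(S("136:T>I;97:R>H;155:S>G"), catalog, "CSN3")
        assert name == "A1.1.1"

    def test_base_is_deepest_subset(self, catalog):
        # superset of A (2 subs) and A1 (1 sub): A wins on overlap
        name = assign_name(S("136:T>I;148:A>D;97:R>H"), catalog, "CSN3")
        assert name == "A.1"

    def test_tie_prefers_higher_occurrence_then_lexicographic(self):
        cat = Catalog()
        cat.add_gene("G", "R")
        cat.add("G", "X", S("5:A>V"))
        cat.add("G", "Y", S("9:L>F"))
        novel = S("5:A>V;9:L>F")
        assert assign_name(novel, cat.copy(), "G", {"X": 3, "Y": 10}) == "Y.1"
        assert assign_name(novel, cat.copy(), "G", {"X": 10, "Y": 3}) == "X.1"
        assert assign_name(novel, cat.copy(), "G", {}) == "X.1"

    def test_dotted_names_are_strict_supersets_of_base(self, catalog):
        assign_name(S("136:T>I;97:R>H"), catalog, "CSN3")
        assign_name(S("136:T>I;97:R>H;155:S>G"), catalog, "CSN3")
        for name, subs in catalog.entries["CSN3"].items():
            if "." in name:
                base = name.rsplit(".", 1)[0]
                assert catalog.entries["CSN3"][base] < subs


class TestNameVariants:
    def test_processing_order_and_determinism(self, catalog):
        hap_subs = {
            "100": S("136:T>I"),
            "010": S("97:R>H;136:T>I"),
            "001": S("155:S>G;136:T>I"),
        }
        occ = {"100": 40, "010": 10, "001": 30}
        out1 = name_variants("CSN3", hap_subs, occ, catalog.copy())
        out2 = name_variants("CSN3", hap_subs, occ, catalog.copy())
        names1 = {format_substitutions(v.substitutions): v.name for v in out1}
        assert names1[format_substitutions(S("155:S>G;136:T>I"))] == "A1.1"  # more copies first
        assert names1[format_substitutions(S("97:R>H;136:T>I"))] == "A1.2"
        assert [(v.name, v.status, v.occurrences) for v in out1] == [
            (v.name, v.status, v.occurrences) for v in out2
        ]

    def test_sub_threshold_novel_flagged_unconfirmed(self, catalog):
        hap_subs = {"1": S("97:R>H"), "2": S("155:S>G")}
        out = name_variants(
            "CSN3", hap_subs, {"1": 1, "2": 5}, catalog.copy(), carriers={"1": 1, "2": 3}
        )
        by_name = {v.name: v for v in out}
        rare = [v for v in out if v.occurrences == 1][0]
        common = [v for v in out if v.occurrences == 5][0]
        assert rare.unconfirmed and not common.unconfirmed


class TestKappaRegion:
    @pytest.mark.parametrize(
        "pos,label",
        [
            (50, "para_kappa"),
            (95, "para_kappa"),
            (105, "chymosin_site"),
            (106, "chymosin_site"),
            (113, "cmp"),
            (149, "cmp"),
            (169, "cmp"),
            (100, "other"),
            (110, "other"),
        ],
    )
    def test_region_intervals(self, pos, label):
        assert kappa_region(pos) == label

    def test_substitution_accepted(self):
        assert kappa_region(Substitution(149, "S", "F")) == "cmp"

    def test_out_of_range(self):
        with pytest.raises(RangeError):
            kappa_region(170)
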