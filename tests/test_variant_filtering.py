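import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from milkvar.errors import PanelError
from milkvar.synthetic_data import filter_fixture_records
from milkvar.variant_filtering import (
    MISSING,
    SamplePanel,
    SequenceVariant,
    apply_filters,
    flag_low_depth,
    label_novelty,
    read_vcf,
    write_vcf,
)


def make_variant(
    qual=50.0,
    mq=60.0,
    genotypes=((0, 1), (0, 1), (0, 0)),
    alt_depths=(4, 4, 0),
    depths=(10, 10, 10),
    pos=100,
):
    return SequenceVariant(
        chrom="6",
        pos=pos,
        id=None,
        ref="A",
        alt="G",
        qual=qual,
        mq=mq,
        genotypes=[tuple(g) for g in genotypes],
        alt_depths=np.array(alt_depths),
        depths=np.array(depths),
    )


class TestApplyFilters:
    def test_qual_boundary_is_strict(self):
        res = apply_filters([make_variant(qual=19.9), make_variant(qual=20.0)])
        assert len(res.kept) == 1
        assert res.removed[0][1] == ("qual",)

    def test_single_carrier_removed(self):
        v = make_variant(genotypes=[(1, 1), (0, 0), (0, 0)], alt_depths=(8, 0, 0))
        res = apply_filters([v])
        assert res.removed[0][1] == ("carriers",)

    def test_alt_read_total_is_cohort_wide(self):
        v = make_variant(alt_depths=(1, 1, 0))  # 2 < 3 in total
        assert apply_filters([v]).removed[0][1] == ("alt_reads",)
        assert apply_filters([v], per_sample_reads=True).removed[0][1] == ("alt_reads",)
        v2 = make_variant(alt_depths=(2, 1, 0))
        assert apply_filters([v2]).kept == [v2]

    def test_missing_ad_passes_and_is_logged(self):
        v = make_variant()
        v.alt_depths = None
        res = apply_filters([v])
        assert res.kept == [v] and res.n_missing_ad == 1

    def test_missing_genotypes_do_not_count_as_carriers(self):
        v = make_variant(genotypes=[(MISSING, MISSING), (0, 1), (0, 0)])
        assert apply_filters([v]).removed[0][1] == ("carriers",)

    def test_partition_invariant(self):
        vs = [make_variant(qual=q, pos=100 + i) for i, q in enumerate((10, 30, 50))]
        res = apply_filters(vs)
        assert len(res.kept) + len(res.removed) == len(vs)
        assert {id(v) for v in res.kept}.isdisjoint({id(v) for v, _ in res.removed})

    @given(
        dq=st.floats(0, 40),
        dmq=st.floats(0, 40),
        dreads=st.integers(0, 10),
        dcarriers=st.integers(0, 3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_filters_are_monotone_in_thresholds(self, dq, dmq, dreads, dcarriers):
        """Raising any threshold never grows the kept set."""
        vs = [
            make_variant(qual=25, mq=25, alt_depths=(2, 2, 0), pos=1),
            make_variant(qual=35, mq=45, alt_depths=(5, 1, 0), pos=2),
            make_variant(genotypes=[(1, 1), (0, 0), (0, 0)], alt_depths=(9, 0, 0), pos=3),
        ]
        base = {v.key for v in apply_filters(vs).kept}
        tight = {
            v.key
            for v in apply_filters(
                vs,
                min_alt_reads=3 + dreads,
                min_qual=20 + dq,
                min_mq=20 + dmq,
                min_carriers=2 + dcarriers,
            ).kept
        }
        assert tight <= base


class TestFiveVariantFixture:
    def test_exactly_the_hand_computed_set_passes(self, milk_models, tmp_path):
        samples, records, kept_keys = filter_fixture_records(milk_models)
        path = tmp_path / "fixture.vcf"
        write_vcf(path, samples, records, [milk_models["CSN3"].chrom])
        panel = SamplePanel(samples, {s: "Breed" for s in samples})
        variants, stats = read_vcf(path, panel, list(milk_models.values()))
        assert stats.n_kept == 5
        res = apply_filters(variants)
        assert [v.key for v in res.kept] == kept_keys
        reasons = {v.key: r for v, r in res.removed}
        assert any("qual" in r for r in reasons.values())
        assert any("carriers" in r for r in reasons.values())


class TestFlagLowDepth:
    def test_uniform_depth_no_flags(self):
        (d,) = flag_low_depth([make_variant(depths=(10, 10, 10))])
        assert d.n_flagged == 0 and d.mean_depth == 10

    def test_threshold_is_strict_less_than(self):
        (d,) = flag_low_depth([make_variant(depths=(4, 6, 8, 10), genotypes=[(0, 1)] * 4, alt_depths=(2, 2, 2, 2))])
        assert d.mean_depth == 7 and d.n_flagged == 1
        assert list(d.low_confidence) == [True, False, False, False]

    def test_single_low_sample(self):
        (d,) = flag_low_depth([make_variant(depths=(5, 10, 10))])
        assert d.n_flagged == 1


class TestNovelty:
    def test_labels(self):
        v1 = make_variant(pos=1)
        v1.id = "rs123"
        v2 = make_variant(pos=2)
        v3 = make_variant(pos=3)
        known = {"rs123", "6:2:A:G"}
        assert label_novelty([v1, v2, v3], known) == ["known", "known", "novel"]

    def test_counts_on_fixture(self):
        vs = [make_variant(pos=p) for p in range(1, 6)]
        known = {f"6:{p}:A:G" for p in (1, 2, 3)}
        labels = label_novelty(vs, known)
        assert labels.count("known") == 3 and labels.count("novel") == 2


class TestReadVcf:
    def test_region_restriction_decomposition_and_indel_skip(self, milk_models, tmp_path):
        m = milk_models["CSN3"]
        samples = ["S1", "S2"]
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={m.chrom}>",
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="x">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2",
            # outside any gene window
            f"{m.chrom}\t1000\t.\tA\tG\t50\tPASS\tMQ=60\tGT\t0/1\t0/0",
            # triallelic SNV -> two biallelic records
            f"{m.chrom}\t{m.start + 100}\t.\tA\tC,T\t50\tPASS\tMQ=60\tGT\t1/2\t0/1",
            # indel -> skipped
            f"{m.chrom}\t{m.start + 200}\t.\tAT\tA\t50\tPASS\tMQ=60\tGT\t0/1\t0/0",
        ]
        path = tmp_path / "in.vcf"
        path.write_text("\n".join(lines) + "\n")
        panel = SamplePanel(samples, {s: "B" for s in samples})
        variants, stats = read_vcf(path, panel, [m])
        assert stats.n_outside == 1 and stats.n_skipped_indel == 1
        assert [v.alt for v in variants] == ["C", "T"]
        # sample 1 is C/T: C-view sees one alt allele, T-view one alt allele
        assert variants[0].genotypes[0] == (1, 0)
        assert variants[1].genotypes[0] == (0, 1)

    def test_sample_mismatch_raises(self, milk_models, tmp_path):
        m = milk_models["CSN3"]
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1",
            f"{m.chrom}\t{m.start}\t.\tA\tG\t50\tPASS\t.\tGT\t0/1",
        ]
        path = tmp_path / "in.vcf"
        path.write_text("\n".join(lines) + "\n")
        panel = SamplePanel(["S1", "S2"], {"S1": "B", "S2": "B"})
        with pytest.raises(PanelError):
            read_vcf(path, panel, [m])

    def test_round_trip_through_writer(self, milk_models, tmp_path):
        samples, records, _ = filter_fixture_records(milk_models)
        path = tmp_path / "rt.vcf"
        write_vcf(path, samples, records, [milk_models["CSN3"].chrom])
        panel = SamplePanel(samples, {s: "B" for s in samples})
        variants, _ = read_vcf(path, panel, list(milk_models.values()))
        for rec, v in zip(records, variants):
            assert (v.chrom, v.pos, v.ref, v.alt) == (rec["chrom"], rec["pos"], rec["ref"], rec["alt"])
            assert v.genotypes == [tuple(g) for g in rec["genotypes"]]
            assert np.array_equal(v.alt_depths, rec["alt_depths"])
            assert v.qual == pytest.approx(rec["qual"])
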