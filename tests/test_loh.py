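"""Informative-SNP selection, deviation segmentation, LOH mechanism calls."""

import numpy as np
import pytest

from oncopanel.cnv import CnSegment
from oncopanel.loh import (
    HetVariant,
    call_imbalance,
    classify_loh,
    deviation_series,
    paired_shift,
    select_informative,
)
from oncopanel.simulate import expected_vaf

from conftest import make_variant


class TestSelectInformative:
    def test_informative_het_kept(self):
        kept = select_informative([make_variant(population_af=0.2, depth=100, vaf=0.45)])
        assert len(kept) == 1

    def test_depth_bound_is_strict(self):
        assert select_informative([make_variant(depth=30)]) == []
        assert len(select_informative([make_variant(depth=31)])) == 1

    def test_population_af_open_interval(self):
        assert select_informative([make_variant(population_af=0.0001)]) == []
        assert select_informative([make_variant(population_af=0.95)]) == []
        assert select_informative([make_variant(population_af=0.00005)]) == []
        assert len(select_informative([make_variant(population_af=0.5)])) == 1

    def test_homozygous_excluded_unless_disabled(self):
        hom = make_variant(vaf=0.99)
        assert select_informative([hom]) == []
        assert len(select_informative([hom], hom_cutoffs=None)) == 1

    def test_sorted_by_position(self):
        vs = [make_variant(pos=500), make_variant(pos=100)]
        kept = select_informative(vs)
        assert [h.pos for h in kept] == [100, 500]


class TestDeviationSeries:
    def test_half_vaf_gives_zero(self):
        assert deviation_series([HetVariant("chr1", 1, 0.5, 100, 0.2)])[0] == 0.0

    def test_allele_swap_symmetry(self):
        d1 = deviation_series([HetVariant("chr1", 1, 0.2, 100, 0.2)])[0]
        d2 = deviation_series([HetVariant("chr1", 1, 0.8, 100, 0.2)])[0]
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert d1 == pytest.approx(0.3)

    def test_boundary_hom_vaf(self):
        assert deviation_series([HetVariant("chr1", 1, 1.0, 100, 0.2)])[0] == 0.5


def _hets(devs, chrom="chr1", start=1000, spacing=1000):
    return [
        HetVariant(chrom, start + i * spacing, 0.5 + d, 150, 0.2)
        for i, d in enumerate(devs)
    ]


class TestCallImbalance:
    def test_balanced_chromosome_single_unaltered_segment(self):
        segs = call_imbalance(_hets([0.02] * 40), seed=0)
        assert len(segs) == 1 and not segs[0].imbalance

    def test_uniform_high_deviation_flagged(self):
        segs = call_imbalance(_hets([0.30] * 40), seed=0)
        assert len(segs) == 1 and segs[0].imbalance

    def test_noise_free_cnloh_block_recovered_exactly(self):
        devs = [0.0] * 15 + [0.5] * 10 + [0.0] * 15
        segs = call_imbalance(_hets(devs), seed=0)
        assert [s.n_variants for s in segs] == [15, 10, 15]
        assert [s.imbalance for s in segs] == [False, True, False]

    def test_too_few_variants_low_confidence_single_segment(self):
        segs = call_imbalance(_hets([0.4, 0.4]), min_bins=3, seed=0)
        assert len(segs) == 1 and segs[0].low_confidence and segs[0].imbalance

    def test_median_statistic_option(self):
        devs = [0.0] * 30 + [0.49]  # one outlier cannot trip the median
        segs = call_imbalance(_hets(devs), statistic="median", seed=0)
        assert all(not s.imbalance for s in segs)


class TestPairedShift:
    def test_identical_tables_no_support(self):
        tumor = [make_variant(pos=i * 100, vaf=0.5) for i in range(20)]
        normal = [make_variant(pos=i * 100, vaf=0.5, sample="n") for i in range(20)]
        segs = call_imbalance(select_informative(tumor), seed=0)
        shifts, segs = paired_shift(normal, tumor, segs)
        assert all(v == 0.0 for v in shifts.values())
        assert all(s.paired_support is False for s in segs)

    def test_shift_magnitude(self):
        tumor = [make_variant(pos=100, vaf=0.9)]
        normal = [make_variant(pos=100, vaf=0.5, sample="n")]
        shifts, _ = paired_shift(normal, tumor, [])
        assert list(shifts.values()) == [pytest.approx(0.4)]

    def test_tumor_only_mode_support_absent(self):
        tumor = [make_variant(pos=i * 100, vaf=0.8) for i in range(10)]
        segs = call_imbalance(select_informative(tumor), seed=0)
        assert all(s.paired_support is None for s in segs)

    def test_no_shared_loci_leaves_segments_unchanged(self):
        tumor = [make_variant(pos=100, vaf=0.8)]
        normal = [make_variant(pos=999, vaf=0.5, sample="n")]
        segs = call_imbalance(select_informative(tumor), seed=0)
        _, segs = paired_shift(normal, tumor, segs)
        assert all(s.paired_support is None for s in segs)


def _dev_segment(imbalance, chrom="chr1", start=0, end=10_000, dev=0.3):
    from oncopanel.loh import DevSegment

    return DevSegment(chrom, start, end, 20, dev if imbalance else 0.02, imbalance)


def _cn(copy_number, chrom="chr1", start=0, end=10_000, n_bins=25):
    return CnSegment(chrom, start, end, n_bins, 0.0, copy_number, None)


class TestClassifyLoh:
    @pytest.mark.parametrize(
        "cn,mech",
        [(2, "cnloh"), (1, "deletion_loh"), (0, "deletion_loh"), (3, "imbalanced_gain")],
    )
    def test_mechanism_rule_table(self, cn, mech):
        calls = classify_loh([_dev_segment(True)], [_cn(cn)])
        assert calls[0].mechanism == mech

    def test_balanced_stays_none_even_with_copy_loss(self):
        calls = classify_loh([_dev_segment(False)], [_cn(1)])
        assert calls[0].mechanism == "none"

    def test_missing_copy_number_reported_unknown(self):
        calls = classify_loh([_dev_segment(True)], [])
        assert calls[0].mechanism == "unknown_copy_state"

    def test_majority_state_resolves_ambiguous_overlap(self):
        cn_segs = [_cn(2, end=8_000, n_bins=20), _cn(1, start=8_000, end=10_000, n_bins=5)]
        calls = classify_loh([_dev_segment(True)], cn_segs)
        assert calls[0].mechanism == "cnloh"


class TestDetectionThreshold:
    """Expected deviation at CN-LOH is purity/2; with the 0.15 rule the
    event is detectable from roughly purity 0.3 upward."""

    def _simulate(self, purity, rng, n_snp=25, depth=150):
        variants = []
        pos = 0
        for block in (1, 2, 1):  # balanced | cnloh | balanced
            for _ in range(n_snp):
                pos += int(rng.integers(500, 1500))
                mult = 1 if block == 1 else int(rng.choice([0, 2]))
                ev = expected_vaf(purity, 2, mult, 1)
                d = int(rng.poisson(depth))
                variants.append(
                    make_variant(pos=pos, vaf=0, depth=d, population_af=0.2)
                )
                variants[-1].alt_count = int(rng.binomial(d, ev))
        return variants

    @pytest.mark.parametrize("purity,lo,hi", [(0.5, 0.9, 1.0), (0.2, 0.0, 0.1)])
    def test_detection_rate_vs_purity(self, purity, lo, hi):
        rng = np.random.default_rng(17)
        detected = 0
        n_rep = 30
        for _ in range(n_rep):
            vs = self._simulate(purity, rng)
            mid = (vs[25].pos, vs[49].pos)
            hets = select_informative(vs)
            segs = call_imbalance(hets, rng=rng)
            votes = [
                s.imbalance
                for h in hets
                if mid[0] <= h.pos <= mid[1]
                for s in segs
                if s.chromosome == h.chromosome and s.start <= h.pos < s.end
            ]
            if votes and np.mean(votes) >= 0.5:
                detected += 1
        assert lo <= detected / n_rep <= hi

    def test_tumor_only_and_paired_agree_on_imbalance_flags(self):
        rng = np.random.default_rng(23)
        vs = self._simulate(0.5, rng)
        hets = select_informative(vs)
        tumor_only = call_imbalance(hets, seed=1)
        paired = call_imbalance(hets, seed=1)
        normal = [make_variant(pos=v.pos, vaf=0.5, sample="n") for v in vs]
        paired_shift(normal, vs, paired)
        assert [s.imbalance for s in tumor_only] == [s.imbalance for s in paired]
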