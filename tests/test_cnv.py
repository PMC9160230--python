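"""Coverage reference model, log2 ratios, recentering, copy states."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oncopanel.cnv import (
    CnSegment,
    CopyStateThresholds,
    STATES,
    build_reference,
    call_copy_number,
    classify_copy_state,
    estimate_copies,
    log2_ratios,
    recenter,
)
from oncopanel.simulate import SimConfig, default_panel, generate_cohort, simulate_normal_coverage


def _cov(depths, chrom="chr1"):
    n = len(depths)
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "start": np.arange(n) * 400,
            "end": (np.arange(n) + 1) * 400,
            "gene": "G",
            "depth": depths,
        }
    )


class TestReference:
    def test_single_normal_reference_is_its_normalized_depths(self):
        ref = build_reference([_cov([10, 20, 30, 40])])
        expected = np.array([10, 20, 30, 40]) / 25.0
        assert np.allclose(ref.bins["location"], expected)

    def test_location_is_per_bin_median(self):
        # equal sample totals, so normalization scaling is common
        n1 = _cov([10, 190])
        n2 = _cov([20, 180])
        n3 = _cov([90, 110])
        ref = build_reference([n1, n2, n3])
        assert ref.bins["location"].iloc[0] * 100.0 == pytest.approx(20.0)

    def test_low_depth_bin_flagged_unreliable(self):
        ref = build_reference([_cov([0, 100, 100, 100])])
        assert not ref.bins["reliable"].iloc[0]
        assert ref.bins["reliable"].iloc[1:].all()

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError, match="grid"):
            build_reference([_cov([1, 2]), _cov([1, 2, 3])])

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="zero total depth"):
            build_reference([_cov([0, 0, 0])])


class TestLog2Ratios:
    def test_sample_equal_to_reference_gives_zero(self):
        normals = [_cov([50, 100, 150, 200])]
        ref = build_reference(normals)
        out = log2_ratios(normals[0], ref)
        assert np.allclose(out["log2_ratio"], 0.0, atol=1e-12)

    def test_global_scaling_removed(self):
        base = [50, 100, 150, 200]
        ref = build_reference([_cov(base)])
        out = log2_ratios(_cov([2 * d for d in base]), ref)
        assert np.allclose(out["log2_ratio"], 0.0, atol=1e-12)

    def test_isolated_doubled_bin_reads_plus_one(self):
        base = [100] * 20
        ref = build_reference([_cov(base)])
        sample = base.copy()
        sample[7] = 200
        out = log2_ratios(_cov(sample), ref)
        # median centering shifts everything slightly; the doubled bin
        # stands ~1 above its neighbours
        vals = out["log2_ratio"].to_numpy()
        assert vals[7] - np.median(np.delete(vals, 7)) == pytest.approx(1.0, abs=1e-6)

    def test_unreliable_bins_excluded(self):
        ref = build_reference([_cov([0, 100, 100, 100])])
        out = log2_ratios(_cov([50, 100, 100, 100]), ref)
        assert len(out) == 3


class TestEstimateCopies:
    @pytest.mark.parametrize(
        "mean_log2,purity,expected",
        [
            (0.0, None, 2),
            (1.0, None, 4),
            (-1.0, 0.5, 0),
            (np.log2(3 / 2), None, 3),
            (-1.0, None, 1),
        ],
    )
    def test_known_values(self, mean_log2, purity, expected):
        assert estimate_copies(mean_log2, purity) == expected

    def test_half_rounds_away_from_zero(self):
        # 2*2^x = 2.5 at x = log2(1.25)
        assert estimate_copies(np.log2(1.25)) == 3

    def test_zero_purity_errors(self):
        with pytest.raises(ValueError):
            estimate_copies(0.0, 0.0)

    def test_purity_inversion_recovers_truth(self):
        for cn in range(0, 9):
            for p in (0.3, 0.6, 0.9, 1.0):
                ratio = (p * cn + (1 - p) * 2) / 2
                assert estimate_copies(np.log2(max(ratio, 1e-9)), p) == cn


class TestCopyState:
    @pytest.mark.parametrize(
        "cn,state",
        [(0, "deep_deletion"), (1, "shallow_deletion"), (2, "neutral"),
         (3, "gain"), (4, "gain"), (5, "amplification"), (12, "amplification")],
    )
    def test_default_classes(self, cn, state):
        assert classify_copy_state(cn) == state

    @given(st.integers(0, 30), st.integers(0, 30))
    def test_monotone_in_copy_number(self, c1, c2):
        lo, hi = sorted((c1, c2))
        assert STATES.index(classify_copy_state(lo)) <= STATES.index(
            classify_copy_state(hi)
        )

    def test_configurable_thresholds(self):
        t = CopyStateThresholds(gain_max=5)
        assert classify_copy_state(5, t) == "gain"


class TestRecenter:
    def _segments(self, means, n_bins=10):
        return [
            CnSegment("chr1", i * 4000, (i + 1) * 4000, n_bins, m)
            for i, m in enumerate(means)
        ]

    def test_zero_shift_is_identity(self):
        segs = recenter(self._segments([0.0, 1.0, 0.0]), shift=0.0)
        assert [s.mean_log2 for s in segs] == [0.0, 1.0, 0.0]

    def test_auto_restores_modal_class_to_zero(self):
        segs = recenter(self._segments([0.3, 0.3, 0.3, 1.3]), shift="auto")
        assert [round(s.mean_log2, 9) for s in segs] == [0.0, 0.0, 0.0, 1.0]
        assert segs[0].copy_number == 2

    def test_auto_recenter_is_idempotent(self):
        once = recenter(self._segments([0.42, 0.40, 0.44, 1.4, -0.6]), shift="auto")
        twice = recenter(once, shift="auto")
        assert [s.mean_log2 for s in once] == pytest.approx(
            [s.mean_log2 for s in twice], abs=1e-12
        )


class TestEndToEnd:
    def test_noise_free_copy_numbers_match_truth(self):
        cfg = SimConfig(n_samples=5, n_paired=0, seed=13).noise_free()
        truths, bundle = generate_cohort(cfg)
        for t, s in zip(truths, bundle.samples):
            segs = call_copy_number(s.coverage, purity=1.0, seed=0)
            seg_by_gene = {g.gene: g for g in t.segments}
            for gene in bundle.panel.genes:
                chrom, lo, hi = bundle.panel.gene_interval(gene)
                overlapping = [
                    x for x in segs
                    if x.chromosome == chrom and x.start < hi and x.end > lo
                ]
                assert overlapping
                want = seg_by_gene[gene].total_copies
                # every overlapping called segment agrees (noise-free)
                for x in overlapping:
                    assert x.copy_number == want

    def test_segments_partition_and_weighted_mean_is_series_mean(self):
        panel = default_panel()
        normals = simulate_normal_coverage(panel, 4, seed=1)
        ref = build_reference(normals)
        tumor = simulate_normal_coverage(panel, 5, seed=2)[4]
        cov = log2_ratios(tumor, ref)
        segs = call_copy_number(cov, seed=3)
        for chrom, sub in cov.groupby("chromosome"):
            csegs = [s for s in segs if s.chromosome == chrom]
            assert sum(s.n_bins for s in csegs) == len(sub)
            weighted = sum(s.n_bins * s.mean_log2 for s in csegs) / len(sub)
            assert weighted == pytest.approx(sub["log2_ratio"].mean(), abs=1e-9)
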