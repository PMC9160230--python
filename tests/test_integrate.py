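"""Gene-level integration: mechanism labels, multiplicity, cohort matrix."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oncopanel.filtering import GeneMutationSummary
from oncopanel.integrate import (
    BIALLELIC_MECHANISMS,
    MECHANISMS,
    build_matrix,
    integrate_gene_sample,
    mechanism_label,
    multiplicity_estimate,
    truth_alterations,
)
from oncopanel.simulate import SimConfig, generate_cohort

from conftest import make_variant


class TestMultiplicity:
    @pytest.mark.parametrize(
        "vaf,cn,purity,expected",
        [(0.5, 2, 1.0, 1.0), (1.0, 2, 1.0, 2.0), (0.25, 4, 0.5, 1.5)],
    )
    def test_known_values(self, vaf, cn, purity, expected):
        assert multiplicity_estimate(vaf, cn, purity) == pytest.approx(expected)

    def test_zero_purity_errors(self):
        with pytest.raises(ValueError):
            multiplicity_estimate(0.5, 2, 0.0)


def _summary(n_mut, vaf=0.4, gene="G"):
    s = GeneMutationSummary(gene, "s1")
    for i in range(n_mut):
        v = make_variant(pos=i, gene=gene, consequence="nonsense", vaf=vaf)
        v.pathogenicity = "pathogenic"
        s.mutations.append(v)
    return s


class TestMechanismLabel:
    @pytest.mark.parametrize(
        "n_mut,state,loh,mult,cn,label,biallelic",
        [
            (0, "deep_deletion", "none", None, 0, "deep_deletion", True),
            (2, "neutral", "none", None, 2, "multiple_mutations", True),
            (1, "shallow_deletion", "deletion_loh", None, 1, "mutation_plus_deletion", True),
            (1, "neutral", "cnloh", None, 2, "mutation_plus_cnloh", True),
            (1, "gain", "none", 2.7, 3, "mutant_allele_amplified", True),
            (0, "amplification", "none", None, 7, "amplification", False),
            (1, "neutral", "none", 1.0, 2, "single_hit", False),
            (0, "neutral", "none", None, 2, "none", False),
            (1, "amplification", "none", 1.0, 6, "single_hit", False),
        ],
    )
    def test_priority_table(self, n_mut, state, loh, mult, cn, label, biallelic):
        assert mechanism_label(n_mut, state, loh, mult, cn) == (label, biallelic)

    @given(
        n_mut=st.integers(0, 3),
        state=st.sampled_from(
            ["deep_deletion", "shallow_deletion", "neutral", "gain", "amplification"]
        ),
        loh=st.sampled_from(["none", "cnloh", "deletion_loh", "imbalanced_gain"]),
        mult=st.one_of(st.none(), st.floats(0, 8)),
        cn=st.integers(0, 10),
    )
    def test_total_and_biallelic_consistent(self, n_mut, state, loh, mult, cn):
        label, biallelic = mechanism_label(n_mut, state, loh, mult, cn)
        assert label in MECHANISMS
        assert biallelic == (label in BIALLELIC_MECHANISMS)

    @given(
        n_mut=st.integers(0, 3),
        state=st.sampled_from(["shallow_deletion", "neutral", "gain"]),
        loh=st.sampled_from(["cnloh", "deletion_loh", "imbalanced_gain"]),
        cn=st.integers(0, 10),
    )
    def test_removing_loh_never_promotes(self, n_mut, state, loh, cn):
        with_loh = mechanism_label(n_mut, state, loh, None, cn)
        without = mechanism_label(n_mut, state, "none", None, cn)
        order = {m: i for i, m in enumerate(MECHANISMS)}
        assert order[with_loh[0]] <= order[without[0]] or with_loh == without
        assert with_loh[1] or not without[1]  # biallelic can only be lost


class TestIntegrateGeneSample:
    def test_mutation_plus_cnloh_biallelic(self):
        alt = integrate_gene_sample("TP53", "s1", _summary(1), 2, "neutral", "cnloh", 0.8)
        assert alt.mechanism_label == "mutation_plus_cnloh" and alt.biallelic

    def test_deep_deletion_biallelic_without_mutation(self):
        alt = integrate_gene_sample("CDKN2A", "s1", None, 0, "deep_deletion", "none", 0.8)
        assert alt.mechanism_label == "deep_deletion" and alt.biallelic

    def test_mutant_allele_amplification_from_high_vaf(self):
        alt = integrate_gene_sample("G", "s1", _summary(1, vaf=0.9), 3, "gain", "none", 1.0)
        assert alt.multiplicity == pytest.approx(2.7)
        assert alt.mechanism_label == "mutant_allele_amplified"

    def test_unknown_purity_marks_putative(self):
        alt = integrate_gene_sample("G", "s1", _summary(1, vaf=0.9), 3, "gain", "none", None)
        assert alt.putative

    def test_contradictory_deep_deletion_with_mutation_flagged(self):
        alt = integrate_gene_sample("G", "s1", _summary(1, vaf=0.5), 0,
                                    "deep_deletion", "none", 0.8)
        assert alt.inconsistent and alt.mechanism_label == "deep_deletion"


class TestBuildMatrix:
    def test_frequency_arithmetic(self):
        alts = []
        for i in range(48):
            alts.append(
                integrate_gene_sample(
                    "TP53", f"s{i}", _summary(1) if i < 10 else None,
                    2, "neutral", "none", 1.0,
                )
            )
        m = build_matrix(alts)
        assert m.frequencies["TP53"] == pytest.approx(10 / 48)

    def test_duplicate_record_errors(self):
        a = integrate_gene_sample("G", "s1", None, 2, "neutral", "none", 1.0)
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix([a, a])

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            build_matrix([])


def test_truth_matrix_consistent_with_truth_bookkeeping():
    truths, _ = generate_cohort(SimConfig(n_samples=6, n_paired=2, seed=2))
    alts = truth_alterations(truths)
    m = build_matrix(alts)
    assert set(m.samples) == {t.sample_id for t in truths}
    # a deep deletion in truth must surface as the deep_deletion label
    for t in truths:
        for seg in t.segments:
            if seg.total_copies == 0:
                assert m.labels.loc[seg.gene, t.sample_id] == "deep_deletion"
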