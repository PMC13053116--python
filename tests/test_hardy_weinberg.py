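"""Aggregate-frequency arithmetic, Hardy-Weinberg identities, formatting.

Independent oracles: plain double loops for the aggregate sums, and the
ordered-pair genotype sum sum_i sum_j q_i q_j for the prevalence square.
"""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoprev.hardy_weinberg import (
    ALL_GROUPS,
    ANCESTRY_GROUPS,
    GroupFrequency,
    ModelError,
    aggregate_allele_frequency,
    carrier_frequency,
    estimate_all_groups,
    format_one_in,
    format_percent,
    genetic_prevalence,
    group_af,
    homozygote_frequency,
    one_in_denominator,
)
from genoprev.ingest import AssertedClass, CandidateVariant, Source, SourceRecord
from genoprev.triage import (
    ClassifiedVariant,
    FinalClass,
    TriageDecision,
    TriagePath,
)
from genoprev.variants import VariantKey


def make_variant(pos, freqs: dict[str, tuple[int, int]]):
    key = VariantKey("chr3", pos, "A", "G")
    return ClassifiedVariant(
        candidate=CandidateVariant(
            key=key,
            provenance=(
                SourceRecord(key=key, source=Source.CLINVAR, asserted_class=AssertedClass.LP),
            ),
            frequencies={
                g: GroupFrequency(g, ac, an) for g, (ac, an) in freqs.items()
            },
        ),
        final_class=FinalClass.LP,
        triage=TriageDecision(TriagePath.ABBREVIATED),
    )


def random_variant_set(seed, n=50):
    rng = random.Random(seed)
    out = []
    for i in range(n):
        freqs = {}
        for g in ANCESTRY_GROUPS:
            an = rng.choice([0, 10_000, 50_000, 200_000])
            if an:
                freqs[g] = (rng.randrange(0, an // 100), an)
        out.append(make_variant(100 + i, freqs))
    return out


class TestGroupFrequency:
    def test_ac_above_an_rejected(self):
        with pytest.raises(ModelError):
            GroupFrequency("nfe", 11, 10)

    def test_homozygotes_bounded_by_ac(self):
        with pytest.raises(ModelError):
            GroupFrequency("nfe", 3, 100, nhomalt=2)


class TestAggregate:
    def test_empty_list_is_zero(self):
        assert aggregate_allele_frequency([], "nfe") == 0.0

    def test_linearity_two_variants(self):
        vs = [
            make_variant(100, {"nfe": (10, 10_000)}),
            make_variant(101, {"nfe": (20, 10_000)}),
        ]
        assert aggregate_allele_frequency(vs, "nfe") == pytest.approx(0.003)

    def test_matches_double_loop_oracle(self):
        vs = random_variant_set(seed=11)
        for g in ANCESTRY_GROUPS:
            expected = 0.0
            for v in vs:  # independent summation
                f = v.candidate.frequencies.get(g)
                if f is not None and f.an > 0:
                    expected += f.ac / f.an
            assert aggregate_allele_frequency(vs, g) == pytest.approx(
                expected, rel=1e-12
            )

    def test_pooled_all_uses_summed_counts(self):
        v = make_variant(100, {"nfe": (10, 10_000), "asj": (90, 10_000)})
        assert group_af(v.candidate.frequencies, ALL_GROUPS) == pytest.approx(
            100 / 20_000
        )

    def test_sum_above_one_is_error(self):
        vs = [make_variant(100 + i, {"nfe": (90, 100)}) for i in range(2)]
        with pytest.raises(ModelError, match="exceeds 1"):
            aggregate_allele_frequency(vs, "nfe")

    def test_missing_group_contributes_zero(self):
        vs = [make_variant(100, {"nfe": (10, 10_000)})]
        assert aggregate_allele_frequency(vs, "asj") == 0.0


class TestHardyWeinbergIdentities:
    @given(sum_q=st.floats(1e-9, 0.4))
    @settings(max_examples=100, derandomize=True)
    def test_carrier_is_twice_sum_q(self, sum_q):
        assert carrier_frequency(sum_q) == 2 * sum_q

    def test_carrier_out_of_domain(self):
        with pytest.raises(ModelError):
            carrier_frequency(0.6)

    def test_prevalence_square(self):
        assert genetic_prevalence(0.5) == 0.25
        assert genetic_prevalence(0.001) == pytest.approx(1e-6)

    def test_prevalence_equals_ordered_pair_genotype_sum(self):
        """(sum q)^2 is the total mass sum_i sum_j q_i q_j of ordered allele
        pairs (homozygous plus compound-heterozygous genotypes)."""
        rng = random.Random(3)
        qs = [rng.uniform(0, 1e-3) for _ in range(40)]
        double_sum = sum(qi * qj for qi in qs for qj in qs)
        assert genetic_prevalence(sum(qs)) == pytest.approx(double_sum, rel=1e-12)

    @given(q=st.floats(0, 0.01))
    @settings(max_examples=100, derandomize=True)
    def test_homozygote_frequency_is_q_squared(self, q):
        an = 1_000_000
        ac = int(q * an)
        v = make_variant(100, {"asj": (ac, an)})
        assert homozygote_frequency(v, "asj") == pytest.approx((ac / an) ** 2)

    def test_homozygote_missing_group_names_group(self):
        v = make_variant(100, {"nfe": (1, 1000)})
        with pytest.raises(ModelError, match="asj"):
            homozygote_frequency(v, "asj")

    def test_aj_signature_homozygote_denominator(self):
        # carrier-frequency q of 1/141.665 squares to ~1/20069 homozygotes
        v = make_variant(100, {"asj": (10_000, 1_416_650)})
        hom = homozygote_frequency(v, "asj")
        assert one_in_denominator(hom) == 20_069


class TestFormatting:
    @pytest.mark.parametrize(
        "freq,expected",
        [
            (0.015625, "1 in 64"),
            (2 / math.sqrt(235_776), "1 in 243"),
            (2 / math.sqrt(1_127_547), "1 in 531"),
        ],
    )
    def test_one_in(self, freq, expected):
        assert format_one_in(freq) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ModelError):
            format_one_in(0.0)

    def test_percent_two_decimals(self):
        assert format_percent(1 / 64) == "1.56%"
        assert format_percent(0.0141) == "1.41%"


class TestEstimateAllGroups:
    def test_single_group_single_variant(self):
        vs = [make_variant(100, {"nfe": (100, 10_000)})]
        est = {e.group: e for e in estimate_all_groups(vs)}
        q = 0.01
        assert est["nfe"].carrier_freq == pytest.approx(2 * q)
        assert est["nfe"].prevalence == pytest.approx(q * q)
        assert est["nfe"].n_variants == 1
        assert est["asj"].sum_q == 0.0 and est["asj"].n_variants == 0

    def test_identity_holds_on_every_estimate(self):
        for e in estimate_all_groups(random_variant_set(seed=5)):
            assert e.prevalence == pytest.approx((e.carrier_freq / 2) ** 2, rel=1e-12)

    def test_matches_per_group_brute_force(self):
        vs = random_variant_set(seed=23)
        est = {e.group: e for e in estimate_all_groups(vs)}
        for g in ANCESTRY_GROUPS:
            sum_q = n = 0
            for v in vs:
                f = v.candidate.frequencies.get(g)
                if f is not None and f.an > 0:
                    sum_q += f.ac / f.an
                    n += f.ac > 0
            assert est[g].sum_q == pytest.approx(sum_q, rel=1e-12)
            assert est[g].n_variants == n

    def test_adding_positive_variant_is_monotone(self):
        base = random_variant_set(seed=9, n=10)
        extra = make_variant(999, {g: (5, 10_000) for g in ANCESTRY_GROUPS})
        before = {e.group: e for e in estimate_all_groups(base)}
        after = {e.group: e for e in estimate_all_groups(base + [extra])}
        for g, e in after.items():
            assert e.sum_q >= before[g].sum_q
            assert e.carrier_freq >= before[g].carrier_freq
            assert e.prevalence >= before[g].prevalence

    def test_display_order(self):
        order = [e.group for e in estimate_all_groups([])]
        assert order == ["all", *ANCESTRY_GROUPS]
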