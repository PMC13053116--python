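"""Triage thresholds, classification reconciliation, inclusion sets."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoprev.hardy_weinberg import GroupFrequency
from genoprev.ingest import AssertedClass, CandidateVariant, Source, SourceRecord
from genoprev.triage import (
    ClassifiedVariant,
    FinalClass,
    TriageDecision,
    TriageError,
    TriagePath,
    inclusion_set,
    reconcile_classification,
    triage_queue,
    triage_variant,
)
from genoprev.variants import VariantKey

_SOURCE_FOR = {
    AssertedClass.P: Source.CLINVAR,
    AssertedClass.LP: Source.CLINVAR,
    AssertedClass.CONFLICTING_WITH_PLP: Source.CLINVAR,
    AssertedClass.VUS: Source.CLINVAR,
    AssertedClass.LB: Source.CLINVAR,
    AssertedClass.B: Source.CLINVAR,
    AssertedClass.DM: Source.HGMD,
    AssertedClass.PLOF_HC: Source.GNOMAD_PLOF,
}


def candidate(asserted: AssertedClass, pos: int = 100, ac_nfe: int = 1):
    key = VariantKey("chr3", pos, "A", "G")
    return CandidateVariant(
        key=key,
        provenance=(
            SourceRecord(key=key, source=_SOURCE_FOR[asserted], asserted_class=asserted),
        ),
        frequencies={"nfe": GroupFrequency("nfe", ac_nfe, 10000)},
    )


class TestTriage:
    @pytest.mark.parametrize(
        "ac,is_plof,path,also_lof",
        [
            (15, False, TriagePath.FULL_ACMG, False),
            (15, True, TriagePath.FULL_ACMG, True),
            (2, True, TriagePath.LOF_CURATION, True),
            (14, False, TriagePath.ABBREVIATED, False),
            (14, True, TriagePath.LOF_CURATION, True),
            (1, True, TriagePath.ABBREVIATED, False),
            (0, True, TriagePath.ABBREVIATED, False),
            (0, False, TriagePath.ABBREVIATED, False),
        ],
    )
    def test_threshold_boundaries(self, ac, is_plof, path, also_lof):
        assert triage_variant(ac, is_plof) == TriageDecision(path, also_lof)

    def test_negative_ac_rejected(self):
        with pytest.raises(TriageError):
            triage_variant(-1, False)

    @given(ac=st.integers(0, 10**6), is_plof=st.booleans())
    @settings(max_examples=300, derandomize=True)
    def test_pure_function_of_ac_and_plof(self, ac, is_plof):
        """Decision matches an independent restatement of the review rules."""
        d = triage_variant(ac, is_plof)
        if ac >= 15:
            expected = TriagePath.FULL_ACMG
        elif is_plof and ac > 1:
            expected = TriagePath.LOF_CURATION
        else:
            expected = TriagePath.ABBREVIATED
        assert d.path is expected
        assert d.also_lof == (is_plof and d.path is not TriagePath.ABBREVIATED)


# Expected reconciliation outcomes, written out by hand over the full grid:
# curated class always wins; uncurated source claims map conservatively
# (only P and LP stand on their own); a VUS counts as a pathogenicity
# downgrade only when the source claim leaned pathogenic (not bare pLoF).
_UNCURATED_EXPECTED = {
    AssertedClass.P: FinalClass.P,
    AssertedClass.LP: FinalClass.LP,
    AssertedClass.CONFLICTING_WITH_PLP: FinalClass.VUS,
    AssertedClass.DM: FinalClass.VUS,
    AssertedClass.PLOF_HC: FinalClass.VUS,
    AssertedClass.VUS: FinalClass.VUS,
    AssertedClass.LB: FinalClass.LB,
    AssertedClass.B: FinalClass.B,
}
_PLP_LEANING = {
    AssertedClass.P,
    AssertedClass.LP,
    AssertedClass.CONFLICTING_WITH_PLP,
    AssertedClass.DM,
}


class TestReconcile:
    @pytest.mark.parametrize("asserted", list(AssertedClass))
    @pytest.mark.parametrize("curated", [None, *FinalClass])
    def test_full_grid_against_policy_table(self, asserted, curated):
        cv = reconcile_classification(candidate(asserted), curated)
        expected = curated if curated is not None else _UNCURATED_EXPECTED[asserted]
        assert cv.final_class is expected
        assert cv.downgraded_from_plp == (
            expected is FinalClass.VUS and asserted in _PLP_LEANING
        )

    def test_clinvar_lp_curated_vus_is_downgrade(self):
        cv = reconcile_classification(candidate(AssertedClass.LP), FinalClass.VUS)
        assert cv.final_class is FinalClass.VUS
        assert cv.downgraded_from_plp

    def test_uncurated_hgmd_dm_held_at_vus(self):
        cv = reconcile_classification(candidate(AssertedClass.DM))
        assert cv.final_class is FinalClass.VUS
        assert cv.downgraded_from_plp

    def test_unknown_label_rejected(self):
        with pytest.raises(TriageError, match="unknown classification"):
            reconcile_classification(candidate(AssertedClass.LP), "probably fine")

    def test_plof_provenance_sets_lof_triage(self):
        cv = reconcile_classification(candidate(AssertedClass.PLOF_HC, ac_nfe=5))
        assert cv.triage.path is TriagePath.LOF_CURATION


def classified(final, downgraded=False, pos=100):
    return ClassifiedVariant(
        candidate=candidate(AssertedClass.LP, pos=pos),
        final_class=final,
        triage=TriageDecision(TriagePath.ABBREVIATED),
        downgraded_from_plp=downgraded,
    )


@st.composite
def classified_lists(draw):
    out = []
    for i, final in enumerate(
        draw(st.lists(st.sampled_from(list(FinalClass)), max_size=30))
    ):
        downgraded = final is FinalClass.VUS and draw(st.booleans())
        out.append(classified(final, downgraded, pos=100 + i))
    return out


class TestInclusion:
    def test_empty_input_empty_output(self):
        assert inclusion_set([], "conservative") == []

    def test_unknown_mode_rejected(self):
        with pytest.raises(TriageError):
            inclusion_set([], "lenient")

    @given(variants=classified_lists())
    @settings(max_examples=150, derandomize=True)
    def test_subset_dominance_and_counts(self, variants):
        cons = inclusion_set(variants, "conservative")
        relax = inclusion_set(variants, "relaxed")
        assert set(id(v) for v in cons) <= set(id(v) for v in relax)
        n_downgraded = sum(
            1 for v in variants if v.final_class is FinalClass.VUS and v.downgraded_from_plp
        )
        assert len(relax) - len(cons) == n_downgraded
        for out in (cons, relax):
            assert all(v.final_class not in (FinalClass.B, FinalClass.LB) for v in out)
            # ordering preserved
            idx = [variants.index(v) for v in out]
            assert idx == sorted(idx)


class TestQueue:
    def test_queue_order_full_then_lof_then_abbreviated_desc_ac(self):
        variants = [
            reconcile_classification(candidate(AssertedClass.LP, pos=101, ac_nfe=3)),
            reconcile_classification(candidate(AssertedClass.PLOF_HC, pos=102, ac_nfe=5)),
            reconcile_classification(candidate(AssertedClass.LP, pos=103, ac_nfe=40)),
            reconcile_classification(candidate(AssertedClass.P, pos=104, ac_nfe=20)),
        ]
        df = triage_queue(variants)
        assert list(df["triage_path"]) == [
            "FULL_ACMG", "FULL_ACMG", "LOF_CURATION", "ABBREVIATED",
        ]
        assert list(df["ac_total"]) == [40, 20, 5, 3]
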