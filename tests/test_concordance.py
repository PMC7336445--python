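"""Concordance metrics, at-least-k consensus, and call-level filters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffpeconcord import (
    ConcordanceResult,
    SampleType,
    concordance_metrics,
    consensus,
    germline_leak_filter,
    match_keys,
    pairwise_caller_overlap,
    top_fraction,
)
from ffpeconcord.synthetic_data import ArtefactModel, SegmentModel, SimulationConfig, simulate_bundle

from conftest import make_call, make_callset, make_key


class TestConcordanceMetrics:
    @pytest.mark.parametrize(
        "n_ff, n_ffpe, n_overlap, sens, prec, f1",
        [
            # single-caller FF-vs-FFPE worked examples
            (10460, 11815, 5755, 0.5502, 0.4871, 0.5167),
            (4067, 1760, 883, 0.2171, 0.5017, 0.3031),
            (8109, 10080, 4865, 0.6000, 0.4826, 0.5349),
            # ensemble-strategy worked examples (intersection of 4 callers:
            # perfect precision, nearly no sensitivity)
            (4656, 16020, 4155, 0.8924, 0.2594, 0.4019),
            (4656, 4232, 3684, 0.7912, 0.8705, 0.8290),
            (4656, 340, 325, 0.0698, 0.9559, 0.1301),
            (4656, 8, 8, 0.0017, 1.0, 0.0034),
        ],
    )
    def test_printed_count_triples_reproduce_printed_ratios(
        self, n_ff, n_ffpe, n_overlap, sens, prec, f1
    ):
        r = ConcordanceResult(n_ff=n_ff, n_ffpe=n_ffpe, n_overlap=n_overlap)
        assert round(r.sensitivity, 4) == sens
        assert round(r.precision, 4) == prec
        assert round(r.f1, 4) == f1

    def test_identical_non_empty_sets_are_perfect(self):
        keys = {make_key(i) for i in range(1, 6)}
        r = concordance_metrics(keys, keys)
        assert (r.sensitivity, r.precision, r.f1) == (1.0, 1.0, 1.0)

    def test_zero_denominators_yield_zero_not_nan(self):
        r = concordance_metrics(set(), set())
        assert (r.sensitivity, r.precision, r.f1) == (0.0, 0.0, 0.0)

    @given(
        n_overlap=st.integers(0, 500),
        extra_ff=st.integers(0, 500),
        extra_ffpe=st.integers(0, 500),
    )
    @settings(max_examples=100, derandomize=True)
    def test_swapping_sides_swaps_sensitivity_precision_keeps_f1(
        self, n_overlap, extra_ff, extra_ffpe
    ):
        a = ConcordanceResult(n_overlap + extra_ff, n_overlap + extra_ffpe, n_overlap)
        b = ConcordanceResult(n_overlap + extra_ffpe, n_overlap + extra_ff, n_overlap)
        assert a.sensitivity == b.precision
        assert a.precision == b.sensitivity
        assert a.f1 == b.f1
        # F1 from counts is exactly 2*overlap/(ff+ffpe)
        denom = a.n_ff + a.n_ffpe
        if denom:
            assert a.f1 == 2 * n_overlap / denom

    def test_overlap_cannot_exceed_either_side(self):
        with pytest.raises(ValueError):
            ConcordanceResult(n_ff=3, n_ffpe=10, n_overlap=5)


class TestMatchKeys:
    def test_self_match_and_disjoint(self):
        keys = [make_key(i) for i in range(1, 6)]
        assert match_keys(keys, keys) == set(keys)
        other = [make_key(i + 100) for i in range(1, 6)]
        assert match_keys(keys, other) == set()

    def test_same_position_different_alt_does_not_match(self):
        a = [make_key(i, ref="C", alt="T") for i in range(1, 11)]
        b = [make_key(i, ref="C", alt="A") for i in range(1, 11)]
        # brute-force pairwise oracle
        expected = {x for x in a for y in b if x == y}
        assert match_keys(a, b) == expected == set()

    def test_matches_callsets_directly(self):
        cs1 = make_callset([make_call(1), make_call(2)])
        cs2 = make_callset([make_call(2), make_call(3)], caller="mutect2")
        assert match_keys(cs1, cs2) == {make_key(2)}


class TestConsensus:
    def _three_sets(self):
        rng = np.random.default_rng(42)
        pool = [make_key(int(p)) for p in rng.choice(10_000, size=60, replace=False)]
        picks = [rng.choice(60, size=30, replace=False) for _ in range(3)]
        callers = ["strelka2", "mutect2", "varscan2"]
        return [
            make_callset([make_call(pool[i].pos) for i in idx], caller=c)
            for idx, c in zip(picks, callers)
        ], pool, picks

    def test_k1_is_union_and_kmax_is_intersection(self):
        sets, pool, picks = self._three_sets()
        union = set().union(*(cs.keys() for cs in sets))
        inter = set.intersection(*(cs.keys() for cs in sets))
        assert consensus(sets, k=1).keys() == union
        assert consensus(sets, k=3).keys() == inter

    def test_membership_equals_brute_force_support_count(self):
        sets, pool, picks = self._three_sets()
        for k in (1, 2, 3):
            expected = {
                key
                for key in set().union(*(cs.keys() for cs in sets))
                if sum(key in cs.keys() for cs in sets) >= k
            }
            assert consensus(sets, k=k).keys() == expected

    def test_monotone_in_k(self):
        sets, _, _ = self._three_sets()
        ks = [consensus(sets, k=k).keys() for k in (1, 2, 3)]
        assert ks[2] <= ks[1] <= ks[0]

    def test_representative_vaf_is_median_of_supporters(self):
        sets = [
            make_callset([make_call(5, tumor_vaf=v)], caller=c)
            for v, c in [(0.1, "strelka2"), (0.3, "mutect2"), (0.2, "varscan2")]
        ]
        cons = consensus(sets, k=3)
        assert cons.representative_vaf(make_key(5)) == pytest.approx(0.2)

    def test_mixed_sample_types_rejected(self):
        a = make_callset([make_call(1)], caller="strelka2", sample_type=SampleType.FF)
        b = make_callset([make_call(1)], caller="mutect2", sample_type=SampleType.FFPE)
        with pytest.raises(ValueError, match="sample"):
            consensus([a, b], k=1)

    def test_k_out_of_range_rejected(self):
        a = make_callset([make_call(1)], caller="strelka2")
        b = make_callset([make_call(1)], caller="mutect2")
        for k in (0, 3):
            with pytest.raises(ValueError):
                consensus([a, b], k=k)

    def test_precision_non_decreasing_in_k_with_independent_fps(self):
        """With independent caller false positives, requiring more callers
        should not hurt precision (against generator truth)."""
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            cfg = SimulationConfig(
                seed=seed, n_clonal=150, n_subclonal=50, n_germline_leak=0,
                ffpe_artefact=ArtefactModel(n_artefacts=0),
                segment_model=SegmentModel(n_ffpe_only_fragments=0),
            )
            for m in cfg.caller_models.values():
                m.fp_count = 60
                m.germline_leak_rate = 0.0
            bundle = simulate_bundle(cfg)
            truth = bundle.truth.keys()
            ff_sets = bundle.callsets_for("FF")
            precisions = []
            for k in range(1, 5):
                keys = consensus(ff_sets, k=k).keys()
                tp = len(keys & truth)
                precisions.append(tp / len(keys) if keys else 1.0)
            if all(b >= a - 1e-12 for a, b in zip(precisions, precisions[1:])):
                wins += 1
        assert wins >= 0.95 * n_rep


class TestGermlineLeakFilter:
    def test_all_zero_normal_unchanged_and_all_positive_emptied(self):
        clean = make_callset([make_call(i, normal_vaf=0.0) for i in range(1, 6)])
        assert germline_leak_filter(clean).keys() == clean.keys()
        dirty = make_callset([make_call(i, normal_vaf=0.4) for i in range(1, 6)])
        assert len(germline_leak_filter(dirty)) == 0

    def test_mixed_fixture_counts(self):
        rng = np.random.default_rng(3)
        flags = rng.permutation([True] * 40 + [False] * 60)
        calls = [
            make_call(i + 1, normal_vaf=0.3 if leak else 0.0)
            for i, leak in enumerate(flags)
        ]
        kept = germline_leak_filter(make_callset(calls, caller="shimmer"))
        assert len(kept) == 60
        assert all(c.normal_vaf == 0.0 for c in kept)


class TestTopFraction:
    def test_q_one_is_identity(self):
        cs = make_callset([make_call(i, score=i) for i in range(1, 9)])
        assert top_fraction(cs, 1.0).keys() == cs.keys()

    def test_quarter_of_eight_distinct_scores_keeps_top_two(self):
        cs = make_callset([make_call(i, score=float(i)) for i in range(1, 9)])
        kept = top_fraction(cs, 0.25)
        # sort-and-slice oracle
        expected = {make_key(8), make_key(7)}
        assert kept.keys() == expected

    def test_lower_better_polarity_reverses_selection(self):
        scores = [0.5, 0.01, 0.3, 0.02, 0.2, 0.04, 0.1, 0.05]
        lower = make_callset(
            [make_call(i + 1, score=s) for i, s in enumerate(scores)], caller="varscan2"
        )
        negated = make_callset(
            [make_call(i + 1, score=-s) for i, s in enumerate(scores)], caller="strelka2"
        )
        assert top_fraction(lower, 0.25).keys() == top_fraction(negated, 0.25).keys()

    def test_ties_at_cutoff_are_all_included(self):
        cs = make_callset(
            [make_call(i, score=s) for i, s in enumerate([9, 5, 5, 5, 1, 1, 1, 1], 1)]
        )
        kept = top_fraction(cs, 0.25)  # ceil(2) -> cutoff score 5, three ties
        assert kept.keys() == {make_key(1), make_key(2), make_key(3), make_key(4)}

    def test_invalid_fraction_rejected(self):
        cs = make_callset([make_call(1)])
        for q in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                top_fraction(cs, q)


class TestPairwiseOverlap:
    def test_identical_sets_have_unit_f1_everywhere(self):
        calls = [make_call(i) for i in range(1, 6)]
        a = make_callset(calls, caller="strelka2")
        b = make_callset(list(calls), caller="mutect2")
        df = pairwise_caller_overlap([a, b])
        assert (df["F1"] == 1.0).all()

    def test_disjoint_sets_have_zero_off_diagonal_f1(self):
        a = make_callset([make_call(i) for i in range(1, 6)], caller="strelka2")
        b = make_callset([make_call(i + 100) for i in range(1, 6)], caller="mutect2")
        df = pairwise_caller_overlap([a, b])
        off = df[df.caller_a != df.caller_b]
        assert (off["F1"] == 0.0).all()
        diag = df[df.caller_a == df.caller_b]
        assert (diag["F1"] == 1.0).all()

    def test_every_cell_equals_pairwise_recompute(self):
        rng = np.random.default_rng(9)
        sets = [
            make_callset(
                [make_call(int(p)) for p in rng.choice(range(1, 201), size=50, replace=False)],
                caller=c,
            )
            for c in ("strelka2", "mutect2", "shimmer")
        ]
        df = pairwise_caller_overlap(sets)
        by_name = {cs.caller: cs for cs in sets}
        for row in df.itertuples(index=False):
            expected = concordance_metrics(
                by_name[row.caller_a].keys(), by_name[row.caller_b].keys()
            )
            assert row.Overlap == expected.n_overlap
            assert row.F1 == round(expected.f1, 4)
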