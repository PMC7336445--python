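"""Diploid filtering, VAF KDE, density segmentation, clonal labelling."""

from __future__ import annotations

import numpy as np
import pytest

from ffpeconcord import (
    CnStatus,
    ConcordanceResult,
    clonal_concordance,
    consensus,
    diploid_filter,
    fit_kde,
    segment_density,
    select_clonal,
)
from ffpeconcord.callset_io import Segment, SegmentSet
from ffpeconcord.clonality import ClonalityResult, label_clonality, BonaFideSet

from conftest import make_call, make_callset, make_key


def _neutral(chrom="1", start=1, end=10_000_000):
    return Segment(chrom=chrom, start=start, end=end, cn_status=CnStatus.NEUTRAL)


def _consensus_of(positions, chroms=None, vafs=None):
    chroms = chroms or ["1"] * len(positions)
    vafs = vafs or [0.25] * len(positions)
    sets = [
        make_callset(
            [make_call(p, chrom=c, tumor_vaf=v) for p, c, v in zip(positions, chroms, vafs)],
            caller=caller,
        )
        for caller in ("strelka2", "mutect2")
    ]
    return consensus(sets, k=2)


class TestDiploidFilter:
    def test_all_neutral_autosomal_is_identity(self):
        cons = _consensus_of([100, 200, 300])
        seg = SegmentSet(segments=[_neutral("1"), _neutral("2")])
        out = diploid_filter(cons, seg, seg)
        assert out.keys() == cons.keys()

    def test_ffpe_only_amplified_segment_drops_contained_call(self):
        cons = _consensus_of([100, 5000, 300])
        seg_ff = SegmentSet(segments=[_neutral("1")])
        seg_ffpe = SegmentSet(
            segments=[
                _neutral("1", 1, 4000),
                Segment(chrom="1", start=4001, end=6000, cn_status=CnStatus.AMPLIFIED),
                _neutral("1", 6001, 10_000_000),
            ]
        )
        out = diploid_filter(cons, seg_ff, seg_ffpe)
        # interval-membership oracle
        expected = {
            k for k in cons.keys()
            if seg_ff.status_at(k.chrom, k.pos) == CnStatus.NEUTRAL
            and seg_ffpe.status_at(k.chrom, k.pos) == CnStatus.NEUTRAL
        }
        assert out.keys() == expected
        assert make_key(5000) not in out.keys()

    def test_sex_chromosomes_dropped_regardless_of_cn(self):
        cons = _consensus_of([100, 200], chroms=["1", "X"])
        seg = SegmentSet(segments=[_neutral("1"), _neutral("X")])
        out = diploid_filter(cons, seg, seg)
        assert {k.chrom for k in out.keys()} == {"1"}

    def test_uncovered_positions_treated_as_non_neutral(self):
        cons = _consensus_of([100, 9_999_999])
        seg = SegmentSet(segments=[_neutral("1", 1, 1000)])
        out = diploid_filter(cons, seg, seg)
        assert out.keys() == {make_key(100)}

    def test_output_subset_of_input_and_stable(self):
        cons = _consensus_of([100, 200, 300])
        seg = SegmentSet(segments=[_neutral("1")])
        once = diploid_filter(cons, seg, seg)
        assert once.keys() <= cons.keys()


class TestFitKde:
    def test_needs_ten_spread_values(self):
        with pytest.raises(ValueError):
            fit_kde([0.2] * 5)
        with pytest.raises(ValueError):
            fit_kde([0.25] * 100)

    def test_single_gaussian_bump_has_one_interior_mode_near_truth(self):
        rng = np.random.default_rng(17)
        vafs = np.clip(rng.normal(0.25, 0.04, 10_000), 0.001, 0.999)
        d = fit_kde(vafs)
        interior = [m for m in d.maxima if 0.0 < m < 1.0]
        assert len(interior) == 1
        assert abs(interior[0] - 0.25) < 0.02

    def test_two_separated_bumps_yield_minimum_between(self):
        rng = np.random.default_rng(18)
        vafs = np.concatenate([
            np.clip(rng.normal(0.05, 0.015, 600), 0.001, 0.999),
            np.clip(rng.normal(0.25, 0.04, 1400), 0.001, 0.999),
        ])
        d = fit_kde(vafs)
        assert any(0.05 < m < 0.25 for m in d.minima)

    def test_symmetric_input_gives_symmetric_density(self):
        rng = np.random.default_rng(19)
        half = np.clip(rng.normal(0.3, 0.05, 2000), 0.001, 0.499)
        vafs = np.concatenate([half, 1.0 - half])
        d = fit_kde(vafs, bandwidth=0.03)
        assert np.allclose(d.density, d.density[::-1], atol=1e-6)

    def test_density_integrates_to_about_one(self):
        rng = np.random.default_rng(20)
        vafs = np.clip(rng.normal(0.3, 0.06, 3000), 0.01, 0.99)
        d = fit_kde(vafs)
        integral = np.trapezoid(d.density, d.grid)
        assert 0.95 <= integral <= 1.05

    def test_minima_and_maxima_interleave(self):
        rng = np.random.default_rng(21)
        vafs = np.concatenate([
            rng.normal(0.08, 0.02, 500),
            rng.normal(0.25, 0.03, 800),
            rng.normal(0.5, 0.04, 300),
        ]).clip(0.001, 0.999)
        d = fit_kde(vafs)
        merged = sorted([(m, "min") for m in d.minima] + [(m, "max") for m in d.maxima])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestSegmentDensity:
    def test_unimodal_gives_single_full_interval(self):
        rng = np.random.default_rng(22)
        d = fit_kde(np.clip(rng.normal(0.25, 0.04, 2000), 0.001, 0.999))
        assert segment_density(d) == [(0.0, 1.0)]

    def test_bimodal_splits_at_grid_argmin(self):
        rng = np.random.default_rng(23)
        vafs = np.concatenate([
            rng.normal(0.05, 0.012, 700),
            rng.normal(0.3, 0.04, 1300),
        ]).clip(0.001, 0.999)
        d = fit_kde(vafs, bandwidth=0.025)
        intervals = segment_density(d)
        assert len(intervals) == 2
        # grid-argmin oracle inside the gap
        gap = (d.grid > 0.07) & (d.grid < 0.28)
        argmin = d.grid[gap][np.argmin(d.density[gap])]
        assert intervals[0][1] == pytest.approx(argmin, abs=1e-9)

    def test_n_minima_give_n_plus_one_intervals(self):
        rng = np.random.default_rng(24)
        vafs = np.concatenate([
            rng.normal(0.07, 0.015, 600),
            rng.normal(0.25, 0.025, 700),
            rng.normal(0.5, 0.03, 500),
        ]).clip(0.001, 0.999)
        d = fit_kde(vafs)
        assert len(segment_density(d)) == len(d.minima) + 1

    def test_partition_is_disjoint_cover(self):
        rng = np.random.default_rng(25)
        vafs = np.concatenate([
            rng.normal(0.05, 0.012, 400), rng.normal(0.3, 0.05, 1000)
        ]).clip(0.001, 0.999)
        intervals = segment_density(fit_kde(vafs))
        assert intervals[0][0] == 0.0 and intervals[-1][1] == 1.0
        for (a, b), (c, d_) in zip(intervals, intervals[1:]):
            assert b == c


def _calls_from_vafs(vafs):
    return [make_call(i + 1, tumor_vaf=float(v)) for i, v in enumerate(vafs)]


class TestSelectClonal:
    def test_single_bump_all_clonal(self):
        rng = np.random.default_rng(26)
        vafs = np.clip(rng.normal(0.25, 0.04, 1000), 0.001, 0.999)
        calls = _calls_from_vafs(vafs)
        d = fit_kde(vafs)
        res = select_clonal(segment_density(d), calls, d)
        assert set(res.labels.values()) == {"clonal"}

    def test_two_bumps_highest_mode_below_cut_is_clonal(self):
        rng = np.random.default_rng(27)
        sub = np.clip(rng.normal(0.05, 0.012, 300), 0.001, 0.999)
        clo = np.clip(rng.normal(0.25, 0.03, 700), 0.001, 0.999)
        vafs = np.concatenate([sub, clo])
        calls = _calls_from_vafs(vafs)
        d = fit_kde(vafs)
        res = select_clonal(segment_density(d), calls, d)
        labels = res.labels
        sub_keys = {calls[i].key for i in range(300)}
        clo_keys = {calls[i].key for i in range(300, 1000)}
        sub_labels = {labels[k] for k in sub_keys}
        clo_labels = {labels[k] for k in clo_keys}
        assert "subclonal" in sub_labels and "clonal" in clo_labels
        # boundary blur allowed, but the bulk must be labelled correctly
        assert sum(labels[k] == "subclonal" for k in sub_keys) > 250
        assert sum(labels[k] == "clonal" for k in clo_keys) > 650

    def test_germline_cut_excludes_high_mode_interval(self):
        rng = np.random.default_rng(28)
        clo = np.clip(rng.normal(0.25, 0.03, 700), 0.001, 0.999)
        germ = np.clip(rng.normal(0.5, 0.03, 300), 0.001, 0.999)
        vafs = np.concatenate([clo, germ])
        calls = _calls_from_vafs(vafs)
        d = fit_kde(vafs)
        res = select_clonal(segment_density(d), calls, d, germline_cut=0.45)
        assert res.clonal_interval[1] < 0.5
        high = [calls[i].key for i in range(700, 1000)]
        assert sum(res.labels[k] == "excluded_high" for k in high) > 250

    def test_no_candidate_interval_instructs_manual_override(self):
        rng = np.random.default_rng(29)
        vafs = np.clip(rng.normal(0.6, 0.03, 500), 0.001, 0.999)
        calls = _calls_from_vafs(vafs)
        d = fit_kde(vafs)
        with pytest.raises(ValueError, match="override"):
            select_clonal(segment_density(d), calls, d)
        res = select_clonal(
            segment_density(d), calls, d, override_interval=(0.4, 0.8)
        )
        assert set(res.labels.values()) == {"clonal"}

    def test_labels_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(30)
        vafs = np.concatenate([
            rng.normal(0.05, 0.012, 200), rng.normal(0.25, 0.03, 700),
            rng.normal(0.55, 0.03, 100),
        ]).clip(0.001, 0.999)
        calls = _calls_from_vafs(vafs)
        res = label_clonality(BonaFideSet(calls=calls))
        assert set(res.labels) == {c.key for c in calls}
        assert set(res.labels.values()) <= {"clonal", "subclonal", "excluded_high"}


class TestClonalConcordance:
    @staticmethod
    def _result(labels):
        return ClonalityResult(labels=labels, clonal_interval=(0.1, 0.4), bandwidth=0.02)

    def test_identical_labelled_sets_have_unit_f1(self):
        labels = {make_key(i): ("clonal" if i % 2 else "subclonal") for i in range(1, 21)}
        cc = clonal_concordance(self._result(labels), self._result(dict(labels)))
        assert cc.clonal_defined and cc.clonal.f1 == 1.0
        assert cc.subclonal_defined and cc.subclonal.f1 == 1.0

    def test_published_count_triple_gives_count_derived_ratios(self):
        # clonal counts 3229/3246/2795: sensitivity and precision follow the
        # counts; the count-derived F1 (0.8633) governs over any rounding
        r = ConcordanceResult(n_ff=3229, n_ffpe=3246, n_overlap=2795)
        assert round(r.sensitivity, 4) == 0.8656
        assert round(r.precision, 4) == 0.8611
        assert round(r.f1, 4) == 0.8633

    def test_side_without_subclonal_is_flagged_undefined(self):
        ff = self._result({make_key(i): ("clonal" if i <= 15 else "subclonal")
                           for i in range(1, 21)})
        ffpe = self._result({make_key(i): "clonal" for i in range(1, 21)})
        cc = clonal_concordance(ff, ffpe)
        assert cc.clonal_defined
        assert not cc.subclonal_defined
        assert cc.subclonal is None

    def test_cross_tab_counts_shared_keys(self):
        ff = self._result({make_key(1): "clonal", make_key(2): "clonal",
                           make_key(3): "subclonal"})
        ffpe = self._result({make_key(1): "clonal", make_key(2): "subclonal",
                             make_key(4): "clonal"})
        cc = clonal_concordance(ff, ffpe)
        assert cc.cross_tab.loc["clonal", "clonal"] == 1
        assert cc.cross_tab.loc["clonal", "subclonal"] == 1
        assert cc.cross_tab.to_numpy().sum() == 2  # only shared keys counted


class TestParameterRecovery:
    @pytest.mark.parametrize("clonal_fraction", [0.5, 0.7, 0.9])
    def test_clonal_fraction_recovered_within_tolerance(self, clonal_fraction):
        """Well-separated bimodal VAF mixtures: the KDE labelling recovers
        the generating clonal fraction to within 0.05 at n=2000."""
        rng = np.random.default_rng(int(clonal_fraction * 100))
        n = 2000
        n_clonal = int(n * clonal_fraction)
        vafs = np.concatenate([
            rng.normal(0.30, 0.03, n_clonal),
            rng.normal(0.08, 0.02, n - n_clonal),
        ]).clip(0.005, 0.995)
        calls = _calls_from_vafs(vafs)
        res = label_clonality(BonaFideSet(calls=calls), min_mass=0.05)
        recovered = sum(v == "clonal" for v in res.labels.values()) / n
        assert abs(recovered - clonal_fraction) < 0.05
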