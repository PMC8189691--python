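import math

import numpy as np
import pytest

from chromdelta import (
    BackgroundFreqs,
    CandidateSegment,
    KarlinParams,
    MergedDomain,
    ValidationError,
    assign_evalues,
    comparison_length,
    effective_group_length,
    filter_dcds,
    merge_candidates,
)
from chromdelta.merge import EffectiveLength
from conftest import make_map


def seg(start, end, score, chrom="chr1", pair=("x1", "y1")):
    return CandidateSegment(chrom, start, end, score, pair)


def params(lam=0.5, K=0.1):
    freqs = BackgroundFreqs([0.5, 0.5], [0.5, 0.5])
    return KarlinParams(lam=lam, K=K, score_range=(-1, 1), freqs=freqs)


def domain(dcs, chrom="chr1", start=0, end=10):
    return MergedDomain(chrom, start, end, dcs, (seg(start, end, max(1, int(dcs))),))


class TestMergeCandidates:
    def test_overlap_takes_union_and_mean_score(self):
        merged = merge_candidates([seg(100, 300, 10), seg(200, 400, 20, pair=("x2", "y1"))])
        assert len(merged) == 1
        dom = merged[0]
        assert (dom.start, dom.end) == (100, 400)
        assert dom.dcs == pytest.approx(15.0)
        assert dom.n_support_pairs == 2

    def test_bookended_intervals_stay_separate(self):
        merged = merge_candidates([seg(0, 200, 5), seg(200, 400, 7)])
        assert [(d.start, d.end, d.dcs) for d in merged] == [(0, 200, 5.0), (200, 400, 7.0)]

    def test_transitive_chain_collapses_to_one_domain(self):
        a, b, c = seg(0, 10, 3), seg(8, 20, 6), seg(18, 30, 9)
        merged = merge_candidates([c, a, b])  # order must not matter
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 30)
        assert merged[0].dcs == pytest.approx(6.0)

    def test_mixed_comparisons_rejected(self):
        # sample "s" appears as group-X member in one pair and group-Y in another
        with pytest.raises(ValidationError, match="both sides"):
            merge_candidates([seg(0, 5, 1, pair=("s", "y")), seg(10, 15, 1, pair=("x", "s"))])

    def test_merging_conserves_union_coverage(self):
        rng = np.random.default_rng(11)
        segments = []
        for _ in range(200):
            start = int(rng.integers(0, 500))
            end = start + int(rng.integers(1, 20))
            segments.append(seg(start, end, int(rng.integers(1, 30))))
        merged = merge_candidates(segments)
        covered = np.zeros(1000, dtype=bool)
        for s in segments:
            covered[s.start:s.end] = True
        merged_cov = np.zeros(1000, dtype=bool)
        for d in merged:
            merged_cov[d.start:d.end] = True
        assert int(merged_cov.sum()) == int(covered.sum())
        # merged domains must be disjoint and sorted
        for prev, cur in zip(merged, merged[1:]):
            assert prev.end <= cur.start


class TestEffectiveLength:
    def test_single_replicate_is_plain_length(self):
        maps = [make_map("a", {"chr1": np.zeros(1000, dtype=int)})]
        assert effective_group_length(maps).total == 1000

    def test_identical_replicates_add_nothing(self):
        vec = np.tile([0, 1, 2, 1], 250)
        maps = [make_map("a", {"chr1": vec}), make_map("b", {"chr1": vec})]
        assert effective_group_length(maps).total == 1000

    def test_discordant_positions_add_their_count(self):
        rng = np.random.default_rng(3)
        vec = rng.integers(0, 3, size=1000)
        other = vec.copy()
        pos = rng.choice(1000, size=37, replace=False)
        other[pos] = (vec[pos] + 1) % 3
        maps = [make_map("a", {"chr1": vec}), make_map("b", {"chr1": other})]
        assert effective_group_length(maps).total == 1037

    def test_order_independent(self):
        rng = np.random.default_rng(4)
        vecs = [rng.integers(0, 4, size=200) for _ in range(3)]
        maps = [make_map(f"s{i}", {"chr1": v}) for i, v in enumerate(vecs)]
        forward = effective_group_length(maps).total
        backward = effective_group_length(maps[::-1]).total
        assert forward == backward

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            effective_group_length([])


class TestComparisonLength:
    def test_equal_components_reduce_to_plain_length(self):
        lx = EffectiveLength({"chr1": 1000})
        assert comparison_length(lx, EffectiveLength({"chr1": 1000})).total == 1000

    def test_max_rule(self):
        lx = EffectiveLength({"chr1": 1037})
        ly = EffectiveLength({"chr1": 1000})
        assert comparison_length(lx, ly).total == 1037

    def test_adding_replicate_never_decreases_length(self):
        rng = np.random.default_rng(9)
        vecs = [rng.integers(0, 4, size=300) for _ in range(3)]
        maps = [make_map(f"s{i}", {"chr1": v}) for i, v in enumerate(vecs)]
        totals = [effective_group_length(maps[: k + 1]).total for k in range(3)]
        assert totals == sorted(totals)

    def test_chromosome_set_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="chromosome"):
            comparison_length(
                EffectiveLength({"chr1": 10}), EffectiveLength({"chr2": 10})
            )


class TestEvalues:
    def test_direct_evaluation(self):
        (dom,) = assign_evalues([domain(dcs=20.0)], params(lam=0.5, K=0.1), 1000)
        assert dom.evalue == pytest.approx(100 * math.exp(-10), rel=1e-12)

    def test_e_of_one_maps_to_zero_neg_log10(self):
        p = params(lam=0.5, K=0.1)
        length = 1000
        dcs = math.log(p.K * length) / p.lam  # E == 1 exactly
        (dom,) = assign_evalues([domain(dcs=dcs)], p, length)
        assert dom.evalue == pytest.approx(1.0, rel=1e-12)
        assert dom.neg_log10_e == pytest.approx(0.0, abs=1e-12)

    def test_doubling_length_doubles_evalue(self):
        p = params()
        (e1,) = assign_evalues([domain(dcs=15.0)], p, 1000)
        (e2,) = assign_evalues([domain(dcs=15.0)], p, 2000)
        assert e2.evalue == pytest.approx(2 * e1.evalue, rel=1e-12)

    def test_strictly_decreasing_in_dcs(self):
        p = params()
        doms = assign_evalues([domain(dcs=d) for d in (5.0, 10.0, 20.0)], p, 1000)
        evals = [d.evalue for d in doms]
        assert evals == sorted(evals, reverse=True)

    def test_huge_score_reports_exact_neg_log10_despite_underflow(self):
        p = params(lam=1.0, K=1.0)
        (dom,) = assign_evalues([domain(dcs=5000.0)], p, 1000)
        assert dom.evalue == 0.0
        assert dom.neg_log10_e == pytest.approx(
            (5000.0 - math.log(1000)) / math.log(10), rel=1e-12
        )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValidationError):
            assign_evalues([domain(dcs=5.0)], params(), 0)


class TestFilter:
    def test_threshold_is_strict(self):
        p = params(lam=1.0, K=1.0)
        length = 1000
        kept_dcs = math.log(length) + 0.0100503  # E ~= 0.99
        drop_dcs = math.log(length)  # E == 1.0 exactly
        doms = assign_evalues(
            [domain(dcs=drop_dcs, start=0, end=5), domain(dcs=kept_dcs, start=10, end=15)],
            p, length,
        )
        kept = filter_dcds(doms)
        assert len(kept) == 1
        assert kept[0].evalue < 1.0

    def test_infinite_threshold_keeps_everything(self):
        doms = assign_evalues(
            [domain(dcs=1.0, start=0, end=5), domain(dcs=2.0, start=6, end=9)],
            params(), 1000,
        )
        assert len(filter_dcds(doms, math.inf)) == 2

    def test_empty_result_is_valid(self):
        doms = assign_evalues([domain(dcs=1.0)], params(), 10**6)
        assert filter_dcds(doms, 1e-6) == []

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            filter_dcds([], -1.0)
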