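import math
import warnings

import numpy as np
import pytest

from condortho.exceptions import ValidationError
from condortho.homology import (
    LengthBinSummary,
    ThresholdCurve,
    assign_homology,
    best_hit_per_query,
    bin_rbb_by_length,
    classify_nonrbb_hits,
    evaluate_assignment,
    fit_threshold_curve,
    reciprocal_best_hits,
)
from condortho.simulate import simulate_homology_truth

from conftest import make_hit


class TestBestHitPerQuery:
    def test_highest_bit_score_wins(self):
        hits = [make_hit(subject="g1", bits=500), make_hit(subject="g2", bits=400)]
        assert best_hit_per_query(hits)["t1"].subject_id == "g1"

    def test_bit_tie_broken_by_smaller_evalue(self):
        hits = [
            make_hit(subject="g1", bits=500, evalue=1e-50),
            make_hit(subject="g2", bits=500, evalue=1e-60),
        ]
        assert best_hit_per_query(hits)["t1"].subject_id == "g2"

    def test_full_tie_broken_lexicographically(self):
        hits = [
            make_hit(subject="g2", bits=500, evalue=1e-50),
            make_hit(subject="g10", bits=500, evalue=1e-50),
        ]
        # "g10" < "g2" as strings
        assert best_hit_per_query(hits)["t1"].subject_id == "g10"

    def test_empty_input_gives_empty_map(self):
        assert best_hit_per_query([]) == {}


class TestReciprocalBestHits:
    def test_mutual_best_pairs(self):
        fwd = [make_hit("t1", "g1")]
        rev = [make_hit("g1", "t1")]
        (pair,) = reciprocal_best_hits(fwd, rev)
        assert (pair.transcript_id, pair.gene_id) == ("t1", "g1")

    def test_non_reciprocating_excluded(self):
        fwd = [make_hit("t1", "g1")]
        rev = [make_hit("g1", "t2")]
        assert reciprocal_best_hits(fwd, rev) == []

    def test_gene_monogamy(self):
        fwd = [make_hit("t1", "g1", bits=500), make_hit("t2", "g1", bits=400)]
        rev = [make_hit("g1", "t1")]
        pairs = reciprocal_best_hits(fwd, rev)
        assert [(p.transcript_id, p.gene_id) for p in pairs] == [("t1", "g1")]

    def test_symmetry_under_role_swap(self, rng):
        # a random bipartite hit structure; swapping the forward/reverse
        # roles must recover the same pair set with roles exchanged
        fwd, rev = [], []
        for i in range(30):
            t, g = f"t{i}", f"g{rng.integers(0, 20)}"
            bits = float(rng.integers(50, 500))
            fwd.append(make_hit(t, g, bits=bits, evalue=10.0 ** -rng.integers(5, 80)))
            rev.append(make_hit(g, t, bits=bits, evalue=10.0 ** -rng.integers(5, 80)))
        direct = {(p.transcript_id, p.gene_id) for p in reciprocal_best_hits(fwd, rev)}
        swapped = {(p.gene_id, p.transcript_id) for p in reciprocal_best_hits(rev, fwd)}
        assert direct == swapped


def _pairs(evalues, lengths=None):
    pairs = []
    for i, ev in enumerate(evalues):
        t = f"t{i:03d}"
        fwd = make_hit(t, f"g{i:03d}", evalue=ev)
        rev = make_hit(f"g{i:03d}", t, evalue=ev)
        pairs.append(
            reciprocal_best_hits([fwd], [rev])[0]
        )
    lens = lengths or {f"t{i:03d}": 100 + i for i in range(len(evalues))}
    return pairs, lens


class TestBinning:
    def test_nearest_rank_percentile_25(self):
        pairs, lens = _pairs([1e-50, 1e-40, 1e-30, 1e-20])
        (b,) = bin_rbb_by_length(pairs, lens, n_bins=1, percentile=25, min_per_bin=1)
        assert b.percentile_evalue == 1e-50  # rank ceil(0.25*4) = 1

    def test_zero_evalues_floored_before_log(self):
        pairs, lens = _pairs([0.0, 0.0, 0.0])
        (b,) = bin_rbb_by_length(
            pairs, lens, n_bins=1, percentile=50, evalue_floor=1e-180, min_per_bin=1
        )
        assert b.log10_percentile == -180.0

    def test_equal_count_bins(self):
        pairs, lens = _pairs([1e-30] * 100)
        bins = bin_rbb_by_length(pairs, lens, n_bins=4, min_per_bin=1)
        assert [b.n_hits for b in bins] == [25, 25, 25, 25]
        assert all(
            b.length_min <= b.representative_length <= b.length_max for b in bins
        )

    def test_bin_count_autoreduces_with_warning(self):
        pairs, lens = _pairs([1e-30] * 50)
        with pytest.warns(UserWarning, match="reducing"):
            bins = bin_rbb_by_length(pairs, lens, n_bins=10, min_per_bin=20)
        assert len(bins) == 2

    def test_zero_pairs_is_an_error(self):
        with pytest.raises(ValidationError, match="self-train"):
            bin_rbb_by_length([], {}, n_bins=1)


class TestCurveFit:
    def test_three_point_interpolation_matches_analytic_solution(self):
        bins = [
            LengthBinSummary(i, L, L, float(L), 10, 10.0 ** y, float(y))
            for i, (L, y) in enumerate([(100, -10), (200, -30), (300, -60)])
        ]
        curve = fit_threshold_curve(bins)
        assert math.isclose(curve.a, -5e-4, rel_tol=1e-8)
        assert math.isclose(curve.b, -0.05, rel_tol=1e-8)
        assert abs(curve.c) < 1e-8

    def test_constant_bins_give_constant_curve(self):
        bins = [
            LengthBinSummary(i, L, L, float(L), 10, 1e-7, -7.0)
            for i, L in enumerate([100, 200, 300, 400])
        ]
        curve = fit_threshold_curve(bins)
        assert abs(curve.a) < 1e-12 and abs(curve.b) < 1e-12
        assert math.isclose(curve.c, -7.0)

    def test_two_bins_fall_back_to_constant(self):
        bins = [
            LengthBinSummary(0, 100, 100, 100.0, 10, 1e-10, -10.0),
            LengthBinSummary(1, 200, 200, 200.0, 10, 1e-20, -20.0),
        ]
        with pytest.warns(UserWarning, match="constant"):
            curve = fit_threshold_curve(bins)
        assert curve.a == 0.0 and curve.b == 0.0
        assert math.isclose(curve.c, -15.0)

    def test_planted_quadratic_recovered_exactly_from_exact_points(self):
        a, b, c = -2e-6, -0.013, -22.0
        lengths = np.linspace(150, 2900, 35)
        bins = [
            LengthBinSummary(i, int(L), int(L), float(L), 30, 10.0 ** (a * L * L + b * L + c), a * L * L + b * L + c)
            for i, L in enumerate(lengths)
        ]
        curve = fit_threshold_curve(bins)
        for got, want in [(curve.a, a), (curve.b, b), (curve.c, c)]:
            assert abs((got - want) / want) < 1e-8


SPEC_CURVE = ThresholdCurve(
    a=-5e-4, b=-0.05, c=0.0, percentile=99.0, evalue_floor=1e-180,
    domain_min=100.0, domain_max=300.0,
)


class TestClassifyNonRbb:
    def test_hit_more_significant_than_curve_accepted(self):
        hit = make_hit(evalue=1e-40, qlen=200)  # curve(200) = -30
        assert classify_nonrbb_hits([hit], [], SPEC_CURVE) == [hit]

    def test_hit_less_significant_than_curve_rejected(self):
        hit = make_hit(evalue=1e-20, qlen=200)
        assert classify_nonrbb_hits([hit], [], SPEC_CURVE) == []

    def test_hit_exactly_on_curve_accepted(self):
        hit = make_hit(evalue=1e-30, qlen=200)
        assert classify_nonrbb_hits([hit], [], SPEC_CURVE) == [hit]

    def test_missing_query_length_names_transcript(self):
        with pytest.raises(ValidationError, match="t1"):
            classify_nonrbb_hits([make_hit(qlen=None)], [], SPEC_CURVE)

    def test_rbb_members_are_skipped(self):
        fwd = [make_hit("t9", "g9", qlen=200)]
        rev = [make_hit("g9", "t9")]
        rbb = reciprocal_best_hits(fwd, rev)
        assert classify_nonrbb_hits(fwd, rbb, SPEC_CURVE) == []

    def test_constant_curve_equals_global_cutoff_oracle(self, rng):
        # single-bin self-training degenerates to the fixed-cutoff baseline
        cutoff_log10 = -25.0
        curve = ThresholdCurve(0.0, 0.0, cutoff_log10, 99.0, 1e-180, 100.0, 300.0)
        hits = [
            make_hit(f"t{i}", "g", evalue=10.0 ** float(rng.uniform(-60, 0)),
                     qlen=int(rng.integers(50, 400)))
            for i in range(200)
        ]
        accepted = {h.query_id for h in classify_nonrbb_hits(hits, [], curve)}
        oracle = {h.query_id for h in hits if h.evalue <= 10.0 ** cutoff_log10}
        assert accepted == oracle


class TestFullAssignment:
    @pytest.fixture(scope="class")
    def sim(self):
        return simulate_homology_truth(n_genes=250, seed=42)

    def _assign(self, sim, **kw):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return assign_homology(sim.forward, sim.reverse, sim.lengths, **kw)

    def test_rbb_entries_never_overwritten_by_conditional(self, sim):
        result = self._assign(sim)
        for pair in result.rbb_pairs:
            entry = result.homology_map[pair.transcript_id]
            assert entry.method == "rbb"
            assert entry.gene_id == pair.gene_id

    def test_lower_percentile_never_grows_accepted_set(self, sim):
        accepted = {}
        for pct in (50.0, 90.0, 99.0):
            result = self._assign(sim, percentile=pct)
            accepted[pct] = {
                t for t, e in result.homology_map.entries.items()
                if e.method == "conditional"
            }
        assert accepted[50.0] <= accepted[90.0] <= accepted[99.0]

    def test_best_accepted_gene_wins(self):
        # self-training on the single anchor puts the threshold at 1e-40;
        # both of t1's hits clear it, the higher bit score decides
        fwd = [
            make_hit("t1", "g1", qlen=200, evalue=1e-45, bits=500),
            make_hit("t1", "g2", qlen=200, evalue=1e-44, bits=450),
            make_hit("anchor", "g1", qlen=200, evalue=1e-40, bits=900),
        ]
        rev = [make_hit("g1", "anchor", evalue=1e-40, bits=900)]
        result = assign_homology(fwd, rev, {"t1": 200, "anchor": 200}, n_bins=1, min_per_bin=1)
        assert result.homology_map["t1"].gene_id == "g1"
        assert result.homology_map["t1"].method == "conditional"

    def test_transcript_with_all_hits_rejected_is_absent(self):
        fwd = [
            make_hit("anchor", "g1", qlen=200, evalue=1e-60, bits=900),
            make_hit("tbad", "g1", qlen=200, evalue=1e-3, bits=40),
        ]
        rev = [make_hit("g1", "anchor", evalue=1e-60, bits=900)]
        result = assign_homology(fwd, rev, {"anchor": 200, "tbad": 200}, n_bins=1, min_per_bin=1)
        assert "tbad" not in result.homology_map


class TestEvaluateAssignment:
    def _map(self, assignments):
        from condortho.io import HomologyEntry, HomologyMap

        m = HomologyMap()
        for t, g in assignments.items():
            m.add(t, HomologyEntry(g, "rbb", 1e-10, 100.0))
        return m

    def test_perfect_map(self):
        truth = {f"t{i}": f"g{i}" for i in range(10)}
        score = evaluate_assignment(self._map(truth), truth)
        assert score == (1.0, 1.0, 1.0)

    def test_empty_map_reports_zeros(self):
        truth = {"t1": "g1"}
        score = evaluate_assignment(self._map({}), truth)
        assert score == (0.0, 0.0, 0.0)

    def test_partial_map_arithmetic(self):
        truth = {f"t{i}": f"g{i}" for i in range(10)}
        assigned = {f"t{i}": f"g{i}" for i in range(6)}  # 6 correct
        assigned["t6"] = "gX"
        assigned["t7"] = "gY"  # 8 assignments total
        score = evaluate_assignment(self._map(assigned), truth)
        assert math.isclose(score.precision, 0.75)
        assert math.isclose(score.recall, 0.6)
        assert math.isclose(score.f1, 2 * 0.75 * 0.6 / 1.35)
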