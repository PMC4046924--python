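import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condortho.exceptions import ValidationError
from condortho.profiles import (
    INCONSISTENT,
    UNCLASSIFIED,
    PatternCatalogue,
    StageProfile,
    bh_adjust,
    classify_gene_profile,
    classify_profiles,
    containment_closure,
    enumerate_behavior_patterns,
    pairwise_de_pvalues,
    profiles_from_counts,
)


def brute_force_closed_sets(n_stages):
    """All non-empty containment-closed interval sets, by exhaustion."""
    intervals = [
        (i, j) for i in range(1, n_stages) for j in range(i + 1, n_stages + 1)
    ]
    closed = []
    for r in range(1, len(intervals) + 1):
        for combo in itertools.combinations(intervals, r):
            s = frozenset(combo)
            if containment_closure(s, n_stages) == s:
                closed.append(s)
    return set(closed)


class TestCatalogue:
    @pytest.mark.parametrize("n_stages", [2, 3, 4, 5])
    def test_enumeration_matches_brute_force(self, n_stages):
        patterns = enumerate_behavior_patterns(n_stages)
        per_direction = {
            p.intervals for p in patterns if p.direction == "ascending"
        }
        assert per_direction == brute_force_closed_sets(n_stages)
        assert len(patterns) == 2 * len(per_direction)

    def test_four_stages_give_thirteen_per_direction(self):
        patterns = enumerate_behavior_patterns(4)
        asc = [p for p in patterns if p.direction == "ascending"]
        desc = [p for p in patterns if p.direction == "descending"]
        assert len(asc) == 13 and len(desc) == 13
        assert [p.pattern_id for p in asc] == [f"A{k:02d}" for k in range(1, 14)]
        assert [p.pattern_id for p in desc] == [f"D{k:02d}" for k in range(1, 14)]

    @pytest.mark.parametrize("n_stages, expected", [(2, 1), (3, 4)])
    def test_small_stage_counts(self, n_stages, expected):
        asc = [
            p for p in enumerate_behavior_patterns(n_stages)
            if p.direction == "ascending"
        ]
        assert len(asc) == expected

    def test_closure_of_adjacent_pair(self):
        assert containment_closure({(1, 2)}, 4) == frozenset(
            {(1, 2), (1, 3), (1, 4)}
        )

    def test_maximal_interval_is_a_closed_singleton(self):
        assert containment_closure({(1, 4)}, 4) == frozenset({(1, 4)})

    def test_patterns_are_containment_closed(self):
        for p in enumerate_behavior_patterns(4):
            assert containment_closure(p.intervals, 4) == p.intervals


class TestBhAdjust:
    def test_stepup_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.5])

    @staticmethod
    def _stepup_oracle(p):
        """Independent BH: adj_(k) = min_{m>=k} p_(m)*n/m, input order."""
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj_sorted = np.minimum.accumulate(
            (p[order] * n / np.arange(1, n + 1))[::-1]
        )[::-1]
        out = np.empty(n)
        out[order] = np.minimum(adj_sorted, 1.0)
        return out

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_independent_stepup_oracle(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(pvals), self._stepup_oracle(pvals), atol=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 0.99), min_size=2, max_size=20), st.data())
    def test_monotone_in_raw_pvalues(self, pvals, data):
        i = data.draw(st.integers(0, len(pvals) - 1))
        bumped = list(pvals)
        bumped[i] = min(1.0, bumped[i] + data.draw(st.floats(0.0, 1.0)))
        assert (bh_adjust(bumped) >= bh_adjust(pvals) - 1e-12).all()


def _counts(rows, stages=("S1", "S1", "S1", "S2", "S2", "S2")):
    cols = [f"{s}_r{i}" for i, s in enumerate(stages)]
    return pd.DataFrame(rows, columns=cols, dtype=float), list(stages)


class TestPairwisePvalues:
    def test_identical_groups_give_p_one(self):
        counts, stages = _counts([[10, 10, 10, 10, 10, 10]])
        pvals, _ = pairwise_de_pvalues(counts, stages)
        assert pvals[(1, 2)].iloc[0] == 1.0

    def test_separated_groups_give_tiny_p(self):
        counts, stages = _counts(
            [[10, 11, 10, 1000, 1001, 1000], [5, 5, 6, 5, 6, 5]]
        )
        pvals, means = pairwise_de_pvalues(counts, stages)
        assert pvals[(1, 2)].iloc[0] < 0.01  # a 100-fold change at 3 reps
        assert means.shape == (2, 2)

    def test_permuting_replicates_within_stage_is_irrelevant(self):
        rows = [[13, 20, 8, 100, 140, 90], [7, 9, 11, 12, 10, 9]]
        counts, stages = _counts(rows)
        shuffled = counts[[counts.columns[i] for i in (2, 0, 1, 4, 5, 3)]]
        p1, _ = pairwise_de_pvalues(counts, stages)
        p2, _ = pairwise_de_pvalues(shuffled, stages)
        np.testing.assert_allclose(p1[(1, 2)], p2[(1, 2)])

    def test_single_replicate_stage_rejected(self):
        counts, _ = _counts([[1, 2, 3, 4, 5, 6]])
        with pytest.raises(ValidationError, match="replicate"):
            pairwise_de_pvalues(counts, ["S1", "S1", "S1", "S2", "S2", "S3"])


def _profile(sig_pairs, n_stages=4, direction=+1, gene="g"):
    """Profile with the given pairs significant and a mean vector whose
    pairwise signs all follow ``direction``."""
    means = np.arange(1, n_stages + 1, dtype=float) * direction
    pvals = {}
    for i in range(1, n_stages):
        for j in range(i + 1, n_stages + 1):
            pvals[(i, j)] = 0.001 if (i, j) in sig_pairs else 0.9
    return StageProfile(gene, means, pvals)


class TestClassifyGene:
    def test_all_pairs_significant_gives_maximal_pattern(self):
        cat = PatternCatalogue(4)
        label = classify_gene_profile(_profile(set(cat["A13"].intervals) | {(1, 2), (2, 3), (3, 4), (1, 3), (2, 4), (1, 4)}), catalogue=cat)
        pattern = cat[label]
        assert len(pattern.intervals) == 6 and pattern.direction == "ascending"

    def test_maximal_interval_singleton_is_classified(self):
        cat = PatternCatalogue(4)
        label = classify_gene_profile(_profile({(1, 4)}), catalogue=cat)
        assert cat[label].intervals == frozenset({(1, 4)})

    def test_nonclosed_set_strict_vs_closure(self):
        cat = PatternCatalogue(4)
        prof = _profile({(1, 2)})
        assert classify_gene_profile(prof, mode="strict", catalogue=cat) == INCONSISTENT
        label = classify_gene_profile(prof, mode="closure", catalogue=cat)
        assert cat[label].intervals == frozenset({(1, 2), (1, 3), (1, 4)})

    def test_no_significant_pair_is_unclassified(self):
        assert classify_gene_profile(_profile(set())) == UNCLASSIFIED

    def test_mixed_directions_are_inconsistent(self):
        prof = _profile({(1, 2), (3, 4)})
        prof.stage_means = np.array([1.0, 2.0, 5.0, 4.0])  # (3,4) decreases
        assert classify_gene_profile(prof) == INCONSISTENT

    def test_zero_difference_on_significant_pair_is_inconsistent(self):
        prof = _profile({(1, 2)})
        prof.stage_means = np.array([2.0, 2.0, 3.0, 4.0])
        assert classify_gene_profile(prof) == INCONSISTENT


class TestClassifyCohort:
    def test_counts_partition_classified_genes(self):
        cat = PatternCatalogue(4)
        profiles = [
            _profile({(1, 4)}, gene="g1"),
            _profile({(1, 4)}, gene="g2"),
            _profile(set(), gene="g3"),
        ]
        result = classify_profiles(profiles, catalogue=cat)
        assert result.n_classified == 2
        assert sum(result.counts.values()) == 3

    def test_direction_symmetry_under_mean_negation(self):
        cat = PatternCatalogue(4)
        for sig in [{(1, 4)}, {(1, 2), (1, 3), (1, 4)}]:
            up = classify_gene_profile(_profile(sig, direction=+1), catalogue=cat)
            down = classify_gene_profile(_profile(sig, direction=-1), catalogue=cat)
            assert up.startswith("A") and down.startswith("D")
            assert up[1:] == down[1:]
            assert cat[up].intervals == cat[down].intervals

    def test_planted_cohort_recovery_through_full_pipeline(self):
        from condortho.simulate import simulate_count_matrix

        sim = simulate_count_matrix(
            genes_per_pattern=10, n_replicates=4, fold_change=8,
            dispersion=0.05, seed=7,
        )
        profiles = profiles_from_counts(sim.counts, sim.stages)
        result = classify_profiles(profiles, alpha=0.05)
        hit = np.mean(
            [result.assignments[g] == p for g, p in sim.truth_patterns.items()]
        )
        assert hit >= 0.9
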