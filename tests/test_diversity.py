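"""node50, MPD, and the pooled-subsampling sesMPD null."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import virhost as vh
from virhost.errors import UndefinedMetricError, ValidationError


def node50_oracle(counts):
    """Exhaustive cumulative-sum reference: try k = 1, 2, ... explicitly."""
    values = sorted((c for c in counts.values() if c > 0), reverse=True)
    total = sum(values)
    running = 0
    for k, v in enumerate(values, start=1):
        running += v
        if 2 * running >= total:
            return k
    raise AssertionError("unreachable for nonempty counts")


def brute_force_mpd(tree, reads):
    """All-pairs double loop over individual reads."""
    n = len(reads)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += tree.patristic_distance(reads[i], reads[j])
    return total / (n * (n - 1) / 2)


class TestNode50:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"A": 100}, 1),
            ({"A": 40, "B": 30, "C": 20, "D": 10}, 2),
            ({"A": 25, "B": 25, "C": 25, "D": 25}, 2),  # the >= rule reaches 50% at two nodes
            ({"A": 49, "B": 48, "C": 3}, 2),
            ({"A": 51, "B": 49}, 1),
        ],
    )
    def test_known_values(self, counts, expected):
        assert vh.node50(counts) == expected

    def test_all_zero_counts_undefined(self):
        with pytest.raises(UndefinedMetricError):
            vh.node50({"A": 0, "B": 0})

    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=40).filter(
            lambda v: sum(v) > 0
        )
    )
    def test_matches_exhaustive_oracle(self, values):
        counts = {f"n{i}": v for i, v in enumerate(values)}
        assert vh.node50(counts) == node50_oracle(counts)

    @given(
        st.lists(st.integers(min_value=1, max_value=1000), min_size=1, max_size=30),
        st.integers(min_value=2, max_value=7),
    )
    def test_invariant_under_label_permutation_and_scaling(self, values, factor):
        counts = {f"n{i}": v for i, v in enumerate(values)}
        permuted = {f"m{i}": v for i, v in enumerate(reversed(values))}
        scaled = {k: v * factor for k, v in counts.items()}
        k = vh.node50(counts)
        assert vh.node50(permuted) == k
        assert vh.node50(scaled) == k
        assert 1 <= k <= sum(v > 0 for v in values)


class TestMPD:
    def test_all_reads_on_one_node_gives_zero(self, cherry):
        assert vh.mpd(cherry, ["A"] * 5) == 0.0

    def test_single_pair(self, cherry):
        assert vh.mpd(cherry, {"A": 1, "B": 1}) == 3.0

    def test_three_reads_enumerated(self, cherry):
        # read pairs (A,A), (A,B), (A,B) -> distances (0, 3, 3), mean 2
        assert vh.mpd(cherry, {"A": 2, "B": 1}) == pytest.approx(2.0)

    def test_matches_brute_force_on_random_instances(self, eight_leaf):
        rng = np.random.default_rng(11)
        leaves = eight_leaf.leaves
        for _ in range(10):
            reads = list(rng.choice(leaves, size=int(rng.integers(2, 50))))
            assert vh.mpd(eight_leaf, reads) == pytest.approx(
                brute_force_mpd(eight_leaf, reads), abs=1e-12
            )

    def test_internal_node_hits_supported(self, balanced):
        # reads placed on the internal clade node and a leaf
        assert vh.mpd(balanced, {"N1": 1, "C": 1}) == pytest.approx(3.0)

    def test_fewer_than_two_reads_undefined(self, cherry):
        with pytest.raises(UndefinedMetricError):
            vh.mpd(cherry, {"A": 1})

    def test_presence_only_mode_ignores_multiplicity(self, cherry):
        assert vh.mpd(cherry, {"A": 10, "B": 1}, presence_only=True) == 3.0


class TestSesMPD:
    def _pool(self, tree, rng, low=5, high=60):
        return {leaf: int(c) for leaf, c in zip(tree.leaves, rng.integers(low, high, len(tree.leaves)))}

    def test_degenerate_null_gives_nan_ses(self, cherry):
        sample = {"A": 2, "B": 1}
        result = vh.ses_mpd(cherry, sample, sample, n_rand=50, seed=0)
        assert math.isnan(result.ses_mpd)
        assert result.null_sd == 0.0
        assert result.mpd_observed == pytest.approx(2.0)

    def test_pool_smaller_than_sample_rejected(self, cherry):
        with pytest.raises(ValidationError):
            vh.ses_mpd(cherry, {"A": 3, "B": 2}, {"A": 2, "B": 1}, seed=0)

    def test_clustered_sample_scores_negative(self, eight_leaf):
        pool = self._pool(eight_leaf, np.random.default_rng(2))
        clustered = {eight_leaf.leaves[0]: 30}
        result = vh.ses_mpd(eight_leaf, clustered, pool, n_rand=100, seed=7)
        assert result.ses_mpd < 0

    def test_seed_fixes_every_draw(self, eight_leaf):
        pool = self._pool(eight_leaf, np.random.default_rng(3))
        sample = {eight_leaf.leaves[0]: 5, eight_leaf.leaves[3]: 7}
        a = vh.ses_mpd(eight_leaf, sample, pool, n_rand=100, seed=42)
        b = vh.ses_mpd(eight_leaf, sample, pool, n_rand=100, seed=42)
        assert a.ses_mpd == b.ses_mpd
        assert a.null_mean == b.null_mean and a.null_sd == b.null_sd

    def test_branch_length_scaling_leaves_ses_unchanged(self, eight_leaf):
        """Scaling the tree by c scales mpd, null mean and SD by c; ses is invariant."""
        pool = self._pool(eight_leaf, np.random.default_rng(4))
        sample = {eight_leaf.leaves[1]: 10, eight_leaf.leaves[5]: 10}
        base = vh.ses_mpd(eight_leaf, sample, pool, n_rand=100, seed=9)
        doubled = vh.ses_mpd(eight_leaf.scaled(2.0), sample, pool, n_rand=100, seed=9)
        assert doubled.mpd_observed == pytest.approx(2.0 * base.mpd_observed, rel=1e-12)
        assert doubled.null_mean == pytest.approx(2.0 * base.null_mean, rel=1e-12)
        assert doubled.null_sd == pytest.approx(2.0 * base.null_sd, rel=1e-12)
        assert doubled.ses_mpd == pytest.approx(base.ses_mpd, rel=1e-9)

    def test_more_randomizations_only_perturb_ses_slightly(self, eight_leaf):
        """On a pool-like sample, 100 vs 1000 randomizations move ses by < 0.5."""
        rng = np.random.default_rng(6)
        pool = self._pool(eight_leaf, rng)
        leaves = eight_leaf.leaves
        expanded = np.repeat(np.arange(len(leaves)), [pool[l] for l in leaves])
        pick = rng.choice(expanded, size=40, replace=False)
        sample = {leaves[i]: int(c) for i, c in zip(*np.unique(pick, return_counts=True))}
        a = vh.ses_mpd(eight_leaf, sample, pool, n_rand=100, seed=1)
        b = vh.ses_mpd(eight_leaf, sample, pool, n_rand=1000, seed=1)
        assert abs(a.ses_mpd - b.ses_mpd) < 0.5

    def test_with_replacement_alternative_runs(self, eight_leaf):
        pool = self._pool(eight_leaf, np.random.default_rng(8))
        sample = {eight_leaf.leaves[0]: 4, eight_leaf.leaves[2]: 4}
        result = vh.ses_mpd(eight_leaf, sample, pool, n_rand=50, seed=3, with_replacement=True)
        assert np.isfinite(result.null_mean)
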