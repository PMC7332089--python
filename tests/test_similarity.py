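"""Window scoring, the distance transform, and UPGMA determinism."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from hypbench.similarity import (ScoringParams, cluster_sites, cross_scores,
                                 linkage_to_newick, pairwise_scores,
                                 score_to_distance, site_score, upgma_linkage)
from hypbench.windows import CANONICAL, SiteWindow

W13 = lambda text: SiteWindow(text=text, origin=("p", 1))  # noqa: E731

window_text = st.text(alphabet=CANONICAL, min_size=6, max_size=6).flatmap(
    lambda left: st.text(alphabet=CANONICAL, min_size=6, max_size=6).map(
        lambda right: left + "P" + right))


class TestSiteScore:
    @pytest.mark.parametrize("a, b, expected", [
        ("AAAAAAPAAAAAA", "AAAAAAPAAAAAA", 55.0),   # 12×B62(A,A) + B62(P,P)
        ("AAAAAAAAAAAAA", "AAAAAAAAAAAAA", 52.0),   # 13×B62(A,A)
        ("AAAAAAPAAAAAA", "------PAAAAAA", 21.0),   # gap run −10 + 31 aligned
    ])
    def test_frozen_examples(self, a, b, expected):
        assert site_score(W13(a), W13(b)) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            site_score(W13("AAAAAAPAAAAAA"), SiteWindow("AAAPAAA", ("p", 1), W=7))

    def test_joint_gap_run_is_charged_once(self):
        # both windows gapped in the same columns -> one run, not two
        a = W13("--AAAAPAAAAAA")
        assert site_score(a, a) == 10 * 4 + 7 + (-5 + -1)

    def test_invalid_gap_params(self):
        with pytest.raises(ValueError):
            ScoringParams(gap_open=-1.0, gap_extend=-5.0)

    @given(a=window_text, b=window_text)
    def test_symmetry_and_self_maximality(self, a, b):
        wa, wb = W13(a), W13(b)
        s_ab = site_score(wa, wb)
        assert s_ab == site_score(wb, wa)
        # gap-free windows: self-score dominates, strictly unless identical
        bound = min(site_score(wa, wa), site_score(wb, wb))
        assert s_ab < bound if a != b else s_ab == bound

    @given(texts=st.lists(window_text, min_size=2, max_size=8, unique=True))
    def test_pairwise_matches_scalar_path(self, texts):
        wins = [W13(t) for t in texts]
        S = pairwise_scores(wins, block=3)
        for i in range(len(wins)):
            for j in range(len(wins)):
                assert S[i, j] == site_score(wins[i], wins[j])

    def test_cross_scores_match_pairwise(self):
        wins = [W13("AAAAAAPAAAAAA"), W13("GGGGGGPGGGGGG"), W13("------PAAAAAA")]
        S = pairwise_scores(wins)
        C = cross_scores(wins[:2], wins, block=1)
        assert np.array_equal(C, S[:2])


class TestScoreToDistance:
    def test_identical_windows_alone_have_zero_distance(self):
        # with no other sites, the identical pair attains S_max itself
        wins = [W13("AAAAAAPAAAAAA")] * 2
        S = pairwise_scores(wins)
        d = score_to_distance([("a", 1), ("b", 1)], S)
        assert d.square()[0, 1] == 0.0

    def test_self_is_nearest(self):
        wins = [W13("AAAAAAPAAAAAA"), W13("GGGGGGPGGGGGG"), W13("WWNFQRPKHEDCY")]
        S = pairwise_scores(wins)
        d = score_to_distance([("a", 1), ("b", 1), ("c", 1)], S)
        sq = d.square()
        for i in range(3):
            self_dist = d.s_max - S[i, i]
            assert all(sq[i, j] > self_dist for j in range(3) if j != i)

    def test_order_reversal_is_exact(self):
        rng = np.random.default_rng(0)
        n = 12
        S = rng.normal(size=(n, n))
        S = (S + S.T) / 2
        np.fill_diagonal(S, S.max() + 1)
        d = score_to_distance([("p", i) for i in range(n)], S)
        iu = np.triu_indices(n, 1)
        rho = spearmanr(S[iu], d.square()[iu]).statistic
        assert rho == -1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score_to_distance([], np.zeros((0, 0)))


class TestClusterSites:
    def _dist(self, wins):
        keys = [("p", i + 1) for i in range(len(wins))]
        return score_to_distance(keys, pairwise_scores(wins))

    def test_identical_windows_form_one_cluster(self):
        d = self._dist([W13("AAAAAAPAAAAAA")] * 5)
        assert cluster_sites(d, 0.0).n_clusters == 1

    def test_two_groups_split_between_merge_heights(self):
        # two identical windows (d = 0) + one maximally dissimilar window
        wins = [W13("AAAAAAPAAAAAA"), W13("AAAAAAPAAAAAA"), W13("WWWWWWPWWWWWW")]
        d = self._dist(wins)
        heights = sorted(set(upgma_linkage(d.condensed, 3)[:, 2]))
        cut = (heights[0] + heights[1]) / 2
        ca = cluster_sites(d, cut)
        assert ca.n_clusters == 2
        assert ca.labels[("p", 1)] == ca.labels[("p", 2)] != ca.labels[("p", 3)]

    def test_cut_zero_gives_singletons(self):
        d = self._dist([W13("AAAAAAPAAAAAA"), W13("GGGGGGPGGGGGG"), W13("WWNFQRPKHEDCY")])
        ca = cluster_sites(d, 0.0)
        assert ca.n_clusters == 3
        # ids contiguous from 1 in site order
        assert [ca.labels[("p", i)] for i in (1, 2, 3)] == [1, 2, 3]

    def test_non_finite_distances_rejected(self):
        d = self._dist([W13("AAAAAAPAAAAAA"), W13("GGGGGGPGGGGGG")])
        d.condensed[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            cluster_sites(d, 1.0)

    @given(n=st.integers(3, 30), seed=st.integers(0, 10_000))
    def test_matches_scipy_on_tie_free_matrices(self, n, seed):
        """Independent cross-check: on generic (tie-free) random distance
        matrices our UPGMA agrees with scipy's average linkage, heights and
        flat partitions alike."""
        rng = np.random.default_rng(seed)
        condensed = rng.uniform(1.0, 2.0, size=n * (n - 1) // 2)
        ours = upgma_linkage(condensed, n)
        theirs = linkage(condensed, method="average")
        assert np.allclose(ours[:, 2], theirs[:, 2])
        cut = rng.uniform(1.0, 2.2)
        ours_flat = fcluster(ours, t=cut, criterion="distance")
        theirs_flat = fcluster(theirs, t=cut, criterion="distance")
        assert _partition(ours_flat) == _partition(theirs_flat)

    def test_newick_contains_all_leaves(self):
        d = self._dist([W13("AAAAAAPAAAAAA"), W13("GGGGGGPGGGGGG"), W13("WWNFQRPKHEDCY")])
        Z = upgma_linkage(d.condensed, 3)
        nwk = linkage_to_newick(Z, ["s1", "s2", "s3"])
        assert nwk.endswith(";") and all(f"s{i}" in nwk for i in (1, 2, 3))


def _partition(labels) -> set[frozenset[int]]:
    groups: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}
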