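"""Negative filtering, split semantics, and balanced replica sampling."""

from __future__ import annotations

import numpy as np
import pytest

from hypbench.assembly import (AssemblyConfig, BenchmarkDataset, build_splits,
                               filter_negatives, make_replicas)
from hypbench.io import ProteinRecord, SiteAnnotation
from hypbench.similarity import ClusterAssignment


def _assignment(mapping: dict) -> ClusterAssignment:
    return ClusterAssignment(labels=mapping, linkage=np.zeros((0, 4)),
                             cut_height=1.0, keys=list(mapping))


def _ann(pid, pos, label, source="Literature", confidence=None):
    return SiteAnnotation(pid, pos, "P", label, source, confidence=confidence)


class TestFilterNegatives:
    def test_negative_sharing_a_positive_cluster_is_removed(self):
        assignment = _assignment({("p", 1): 1, ("p", 2): 1, ("p", 3): 2})
        anns = [_ann("p", 1, "positive"), _ann("p", 2, "negative"),
                _ann("p", 3, "negative")]
        pool, removed = filter_negatives(assignment, anns)
        assert pool == {("p", 3)} and removed == {("p", 2)}

    def test_no_positives_keeps_every_negative(self):
        assignment = _assignment({("p", 1): 1, ("p", 2): 2})
        anns = [_ann("p", 1, "negative"), _ann("p", 2, "negative")]
        pool, removed = filter_negatives(assignment, anns)
        assert pool == {("p", 1), ("p", 2)} and not removed

    def test_everything_in_one_positive_cluster_warns(self):
        assignment = _assignment({("p", 1): 1, ("p", 2): 1})
        anns = [_ann("p", 1, "positive"), _ann("p", 2, "negative")]
        with pytest.warns(UserWarning, match="empty"):
            pool, removed = filter_negatives(assignment, anns)
        assert not pool and removed == {("p", 2)}

    def test_unclustered_site_is_an_error(self):
        assignment = _assignment({("p", 1): 1})
        anns = [_ann("p", 1, "positive"), _ann("p", 9, "negative")]
        with pytest.raises(KeyError, match=r"\('p', 9\)"):
            filter_negatives(assignment, anns)


class TestBuildSplits:
    proteins = {"col": ProteinRecord("col", "P" * 40, collagen=True),
                "oth": ProteinRecord("oth", "P" * 40)}

    def test_partition_by_source_and_union(self):
        anns = ([_ann("oth", i, "positive", "Literature") for i in (1, 2, 3)]
                + [_ann("oth", i, "positive", "MS-Kim") for i in (10, 11)]
                + [_ann("oth", 11, "positive", "MS-HeLa", confidence=0.95)]
                + [_ann("oth", 30, "negative")])
        splits = build_splits(anns, self.proteins, {("oth", 30)})
        assert len(splits["Literature"].positives) == 3
        assert len(splits["MS-Kim"].positives) == 2
        assert len(splits["MS-HeLa"].positives) == 1
        # shared site (oth, 11) deduplicated in the MS union
        assert len(splits["MS"].positives) == 2
        assert len(splits["Collagen"].positives) == 0

    def test_low_confidence_hela_site_dropped_everywhere(self):
        anns = [_ann("oth", 1, "positive", "MS-HeLa", confidence=0.5),
                _ann("oth", 2, "positive", "MS-HeLa", confidence=0.9),
                _ann("oth", 30, "negative")]
        splits = build_splits(anns, self.proteins, {("oth", 30)})
        for name in ("MS-HeLa", "MS"):
            assert ("oth", 1) not in splits[name].positives
        assert ("oth", 2) in splits["MS-HeLa"].positives

    def test_collagen_sites_appear_in_both_parent_and_collagen_split(self):
        anns = ([_ann("col", i, "positive", "Literature") for i in (1, 2, 3, 4)]
                + [_ann("oth", 30, "negative")])
        splits = build_splits(anns, self.proteins, {("oth", 30)})
        for name in ("Literature", "Literature-collagen", "Collagen"):
            assert len(splits[name].positives) == 4
        assert splits["MS-collagen"].positives == []

    def test_all_splits_share_the_negative_pool(self):
        anns = [_ann("oth", 1, "positive", "Literature"), _ann("oth", 30, "negative")]
        splits = build_splits(anns, self.proteins, {("oth", 30)})
        pools = {tuple(ds.negatives) for ds in splits.values()}
        assert pools == {(("oth", 30),)}

    def test_positive_negative_overlap_rejected(self):
        with pytest.raises(ValueError, match="both positive and negative"):
            BenchmarkDataset("x", positives=[("p", 1)], negatives=[("p", 1)])

    def test_bad_confidence_threshold(self):
        with pytest.raises(ValueError):
            AssemblyConfig(confidence_min=1.5)


class TestMakeReplicas:
    dataset = BenchmarkDataset(
        split="t",
        positives=[("p", i) for i in range(1, 11)],
        negatives=[("n", i) for i in range(1, 41)],
    )

    def test_seventy_percent_balance(self):
        reps = make_replicas(self.dataset, n_replicas=5, seed=1)
        for r in reps:
            assert len(r.positives) == len(r.negatives) == 7  # floor(0.7 × 10)
            assert len(set(r.positives)) == 7 and len(set(r.negatives)) == 7

    def test_determinism_and_seed_sensitivity(self):
        a = make_replicas(self.dataset, n_replicas=3, seed=9)
        b = make_replicas(self.dataset, n_replicas=3, seed=9)
        c = make_replicas(self.dataset, n_replicas=3, seed=10)
        assert [(r.positives, r.negatives) for r in a] == [(r.positives, r.negatives) for r in b]
        assert any(x.negatives != y.negatives for x, y in zip(a, c))

    def test_replicas_are_independently_reproducible(self):
        full = make_replicas(self.dataset, n_replicas=5, seed=9)
        # rebuilding only replica 4 (same derived stream) gives the same draw
        again = make_replicas(self.dataset, n_replicas=5, seed=9)[4]
        assert full[4].positives == again.positives

    def test_pool_too_small(self):
        tiny = BenchmarkDataset("t", positives=[("p", i) for i in range(1, 11)],
                                negatives=[("n", 1)])
        with pytest.raises(ValueError, match="need 7, have 1"):
            make_replicas(tiny, n_replicas=1)

    def test_negatives_resampled_per_replica(self):
        reps = make_replicas(self.dataset, n_replicas=50, seed=3)
        assert len({tuple(sorted(r.negatives)) for r in reps}) == 50
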