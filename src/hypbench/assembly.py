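"""From clustered, labeled sites to evaluation datasets.

Three stages:

1. *Negative filtering* — negatives that fall in a cluster containing at
   least one hydroxylated proline are too similar to positives to be trusted
   as negatives, and are removed; the surviving negatives form a single pool
   shared by every split.
2. *Splits* — positives are partitioned by evidence source (Literature,
   MS-HeLa, MS-Kim, their union MS) and by the collagen flag of the host
   protein (Literature-collagen, MS-collagen, Collagen).  MS-HeLa sites are
   first filtered to confidence ≥ 0.8 to limit assignment errors.
3. *Replicas* — each evaluation runs on 1,000 balanced subsamples: 70% of a
   split's positives and the same number of negatives, both drawn without
   replacement, negatives re-drawn independently for every replica.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from hypbench.io import ProteinRecord, SiteAnnotation, SiteKey, SOURCES
from hypbench.similarity import ClusterAssignment

logger = logging.getLogger(__name__)

SPLIT_NAMES = ("Literature", "MS-HeLa", "MS-Kim", "MS",
               "Literature-collagen", "MS-collagen", "Collagen")


@dataclass(frozen=True)
class AssemblyConfig:
    """Dataset-construction knobs.

    ``confidence_min`` drops low-confidence positives before splitting; it
    applies to the sources in ``confidence_sources`` (MS-HeLa by default,
    since that collection reports per-site assignment probabilities).
    """

    confidence_min: float = 0.8
    confidence_sources: tuple[str, ...] = ("MS-HeLa",)
    splits: tuple[str, ...] = SPLIT_NAMES

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_min <= 1.0:
            raise ValueError(f"confidence_min {self.confidence_min} outside [0, 1]")
        unknown = set(self.splits) - set(SPLIT_NAMES)
        if unknown:
            raise ValueError(f"unknown split names: {sorted(unknown)}")


@dataclass
class BenchmarkDataset:
    """One named evaluation split: its positives plus the shared negative pool."""

    split: str
    positives: list[SiteKey]
    negatives: list[SiteKey]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"split {self.split!r}: {len(overlap)} sites are both "
                             f"positive and negative")


@dataclass(frozen=True)
class ReplicaSet:
    """One balanced subsample: equal numbers of positives and negatives."""

    index: int
    positives: tuple[SiteKey, ...]
    negatives: tuple[SiteKey, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("replica is not balanced")

    @property
    def sites(self) -> tuple[SiteKey, ...]:
        return self.positives + self.negatives


def positive_keys(annotations: Iterable[SiteAnnotation]) -> set[SiteKey]:
    """Sites positive under at least one evidence source."""
    return {a.key for a in annotations if a.is_positive}


def filter_negatives(assignment: ClusterAssignment,
                     annotations: Sequence[SiteAnnotation]) -> tuple[set[SiteKey], set[SiteKey]]:
    """Split the negatives into (kept pool, removed) by the positive-cluster rule.

    A negative survives only if its cluster contains no positive site.
    Returns ``(pool, removed)``; every annotated site must have a cluster id.
    """
    pos = positive_keys(annotations)
    neg = {a.key for a in annotations} - pos
    for key in sorted(pos | neg):
        if key not in assignment.labels:
            raise KeyError(f"site {key} has no cluster assignment")
    positive_clusters = {assignment.labels[k] for k in pos}
    pool = {k for k in neg if assignment.labels[k] not in positive_clusters}
    removed = neg - pool
    logger.info("negative filtering: %d kept, %d removed (fell in %d positive clusters)",
                len(pool), len(removed), len(positive_clusters))
    if neg and not pool:
        warnings.warn("all negatives fall in positive clusters; the negative pool is empty",
                      stacklevel=2)
    return pool, removed


def build_splits(annotations: Sequence[SiteAnnotation],
                 proteins: Mapping[str, ProteinRecord],
                 negative_pool: set[SiteKey],
                 config: AssemblyConfig = AssemblyConfig(),
                 metadata: dict | None = None) -> dict[str, BenchmarkDataset]:
    """Build the named evaluation splits over a shared negative pool.

    Positives are deduplicated by (protein, position) within each split; a
    site reported by both MS sources appears in both MS-HeLa and MS-Kim and
    once in MS.  Low-confidence positives from the configured sources are
    dropped everywhere (a logged count records how many).
    """
    dropped_conf = 0
    by_source: dict[str, set[SiteKey]] = {s: set() for s in SOURCES}
    for a in annotations:
        if not a.is_positive:
            continue
        if a.source not in SOURCES:
            raise ValueError(f"unknown source tag {a.source!r} for site {a.key}")
        if (a.source in config.confidence_sources and a.confidence is not None
                and a.confidence < config.confidence_min):
            dropped_conf += 1
            continue
        by_source[a.source].add(a.key)
    if dropped_conf:
        logger.info("confidence filter (< %.2f): dropped %d positive annotations",
                    config.confidence_min, dropped_conf)

    def is_collagen(key: SiteKey) -> bool:
        return proteins[key[0]].collagen

    ms = by_source["MS-HeLa"] | by_source["MS-Kim"]
    literature = by_source["Literature"]
    members: dict[str, set[SiteKey]] = {
        "Literature": literature,
        "MS-HeLa": by_source["MS-HeLa"],
        "MS-Kim": by_source["MS-Kim"],
        "MS": ms,
        "Literature-collagen": {k for k in literature if is_collagen(k)},
        "MS-collagen": {k for k in ms if is_collagen(k)},
        "Collagen": {k for k in literature | ms if is_collagen(k)},
    }
    meta = dict(metadata or {})
    meta["confidence_dropped"] = dropped_conf
    pool = sorted(negative_pool)
    datasets = {}
    for name in config.splits:
        datasets[name] = BenchmarkDataset(
            split=name, positives=sorted(members[name]), negatives=list(pool),
            metadata=dict(meta),
        )
    return datasets


def make_replicas(dataset: BenchmarkDataset, n_replicas: int = 1000,
                  frac: float = 0.7, seed: int = 0) -> list[ReplicaSet]:
    """Balanced replica subsamples of one split.

    Each replica draws floor(frac × P) positives without replacement from the
    split's positives and the same number of negatives without replacement
    from the shared pool; negatives are re-drawn independently per replica.
    Replica r uses the derived stream (seed, r), so any single replica can be
    regenerated without the others.
    """
    if n_replicas < 1:
        raise ValueError(f"n_replicas must be >= 1, got {n_replicas}")
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    P = len(dataset.positives)
    k = int(np.floor(frac * P))
    if k < 1:
        raise ValueError(f"split {dataset.split!r}: {P} positives yield empty replicas at frac={frac}")
    if len(dataset.negatives) < k:
        raise ValueError(
            f"split {dataset.split!r}: negative pool too small: need {k}, have {len(dataset.negatives)}"
        )
    replicas = []
    for r in range(n_replicas):
        rng = np.random.default_rng([seed, r])
        pos_idx = rng.choice(P, size=k, replace=False)
        neg_idx = rng.choice(len(dataset.negatives), size=k, replace=False)
        replicas.append(ReplicaSet(
            index=r,
            positives=tuple(dataset.positives[i] for i in pos_idx),
            negatives=tuple(dataset.negatives[i] for i in neg_idx),
            seed=seed,
        ))
    return replicas
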