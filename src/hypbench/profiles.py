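"""Cluster-seeded positional-profile baseline ("naive" upper bound).

Every cluster that contains at least one positive site seeds one profile:
a per-column log-odds matrix over the 20 residues plus the gap symbol (a
21st emission — terminal padding is itself informative), estimated from ALL
member windows of the cluster with a small pseudocount.  Because windows are
fixed-length and pre-aligned on the central proline, positional score
matrices carry the same information as profile HMMs would at this width; no
insert/delete states are needed.

A site is scanned against the whole database; its best score s is converted
to an E-value E(s) = D × P_null(best-of-database score ≥ s), where the null
is a right-tail Gumbel fitted to the max-over-profiles score of windows
sampled i.i.d. from background residue frequencies.  Hits with E ≤ 1.0 are
positive predictions.  By construction a background window exceeds the E ≤ 1
cut with probability ≈ 1/D.

This baseline deliberately overlaps its training and test positives; it is
an upper performance bound, not a usable predictor for novel sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gumbel_r

from hypbench.io import PredictionRecord, ProteinRecord, SiteKey
from hypbench.similarity import ClusterAssignment
from hypbench.windows import CANONICAL, GAP_CODE, SiteWindow, encode_windows

logger = logging.getLogger(__name__)

N_SYMBOLS = 21  # 20 residues + gap


@dataclass
class ProfileModel:
    """Per-column log-odds for one positive cluster."""

    cluster_id: int
    log_odds: np.ndarray  # (W, 21)
    seed_members: tuple[SiteKey, ...]
    background: np.ndarray  # (21,)

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_odds).all():
            raise ValueError(f"profile {self.cluster_id}: non-finite log-odds")
        if not self.seed_members:
            raise ValueError(f"profile {self.cluster_id}: empty seed membership")

    @property
    def W(self) -> int:
        return self.log_odds.shape[0]


@dataclass
class ProfileDatabase:
    profiles: list[ProfileModel]
    W: int
    background: np.ndarray

    def __len__(self) -> int:
        return len(self.profiles)

    def score_windows(self, windows: Sequence[SiteWindow]) -> np.ndarray:
        """(n_windows, n_profiles) raw log-odds scores."""
        enc = encode_windows(windows)
        cols = np.arange(self.W)
        out = np.empty((len(windows), len(self.profiles)), dtype=np.float64)
        for j, prof in enumerate(self.profiles):
            out[:, j] = prof.log_odds[cols, enc].sum(axis=1)
        return out


@dataclass(frozen=True)
class ProfileScanConfig:
    """Decision rule and calibrated null model for profile scanning."""

    evalue_max: float = 1.0
    database_size: int = 0
    null_loc: float | None = None
    null_scale: float | None = None

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError(f"evalue_max must be positive, got {self.evalue_max}")

    @property
    def calibrated(self) -> bool:
        return self.null_loc is not None and self.null_scale is not None

    def evalue(self, score: float | np.ndarray) -> float | np.ndarray:
        if not self.calibrated:
            raise RuntimeError("profile database is not calibrated; run calibrate_null first")
        return self.database_size * gumbel_r.sf(score, loc=self.null_loc, scale=self.null_scale)


def background_from_proteins(proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
                             gap_freq: float = 0.01) -> np.ndarray:
    """21-symbol background: proteome residue composition plus a small gap mass."""
    records = proteins.values() if isinstance(proteins, Mapping) else proteins
    counts = np.zeros(20, dtype=np.float64)
    index = {aa: i for i, aa in enumerate(CANONICAL)}
    for prot in records:
        for aa in prot.sequence:
            i = index.get(aa)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        raise ValueError("no canonical residues in proteome")
    bg = np.empty(N_SYMBOLS)
    bg[:20] = counts / counts.sum() * (1.0 - gap_freq)
    bg[GAP_CODE] = gap_freq
    return bg


def build_profiles(assignment: ClusterAssignment,
                   windows_by_key: Mapping[SiteKey, SiteWindow],
                   positives: set[SiteKey],
                   pseudocount: float = 0.05,
                   background: np.ndarray | None = None) -> ProfileDatabase:
    """One profile per cluster containing at least one positive site.

    All member windows of a seed cluster contribute — including its negative
    sites, which are deliberately retained in the seeds.  The default
    pseudocount is weak (0.05 ≪ 1/21) so that small seeds — the common case
    outside collagen — remain sharply discriminative while large diffuse
    seeds keep their members well inside the significant tail.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    members = assignment.members()
    positive_clusters = sorted({assignment.labels[k] for k in positives
                                if k in assignment.labels})
    if not positive_clusters:
        raise ValueError("no clusters contain a positive site; nothing to seed")
    some_key = next(iter(windows_by_key))
    W = windows_by_key[some_key].W
    if background is None:
        counts = np.bincount(
            encode_windows(list(windows_by_key.values())).ravel(), minlength=N_SYMBOLS
        ).astype(float)
        background = np.maximum(counts / counts.sum(), 1e-4)
        background /= background.sum()
    profiles = []
    for cid in positive_clusters:
        seed_keys = tuple(members[cid])
        enc = encode_windows([windows_by_key[k] for k in seed_keys])
        counts = np.zeros((W, N_SYMBOLS), dtype=np.float64)
        for c in range(W):
            counts[c] = np.bincount(enc[:, c], minlength=N_SYMBOLS)
        freqs = (counts + pseudocount) / (len(seed_keys) + N_SYMBOLS * pseudocount)
        profiles.append(ProfileModel(cluster_id=cid,
                                     log_odds=np.log(freqs / background),
                                     seed_members=seed_keys,
                                     background=background))
    logger.info("profile database: %d profiles seeded from %d positive clusters",
                len(profiles), len(positive_clusters))
    return ProfileDatabase(profiles=profiles, W=W, background=background)


def sample_null_windows(background: np.ndarray, W: int, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Encoded windows drawn i.i.d. from the background residue distribution.

    Null windows are gap-free: the null models a random stretch of real
    sequence, not a terminal padding pattern.
    """
    res_bg = background[:20] / background[:20].sum()
    return rng.choice(20, size=(n, W), p=res_bg).astype(np.int8)


def calibrate_null(db: ProfileDatabase, n_null: int = 20000, seed: int = 0,
                   evalue_max: float = 1.0) -> ProfileScanConfig:
    """Fit the null distribution of the best-of-database score.

    Scores of ``n_null`` background windows against every profile are reduced
    to their per-window maximum; a Gumbel (the natural family for a maximum)
    is fitted to those maxima and supplies the tail probability behind the
    E-value.
    """
    if n_null < 1000:
        warnings.warn(f"n_null={n_null} is small; the E-value tail will be poorly estimated",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    enc = sample_null_windows(db.background, db.W, n_null, rng)
    cols = np.arange(db.W)
    best = np.full(n_null, -np.inf)
    for prof in db.profiles:
        np.maximum(best, prof.log_odds[cols, enc].sum(axis=1), out=best)
    loc, scale = gumbel_r.fit(best)
    logger.info("null calibration: %d windows, best-score Gumbel loc=%.3f scale=%.3f",
                n_null, loc, scale)
    return ProfileScanConfig(evalue_max=evalue_max, database_size=len(db),
                             null_loc=float(loc), null_scale=float(scale))


def scan_site(window: SiteWindow, db: ProfileDatabase,
              cfg: ProfileScanConfig) -> tuple[float, int]:
    """Best E-value of one window against the database, and the binary call."""
    row = scan_sites([window], db, cfg)
    return float(row["evalue"].iloc[0]), int(row["call"].iloc[0])


def scan_sites(windows: Sequence[SiteWindow], db: ProfileDatabase,
               cfg: ProfileScanConfig) -> pd.DataFrame:
    """Scan windows against the profile database.

    Returns a frame with columns protein_id, position, score (best raw
    log-odds), evalue, call (1 iff E ≤ evalue_max).
    """
    if not cfg.calibrated:
        raise RuntimeError("profile database is not calibrated; run calibrate_null first")
    scores = db.score_windows(windows)
    best = scores.max(axis=1)
    evalues = np.asarray(cfg.evalue(best), dtype=float)
    return pd.DataFrame({
        "protein_id": [w.origin[0] for w in windows],
        "position": [w.origin[1] for w in windows],
        "score": best,
        "evalue": evalues,
        "call": (evalues <= cfg.evalue_max).astype(int),
    })


def predictions_from_scan(scan: pd.DataFrame, method: str = "Naive-Profile",
                          level: str | None = None) -> list[PredictionRecord]:
    """Convert a scan result into prediction records (score = −log10 E)."""
    tiny = np.finfo(float).tiny
    return [
        PredictionRecord(protein_id=row.protein_id, position=int(row.position),
                         call=int(row.call),
                         score=float(-np.log10(max(row.evalue, tiny))),
                         method=method, level=level)
        for row in scan.itertuples(index=False)
    ]


def profiles_to_tsv(db: ProfileDatabase, path) -> None:
    """Serialize the database as TSV: cluster id, column, 21 scores."""
    symbols = list(CANONICAL) + ["-"]
    with open(path, "w") as fh:
        fh.write("cluster_id\tcolumn\t" + "\t".join(symbols) + "\n")
        for prof in db.profiles:
            for c in range(prof.W):
                vals = "\t".join(f"{v:.6g}" for v in prof.log_odds[c])
                fh.write(f"{prof.cluster_id}\t{c}\t{vals}\n")


def rescan_config(cfg: ProfileScanConfig, evalue_max: float) -> ProfileScanConfig:
    """Same calibration, different decision threshold."""
    return replace(cfg, evalue_max=evalue_max)
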