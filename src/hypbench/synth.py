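"""Synthetic proteomes with hydroxylation-like site structure.

The generator emulates the statistical shape of a real proline-hydroxylation
benchmark without imitating mass-spectrometry physics:

* *Collagen-like proteins* carry an (X-Y-Gly)n triple-helix repeat between
  random flanks.  X positions are proline with probability 0.28 and Y
  positions with 0.45; a Y-position proline is a true hydroxylation site
  with probability 0.85, so ~38% of triplets carry a Y-hydroxyproline —
  the canonical collagen statistics.
* *Non-collagen proteins* are background-composition sequences with a few
  disorder-marked intervals; short proline-bearing signalling motifs are
  embedded only inside disorder, and each occurrence is a true site with a
  configurable probability.  Two motifs exist: a "known" motif whose sites
  are mostly literature-annotated (the training era) and a "novel" motif
  whose sites surface only in the MS sources — the structure that lets a
  memorizing predictor look perfect on old data and random on new data.
* *Annotation incompleteness* h relabels a fraction of true positives as
  negatives in the observed table, emulating sites not yet discovered.

True labels go to a separate manifest that the benchmarking pipeline never
reads; observed annotations, sequences and feature tracks are emitted in
exactly the formats the loaders accept.  Everything is reproducible from the
master seed, including byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hypbench.assembly import BenchmarkDataset
from hypbench.io import (PredictionRecord, ProteinRecord, SiteAnnotation, SiteKey,
                         write_annotations, write_fasta, write_tracks)
from hypbench.similarity import ScoringParams, _matrix_array, cross_scores
from hypbench.windows import CANONICAL, SiteWindow

#: Average residue composition of well-curated proteomes, in CANONICAL order.
BACKGROUND_FREQS = np.array([
    0.0825, 0.0138, 0.0546, 0.0672, 0.0386, 0.0707, 0.0228, 0.0591, 0.0580,
    0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0665, 0.0536, 0.0686,
    0.0110, 0.0292,
])
BACKGROUND_FREQS /= BACKGROUND_FREQS.sum()

_P_INDEX = CANONICAL.index("P")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic benchmark (defaults = the standard
    desk-scale benchmark used throughout the test-suite and examples)."""

    n_collagen: int = 10
    n_other: int = 150
    other_length: tuple[int, int] = (150, 350)
    collagen_repeats: int = 25           # (X-Y-G) triplets per protein
    collagen_flank: tuple[int, int] = (20, 40)
    collagen_x_pro: float = 0.28         # P(X position is proline)
    collagen_y_pro: float = 0.45         # P(Y position is proline)
    y_hydroxylation_prob: float = 0.85   # P(Y-proline is a true site)
    motif_known: str = "LSPTEK"          # training-era signalling motif
    motif_novel: str = "WNPFGQ"          # novel motif seen only in MS sources
    motif_rate: float = 0.6              # Poisson mean occurrences/protein/motif
    motif_positive_prob: float = 0.8
    disorder_regions: tuple[int, int] = (1, 3)
    disorder_length: tuple[int, int] = (25, 60)
    incompleteness: float = 0.0          # h: fraction of true positives unlabeled
    target_prevalence: float = 0.10      # intended positive fraction among prolines
    collagen_literature_prob: float = 0.85
    known_literature_prob: float = 0.70
    novel_hela_prob: float = 0.50        # remainder of each group goes to MS-Kim
    hela_certain_prob: float = 0.75      # P(MS-HeLa confidence == 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("collagen_x_pro", "collagen_y_pro", "y_hydroxylation_prob",
                     "motif_positive_prob", "collagen_literature_prob",
                     "known_literature_prob", "novel_hela_prob", "hela_certain_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.incompleteness < 1.0:
            raise ValueError(f"incompleteness must be in [0, 1), got {self.incompleteness}")
        if min(self.n_collagen, self.n_other) < 0:
            raise ValueError("protein counts must be non-negative")
        for m in (self.motif_known, self.motif_novel):
            if m.count("P") != 1:
                raise ValueError(f"motif {m!r} must contain exactly one proline")


@dataclass
class SyntheticBenchmark:
    """Generator output: records, observed annotations, and the truth manifest."""

    proteins: dict[str, ProteinRecord]
    annotations: list[SiteAnnotation]
    manifest: pd.DataFrame
    config: SyntheticConfig = field(repr=False, default=None)


def expected_prevalence(cfg: SyntheticConfig) -> float:
    """Analytic expectation of the true-positive fraction among prolines."""
    bg_p = BACKGROUND_FREQS[_P_INDEX]
    fl = (cfg.collagen_flank[0] + cfg.collagen_flank[1]) / 2
    col_pro = cfg.collagen_repeats * (cfg.collagen_x_pro + cfg.collagen_y_pro) + 2 * fl * bg_p
    col_pos = cfg.collagen_repeats * cfg.collagen_y_pro * cfg.y_hydroxylation_prob
    length = (cfg.other_length[0] + cfg.other_length[1]) / 2
    n_occ = 2 * cfg.motif_rate  # both motifs
    oth_pro = length * bg_p + n_occ * (1 - len(cfg.motif_known) * bg_p)
    oth_pos = n_occ * cfg.motif_positive_prob
    prolines = cfg.n_collagen * col_pro + cfg.n_other * oth_pro
    positives = cfg.n_collagen * col_pos + cfg.n_other * oth_pos
    if prolines == 0:
        raise ValueError("configuration yields no candidate prolines")
    return positives / prolines


def _draw_background(rng: np.random.Generator, n: int) -> str:
    return "".join(CANONICAL[i] for i in rng.choice(20, size=n, p=BACKGROUND_FREQS))


def _collagen_protein(cfg: SyntheticConfig, rng: np.random.Generator,
                      pid: str) -> tuple[ProteinRecord, list[tuple[int, str, bool]]]:
    """Returns the record and a list of (1-based position, site_type, true_positive)."""
    n_flank = rng.integers(cfg.collagen_flank[0], cfg.collagen_flank[1] + 1)
    c_flank = rng.integers(cfg.collagen_flank[0], cfg.collagen_flank[1] + 1)
    n_seq = _draw_background(rng, int(n_flank))
    c_seq = _draw_background(rng, int(c_flank))
    repeat = []
    for _ in range(cfg.collagen_repeats):
        x = "P" if rng.random() < cfg.collagen_x_pro else _draw_background(rng, 1)
        y = "P" if rng.random() < cfg.collagen_y_pro else _draw_background(rng, 1)
        repeat.append(x + y + "G")
    region = "".join(repeat)
    seq = n_seq + region + c_seq
    sites = []
    for t in range(cfg.collagen_repeats):
        y_off = 3 * t + 1  # 0-based within the repeat region
        if region[y_off] == "P":
            pos = int(n_flank) + y_off + 1  # 1-based in the full sequence
            positive = rng.random() < cfg.y_hydroxylation_prob
            sites.append((pos, "collagen_y", positive))
    prot = ProteinRecord(id=pid, sequence=seq, collagen=True)
    lc = np.zeros(len(seq), dtype=np.int8)
    lc[int(n_flank):int(n_flank) + len(region)] = 1
    prot.tracks = {"disorder": np.zeros(len(seq), dtype=np.int8),
                   "helix": np.zeros(len(seq), dtype=np.int8),
                   "sheet": np.zeros(len(seq), dtype=np.int8),
                   "low_complexity": lc}
    return prot, sites


def _other_protein(cfg: SyntheticConfig, rng: np.random.Generator,
                   pid: str) -> tuple[ProteinRecord, list[tuple[int, str, bool]]]:
    length = int(rng.integers(cfg.other_length[0], cfg.other_length[1] + 1))
    seq = list(_draw_background(rng, length))
    # Disorder intervals, one per roughly equal chunk of the sequence.
    n_dis = int(rng.integers(cfg.disorder_regions[0], cfg.disorder_regions[1] + 1))
    disorder = np.zeros(length, dtype=np.int8)
    chunk = length // n_dis
    intervals = []
    for d in range(n_dis):
        dlen = int(rng.integers(cfg.disorder_length[0], cfg.disorder_length[1] + 1))
        lo, hi = d * chunk, min((d + 1) * chunk, length)
        dlen = min(dlen, hi - lo)
        start = int(rng.integers(lo, hi - dlen + 1)) if hi - lo > dlen else lo
        disorder[start:start + dlen] = 1
        intervals.append((start, start + dlen))
    # Embed motif occurrences inside disorder, never within 7 of either end
    # and never overlapping a previous occurrence.
    sites = []
    occupied: list[tuple[int, int]] = []
    for motif, site_type in ((cfg.motif_known, "motif_known"),
                             (cfg.motif_novel, "motif_novel")):
        m = len(motif)
        p_off = motif.index("P")
        for _ in range(int(rng.poisson(cfg.motif_rate))):
            for _attempt in range(20):
                lo, hi = intervals[int(rng.integers(len(intervals)))]
                lo, hi = max(lo, 7), min(hi, length - 7 - m)
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                if any(start < e and start + m > s for s, e in occupied):
                    continue
                seq[start:start + m] = motif
                occupied.append((start, start + m))
                positive = rng.random() < cfg.motif_positive_prob
                sites.append((start + p_off + 1, site_type, positive))
                break
    # Helix/sheet stretches outside disorder; short low-complexity patches.
    helix = np.zeros(length, dtype=np.int8)
    sheet = np.zeros(length, dtype=np.int8)
    lc = np.zeros(length, dtype=np.int8)
    for track, n_iv, span in ((helix, 3, (8, 25)), (sheet, 3, (5, 12)), (lc, 1, (6, 15))):
        for _ in range(int(rng.integers(0, n_iv + 1))):
            ivlen = int(rng.integers(span[0], span[1] + 1))
            if length <= ivlen:
                continue
            start = int(rng.integers(0, length - ivlen))
            if track is not lc and disorder[start:start + ivlen].any():
                continue
            track[start:start + ivlen] = 1
    prot = ProteinRecord(id=pid, sequence="".join(seq), collagen=False)
    prot.tracks = {"disorder": disorder, "helix": helix, "sheet": sheet,
                   "low_complexity": lc}
    return prot, sites


def _assign_source(site_type: str, cfg: SyntheticConfig, rng: np.random.Generator) -> str:
    if site_type == "collagen_y":
        return "Literature" if rng.random() < cfg.collagen_literature_prob else "MS-Kim"
    if site_type == "motif_known":
        return "Literature" if rng.random() < cfg.known_literature_prob else "MS-Kim"
    if site_type == "motif_novel":
        return "MS-HeLa" if rng.random() < cfg.novel_hela_prob else "MS-Kim"
    raise ValueError(site_type)


def generate_proteome(cfg: SyntheticConfig = SyntheticConfig()) -> SyntheticBenchmark:
    """Generate proteins, observed annotations, tracks and the truth manifest.

    Raises if the configured motif densities cannot plausibly deliver the
    target positive-proline prevalence (off by more than a factor of two).
    """
    exp_prev = expected_prevalence(cfg)
    if not cfg.target_prevalence / 2 <= exp_prev <= cfg.target_prevalence * 2:
        raise ValueError(
            f"infeasible prevalence target {cfg.target_prevalence}: the configured "
            f"collagen/motif densities give an expected prevalence of {exp_prev:.3f}; "
            f"adjust protein counts, repeat probabilities or motif rates"
        )
    rng = np.random.default_rng(cfg.seed)
    proteins: dict[str, ProteinRecord] = {}
    typed_sites: dict[SiteKey, tuple[str, bool]] = {}
    for i in range(cfg.n_collagen):
        prot, sites = _collagen_protein(cfg, rng, f"COL{i + 1:04d}")
        proteins[prot.id] = prot
        typed_sites.update({(prot.id, pos): (t, p) for pos, t, p in sites})
    for i in range(cfg.n_other):
        prot, sites = _other_protein(cfg, rng, f"OTH{i + 1:04d}")
        proteins[prot.id] = prot
        typed_sites.update({(prot.id, pos): (t, p) for pos, t, p in sites})

    annotations: list[SiteAnnotation] = []
    manifest_rows = []
    for pid in proteins:
        prot = proteins[pid]
        for idx, aa in enumerate(prot.sequence):
            if aa != "P":
                continue
            key = (pid, idx + 1)
            site_type, true_pos = typed_sites.get(key, ("background", False))
            observed = true_pos and rng.random() >= cfg.incompleteness
            if observed:
                source = _assign_source(site_type, cfg, rng)
                confidence = None
                evidence = None
                if source == "MS-HeLa":
                    confidence = (1.0 if rng.random() < cfg.hela_certain_prob
                                  else float(np.round(rng.uniform(0.5, 1.0), 3)))
                elif source == "Literature":
                    evidence = "ECO:0000269"
            else:
                source = ("Literature", "MS-HeLa", "MS-Kim")[int(rng.integers(3))]
                confidence, evidence = None, None
            annotations.append(SiteAnnotation(
                protein_id=pid, position=idx + 1, residue="P",
                label="positive" if observed else "negative",
                source=source, confidence=confidence, evidence_code=evidence,
            ))
            manifest_rows.append({
                "protein_id": pid, "position": idx + 1, "site_type": site_type,
                "true_label": int(true_pos), "observed_label": int(observed),
                "source": source,
                "confidence": "" if confidence is None else confidence,
                "collagen": int(prot.collagen),
            })
    manifest = pd.DataFrame(manifest_rows)
    return SyntheticBenchmark(proteins=proteins, annotations=annotations,
                              manifest=manifest, config=cfg)


def write_benchmark(bench: SyntheticBenchmark, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA + annotation/track TSVs (pipeline inputs) and the truth
    manifest (tests only); byte-identical for identical configs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteome.fasta",
        "annotations": outdir / "annotations.tsv",
        "tracks": outdir / "tracks.tsv",
        "manifest": outdir / "truth_manifest.tsv",
    }
    write_fasta(bench.proteins, paths["fasta"])
    collagen_ids = {p.id for p in bench.proteins.values() if p.collagen}
    write_annotations(bench.annotations, paths["annotations"], collagen_ids=collagen_ids)
    write_tracks(bench.proteins, paths["tracks"])
    bench.manifest.to_csv(paths["manifest"], sep="\t", index=False, lineterminator="\n")
    return paths


@dataclass(frozen=True)
class SimulatedPredictorConfig:
    """A tunable caricature of a trained site predictor.

    With memorization weight λ the predictor fires on sites whose window
    scores at least τ (BLOSUM62 scale) against some training positive; with
    weight 1−λ it generalizes, recognizing genuinely modified sites with
    probability g.  Every call is flipped with noise ε.  λ=1 with small ε is
    the pure memorizer that looks excellent on its training era and random
    on novel motifs.
    """

    training_split: str = "Literature"
    lam: float = 1.0
    tau: float = 35.0  # between within-motif-family (~40+) and cross-family (~25) scores
    g: float = 0.0
    epsilon: float = 0.01
    seed: int = 0
    method: str = "SimPredictor"

    def __post_init__(self) -> None:
        for name in ("lam", "g", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def simulate_predictor(windows_by_key: Mapping[SiteKey, SiteWindow],
                       splits: Mapping[str, BenchmarkDataset],
                       manifest: pd.DataFrame,
                       cfg: SimulatedPredictorConfig = SimulatedPredictorConfig(),
                       params: ScoringParams = ScoringParams()) -> list[PredictionRecord]:
    """Predictions over every candidate site from the simulated predictor.

    The memorization term thresholds the maximum window similarity against
    the training split's positive windows; the generalization term uses the
    manifest's true labels (a predictor that truly learned the motif).
    Scores carry the pre-noise propensity.
    """
    max_self = params_scale_limit(params, next(iter(windows_by_key.values())).W)
    if cfg.tau > max_self:
        raise ValueError(f"tau={cfg.tau} exceeds the maximum attainable window "
                         f"self-score {max_self} for this scoring scale")
    if cfg.training_split not in splits:
        raise KeyError(f"unknown training split {cfg.training_split!r}")
    training = [windows_by_key[k] for k in splits[cfg.training_split].positives]
    keys = sorted(windows_by_key)
    truth = {(r.protein_id, r.position): int(r.true_label)
             for r in manifest.itertuples(index=False)}
    memorized = np.zeros(len(keys), dtype=bool)
    if training and cfg.lam > 0:
        sims = cross_scores([windows_by_key[k] for k in keys], training, params)
        memorized = sims.max(axis=1) >= cfg.tau
    propensity = (cfg.lam * memorized
                  + (1 - cfg.lam) * cfg.g * np.array([truth.get(k, 0) for k in keys]))
    rng = np.random.default_rng(cfg.seed)
    calls = rng.random(len(keys)) < propensity
    flips = rng.random(len(keys)) < cfg.epsilon
    calls = calls ^ flips
    return [PredictionRecord(protein_id=k[0], position=k[1], call=int(c),
                             score=float(p), method=cfg.method)
            for k, c, p in zip(keys, calls, propensity)]


def params_scale_limit(params: ScoringParams, W: int) -> float:
    """Largest self-score any window of width W can reach under the matrix."""
    return float(np.diag(_matrix_array(params.matrix_name)[:20, :20]).max()) * W
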