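"""File formats and the shared protein / site / prediction data model.

Sequences travel as multi-record FASTA; site annotations, predictor outputs
and per-residue feature tracks as tab-separated tables with named header
columns; metric results as JSON.  Positions are 1-based inclusive throughout
the external formats (UniProt site-annotation convention); conversion to
0-based indexing happens only inside the modules that need it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Source tags for site annotations: curated single-protein experiments vs
#: the two large mass-spectrometry site collections.
SOURCES = ("Literature", "MS-HeLa", "MS-Kim")

#: Evidence codes kept when evidence-based filtering is requested:
#: experimental evidence / curator inference used in manual assertion.
MANUAL_EVIDENCE_CODES = ("ECO:0000269", "ECO:0000305")

SiteKey = tuple[str, int]


@dataclass
class ProteinRecord:
    """A protein sequence with its collagen flag and optional feature tracks.

    ``collagen`` stands in for recognition of the collagen triple-helix
    repeat (Pfam PF01391); ``tracks`` maps feature names (disorder, helix,
    sheet, low_complexity) to per-residue 0/1 vectors of sequence length.
    """

    id: str
    sequence: str
    collagen: bool = False
    tracks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        for name, track in self.tracks.items():
            if len(track) != len(self.sequence):
                raise ValueError(
                    f"protein {self.id!r}: track {name!r} has {len(track)} entries, "
                    f"sequence has {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """One labeled candidate site (a proline, for hydroxylation benchmarks).

    ``position`` is 1-based; ``confidence`` is an assignment probability in
    [0, 1] or ``None`` when the source does not report one.
    """

    protein_id: str
    position: int
    residue: str
    label: str  # "positive" | "negative"
    source: str  # one of SOURCES
    confidence: Optional[float] = None
    evidence_code: Optional[str] = None

    @property
    def key(self) -> SiteKey:
        return (self.protein_id, self.position)

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"


@dataclass(frozen=True)
class PredictionRecord:
    """One binary site call from a predictor, with an optional score.

    A predictor exposing several quality thresholds is evaluated as one
    independent predictor per (method, level) pair.
    """

    protein_id: str
    position: int
    call: int  # 1 = modified, 0 = not modified
    method: str
    score: Optional[float] = None
    level: Optional[str] = None

    @property
    def key(self) -> SiteKey:
        return (self.protein_id, self.position)


class LoaderError(ValueError):
    """Malformed or inconsistent input that cannot be partially accepted."""


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoaderError(f"{path}: missing required columns {missing}")
    return df


def _parse_position(raw: str, row: int, path: str | Path) -> int:
    try:
        pos = int(raw)
    except (TypeError, ValueError):
        raise LoaderError(f"{path}: row {row}: position {raw!r} is not an integer") from None
    if pos < 1:
        raise LoaderError(f"{path}: row {row}: position {pos} violates the 1-based convention")
    return pos


def read_proteome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    track_path: str | Path | None = None,
    evidence_filter: bool = False,
) -> tuple[dict[str, ProteinRecord], list[SiteAnnotation], pd.DataFrame]:
    """Load sequences, site annotations and optional feature tracks.

    Returns ``(proteins, annotations, rejections)``.  Rows whose stated
    residue does not match the sequence (and, with ``evidence_filter=True``,
    rows lacking a manual-assertion evidence code) are not silently dropped:
    they are returned in the ``rejections`` frame with a reason, so that
    accepted + rejected always equals the number of input rows.

    Structural defects — an annotation referencing an unknown protein, or a
    malformed / out-of-range position — raise :class:`LoaderError` naming the
    offending row, because they indicate a broken table rather than a
    disagreement between two valid data sources.
    """
    proteins: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in proteins:
            raise LoaderError(f"{fasta_path}: duplicate protein id {rec.id!r}")
        proteins[rec.id] = ProteinRecord(id=rec.id, sequence=str(rec.seq))

    df = _read_table(annotation_path, ["protein_id", "position", "residue", "label", "source"])
    annotations: list[SiteAnnotation] = []
    rejected_rows: list[dict] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        pid = row.protein_id
        if pid not in proteins:
            raise LoaderError(f"{annotation_path}: row {idx}: unknown protein id {pid!r}")
        pos = _parse_position(row.position, idx, annotation_path)
        prot = proteins[pid]
        if pos > len(prot):
            raise LoaderError(
                f"{annotation_path}: row {idx}: position {pos} beyond sequence "
                f"length {len(prot)} of {pid!r}"
            )
        if row.label not in ("positive", "negative"):
            raise LoaderError(f"{annotation_path}: row {idx}: label {row.label!r} not positive/negative")
        if row.source not in SOURCES:
            raise LoaderError(f"{annotation_path}: row {idx}: unknown source tag {row.source!r}")
        residue = row.residue.upper()
        if prot.sequence[pos - 1] != residue:
            rejected_rows.append(
                {"row": idx, "protein_id": pid, "position": pos,
                 "reason": f"residue mismatch: annotated {residue!r}, sequence has "
                           f"{prot.sequence[pos - 1]!r}"}
            )
            continue
        evidence = getattr(row, "evidence_code", "") or None
        if evidence_filter and evidence not in MANUAL_EVIDENCE_CODES:
            rejected_rows.append(
                {"row": idx, "protein_id": pid, "position": pos,
                 "reason": f"evidence code {evidence!r} not a manual assertion"}
            )
            continue
        conf_raw = getattr(row, "confidence", "")
        confidence = None
        if conf_raw not in ("", None):
            confidence = float(conf_raw)
            if not 0.0 <= confidence <= 1.0:
                raise LoaderError(f"{annotation_path}: row {idx}: confidence {confidence} outside [0, 1]")
        collagen_raw = getattr(row, "collagen", "")
        if collagen_raw not in ("", None):
            flag = collagen_raw in ("1", "true", "True")
            if proteins[pid].collagen and not flag:
                raise LoaderError(
                    f"{annotation_path}: row {idx}: collagen flag contradicts earlier rows for {pid!r}"
                )
            if flag:
                proteins[pid].collagen = True
        annotations.append(
            SiteAnnotation(
                protein_id=pid, position=pos, residue=residue, label=row.label,
                source=row.source, confidence=confidence, evidence_code=evidence,
            )
        )

    if track_path is not None:
        tdf = _read_table(track_path, ["protein_id", "feature", "track"])
        for idx, row in enumerate(tdf.itertuples(index=False), start=2):
            if row.protein_id not in proteins:
                raise LoaderError(f"{track_path}: row {idx}: unknown protein id {row.protein_id!r}")
            prot = proteins[row.protein_id]
            vec = np.frombuffer(row.track.encode(), dtype=np.uint8) - ord("0")
            if len(vec) != len(prot) or not np.isin(vec, (0, 1)).all():
                raise LoaderError(
                    f"{track_path}: row {idx}: track for {row.protein_id!r} must be a 0/1 "
                    f"string of length {len(prot)}"
                )
            prot.tracks[row.feature] = vec.astype(np.int8)

    rejections = pd.DataFrame(rejected_rows, columns=["row", "protein_id", "position", "reason"])
    return proteins, annotations, rejections


def write_annotations(annotations: Iterable[SiteAnnotation], path: str | Path,
                      collagen_ids: Optional[set[str]] = None) -> None:
    """Write an annotation table in the format :func:`read_proteome` accepts."""
    rows = []
    for a in annotations:
        rows.append({
            "protein_id": a.protein_id,
            "position": a.position,
            "residue": a.residue,
            "label": a.label,
            "source": a.source,
            "confidence": "" if a.confidence is None else repr(a.confidence),
            "collagen": int(a.protein_id in collagen_ids) if collagen_ids is not None else "",
            "evidence_code": a.evidence_code or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_predictions(tsv_path: str | Path) -> list[PredictionRecord]:
    """Load a predictor output table.

    Required columns: protein_id, position, call, method; optional: score,
    level.  Duplicate (protein, position, method, level) rows are a hard
    error, as is any call that is not 0/1.
    """
    df = _read_table(tsv_path, ["protein_id", "position", "call", "method"])
    records: list[PredictionRecord] = []
    seen: set[tuple] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        pos = _parse_position(row.position, idx, tsv_path)
        if row.call not in ("0", "1"):
            raise LoaderError(f"{tsv_path}: row {idx}: call {row.call!r} is not binary (0/1)")
        level = getattr(row, "level", "") or None
        ident = (row.protein_id, pos, row.method, level)
        if ident in seen:
            raise LoaderError(f"{tsv_path}: row {idx}: duplicate prediction for {ident}")
        seen.add(ident)
        score_raw = getattr(row, "score", "")
        records.append(
            PredictionRecord(
                protein_id=row.protein_id, position=pos, call=int(row.call),
                method=row.method, level=level,
                score=None if score_raw in ("", None) else float(score_raw),
            )
        )
    return records


def write_predictions(records: Iterable[PredictionRecord], path: str | Path) -> None:
    rows = [{
        "protein_id": r.protein_id, "position": r.position, "call": r.call,
        "method": r.method, "score": "" if r.score is None else repr(r.score),
        "level": r.level or "",
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_metrics(results: list[dict], json_path: str | Path) -> None:
    """Serialize aggregated metric results as JSON.

    ``results`` is a list of entries of the form::

        {"method": ..., "level": ..., "split": ..., "n_replicas": int,
         "seed": int, "metrics": {"Sn": {"mean": float, "stdev": float}, ...}}

    Floats are written with ``repr`` precision, so a read-back reproduces the
    values bit-exactly.
    """
    for entry in results:
        for name, stats in entry.get("metrics", {}).items():
            for k, v in stats.items():
                if not math.isfinite(v):
                    raise ValueError(f"non-finite {name}.{k} in metrics for {entry.get('method')}")
    Path(json_path).write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")


def read_metrics(json_path: str | Path) -> list[dict]:
    return json.loads(Path(json_path).read_text())


def write_fasta(proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
                path: str | Path) -> None:
    records = proteins.values() if isinstance(proteins, Mapping) else proteins
    with open(path, "w") as fh:
        for prot in records:
            fh.write(f">{prot.id}\n")
            for i in range(0, len(prot.sequence), 60):
                fh.write(prot.sequence[i:i + 60] + "\n")


def write_tracks(proteins: Mapping[str, ProteinRecord], path: str | Path) -> None:
    rows = []
    for prot in proteins.values():
        for feature, track in sorted(prot.tracks.items()):
            rows.append({"protein_id": prot.id, "feature": feature,
                         "track": "".join(str(int(v)) for v in track)})
    pd.DataFrame(rows, columns=["protein_id", "feature", "track"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
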