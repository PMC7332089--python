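"""Dataset description: positional residue frequencies around the modified
proline, per-site feature content, and sites-per-protein density."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from hypbench.io import ProteinRecord, SiteAnnotation
from hypbench.windows import ALPHABET, GAP, SiteWindow, encode_windows


@dataclass
class FrequencyProfile:
    """Per-window-position symbol distribution (residues + gap)."""

    frequencies: pd.DataFrame  # index: position offset from center; columns: symbols
    n_sites: int

    def __post_init__(self) -> None:
        sums = self.frequencies.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("frequency rows must each sum to 1")


def residue_frequency_profile(windows: Sequence[SiteWindow]) -> FrequencyProfile:
    """Empirical frequency of every symbol at each window position."""
    if not windows:
        raise ValueError("no windows")
    widths = {w.W for w in windows}
    if len(widths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(widths)}")
    W = widths.pop()
    enc = encode_windows(windows)
    freq = np.zeros((W, len(ALPHABET)))
    for c in range(W):
        freq[c] = np.bincount(enc[:, c], minlength=len(ALPHABET))
    freq /= len(windows)
    half = (W - 1) // 2
    df = pd.DataFrame(freq, index=range(-half, half + 1), columns=list(ALPHABET))
    return FrequencyProfile(frequencies=df, n_sites=len(windows))


def site_content(window: SiteWindow, protein: ProteinRecord | None = None,
                 feature: str | None = None, residue: str | None = None) -> float:
    """Fraction of window positions carrying a feature (or being a residue).

    Exactly one of ``feature`` (a per-residue 0/1 track on the host protein)
    or ``residue`` (e.g. 'P' for proline content) must be given.  Gap
    positions are excluded from the denominator: a terminal, padded window
    should not have its content diluted by non-residues.
    """
    if (feature is None) == (residue is None):
        raise ValueError("give exactly one of feature or residue")
    half = (window.W - 1) // 2
    non_gap = 0
    hits = 0
    if feature is not None:
        if protein is None or feature not in protein.tracks:
            raise KeyError(f"protein track {feature!r} unavailable for window {window.origin}")
        track = protein.tracks[feature]
    start = window.origin[1] - 1 - half  # 0-based index of the window's first column
    for c, ch in enumerate(window.text):
        if ch == GAP:
            continue
        non_gap += 1
        if residue is not None:
            hits += ch == residue
        else:
            hits += int(track[start + c]) == 1
    return hits / non_gap


def content_summary(windows: Iterable[SiteWindow],
                    proteins: Mapping[str, ProteinRecord],
                    feature: str | None = None, residue: str | None = None,
                    skip_missing: bool = False) -> np.ndarray:
    """Per-site content values across a dataset (for distribution plots).

    With ``skip_missing`` the batch silently drops windows whose protein has
    no such track, otherwise a missing track raises.
    """
    values = []
    for w in windows:
        prot = proteins[w.origin[0]]
        if feature is not None and feature not in prot.tracks:
            if skip_missing:
                continue
            raise KeyError(f"protein track {feature!r} unavailable for window {w.origin}")
        values.append(site_content(w, prot, feature=feature, residue=residue))
    return np.asarray(values)


def sites_per_protein_density(annotations: Iterable[SiteAnnotation],
                              normalize: bool = False) -> dict[int, float]:
    """Histogram of positive-site counts per protein.

    Maps k → number (or, normalized, fraction) of proteins carrying exactly k
    positive sites; proteins with no positives do not appear.
    """
    per_protein: Counter[str] = Counter()
    for a in annotations:
        if a.is_positive:
            per_protein[a.protein_id] += 1
    hist = Counter(per_protein.values())
    total = sum(hist.values())
    if normalize and total:
        return {k: v / total for k, v in sorted(hist.items())}
    return {k: float(v) for k, v in sorted(hist.items())}


def frequency_profile_to_tsv(profile: FrequencyProfile, path) -> None:
    profile.frequencies.to_csv(path, sep="\t", index_label="offset",
                               lineterminator="\n")
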