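"""Fixed-length gapped sequence windows around candidate sites.

A site is represented by the W residues centered on the candidate proline
(default W = 13, odd).  Flanking positions that fall beyond either sequence
end are padded with the gap character '-', and any non-canonical letter
(B, Z, J, U, O, X, ...) inside the window is likewise replaced by a gap.
The center character is always the genuine residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from hypbench.io import ProteinRecord, SiteKey

#: The 20 canonical amino-acid one-letter codes, in the fixed alphabet order
#: used for encoding windows and profile columns.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Encoding alphabet: canonical residues 0..19, gap = 20.
ALPHABET = CANONICAL + GAP
GAP_CODE = 20

_CODE = {aa: i for i, aa in enumerate(ALPHABET)}
_CANONICAL_SET = frozenset(CANONICAL)

DEFAULT_W = 13


@dataclass(frozen=True)
class SiteWindow:
    """A gapped window of odd length W centered on a candidate residue."""

    text: str
    origin: SiteKey
    W: int = DEFAULT_W

    def __post_init__(self) -> None:
        if self.W % 2 == 0:
            raise ValueError(f"window length must be odd, got {self.W}")
        if len(self.text) != self.W:
            raise ValueError(f"window text {self.text!r} has length {len(self.text)}, expected {self.W}")
        if self.text[self.center_index] == GAP:
            raise ValueError(f"window {self.text!r}: center character may not be a gap")

    @property
    def center_index(self) -> int:
        return (self.W - 1) // 2


def extract_window(protein: ProteinRecord, position: int, W: int = DEFAULT_W) -> SiteWindow:
    """Extract the W-residue window centered on ``position`` (1-based).

    Gaps substitute non-canonical residues and pad past either sequence end;
    the center residue itself must be canonical.
    """
    if W % 2 == 0 or W < 1:
        raise ValueError(f"window length must be a positive odd number, got {W}")
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} out of range for protein {protein.id!r} "
                         f"(length {len(seq)})")
    center = seq[position - 1]
    if center not in _CANONICAL_SET:
        raise ValueError(f"protein {protein.id!r} position {position}: center residue "
                         f"{center!r} is not a canonical amino acid")
    half = (W - 1) // 2
    chars = []
    for i in range(position - 1 - half, position - 1 + half + 1):
        if 0 <= i < len(seq) and seq[i] in _CANONICAL_SET:
            chars.append(seq[i])
        else:
            chars.append(GAP)
    return SiteWindow(text="".join(chars), origin=(protein.id, position), W=W)


def enumerate_candidate_sites(proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
                              target_residue: str = "P") -> list[SiteKey]:
    """All (protein_id, 1-based position) pairs whose residue is the target."""
    records = proteins.values() if isinstance(proteins, Mapping) else proteins
    sites: list[SiteKey] = []
    for prot in records:
        for i, aa in enumerate(prot.sequence):
            if aa == target_residue:
                sites.append((prot.id, i + 1))
    return sites


def encode_windows(windows: Iterable[SiteWindow]) -> np.ndarray:
    """Encode windows as an (n, W) int8 array over the 21-symbol alphabet."""
    rows = [[_CODE[c] for c in w.text] for w in windows]
    return np.asarray(rows, dtype=np.int8)


def windows_to_tsv(windows: Iterable[SiteWindow], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\twindow\n")
        for w in windows:
            fh.write(f"{w.origin[0]}\t{w.origin[1]}\t{w.text}\n")
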