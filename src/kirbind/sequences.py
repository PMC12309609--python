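"""Aligned allotype sequences, region masks and one-hot encoding.

Sequences are aligned amino-acid strings over 1-based mature-protein
positions. Unknown residues (and alignment gaps in input files) are
represented by ``'*'`` and contribute nothing to the encoding.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN = "*"
_VALID_CHARS = frozenset(AA_ALPHABET) | {UNKNOWN}
#: characters in input alignments treated as "unknown residue"
_GAP_CHARS = {"-", ".", "X", "x", "*"}

VALID_LOCI = ("A", "B", "C", "KIR3DL1")

#: loop segments connecting the structured elements of the alpha-1/alpha-2
#: domains, 1-based inclusive
LOOP_RANGES = (
    (16, 19),
    (39, 44),
    (49, 56),
    (86, 90),
    (106, 107),
    (128, 131),
    (137, 140),
    (151, 152),
    (176, 179),
    (180, 183),
)

#: the six Bw4-motif positions on the alpha-1 helix
BW4_POSITIONS = (76, 77, 80, 81, 82, 83)

#: alpha-helix segments, 1-based inclusive
HELIX_RANGES = ((57, 85), (141, 175))

MASK_NAMES = ("all", "bw4", "no_loops", "helices")


@dataclass(frozen=True)
class AlleleSequence:
    """A named allotype with an aligned amino-acid string.

    Parameters
    ----------
    name:
        Allele identifier, e.g. ``"B*57:01"``.
    locus:
        One of ``A``, ``B``, ``C`` or ``KIR3DL1``.
    residues:
        Aligned one-letter residues over positions ``1..len(residues)``;
        unknown positions hold ``'*'``.
    """

    name: str
    locus: str
    residues: str

    def __post_init__(self) -> None:
        if self.locus not in VALID_LOCI:
            raise ValueError(
                f"unknown locus {self.locus!r}; expected one of {VALID_LOCI}"
            )
        bad = set(self.residues) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"invalid residue characters {sorted(bad)} in {self.name}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]


@dataclass(frozen=True)
class RegionMask:
    """A static set of 1-based sequence positions."""

    name: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if tuple(sorted(set(self.positions))) != self.positions:
            raise ValueError("positions must be sorted and unique")

    def __contains__(self, position: int) -> bool:
        return position in set(self.positions)

    def __len__(self) -> int:
        return len(self.positions)


def _expand(ranges: Iterable[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for lo, hi in ranges:
        out.update(range(lo, hi + 1))
    return out


def build_region_mask(name: str, panel_length: int) -> RegionMask:
    """Build one of the four static region masks, clipped to ``1..panel_length``.

    Masks
    -----
    - ``all``: every position.
    - ``bw4``: the six Bw4-motif positions {76, 77, 80, 81, 82, 83}.
    - ``no_loops``: every position minus the loop segments.
    - ``helices``: the alpha-helix segments [57..85] and [141..175].
    """
    if panel_length < 1:
        raise ValueError("panel_length must be positive")
    if name == "all":
        positions = set(range(1, panel_length + 1))
    elif name == "bw4":
        positions = set(BW4_POSITIONS)
    elif name == "no_loops":
        positions = set(range(1, panel_length + 1)) - _expand(LOOP_RANGES)
    elif name == "helices":
        positions = _expand(HELIX_RANGES)
    else:
        raise ValueError(f"unknown mask {name!r}; valid masks: {MASK_NAMES}")
    positions = {p for p in positions if 1 <= p <= panel_length}
    return RegionMask(name=name, positions=tuple(sorted(positions)))


@dataclass
class EncodedPanel:
    """Binary (position, residue) indicator matrix for an allele panel.

    Features exist only for residues observed at positions that are
    polymorphic (more than one known residue) across the panel.
    """

    feature_labels: list[tuple[int, str]]
    matrix: np.ndarray
    allele_names: list[str]
    mask_name: str = "all"
    loci: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_labels)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{res}{pos}" for pos, res in self.feature_labels]
        return pd.DataFrame(self.matrix, index=self.allele_names, columns=cols)


def one_hot_encode(panel: Sequence[AlleleSequence], mask: RegionMask) -> EncodedPanel:
    """One-hot encode a panel over masked, polymorphic positions.

    Each retained (position, residue) pair observed in the panel becomes a
    binary feature; positions with a single known residue across the whole
    panel are dropped. Unknown (``'*'``) positions yield all-zero
    indicators for that allele. Feature order is ascending position, then
    residue alphabetical.
    """
    if not panel:
        raise ValueError("empty panel")
    length = len(panel[0])
    for seq in panel:
        if len(seq) != length:
            raise ValueError(
                f"unequal sequence lengths: {seq.name} has {len(seq)}, expected {length}"
            )
    if mask.positions and mask.positions[-1] > length:
        raise ValueError("mask extends beyond sequence length")

    feature_labels: list[tuple[int, str]] = []
    for pos in mask.positions:
        observed = {seq.residues[pos - 1] for seq in panel} - {UNKNOWN}
        if len(observed) >= 2:
            feature_labels.extend((pos, res) for res in sorted(observed))

    index = {lab: j for j, lab in enumerate(feature_labels)}
    matrix = np.zeros((len(panel), len(feature_labels)), dtype=np.int8)
    for i, seq in enumerate(panel):
        for pos, res in feature_labels:
            if seq.residues[pos - 1] == res:
                matrix[i, index[(pos, res)]] = 1

    return EncodedPanel(
        feature_labels=feature_labels,
        matrix=matrix,
        allele_names=[s.name for s in panel],
        mask_name=mask.name,
        loci={s.name: s.locus for s in panel},
    )


def encode_sequence(
    residues: str, feature_labels: Sequence[tuple[int, str]]
) -> tuple[np.ndarray, int]:
    """Encode a single aligned sequence against a fixed feature list.

    Returns the indicator vector and the number of masked positions whose
    residue was unknown or never seen in training (those contribute zero).
    """
    x = np.zeros(len(feature_labels), dtype=float)
    positions = sorted({pos for pos, _ in feature_labels})
    known = {}
    for j, (pos, res) in enumerate(feature_labels):
        known.setdefault(pos, set()).add(res)
        if pos <= len(residues) and residues[pos - 1] == res:
            x[j] = 1.0
    n_ignored = 0
    for pos in positions:
        if pos > len(residues):
            n_ignored += 1
            continue
        r = residues[pos - 1]
        if r == UNKNOWN or r not in known[pos]:
            n_ignored += 1
    return x, n_ignored


def hamming_distance(a: AlleleSequence | str, b: AlleleSequence | str) -> int:
    """Number of aligned positions at which two sequences differ."""
    ra = a.residues if isinstance(a, AlleleSequence) else a
    rb = b.residues if isinstance(b, AlleleSequence) else b
    if len(ra) != len(rb):
        raise ValueError(f"unequal lengths: {len(ra)} vs {len(rb)}")
    return int(sum(x != y for x, y in zip(ra, rb)))


def infer_locus(name: str) -> str:
    """Infer the locus from an allele name prefix; defaults to 'A'."""
    upper = name.upper()
    if upper.startswith("KIR3DL1"):
        return "KIR3DL1"
    for locus in ("A", "B", "C"):
        if upper.startswith(locus + "*") or upper.startswith(f"HLA-{locus}"):
            return locus
    return "A"


def clean_residues(raw: str) -> str:
    """Uppercase a raw aligned string and map gap characters to ``'*'``."""
    out = []
    for ch in raw.strip().upper():
        out.append(UNKNOWN if ch in _GAP_CHARS else ch)
    return "".join(out)


def read_fasta(path_or_handle) -> list[AlleleSequence]:
    """Read an aligned panel from FASTA; headers are allele names."""
    from Bio import SeqIO

    if isinstance(path_or_handle, (str,)):
        handle: io.TextIOBase | str = path_or_handle
    else:
        handle = path_or_handle
    panel = []
    for record in SeqIO.parse(handle, "fasta"):
        residues = clean_residues(str(record.seq))
        panel.append(
            AlleleSequence(
                name=record.id, locus=infer_locus(record.id), residues=residues
            )
        )
    if not panel:
        raise ValueError("no sequences found")
    return panel


def write_fasta(panel: Sequence[AlleleSequence], path: str) -> None:
    with open(path, "w") as fh:
        for seq in panel:
            fh.write(f">{seq.name}\n{seq.residues}\n")


def read_panel_tsv(path) -> list[AlleleSequence]:
    """Read an aligned panel from a two-column (allele, sequence) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("expected at least two columns: allele, sequence")
    panel = []
    for _, row in df.iterrows():
        name = str(row.iloc[0])
        panel.append(
            AlleleSequence(
                name=name, locus=infer_locus(name), residues=clean_residues(row.iloc[1])
            )
        )
    return panel
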