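"""Two-sample logo statistics: per-(position, residue) enrichment between
two groups of aligned sequences, with binomial testing and Bonferroni
family-wise control."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .sequences import AlleleSequence, UNKNOWN


@dataclass(frozen=True)
class LogoEntry:
    position: int
    residue: str
    enriched_in: str  # "A" or "B"
    effect: float  # freqA - freqB, in [-1, 1]
    p_raw: float
    significant: bool


@dataclass
class LogoResult:
    entries: list[LogoEntry]
    alpha: float
    n_tests: int

    def significant_entries(self) -> list[LogoEntry]:
        return [e for e in self.entries if e.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


def _counts(group: Sequence[AlleleSequence], position: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for seq in group:
        res = seq.residues[position - 1]
        if res != UNKNOWN:
            out[res] = out.get(res, 0) + 1
    return out


def two_sample_logo(
    group_a: Sequence[AlleleSequence],
    group_b: Sequence[AlleleSequence],
    alpha: float = 0.05,
    *,
    null: str = "pooled",
) -> LogoResult:
    """Per-(position, residue) frequency comparison between two groups.

    For every residue observed at a position in either group, the count in
    the group where it is enriched is tested with a two-sided binomial test
    against a null proportion: the pooled frequency of that residue across
    both groups (``null="pooled"``, default) or its frequency in the other
    group (``null="other"``). Unknown (``'*'``) residues are excluded from
    the counts at each position. Significance is Bonferroni-controlled at
    ``alpha`` over all tested (position, residue) pairs.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    length = len(group_a[0])
    for seq in list(group_a) + list(group_b):
        if len(seq) != length:
            raise ValueError("sequences are not aligned to a common length")

    raw: list[tuple[int, str, float, float]] = []
    for pos in range(1, length + 1):
        ca, cb = _counts(group_a, pos), _counts(group_b, pos)
        na, nb = sum(ca.values()), sum(cb.values())
        if na == 0 or nb == 0:
            continue
        for res in sorted(set(ca) | set(cb)):
            ka, kb = ca.get(res, 0), cb.get(res, 0)
            fa, fb = ka / na, kb / nb
            effect = fa - fb
            # test the enriched group's count against the null proportion
            if effect >= 0:
                k, n, k_other, n_other = ka, na, kb, nb
            else:
                k, n, k_other, n_other = kb, nb, ka, na
            if null == "pooled":
                p0 = (ka + kb) / (na + nb)
            elif null == "other":
                p0 = k_other / n_other
            else:
                raise ValueError(f"unknown null {null!r}")
            p0 = min(max(p0, 0.0), 1.0)
            p_raw = float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
            raw.append((pos, res, effect, p_raw))

    n_tests = len(raw)
    threshold = alpha / n_tests if n_tests else 0.0
    entries = [
        LogoEntry(
            position=pos,
            residue=res,
            enriched_in="A" if effect >= 0 else "B",
            effect=effect,
            p_raw=p_raw,
            significant=p_raw < threshold,
        )
        for pos, res, effect, p_raw in raw
    ]
    return LogoResult(entries=entries, alpha=alpha, n_tests=n_tests)


def letter_heights(result: LogoResult, significant_only: bool = True) -> pd.DataFrame:
    """Per-position letter heights proportional to |effect| for rendering."""
    entries = result.significant_entries() if significant_only else result.entries
    rows = [
        {"position": e.position, "residue": e.residue,
         "height": abs(e.effect), "enriched_in": e.enriched_in}
        for e in entries
    ]
    return pd.DataFrame(rows)
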