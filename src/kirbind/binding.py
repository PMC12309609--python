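"""Replicate aggregation and transforms of the KIR x HLA binding matrix."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class BindingMatrix:
    """KIR allotype x HLA allotype binding values in [0, 1].

    After :func:`aggregate_replicates` each KIR row is normalized by its own
    maximal response, so the per-row maximum is 1.
    """

    kir_names: list[str]
    hla_names: list[str]
    values: np.ndarray
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.kir_names), len(self.hla_names)):
            raise ValueError("values shape does not match axis names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.kir_names, columns=self.hla_names)


@dataclass
class LogBindingMatrix:
    """Natural-log binding values; zeros were floored before logging."""

    kir_names: list[str]
    hla_names: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.kir_names, columns=self.hla_names)


@dataclass
class NormalizedBindingMatrix:
    """Per-KIR min-max view of the log matrix, scaled to [0, 100]."""

    kir_names: list[str]
    hla_names: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.kir_names, columns=self.hla_names)


def aggregate_replicates(
    runs: Sequence[BindingMatrix],
    *,
    normalize: str = "after_mean",
    scope: str = "per_kir",
) -> BindingMatrix:
    """Average replicate runs and normalize against the maximal response.

    Parameters
    ----------
    runs:
        Replicate matrices with identical axes.
    normalize:
        ``"after_mean"`` (default) averages runs then divides each KIR row
        by its maximum; ``"before_mean"`` normalizes each run first.
    scope:
        ``"per_kir"`` divides each row by its own maximum; ``"global"``
        divides the whole matrix by its overall maximum.
    """
    if not runs:
        raise ValueError("need at least one run")
    first = runs[0]
    for r in runs[1:]:
        if r.kir_names != first.kir_names or r.hla_names != first.hla_names:
            raise ValueError("replicate runs have mismatched axes")

    def _norm(values: np.ndarray) -> np.ndarray:
        if scope == "per_kir":
            row_max = np.nanmax(values, axis=1, keepdims=True)
            if np.any(row_max <= 0):
                bad = [first.kir_names[i] for i in np.where(row_max.ravel() <= 0)[0]]
                raise ValueError(f"cannot normalize all-zero KIR rows: {bad}")
            return values / row_max
        if scope == "global":
            top = np.nanmax(values)
            if top <= 0:
                raise ValueError("cannot normalize an all-zero matrix")
            return values / top
        raise ValueError(f"unknown scope {scope!r}")

    stack = np.stack([r.values for r in runs])
    if normalize == "after_mean":
        values = _norm(np.nanmean(stack, axis=0))
    elif normalize == "before_mean":
        values = np.nanmean(np.stack([_norm(r.values) for r in runs]), axis=0)
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")

    return BindingMatrix(
        kir_names=list(first.kir_names),
        hla_names=list(first.hla_names),
        values=values,
        n_replicates=len(runs),
    )


def log_transform(m: BindingMatrix, *, floor_scope: str = "global") -> LogBindingMatrix:
    """Replace zeros by 1% of the minimal positive value, then take ln.

    The floor is computed over the whole matrix by default
    (``floor_scope="global"``); ``"per_kir"`` uses each row's own minimal
    positive value.
    """
    values = np.array(m.values, dtype=float)
    if np.any(values < 0):
        raise ValueError("binding values must be non-negative")
    positive = values[np.isfinite(values) & (values > 0)]
    if positive.size == 0:
        raise ValueError("all-zero matrix: no positive minimum exists")
    if floor_scope == "global":
        floor = 0.01 * positive.min()
        values = np.where(values == 0, floor, values)
    elif floor_scope == "per_kir":
        for i in range(values.shape[0]):
            row = values[i]
            pos = row[np.isfinite(row) & (row > 0)]
            if pos.size == 0:
                raise ValueError(f"all-zero KIR row {m.kir_names[i]!r}")
            values[i] = np.where(row == 0, 0.01 * pos.min(), row)
    else:
        raise ValueError(f"unknown floor_scope {floor_scope!r}")
    return LogBindingMatrix(
        kir_names=list(m.kir_names), hla_names=list(m.hla_names), values=np.log(values)
    )


def minmax_per_kir(m: LogBindingMatrix) -> NormalizedBindingMatrix:
    """Affinely map each KIR row onto [0, 100]."""
    values = np.array(m.values, dtype=float)
    lo = np.nanmin(values, axis=1, keepdims=True)
    hi = np.nanmax(values, axis=1, keepdims=True)
    span = hi - lo
    if np.any(span == 0):
        bad = [m.kir_names[i] for i in np.where(span.ravel() == 0)[0]]
        raise ValueError(f"constant KIR rows cannot be min-max scaled: {bad}")
    return NormalizedBindingMatrix(
        kir_names=list(m.kir_names),
        hla_names=list(m.hla_names),
        values=100.0 * (values - lo) / span,
    )


def read_matrix_tsv(path) -> BindingMatrix:
    """Read a wide matrix: rows = KIR allotypes, columns = HLA allotypes."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    kir_names = df.iloc[:, 0].astype(str).tolist()
    return BindingMatrix(
        kir_names=kir_names,
        hla_names=[str(c) for c in df.columns[1:]],
        values=df.iloc[:, 1:].to_numpy(dtype=float),
    )


def write_matrix_tsv(m, path) -> None:
    m.to_frame().to_csv(path, sep="\t")


def read_replicates_long(path) -> list[BindingMatrix]:
    """Read long-format replicates with columns (kir, hla, run, value)."""
    df = pd.read_csv(path, sep="\t")
    required = {"kir", "hla", "run", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    df["kir"] = df["kir"].astype(str)
    df["hla"] = df["hla"].astype(str)
    kir_names = sorted(df["kir"].astype(str).unique())
    hla_names = sorted(df["hla"].astype(str).unique())
    runs = []
    for _, sub in df.groupby("run"):
        wide = sub.pivot(index="kir", columns="hla", values="value")
        wide = wide.reindex(index=kir_names, columns=hla_names)
        runs.append(
            BindingMatrix(
                kir_names=kir_names,
                hla_names=hla_names,
                values=wide.to_numpy(dtype=float),
            )
        )
    return runs
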