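"""Population coverage of the experimental KIR/HLA panel.

Per-locus coverage sums the frequencies of tested alleles; the joint
KIR x HLA partition and the full-genotype coverage both assume
independence (Hardy-Weinberg for the two alleles per locus).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class FrequencyTable:
    population: str
    locus: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty frequency table")
        if any(f < 0 for f in self.entries.values()):
            raise ValueError("negative frequencies")
        total = sum(self.entries.values())
        if total > 1.0 + 1e-6:
            raise ValueError(f"frequencies sum to {total:.6f} > 1")

    @property
    def total(self) -> float:
        return sum(self.entries.values())


def locus_coverage(
    table: FrequencyTable, tested: set[str], *, renormalize: bool = True
) -> float:
    """Fraction of the population whose allele was experimentally tested.

    With ``renormalize`` (default) the typed frequencies are scaled to sum
    to 1 before coverage; otherwise the untyped remainder counts as
    uncovered.
    """
    covered = sum(f for a, f in table.entries.items() if a in tested)
    denom = table.total if renormalize else 1.0
    return covered / denom


def joint_partition(kir_cov: float, hla_cov: float) -> dict[str, float]:
    """Split the population into (both, kir_only, hla_only, neither)."""
    for v in (kir_cov, hla_cov):
        if not 0.0 <= v <= 1.0:
            raise ValueError("coverages must be in [0, 1]")
    return {
        "both": kir_cov * hla_cov,
        "kir_only": kir_cov * (1.0 - hla_cov),
        "hla_only": (1.0 - kir_cov) * hla_cov,
        "neither": (1.0 - kir_cov) * (1.0 - hla_cov),
    }


def genotype_coverage(
    cov_a: float, cov_b: float, cov_c: float, kir_cov: float | None = None
) -> float:
    """Fraction of full HLA-I genotypes (two alleles at each of A, B, C)
    entirely covered, assuming independence: the product of squared
    per-locus coverages. An optional KIR factor multiplies in squared
    KIR3DL1 coverage."""
    out = 1.0
    for v in (cov_a, cov_b, cov_c):
        if not 0.0 <= v <= 1.0:
            raise ValueError("coverages must be in [0, 1]")
        out *= v * v
    if kir_cov is not None:
        if not 0.0 <= kir_cov <= 1.0:
            raise ValueError("coverages must be in [0, 1]")
        out *= kir_cov * kir_cov
    return out


def read_frequency_tsv(path) -> list[FrequencyTable]:
    """Read tables from a TSV with columns population, locus, allele, frequency."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "locus", "allele", "frequency"}
    if not required.issubset(df.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    tables = []
    for (pop, locus), sub in df.groupby(["population", "locus"]):
        tables.append(
            FrequencyTable(
                population=str(pop),
                locus=str(locus),
                entries=dict(zip(sub["allele"].astype(str), sub["frequency"].astype(float))),
            )
        )
    return tables


def coverage_report(
    tables: list[FrequencyTable], tested: dict[str, set[str]]
) -> pd.DataFrame:
    """Per-(population, locus) coverage plus the HLA genotype coverage.

    ``tested`` maps locus -> set of tested allele names.
    """
    rows = []
    per_pop: dict[str, dict[str, float]] = {}
    for t in tables:
        cov = locus_coverage(t, tested.get(t.locus, set()))
        per_pop.setdefault(t.population, {})[t.locus] = cov
        rows.append({"population": t.population, "locus": t.locus, "coverage": cov})
    for pop, cov in per_pop.items():
        if {"A", "B", "C"}.issubset(cov):
            rows.append(
                {
                    "population": pop,
                    "locus": "genotype",
                    "coverage": genotype_coverage(cov["A"], cov["B"], cov["C"]),
                }
            )
    return pd.DataFrame(rows)
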