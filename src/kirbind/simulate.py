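"""Synthetic fixtures: polymorphic sequence panels, planted log-linear
binding models with three binding classes, Dirichlet frequency tables,
and block matrices for clustering tests.

Everything is seeded and reproducible; default dimensions mimic the real
study scale (97 HLA allotypes x 9 KIR allotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .binding import BindingMatrix
from .coverage import FrequencyTable
from .sequences import AA_ALPHABET, AlleleSequence

DEFAULT_KIR_IDS = ("001", "002", "004", "005", "008", "009", "015", "020", "029")

#: default planted signal positions: Bw4-motif residues plus helix
#: positions that separate high from low binders
DEFAULT_SIGNAL_POSITIONS = (77, 80, 83, 62, 65, 66)


@dataclass
class PlantedModel:
    """Ground-truth log-linear binding model.

    ``betas`` maps (position, residue) -> per-KIR coefficient array; the
    log binding of an allele for one KIR is the sum of its residues'
    coefficients plus Gaussian noise.
    """

    kir_ids: tuple[str, ...]
    betas: dict[tuple[int, str], np.ndarray]
    noise_sigma: float
    thresholds: tuple[float, float]  # (non|low, low|high) on mean log binding
    seed: int = 0
    baseline: float = 0.0

    @property
    def signal_positions(self) -> tuple[int, ...]:
        return tuple(sorted({pos for pos, _ in self.betas}))


def generate_panel(
    n_alleles: int,
    length: int = 183,
    polymorphic_positions: Optional[Sequence[int]] = None,
    alphabet_per_position: Optional[dict[int, str]] = None,
    seed: int = 0,
    loci: Sequence[str] = ("A", "B", "C"),
    n_founders: Optional[int] = None,
    flip_prob: float = 0.1,
    weights_per_position: Optional[dict[int, Sequence[float]]] = None,
) -> list[AlleleSequence]:
    """Aligned random panel with the requested positions polymorphic.

    Positions not listed are constant across the panel; loci are assigned
    round-robin. Residues at polymorphic positions are drawn uniformly
    from that position's alphabet (two letters by default). With
    ``n_founders`` set, each allele instead copies one of that many founder
    haplotypes and resamples each polymorphic position with probability
    ``flip_prob`` — mimicking the linkage structure of real allele
    families, which concentrates panel variance on few axes.
    ``weights_per_position`` gives per-position residue sampling weights
    (aligned with that position's alphabet); unlisted positions are
    sampled uniformly.
    """
    if n_alleles < 2:
        raise ValueError("need at least two alleles")
    rng = np.random.default_rng(seed)
    if polymorphic_positions is None:
        polymorphic_positions = DEFAULT_SIGNAL_POSITIONS
    alphabet_per_position = dict(alphabet_per_position or {})
    for pos in polymorphic_positions:
        if pos not in alphabet_per_position:
            letters = rng.choice(list(AA_ALPHABET), size=2, replace=False)
            alphabet_per_position[pos] = "".join(letters)
        if len(set(alphabet_per_position[pos])) < 2:
            raise ValueError(f"position {pos} needs an alphabet of size >= 2")

    weights_per_position = dict(weights_per_position or {})

    def draw(pos):
        letters = list(alphabet_per_position[pos])
        w = weights_per_position.get(pos)
        if w is None:
            return rng.choice(letters)
        w = np.asarray(w, dtype=float)
        return rng.choice(letters, p=w / w.sum())

    founders = None
    if n_founders is not None:
        founders = [
            {pos: draw(pos) for pos in polymorphic_positions}
            for _ in range(n_founders)
        ]

    backbone = rng.choice(list(AA_ALPHABET), size=length)
    panel = []
    for i in range(n_alleles):
        residues = backbone.copy()
        if founders is None:
            for pos in polymorphic_positions:
                residues[pos - 1] = draw(pos)
        else:
            founder = founders[rng.integers(len(founders))]
            for pos in polymorphic_positions:
                if rng.random() < flip_prob:
                    residues[pos - 1] = draw(pos)
                else:
                    residues[pos - 1] = founder[pos]
        locus = loci[i % len(loci)]
        panel.append(
            AlleleSequence(
                name=f"{locus}*{i // len(loci) + 1:02d}:{i + 1:02d}",
                locus=locus,
                residues="".join(residues),
            )
        )
    return panel


def default_planted_model(
    panel: Sequence[AlleleSequence],
    signal_positions: Sequence[int] = DEFAULT_SIGNAL_POSITIONS,
    kir_ids: Sequence[str] = DEFAULT_KIR_IDS,
    noise_sigma: float = 0.3,
    effect_size: float = 2.0,
    seed: int = 0,
    class_quantiles: tuple[float, float] = (0.4, 0.75),
) -> PlantedModel:
    """Build a planted model whose signal sits on ``signal_positions``.

    One residue per signal position is deemed favourable and adds
    ``effect_size`` (with small per-KIR jitter) to the log binding. Class
    thresholds are placed at quantiles of the panel's noiseless mean log
    binding so all three classes are non-empty.
    """
    rng = np.random.default_rng(seed)
    n_kir = len(kir_ids)
    betas: dict[tuple[int, str], np.ndarray] = {}
    for pos in signal_positions:
        observed = sorted({s.residues[pos - 1] for s in panel})
        if len(observed) < 2:
            raise ValueError(f"position {pos} is not polymorphic in the panel")
        favoured = observed[0]
        jitter = rng.normal(0.0, 0.15 * effect_size, size=n_kir)
        betas[(pos, favoured)] = effect_size + jitter
        for res in observed[1:]:
            betas[(pos, res)] = np.zeros(n_kir)

    mean_log = _noiseless_mean_log(panel, betas, n_kir)
    lo, hi = np.quantile(mean_log, class_quantiles)
    if lo == hi:
        raise ValueError("degenerate thresholds: classes would be empty")
    return PlantedModel(
        kir_ids=tuple(kir_ids),
        betas=betas,
        noise_sigma=noise_sigma,
        thresholds=(float(lo), float(hi)),
        seed=seed,
    )


def _noiseless_log(panel, betas, n_kir) -> np.ndarray:
    """n_kir x n_alleles noiseless log-binding."""
    out = np.zeros((n_kir, len(panel)))
    for j, seq in enumerate(panel):
        for (pos, res), coef in betas.items():
            if seq.residues[pos - 1] == res:
                out[:, j] += coef
    return out


def _noiseless_mean_log(panel, betas, n_kir) -> np.ndarray:
    return _noiseless_log(panel, betas, n_kir).mean(axis=0)


def generate_binding(
    panel: Sequence[AlleleSequence],
    model: PlantedModel,
    n_replicates: int = 3,
    seed: Optional[int] = None,
) -> tuple[list[BindingMatrix], dict[str, str]]:
    """Emit replicate raw-binding runs plus true three-class labels.

    Per replicate, log binding = planted score + N(0, sigma); values are
    exponentiated and max-normalized per KIR so each run lies in [0, 1].
    Labels come from thresholding the noiseless mean log binding.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    n_kir = len(model.kir_ids)
    clean = model.baseline + _noiseless_log(panel, model.betas, n_kir)

    runs = []
    for _ in range(n_replicates):
        noisy = clean + rng.normal(0.0, model.noise_sigma, size=clean.shape)
        raw = np.exp(noisy)
        raw = raw / raw.max(axis=1, keepdims=True)
        runs.append(
            BindingMatrix(
                kir_names=list(model.kir_ids),
                hla_names=[s.name for s in panel],
                values=raw,
            )
        )

    mean_log = clean.mean(axis=0)
    lo, hi = model.thresholds
    labels = {}
    for seq, v in zip(panel, mean_log):
        labels[seq.name] = "non" if v < lo else ("low" if v < hi else "high")
    if len(set(labels.values())) < 3:
        raise ValueError("thresholds produced an empty class")
    return runs, labels


def generate_block_matrix(
    n_hla: int = 97,
    n_kir: int = 9,
    means: Sequence[float] = (90.0, 30.0, 1.0),
    sigma: float = 2.0,
    proportions: Sequence[float] = (0.3, 0.3, 0.4),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted 3-block KIR x HLA matrix for clustering tests.

    Returns (values, true_block) where ``true_block`` holds 0/1/2 per HLA
    column in descending mean-binding order.
    """
    rng = np.random.default_rng(seed)
    sizes = np.round(np.asarray(proportions) * n_hla).astype(int)
    sizes[-1] = n_hla - sizes[:-1].sum()
    blocks = np.repeat(np.arange(len(means)), sizes)
    rng.shuffle(blocks)
    values = np.empty((n_kir, n_hla))
    for j, b in enumerate(blocks):
        values[:, j] = means[b] + rng.normal(0.0, sigma, size=n_kir)
    return values, blocks


def generate_frequencies(
    n_alleles: int,
    concentration: float = 1.0,
    seed: int = 0,
    population: str = "synthetic",
    locus: str = "B",
) -> FrequencyTable:
    """Dirichlet-distributed allele frequency table summing to 1."""
    if n_alleles < 1:
        raise ValueError("need at least one allele")
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.full(n_alleles, concentration))
    entries = {f"{locus}*{i + 1:02d}:01": float(f) for i, f in enumerate(freqs)}
    return FrequencyTable(population=population, locus=locus, entries=entries)


def generate_degranulation(
    scores: Sequence[float],
    slope: float = 1.0,
    baseline: float = 100.0,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Degranulation responses monotone-decreasing in binding score
    (inhibitory receptor), on a positive scale with a parental baseline."""
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    log_resp = -slope * scores + rng.normal(0.0, sigma, size=scores.shape)
    return baseline * np.exp(log_resp), baseline
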