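"""The deployable 11-model bundle: training, scoring arbitrary sequences,
genotype averaging, mutation deltas, and the validation statistics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import classifiers, dimred
from .binding import LogBindingMatrix
from .classifiers import MODEL_IDS, LinearModel
from .clustering import BindingClassLabels
from .evaluation import _standardize
from .sequences import (
    AlleleSequence,
    UNKNOWN,
    build_region_mask,
    encode_sequence,
    one_hot_encode,
)


@dataclass
class PredictionReport:
    allele: str
    scores: dict[str, float]
    percentiles: dict[str, float]
    n_ignored_positions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": list(self.scores),
                "score": list(self.scores.values()),
                "percentile": [self.percentiles[m] for m in self.scores],
            }
        )


@dataclass
class ModelBundle:
    """The trained models plus reference scores for percentile reporting."""

    models: dict[str, LinearModel]
    feature_labels: list[tuple[int, str]]
    sequence_length: int
    reference_scores: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in self.models if self.models[m].betas is None]
        if missing:
            raise ValueError(f"bundle models must carry betas: {missing}")


def train_bundle(
    panel: Sequence[AlleleSequence],
    log_binding: LogBindingMatrix,
    labels: BindingClassLabels,
    *,
    mask: str = "helices",
    loci: tuple[str, ...] = ("A", "B", "C"),
    method: str = "mlvo",
    k_dim: int = 7,
    mlvo_mu: float = 1.0,
    kir_ids: Optional[Sequence[str]] = None,
) -> ModelBundle:
    """Train the full model set on one panel.

    Models: ``overall_binder`` (binder vs non), ``high_vs_low`` (on binder
    alleles), and one binder/non model per KIR allotype whose continuous
    label is that allotype's log-binding column. All models share one
    encoding and one projection, and are back-projected to per-feature
    betas so they can score raw sequences.
    """
    panel = [s for s in panel if s.locus in loci]
    region = build_region_mask(mask, len(panel[0]))
    encoded = one_hot_encode(panel, region)
    frame = log_binding.to_frame()
    if kir_ids is None:
        kir_ids = list(frame.index)

    names = encoded.allele_names
    keep = [i for i, n in enumerate(names) if n in labels.class_of and n in frame.columns]
    names = [names[i] for i in keep]
    Xfeat = encoded.matrix[keep].astype(float)

    use_projection = mask != "bw4"
    projection = None
    if use_projection:
        projection = dimred.fit_pca(Xfeat, K=k_dim, feature_labels=encoded.feature_labels)
        X = dimred.project(projection, Xfeat)
    else:
        X = Xfeat

    binder = labels.binder_labels
    high_low = labels.high_low_labels
    mean_log = _standardize(np.array([float(frame[n].mean()) for n in names]))

    def fit(model_id, y_bin, y_cont):
        has = ~np.isnan(y_bin) | ~np.isnan(y_cont)
        if method == "svm":
            m = ~np.isnan(y_bin)
            model = classifiers.fit_svm(X[m], y_bin[m], model_id=model_id)
        else:
            model = classifiers.fit_mlvo(
                classifiers.MLVOProblem(
                    X=X[has], y_bin=y_bin[has], y_cont=y_cont[has], mu=mlvo_mu
                ),
                model_id=model_id,
                polish="fast",
            )
        model.metadata.update({"mask": mask, "loci": list(loci), "method": method})
        classifiers.back_project(model, projection)
        if not use_projection:
            model.feature_labels = list(encoded.feature_labels)
        return model

    models: dict[str, LinearModel] = {}
    y_binder = np.array([float(binder[n]) for n in names])
    models["overall_binder"] = fit("overall_binder", y_binder, mean_log)

    y_hl = np.array([float(high_low.get(n, np.nan)) for n in names])
    y_hl_cont = np.where(np.isnan(y_hl), np.nan, mean_log)
    models["high_vs_low"] = fit("high_vs_low", y_hl, y_hl_cont)

    for kir in kir_ids:
        y_cont = _standardize(np.array([float(frame.loc[kir, n]) for n in names]))
        models[str(kir)] = fit(str(kir), y_binder, y_cont)

    bundle = ModelBundle(
        models=models,
        feature_labels=list(encoded.feature_labels),
        sequence_length=len(panel[0]),
        metadata={"mask": mask, "loci": list(loci), "method": method, "k_dim": k_dim},
    )
    set_reference(bundle, panel)
    return bundle


def set_reference(bundle: ModelBundle, panel: Sequence[AlleleSequence]) -> None:
    """Recompute per-model reference score distributions from a panel."""
    bundle.reference_scores = {}
    for model_id, model in bundle.models.items():
        scores = [
            _raw_score(bundle, model, seq.residues)[0] for seq in panel
        ]
        bundle.reference_scores[model_id] = np.sort(np.asarray(scores, dtype=float))


def _raw_score(bundle: ModelBundle, model: LinearModel, residues: str):
    x, n_ignored = encode_sequence(residues, bundle.feature_labels)
    return float(x @ model.betas + model.intercept), n_ignored


def percentile_of(reference: np.ndarray, value: float, ties: str = "upper") -> float:
    """Percentile of ``value`` within a sorted reference score list.

    ``ties="upper"`` counts tied reference scores as below (so the maximal
    reference score sits at percentile 100); ``"midpoint"`` counts half.
    """
    n = len(reference)
    if n == 0:
        raise ValueError("empty reference")
    # scores that survive a CSV round trip should still count as ties
    tol = 1e-9 * max(1.0, abs(value))
    below = float(np.sum(reference < value - tol))
    equal = float(np.sum(np.abs(reference - value) <= tol))
    weight = 1.0 if ties == "upper" else 0.5
    return 100.0 * (below + weight * equal) / n


def predict(
    bundle: ModelBundle, seq: AlleleSequence | str, ties: str = "upper"
) -> PredictionReport:
    """Score a sequence with every model; unknown residues contribute 0.

    Residues marked ``'*'`` (and residues never seen in training at a
    position) are ignored and counted in ``n_ignored_positions``.
    """
    if isinstance(seq, AlleleSequence):
        name, residues = seq.name, seq.residues
    else:
        name, residues = "query", str(seq)
    if len(residues) != bundle.sequence_length:
        raise ValueError(
            f"sequence length {len(residues)} does not match the model "
            f"coordinate system ({bundle.sequence_length})"
        )
    scores: dict[str, float] = {}
    percentiles: dict[str, float] = {}
    n_ignored = 0
    for model_id, model in bundle.models.items():
        s, n_ignored = _raw_score(bundle, model, residues)
        scores[model_id] = s
        if model_id in bundle.reference_scores:
            percentiles[model_id] = percentile_of(
                bundle.reference_scores[model_id], s, ties=ties
            )
    return PredictionReport(
        allele=name, scores=scores, percentiles=percentiles, n_ignored_positions=n_ignored
    )


def predict_genotype(
    bundle: ModelBundle, seq: AlleleSequence | str, kir_alleles: Sequence[str]
) -> float:
    """Average per-allotype scores over the expressed KIR3DL1 alleles."""
    if not kir_alleles:
        raise ValueError("need at least one KIR allotype")
    report = predict(bundle, seq)
    missing = [k for k in kir_alleles if k not in report.scores]
    if missing:
        raise ValueError(f"no per-allotype model for: {missing}")
    return float(np.mean([report.scores[k] for k in kir_alleles]))


def mutation_delta(
    bundle: ModelBundle,
    seq: AlleleSequence | str,
    mutation: tuple[int, str, str],
) -> dict[str, float]:
    """Per-model score change of a point mutation (position, from, to)."""
    residues = seq.residues if isinstance(seq, AlleleSequence) else str(seq)
    pos, src, dst = mutation
    if residues[pos - 1] != src:
        raise ValueError(
            f"sequence has {residues[pos - 1]!r} at position {pos}, expected {src!r}"
        )
    mutant = residues[: pos - 1] + dst + residues[pos:]
    wild = predict(bundle, residues)
    mut = predict(bundle, mutant)
    return {m: mut.scores[m] - wild.scores[m] for m in bundle.models}


def reciprocity_analysis(pairs: Sequence[tuple[float, float]]) -> dict:
    """Direct-vs-inverse mutation comparison.

    Each pair holds the log-ratio effect of a mutation and of its reverse
    on the opposite background; the inverse effect is negated so a purely
    additive model puts every point on the diagonal. Returns the plotted
    (x, y) pairs and their Pearson correlation.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 mutation pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = -np.array([p[1] for p in pairs], dtype=float)
    r, p = stats.pearsonr(x, y)
    return {"x": x, "y": y, "correlation": float(r), "p": float(p)}


def degranulation_correlation(
    predicted: Sequence[float],
    degranulation: Sequence[float],
    baseline: Sequence[float] | float,
) -> dict:
    """Spearman correlation of predicted score with normalized degranulation.

    Degranulation is divided by the matched parental-line baseline and
    log-scaled (natural log) before rank correlation.
    """
    predicted = np.asarray(predicted, dtype=float)
    degranulation = np.asarray(degranulation, dtype=float)
    baseline = np.broadcast_to(np.asarray(baseline, dtype=float), degranulation.shape)
    if predicted.shape != degranulation.shape:
        raise ValueError("predicted and degranulation must be matched")
    if np.any(baseline <= 0):
        raise ValueError("baseline responses must be positive")
    normalized = np.log(degranulation / baseline)
    if np.all(predicted == predicted[0]) or np.all(normalized == normalized[0]):
        raise ValueError("constant vectors have no defined rank correlation")
    rho, p = stats.spearmanr(predicted, normalized)
    return {"rho": float(rho), "p": float(p), "n": int(len(predicted))}


# ---------------------------------------------------------------------------
# beta-matrix serialization (the downloadable model artifact)

def export_beta_csv(bundle: ModelBundle, path) -> None:
    """Write the (position, residue) x model beta matrix, with a final
    ``intercept`` row, as plain CSV."""
    ids = list(bundle.models)
    data = {
        "position": [pos for pos, _ in bundle.feature_labels] + [0],
        "residue": [res for _, res in bundle.feature_labels] + ["intercept"],
    }
    for model_id in ids:
        model = bundle.models[model_id]
        data[model_id] = list(model.betas) + [model.intercept]
    pd.DataFrame(data).to_csv(path, index=False)


def import_beta_csv(path, sequence_length: int) -> ModelBundle:
    """Rebuild a scoring bundle from an exported beta CSV."""
    df = pd.read_csv(path)
    body = df[df["residue"] != "intercept"]
    intercepts = df[df["residue"] == "intercept"]
    feature_labels = [(int(p), str(r)) for p, r in zip(body["position"], body["residue"])]
    models = {}
    for model_id in [c for c in df.columns if c not in ("position", "residue")]:
        betas = body[model_id].to_numpy(dtype=float)
        models[model_id] = LinearModel(
            model_id=model_id,
            w=betas.copy(),
            b=float(intercepts[model_id].iloc[0]),
            betas=betas,
            intercept=float(intercepts[model_id].iloc[0]),
            feature_labels=feature_labels,
        )
    return ModelBundle(
        models=models, feature_labels=feature_labels, sequence_length=sequence_length
    )


def save_bundle(bundle: ModelBundle, beta_path, meta_path) -> None:
    export_beta_csv(bundle, beta_path)
    meta = {
        "sequence_length": bundle.sequence_length,
        "metadata": bundle.metadata,
        "reference_scores": {
            k: [float(v) for v in arr] for k, arr in bundle.reference_scores.items()
        },
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh)


def load_bundle(beta_path, meta_path) -> ModelBundle:
    with open(meta_path) as fh:
        meta = json.load(fh)
    bundle = import_beta_csv(beta_path, sequence_length=int(meta["sequence_length"]))
    bundle.metadata = meta.get("metadata", {})
    bundle.reference_scores = {
        k: np.asarray(v, dtype=float) for k, v in meta.get("reference_scores", {}).items()
    }
    return bundle
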