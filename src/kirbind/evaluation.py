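"""Allele-level cross-validation, AUC, and model-configuration comparisons.

Fold assignment is made once per HLA allele and reused identically across
every KIR task, so an allele is always entirely in the training set or
entirely in the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import classifiers, dimred
from .binding import LogBindingMatrix
from .clustering import BindingClassLabels
from .sequences import EncodedPanel, build_region_mask, one_hot_encode


@dataclass
class CVScheme:
    """Allele -> fold assignment shared across all KIR tasks."""

    fold_of_allele: dict[str, int]
    k: int
    seed: int

    def fold_members(self, fold: int) -> list[str]:
        return [a for a, f in self.fold_of_allele.items() if f == fold]


def make_folds(
    alleles: list[str], k: int = 5, seed: int = 0, stratify: dict[str, object] | None = None
) -> CVScheme:
    """Random near-equal partition of alleles into k folds.

    Fold sizes differ by at most one. With ``stratify`` (allele -> label),
    labels are spread across folds round-robin to avoid single-class folds
    on small panels. Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(alleles) < k:
        raise ValueError(f"need at least {k} alleles for {k} folds")
    rng = np.random.default_rng(seed)
    if stratify is None:
        order = list(alleles)
        rng.shuffle(order)
    else:
        order = []
        by_label: dict[object, list[str]] = {}
        for a in alleles:
            by_label.setdefault(stratify[a], []).append(a)
        for label in sorted(by_label, key=str):
            group = by_label[label]
            rng.shuffle(group)
            order.extend(group)
    fold_of = {a: i % k for i, a in enumerate(order)}
    return CVScheme(fold_of_allele=fold_of, k=k, seed=seed)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(positive outscores negative), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels > 0]
    neg = scores[labels <= 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _fit_task(X, y_bin, y_cont, method, mlvo_mu=1.0, C=classifiers.DEFAULT_C):
    if method == "svm":
        mask = ~np.isnan(y_bin)
        return classifiers.fit_svm(X[mask], y_bin[mask], C=C)
    if method == "mlvo":
        problem = classifiers.MLVOProblem(
            X=X, y_bin=y_bin, y_cont=y_cont, mu=mlvo_mu, C=C
        )
        return classifiers.fit_mlvo(problem, polish="fast")
    raise ValueError(f"unknown method {method!r}")


def _standardize(y: np.ndarray) -> np.ndarray:
    m = ~np.isnan(y)
    if m.sum() < 2 or np.nanstd(y) == 0:
        return y
    out = y.copy()
    out[m] = (y[m] - np.nanmean(y)) / np.nanstd(y)
    return out


def run_cv_experiment(
    panel,
    log_binding: LogBindingMatrix,
    labels: BindingClassLabels,
    *,
    mask: str = "helices",
    loci: tuple[str, ...] = ("A", "B", "C"),
    task: str = "overall_binder",
    method: str = "mlvo",
    k_folds: int = 5,
    k_dim: int = 7,
    reduction: str = "pca",
    seed: int = 0,
    scheme: CVScheme | None = None,
    per_fold_projection: bool = False,
    mlvo_mu: float = 1.0,
) -> pd.DataFrame:
    """Cross-validated AUCs for one configuration.

    ``task`` is ``overall_binder`` (binder vs non-binder), ``high_vs_low``
    (defined on binder alleles only) or a KIR id (per-allotype binder task
    with that allotype's log-binding column as the continuous label).
    Returns a tidy frame with one row per fold: mask, loci, task, method,
    fold, n_train, n_test, train_auc, test_auc.

    The Bw4 mask skips dimensionality reduction and trains on the one-hot
    vectors directly.
    """
    panel = [s for s in panel if s.locus in loci]
    if not panel:
        raise ValueError(f"no alleles on loci {loci}")
    region = build_region_mask(mask, len(panel[0]))
    encoded = one_hot_encode(panel, region)
    names = encoded.allele_names
    frame = log_binding.to_frame()

    # labels for this task
    if task == "overall_binder":
        lbl = labels.binder_labels
        cont = frame.mean(axis=0)  # mean log binding across KIR allotypes
    elif task == "high_vs_low":
        lbl = labels.high_low_labels
        cont = frame.mean(axis=0)
    else:
        if task not in frame.index:
            raise ValueError(f"unknown task / KIR id {task!r}")
        lbl = labels.binder_labels
        cont = frame.loc[task]

    keep = [i for i, n in enumerate(names) if n in lbl and n in cont.index]
    if not keep:
        raise ValueError("no labeled alleles for this task")
    names = [names[i] for i in keep]
    Xfeat = encoded.matrix[keep].astype(float)
    y_bin = np.array([float(lbl[n]) for n in names])
    y_cont = _standardize(np.array([float(cont[n]) for n in names]))

    if scheme is None:
        scheme = make_folds(names, k=k_folds, seed=seed, stratify={n: lbl[n] for n in names})
    folds = sorted(set(scheme.fold_of_allele[n] for n in names))

    use_projection = mask != "bw4" and reduction != "none"
    if use_projection and not per_fold_projection:
        fit = dimred.fit_pca if reduction == "pca" else dimred.fit_mca
        proj = fit(Xfeat, K=k_dim, feature_labels=encoded.feature_labels)

    rows = []
    for fold in folds:
        test_idx = np.array([scheme.fold_of_allele[n] == fold for n in names])
        train_idx = ~test_idx
        # leakage guard: folds partition the alleles
        assert not np.any(train_idx & test_idx)
        if len(np.unique(y_bin[train_idx])) < 2 or len(np.unique(y_bin[test_idx])) < 2:
            warnings.warn(f"fold {fold} lacks both classes; skipped", stacklevel=2)
            continue
        if use_projection:
            if per_fold_projection:
                fit = dimred.fit_pca if reduction == "pca" else dimred.fit_mca
                proj = fit(Xfeat[train_idx], K=k_dim, feature_labels=encoded.feature_labels)
            X = dimred.project(proj, Xfeat)
        else:
            X = Xfeat
        yb_train = y_bin.copy()
        yb_train[test_idx] = np.nan
        yc_train = y_cont.copy()
        yc_train[test_idx] = np.nan
        model = _fit_task(X[train_idx], y_bin[train_idx], y_cont[train_idx],
                          method, mlvo_mu=mlvo_mu)
        rows.append(
            {
                "mask": mask,
                "loci": "/".join(loci),
                "task": task,
                "method": method,
                "fold": fold,
                "n_train": int(train_idx.sum()),
                "n_test": int(test_idx.sum()),
                "train_auc": auc(classifiers.score(model, X[train_idx]), y_bin[train_idx]),
                "test_auc": auc(classifiers.score(model, X[test_idx]), y_bin[test_idx]),
            }
        )
    return pd.DataFrame(rows)


def summarize_auc(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of test AUC per (mask, loci, task, method)."""
    return (
        table.groupby(["mask", "loci", "task", "method"])["test_auc"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def compare_configurations(table: pd.DataFrame, factors=("mask", "loci")) -> dict:
    """Two-way ANOVA over the chosen factors plus all-pairs Tukey per factor.

    Expects a tidy AUC table from :func:`run_cv_experiment` with at least
    two levels per factor; missing cells are reported, not silently dropped.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    fa, fb = factors
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least two levels")
    cells = table.groupby([fa, fb]).size()
    expected = table[fa].nunique() * table[fb].nunique()
    report: dict = {"balanced": len(cells) == expected}
    if not report["balanced"]:
        report["missing_cells"] = expected - len(cells)

    model = ols(f"test_auc ~ C({fa}) * C({fb})", data=table).fit()
    report["anova"] = sm.stats.anova_lm(model, typ=2)

    tukey = {}
    for f in factors:
        levels = sorted(table[f].unique())
        samples = [table.loc[table[f] == lv, "test_auc"].to_numpy() for lv in levels]
        res = stats.tukey_hsd(*samples)
        pairs = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                pairs.append(
                    {"a": levels[i], "b": levels[j], "p_adj": float(res.pvalue[i, j])}
                )
        tukey[f] = pd.DataFrame(pairs)
    report["tukey"] = tukey
    return report


def one_way_anova_tasks(table: pd.DataFrame) -> dict:
    """One-way ANOVA of test AUC across per-allotype tasks."""
    tasks = sorted(table["task"].unique())
    samples = [table.loc[table["task"] == t, "test_auc"].to_numpy() for t in tasks]
    f_stat, p = stats.f_oneway(*samples)
    return {"F": float(f_stat), "p": float(p), "tasks": tasks}
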