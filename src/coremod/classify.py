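"""SVM/LOOCV evaluation of gene sets and random-set comparisons.

A radial-kernel SVM is trained once per left-out sample (features
standardized on the training fold only); the ROC AUC is computed from the
pooled left-out decision values. Core genes are benchmarked against random
gene sets of equal size (optionally matched on DEG composition) with a
one-sample Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from coremod.prep import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class ClassificationResult:
    feature_genes: tuple[str, ...]
    contrast: tuple[str, str]
    auc: float
    fold_scores: list[tuple[float, int]]  # (decision value, true label)


@dataclass
class RandomSetComparison:
    scheme: str
    n_reps: int
    random_aucs: list[float]
    core_auc: float
    wilcoxon_p: float


def svm_loocv_auc(
    ds: ExpressionDataset,
    genes,
    contrast: tuple[str, str],
    C: float = 1.0,
    gamma: str | float = "scale",
    class_weight: str | dict | None = "balanced",
) -> ClassificationResult:
    """Leave-one-out AUC of a radial-kernel SVM on a gene set's expression.

    Class weights default to "balanced": leaving one sample out tilts the
    training fold against that sample's class, which otherwise biases the
    pooled null AUC well below 0.5 on small cohorts.
    """
    genes = list(genes)
    for g in genes:
        if not ds.has_gene(g):
            raise KeyError(f"gene {g!r} missing from the expression matrix")
    s1, s2 = contrast
    idx1, idx2 = ds.samples_in_state(s1), ds.samples_in_state(s2)
    if len(idx1) < 3 or len(idx2) < 3:
        raise ValueError("need >= 3 samples per state")
    cols = idx1 + idx2
    y = np.array([0] * len(idx1) + [1] * len(idx2))
    X = ds.gene_rows(genes)[:, cols].T  # samples x features

    fold_scores: list[tuple[float, int]] = []
    n = len(cols)
    for i in range(n):
        train = np.array([j for j in range(n) if j != i])
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
        clf.fit(scaler.transform(X[train]), y[train])
        score = float(clf.decision_function(scaler.transform(X[i:i + 1]))[0])
        fold_scores.append((score, int(y[i])))
    dec = np.array([s for s, _ in fold_scores])
    labels = np.array([l for _, l in fold_scores])
    auc = float(roc_auc_score(labels, dec))
    return ClassificationResult(tuple(genes), contrast, auc, fold_scores)


def random_set_comparison(
    ds: ExpressionDataset,
    core: set[str],
    pool: set[str],
    degs: set[str],
    scheme: str,
    contrast: tuple[str, str],
    rng: np.random.Generator,
    n_reps: int = 100,
    **svm_kwargs,
) -> RandomSetComparison:
    """Compare the core set's LOOCV AUC with n_reps random sets.

    scheme ``"candidates_minus_core"``: uniform draws of |core| genes from
    pool minus core. scheme ``"composition_matched"``: draws from pool
    matching the core set's DEG / non-DEG split. The Wilcoxon signed-rank
    test is one-sample, two-sided, on (random_aucs - core_auc).
    """
    core = set(core)
    k = len(core)
    core_auc = svm_loocv_auc(ds, sorted(core), contrast, **svm_kwargs).auc

    if scheme == "candidates_minus_core":
        source = sorted(set(pool) - core)
        if len(source) < k:
            raise ValueError(f"pool of {len(source)} genes cannot supply sets of {k}")
        draw = lambda: [source[i] for i in rng.choice(len(source), k, replace=False)]
    elif scheme == "composition_matched":
        n_deg = len(core & degs)
        deg_pool = sorted(set(pool) & degs)
        non_pool = sorted(set(pool) - degs)
        if len(deg_pool) < n_deg or len(non_pool) < k - n_deg:
            raise ValueError("pool cannot match the core set's DEG composition")

        def draw() -> list[str]:
            a = [deg_pool[i] for i in rng.choice(len(deg_pool), n_deg, replace=False)]
            b = [non_pool[i] for i in rng.choice(len(non_pool), k - n_deg, replace=False)]
            return a + b
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    aucs = [svm_loocv_auc(ds, draw(), contrast, **svm_kwargs).auc
            for _ in range(n_reps)]
    diffs = np.array(aucs) - core_auc
    if np.all(diffs == 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs, zero_method="wilcox").pvalue)
    return RandomSetComparison(scheme=scheme, n_reps=n_reps, random_aucs=aucs,
                               core_auc=core_auc, wilcoxon_p=p)
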