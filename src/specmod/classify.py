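"""Supervised re-classification of unremarkable genes.

The remarkable genes' rows of the spectral embedding Y' form the training
set; a k-nearest-neighbours classifier (default) or one-vs-rest logistic
regression assigns final module labels to the unremarkable genes.  The
kNN neighbour count is selected from the grid [20, 20 + 2k] (or [20, 30]
when 2k > 30), capped below the training-set size, by stratified
cross-validated accuracy.  Remarkable genes always keep their training
labels; only unremarkable genes can change module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier

from .clustering import Clustering, Embedding
from .semilabel import SemiLabeling

logger = logging.getLogger(__name__)

_CV_FOLDS = 5


@dataclass
class ModuleSet:
    """Final module labels for every gene.

    ``changed_fraction`` is the fraction of unremarkable genes whose final
    label differs from their initial cluster's mapped label (genes of a
    dropped cluster count as changed).
    """

    labels: dict[str, int]
    k_prime: int
    classifier_kind: str
    chosen_hyperparam: float | int | None
    changed_fraction: float

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return dict(sorted(sizes.items()))


def knn_neighbor_grid(k: int, n_train: int) -> list[int]:
    """Candidate neighbour counts: [20, 20 + 2k] if 2k <= 30 else [20, 30].

    Counts are capped at n_train - 1; if the whole grid collapses the
    floor is lowered to 1 (tiny training sets) with a warning.
    """
    hi = 20 + 2 * k if 2 * k <= 30 else 30
    grid = [c for c in range(20, hi + 1) if c <= n_train - 1]
    if not grid:
        logger.warning(
            "training set of %d too small for the neighbour grid; "
            "falling back to counts below %d", n_train, n_train,
        )
        grid = list(range(1, max(n_train, 2)))
    return grid


def _pick_neighbors(x: np.ndarray, y: np.ndarray, k: int, seed: int) -> int:
    grid = knn_neighbor_grid(k, len(y))
    if len(grid) == 1:
        return grid[0]
    _, counts = np.unique(y, return_counts=True)
    n_splits = min(_CV_FOLDS, int(counts.min()))
    if n_splits < 2:
        logger.warning("a class has a single training member; skipping CV")
        return grid[0]
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31))
    # a fold fits on at most len(y) - ceil(len(y) / n_splits) points
    min_fit = len(y) - -(-len(y) // n_splits)
    cv_grid = [c for c in grid if c <= min_fit] or grid[:1]
    scores = [
        cross_val_score(KNeighborsClassifier(n_neighbors=c), x, y, cv=cv).mean()
        for c in cv_grid
    ]
    return cv_grid[int(np.argmax(scores))]  # ties -> smaller count (grid ascending)


def train_and_classify(
    e: Embedding,
    sl: SemiLabeling,
    kind: str = "knn",
    seed: int = 0,
) -> ModuleSet:
    """Train on remarkable genes' embedding rows, label the unremarkable.

    With k' = 1 every gene receives the single label (warned); with no
    unremarkable genes the modules equal the mapped initial clusters.
    """
    if e.gene_ids is None:
        raise ValueError("embedding carries no gene identifiers")
    if sl.k_prime < 1:
        raise ValueError("need at least one class with remarkable genes")
    row = {g: i for i, g in enumerate(e.gene_ids)}
    train_genes = sorted(sl.remarkable)
    test_genes = sorted(sl.unremarkable)
    labels: dict[str, int] = dict(sl.remarkable)
    chosen: float | int | None = None

    if sl.k_prime == 1:
        logger.warning("only one class with remarkable genes; all genes get label 1")
        labels.update({g: 1 for g in test_genes})
    elif test_genes:
        x_train = e.values[[row[g] for g in train_genes]]
        y_train = np.array([sl.remarkable[g] for g in train_genes])
        x_test = e.values[[row[g] for g in test_genes]]
        if kind == "knn":
            chosen = _pick_neighbors(x_train, y_train, e.k, seed)
            model = KNeighborsClassifier(n_neighbors=chosen)
        elif kind == "logistic":
            chosen = 1.0  # fixed L2 strength
            model = OneVsRestClassifier(
                LogisticRegression(C=1.0, max_iter=1000)
            )
        else:
            raise ValueError(f"classifier kind must be 'knn' or 'logistic': {kind!r}")
        model.fit(x_train, y_train)
        pred = model.predict(x_test)
        labels.update({g: int(p) for g, p in zip(test_genes, pred)})
    return ModuleSet(
        labels=labels,
        k_prime=sl.k_prime,
        classifier_kind=kind,
        chosen_hyperparam=chosen,
        changed_fraction=_changed_fraction(labels, sl),
    )


def _changed_fraction(labels: dict[str, int], sl: SemiLabeling) -> float:
    if not sl.unremarkable:
        return 0.0
    changed = 0
    # mapped initial label of an unremarkable gene; dropped cluster -> changed
    for gene in sl.unremarkable:
        mapped = sl.initial_mapped_label(gene)
        if mapped is None or labels[gene] != mapped:
            changed += 1
    return changed / len(sl.unremarkable)


def summarize_refinement(
    clustering: Clustering, sl: SemiLabeling, ms: ModuleSet
) -> dict:
    """Refinement summary: %UNR, %CH, k -> k', module sizes."""
    m = len(clustering.gene_ids)
    pct_unr = 100.0 * len(sl.unremarkable) / m
    return {
        "n_genes": m,
        "k_initial": clustering.k,
        "k_prime": sl.k_prime,
        "method": clustering.method,
        "pct_unremarkable": pct_unr,
        "pct_changed": 100.0 * ms.changed_fraction,
        "changed_defined": bool(sl.unremarkable),
        "classifier": ms.classifier_kind,
        "chosen_hyperparam": ms.chosen_hyperparam,
        "module_sizes": ms.module_sizes(),
    }
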