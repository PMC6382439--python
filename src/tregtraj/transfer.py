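"""Label transfer between annotated cell populations.

A sparse (L1-penalised, one-vs-rest) logistic regression is trained on the
counts and subpopulation labels of a reference dataset; query cells receive
the label with the highest predicted probability.  Raw counts are the
default input scale; normalized input is an option since it changes the
coefficients.  Cells whose maximum class
probability falls below 0.5 are flagged low-confidence — the flag never
changes the assigned label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier

__all__ = ["TransferModel", "train_classifier", "predict_labels", "composition_matrix"]


@dataclass
class TransferModel:
    """Trained multinomial (one-vs-rest) L1 logistic model."""

    genes: list
    classes: list
    coef: np.ndarray        # n_classes x n_genes
    intercept: np.ndarray   # n_classes
    l1_strength: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "genes": list(map(str, self.genes)),
            "classes": list(map(str, self.classes)),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "l1_strength": self.l1_strength,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TransferModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["genes"], d["classes"], np.asarray(d["coef"]),
                   np.asarray(d["intercept"]), d["l1_strength"], d["seed"])


def _matrix_genes(data, gene_ids):
    if isinstance(data, ad.AnnData):
        X = data.layers.get("counts", data.X)
        return X, list(data.var_names)
    return data, list(gene_ids)


def train_classifier(ref, labels, gene_ids=None, l1_strength: float = 1.0,
                     seed: int = 0, max_iter: int = 2000) -> TransferModel:
    """Fit the reference model; deterministic under a fixed seed.

    ``l1_strength`` follows scikit-learn's inverse-regularization
    convention (C); every class needs at least 2 cells.
    """
    X, genes = _matrix_genes(ref, gene_ids)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if (counts < 2).any():
        small = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 cells: {list(small)}")
    base = LogisticRegression(l1_ratio=1.0, C=l1_strength, solver="liblinear",
                              random_state=seed, max_iter=max_iter)
    clf = OneVsRestClassifier(base) if classes.size > 2 else base
    clf.fit(X if sp.issparse(X) else np.asarray(X), y)
    if isinstance(clf, OneVsRestClassifier):
        coef = np.vstack([est.coef_ for est in clf.estimators_])
        intercept = np.concatenate([est.intercept_ for est in clf.estimators_])
    else:
        coef, intercept = np.asarray(clf.coef_), np.asarray(clf.intercept_)
    return TransferModel(genes=list(genes), classes=list(clf.classes_),
                         coef=coef, intercept=intercept,
                         l1_strength=l1_strength, seed=seed)


def _align_query(model: TransferModel, X, gene_ids):
    """Reorder query genes to the model's feature space; absent features are
    imputed as zero (reported via the returned count)."""
    gene_ids = list(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    hits = [pos.get(g, -1) for g in model.genes]
    n_missing = sum(h < 0 for h in hits)
    if n_missing == len(model.genes):
        raise ValueError("query shares no genes with the model's feature space")
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    out = np.zeros((X.shape[0], len(model.genes)))
    for j, h in enumerate(hits):
        if h >= 0:
            out[:, j] = X[:, h]
    return out, n_missing


def predict_labels(model: TransferModel, query, gene_ids=None):
    """Assign each query cell the argmax-probability reference label.

    Returns a DataFrame with the predicted label, its probability, a
    low-confidence flag (max probability < 0.5) and one probability column
    per class (one-vs-rest sigmoid scores normalized to sum to one).
    """
    X, genes = _matrix_genes(query, gene_ids)
    Xq, n_missing = _align_query(model, X, genes)
    # one-vs-rest decision functions -> normalized probabilities, as in
    # scikit-learn's liblinear predict_proba
    scores = Xq @ model.coef.T + model.intercept
    probs = 1.0 / (1.0 + np.exp(-scores))
    if len(model.classes) == 2 and probs.shape[1] == 1:
        # binary liblinear models carry a single coefficient row
        probs = np.column_stack([1.0 - probs[:, 0], probs[:, 0]])
    probs = probs / probs.sum(axis=1, keepdims=True)
    best = probs.argmax(axis=1)
    index = query.obs_names if isinstance(query, ad.AnnData) else pd.RangeIndex(Xq.shape[0])
    out = pd.DataFrame(
        {
            "label": [model.classes[i] for i in best],
            "probability": probs[np.arange(len(best)), best],
            "low_confidence": probs.max(axis=1) < 0.5,
        },
        index=index,
    )
    for i, c in enumerate(model.classes):
        out[f"p_{c}"] = probs[:, i]
    out.attrs["n_missing_genes"] = n_missing
    return out


def composition_matrix(predicted_labels, query_clusters) -> pd.DataFrame:
    """Row-normalized percentage cross-tabulation: for each query
    subpopulation (rows), the percentage of its cells assigned each
    reference label (columns).  Rows sum to 100."""
    pred = pd.Series(np.asarray(predicted_labels), name="predicted")
    clus = pd.Series(np.asarray(query_clusters), name="cluster")
    if len(pred) != len(clus):
        raise ValueError("every query cell needs both labels")
    tab = pd.crosstab(clus, pred)
    return tab.div(tab.sum(axis=1), axis=0) * 100.0
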