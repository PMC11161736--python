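"""Metagene-restricted subtype classification with a repeated-prediction
consistency rule.

A small neural network (single-hidden-layer perceptron) is trained on the
metagene feature profiles of the labeled panel using a stratified 9:1
train/validation split. To make external assignments robust to the
stochasticity of the split and the weight initialization, prediction is
repeated ``n_reps`` times (default 500) with a fresh split and fresh
initialization each time; a sample keeps a label only if that label wins
more than one third of the repetitions (for 500 repetitions: at least 167),
otherwise it stays "unassigned".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

UNASSIGNED = "unassigned"


def apply_consistency_rule(counts: pd.DataFrame, n_reps: int,
                           threshold: float = 1.0 / 3.0) -> pd.DataFrame:
    """Kept iff the winning label's count strictly exceeds ``threshold * n_reps``.

    ``counts`` is samples x labels of per-label repetition counts (summing to
    ``n_reps`` per row). For 500 repetitions and the default threshold a
    sample needs > 166 wins, i.e. >= 167. Returns columns ``assigned``
    (winning label or "unassigned"), ``max_count``, ``kept``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not np.allclose(counts.sum(axis=1), n_reps):
        raise ValueError("per-sample counts must sum to n_reps")
    win = counts.idxmax(axis=1)
    max_count = counts.max(axis=1)
    kept = max_count > threshold * n_reps
    return pd.DataFrame({
        "assigned": np.where(kept, win.astype(str), UNASSIGNED),
        "max_count": max_count.astype(int),
        "kept": kept,
    }, index=counts.index)


class ConsistencyClassifier(ClassifierMixin, BaseEstimator):
    """Stochastic classifier wrapper with majority-over-repetitions gating.

    Parameters
    ----------
    hidden_layer_size : width of the single hidden layer.
    n_reps : repetitions of train+predict when assigning new samples.
    threshold : consistency fraction a winning label must strictly exceed.
    validation_size : held-out fraction of the stratified split (0.1 = 9:1).
    resplit : draw a fresh train/validation split every repetition; if
        False only the weight initialization is re-drawn.
    max_iter, random_state : passed to the underlying MLP / seed sequence.

    Attributes
    ----------
    classes_ : label set.
    validation_accuracy_ : accuracy of the reference model on its held-out
        fold.
    """

    def __init__(self, hidden_layer_size: int = 16, n_reps: int = 500,
                 threshold: float = 1.0 / 3.0, validation_size: float = 0.1,
                 resplit: bool = True, max_iter: int = 800,
                 random_state: int | None = 0):
        self.hidden_layer_size = hidden_layer_size
        self.n_reps = n_reps
        self.threshold = threshold
        self.validation_size = validation_size
        self.resplit = resplit
        self.max_iter = max_iter
        self.random_state = random_state

    def _new_model(self, seed: int) -> MLPClassifier:
        return MLPClassifier(hidden_layer_sizes=(self.hidden_layer_size,),
                             solver="lbfgs", max_iter=self.max_iter,
                             random_state=seed)

    def _split(self, seed: int):
        return train_test_split(
            self._X, self._y, test_size=self.validation_size,
            stratify=self._y, random_state=seed,
        )

    def fit(self, X, y):
        """Standardize features, train a reference model on a stratified 9:1 split."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] < 10:
            raise ValueError("need >= 10 samples for a 9:1 split")
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("every class needs >= 2 samples for stratification")
        self._scaler = StandardScaler().fit(X)
        self._X = self._scaler.transform(X)
        self._y = y
        self.classes_ = classes
        root = np.random.SeedSequence(self.random_state).generate_state(2)
        self._rep_entropy = int(root[1])
        ref_seed = int(root[0] % (2**31 - 1))
        X_tr, X_val, y_tr, y_val = self._split(ref_seed)
        model = self._new_model(ref_seed).fit(X_tr, y_tr)
        self.validation_accuracy_ = float(model.score(X_val, y_val))
        self._reference_model = model
        self.n_features_in_ = X.shape[1]
        return self

    def consistency_counts(self, X) -> pd.DataFrame:
        """Per-label counts over ``n_reps`` repeated train+predict rounds."""
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        X = self._scaler.transform(np.asarray(X, dtype=float))
        counts = pd.DataFrame(0, index=range(X.shape[0]),
                              columns=[str(c) for c in self.classes_], dtype=int)
        seeds = np.random.SeedSequence(self._rep_entropy).generate_state(self.n_reps)
        for seed in seeds:
            seed = int(seed % (2**31 - 1))
            if self.resplit:
                X_tr, _, y_tr, _ = self._split(seed)
            else:
                X_tr, _, y_tr, _ = self._split(0)
            model = self._new_model(seed).fit(X_tr, y_tr)
            pred = model.predict(X)
            for i, lab in enumerate(pred):
                counts.iat[i, counts.columns.get_loc(str(lab))] += 1
        return counts

    def predict_with_consistency(self, X, sample_ids=None) -> pd.DataFrame:
        """Counts plus the consistency gate; index by ``sample_ids`` if given."""
        counts = self.consistency_counts(X)
        if sample_ids is not None:
            counts.index = list(sample_ids)
        out = apply_consistency_rule(counts, self.n_reps, self.threshold)
        return pd.concat([counts, out], axis=1)

    def predict(self, X):
        """Winning label per sample, or "unassigned" below the consistency bar."""
        return self.predict_with_consistency(X)["assigned"].to_numpy()


def train_classifier(
    signature_matrix: pd.DataFrame,
    labels: pd.Series,
    seed: int | None = 0,
    **params,
) -> ConsistencyClassifier:
    """Fit a :class:`ConsistencyClassifier` on a features x samples table.

    ``signature_matrix`` rows are metagene features, columns samples;
    ``labels`` maps sample -> subtype. Returns the fitted classifier (its
    ``validation_accuracy_`` reports the held-out fold).
    """
    samples = [s for s in signature_matrix.columns if s in labels.index]
    X = signature_matrix[samples].to_numpy().T
    clf = ConsistencyClassifier(random_state=seed, **params)
    return clf.fit(X, labels.loc[samples].to_numpy())
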