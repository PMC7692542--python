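"""Feature selection: correlation-based subset search and SVM-RFE.

Both selectors are scikit-learn estimators (``fit`` on training data only,
``transform``/``get_support`` afterwards) so they compose with Pipelines and
model selection, and leakage guards can assert that neither ever sees test
rows.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted, check_X_y

log = logging.getLogger(__name__)


def cfs_merit(r_cf: np.ndarray, r_ff: np.ndarray, subset: list[int]) -> float:
    """Merit of a feature subset: k * rcf_bar / sqrt(k + k(k-1) * rff_bar).

    ``r_cf`` holds |feature-label| correlations, ``r_ff`` the |feature-feature|
    correlation matrix. Larger merit rewards label-correlated features and
    penalizes mutually redundant ones.
    """
    k = len(subset)
    if k == 0:
        return 0.0
    rcf_bar = float(np.mean(r_cf[subset]))
    if k == 1:
        rff_bar = 0.0
    else:
        sub = r_ff[np.ix_(subset, subset)]
        rff_bar = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return k * rcf_bar / np.sqrt(k + k * (k - 1) * rff_bar)


class CFSSelector(SelectorMixin, BaseEstimator):
    """Correlation-based feature selection by greedy forward merit search.

    Starting from the empty set, the feature whose addition most increases
    the subset merit is added; the search stops when no addition improves
    merit. Constant features (undefined correlation) are skipped with a log
    entry. Correlations with the binary label are point-biserial, i.e.
    plain Pearson r against the 0/1 coding.
    """

    def __init__(self, max_features: int | None = None):
        self.max_features = max_features

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = np.asarray(y, dtype=float)
        n_features = X.shape[1]

        sd = X.std(axis=0)
        usable = sd > 0
        if not usable.all():
            log.info("CFS: skipping %d constant feature(s)", int((~usable).sum()))
        if y.std() == 0:
            raise ValueError("label vector is constant")

        Xz = np.where(usable, (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
        yz = (y - y.mean()) / y.std()
        r_cf = np.abs(Xz.T @ yz / len(y))
        r_ff = np.abs(Xz.T @ Xz / len(y))
        r_cf[~usable] = -np.inf

        subset: list[int] = []
        merit = 0.0
        limit = self.max_features or n_features
        while len(subset) < limit:
            best_gain, best_j = 0.0, -1
            in_set = np.zeros(n_features, dtype=bool)
            in_set[subset] = True
            for j in range(n_features):
                if in_set[j] or not usable[j]:
                    continue
                m = cfs_merit(r_cf, r_ff, subset + [j])
                if m > merit + best_gain + 1e-12:
                    best_gain = m - merit
                    best_j = j
            if best_j < 0:
                break
            subset.append(best_j)
            merit += best_gain
        if not subset:
            # degenerate all-noise input: keep the single best feature
            subset = [int(np.argmax(r_cf))]
            merit = cfs_merit(r_cf, r_ff, subset)
        self.n_features_in_ = n_features
        self.selected_ = np.array(sorted(subset), dtype=int)
        self.merit_ = float(merit)
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[self.selected_] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class SVMRFESelector(SelectorMixin, BaseEstimator):
    """Recursive feature elimination with a linear soft-margin SVM.

    Features are standardized, an L2 SVM is fitted, and the feature with the
    smallest squared weight is removed; this repeats until ``target_k``
    features remain. The elimination order is recorded (first eliminated
    first). If the input already has <= target_k features, the selector is
    the identity.
    """

    def __init__(self, target_k: int = 23, C: float = 1.0, random_state: int = 0):
        self.target_k = target_k
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        n_features = X.shape[1]
        remaining = list(range(n_features))
        eliminated: list[int] = []
        while len(remaining) > self.target_k:
            Xs = StandardScaler().fit_transform(X[:, remaining])
            svm = LinearSVC(
                C=self.C, dual=True, max_iter=20000,
                random_state=self.random_state,
            )
            svm.fit(Xs, y)
            w2 = np.ravel(svm.coef_) ** 2
            drop = int(np.argmin(w2))
            eliminated.append(remaining.pop(drop))
        self.n_features_in_ = n_features
        self.selected_ = np.array(sorted(remaining), dtype=int)
        self.elimination_order_ = np.array(eliminated, dtype=int)
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[self.selected_] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def cfs_select(X, y, feature_names=None) -> list:
    """Functional wrapper: names (or indices) of the CFS-selected subset."""
    sel = CFSSelector().fit(X, y)
    idx = sel.selected_
    if feature_names is not None:
        return [feature_names[i] for i in idx]
    return list(idx)


def svm_rfe(X, y, target_k: int = 23, feature_names=None) -> list:
    """Functional wrapper: names (or indices) of the RFE-surviving subset."""
    sel = SVMRFESelector(target_k=target_k).fit(X, y)
    idx = sel.selected_
    if feature_names is not None:
        return [feature_names[i] for i in idx]
    return list(idx)
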