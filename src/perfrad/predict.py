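"""Two-loop leave-one-out feature selection with an LDA combined response index.

The decision variable ("combined response index") is a Fisher linear
discriminant: weights ``w = S_w^{-1} (m1 - m0)`` from the pooled within-class
covariance and class means, intercept centring the index at the midpoint of
the projected class means, oriented so larger values indicate the positive
class (here: failure to achieve one-year disease-free survival).

The nested construction is the point of this module.  The **outer** loop
leaves one case out entirely; the **inner** loop — greedy forward feature
selection scored by leave-one-out AUC of the LDA index — runs only on the
remaining n-1 cases.  The held-out index for each case therefore comes from a
model (and a feature set) that never saw that case, so held-out AUC is free
of selection bias, while resubstitution ("training") AUC is not; the gap
between the two is what the nesting exposes.

Missing feature values are never imputed: a case with a missing value in a
candidate feature disqualifies that feature for the fold (warned), keeping
the leakage guarantee intact.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

RIDGE_CONDITION_LIMIT = 1e8
RIDGE_SCALE = 1e-6


class InsufficientDataError(ValueError):
    pass


@dataclasses.dataclass
class LDAModel:
    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    condition_number: float
    ridge_used: bool

    def decision_index(self, X: np.ndarray) -> np.ndarray:
        """Combined response index for rows of X (columns = selected features)."""
        X = np.asarray(X, dtype=float)
        return X @ self.weights + self.intercept


def _pooled_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m0 = X[y == 0].mean(axis=0)
    m1 = X[y == 1].mean(axis=0)
    n = len(y)
    d0 = X[y == 0] - m0
    d1 = X[y == 1] - m1
    sw = (d0.T @ d0 + d1.T @ d1) / (n - 2)
    return m0, m1, sw


def fit_lda(X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None) -> LDAModel:
    """Fit the two-class LDA index.

    Requires at least two cases per class and no missing values.  Constant
    (zero-variance) features are dropped with a warning (their weight is
    reported as 0).  When the pooled covariance is ill-conditioned
    (condition number > 1e8) a ridge ``eps = 1e-6 * trace/p`` is added.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(int)
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed in fit_lda")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise InsufficientDataError(f"need >=2 cases per class, got {n0} and {n1}")
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]

    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [names[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance features: {dropped}")
    if not keep.any():
        raise InsufficientDataError("all features are constant")
    Xk = X[:, keep]
    m0, m1, sw = _pooled_stats(Xk, y)
    cond = float(np.linalg.cond(sw))
    ridge_used = not np.isfinite(cond) or cond > RIDGE_CONDITION_LIMIT
    if ridge_used:
        sw = sw + np.eye(sw.shape[0]) * (RIDGE_SCALE * np.trace(sw) / sw.shape[0])
    w_k = np.linalg.solve(sw, m1 - m0)
    weights = np.zeros(X.shape[1])
    weights[keep] = w_k
    intercept = -float(w_k @ (m0 + m1) / 2.0)
    return LDAModel(list(names), weights, intercept, cond, ridge_used)


def _loo_lda_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Held-out LDA index for each case from a model fit on the other n-1.

    Vectorised across the left-out index via rank-one downdates of the class
    sums and scatters; used as the inner-loop selection criterion.  Matches a
    naive per-fold :func:`fit_lda` loop (tested).  Cases whose removal leaves
    a class with fewer than two members get NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    is1 = (y == 1).astype(float)
    is0 = 1.0 - is1
    n0, n1 = int(is0.sum()), int(is1.sum())
    S0 = (X * is0[:, None]).sum(axis=0)
    S1 = (X * is1[:, None]).sum(axis=0)
    Q0 = np.einsum("ij,ik,i->jk", X, X, is0)
    Q1 = np.einsum("ij,ik,i->jk", X, X, is1)
    outer_x = np.einsum("ij,ik->ijk", X, X)

    nc0 = n0 - is0
    nc1 = n1 - is1
    valid = (nc0 >= 2) & (nc1 >= 2)
    nc0 = np.maximum(nc0, 1)
    nc1 = np.maximum(nc1, 1)
    s0 = S0[None, :] - X * is0[:, None]
    s1 = S1[None, :] - X * is1[:, None]
    q0 = Q0[None, :, :] - outer_x * is0[:, None, None]
    q1 = Q1[None, :, :] - outer_x * is1[:, None, None]
    m0 = s0 / nc0[:, None]
    m1 = s1 / nc1[:, None]
    scat = (
        q0 - nc0[:, None, None] * np.einsum("ij,ik->ijk", m0, m0)
        + q1 - nc1[:, None, None] * np.einsum("ij,ik->ijk", m1, m1)
    )
    sw = scat / float(n - 3)  # (n-1) training cases, minus two class means

    ev = np.linalg.eigvalsh(sw)
    ev_min, ev_max = ev[:, 0], ev[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.abs(ev_max) / np.abs(ev_min)
    need_ridge = ~np.isfinite(cond) | (cond > RIDGE_CONDITION_LIMIT) | (ev_min <= 0)
    if need_ridge.any():
        tr = np.einsum("ijj->i", sw)
        eps = RIDGE_SCALE * tr / p
        sw = sw + need_ridge[:, None, None] * eps[:, None, None] * np.eye(p)[None, :, :]
    diff = m1 - m0
    try:
        w = np.linalg.solve(sw, diff[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        w = np.linalg.solve(sw + 1e-12 * np.eye(p)[None, :, :], diff[:, :, None])[:, :, 0]
    scores = np.einsum("ij,ij->i", X, w) - 0.5 * np.einsum("ij,ij->i", w, m0 + m1)
    scores[~valid] = np.nan
    return scores


def empirical_auc_fast(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2 (rank implementation)."""
    from scipy.stats import rankdata

    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    max_features: int = 2,
) -> list[str]:
    """Greedy forward selection scored by inner-leave-one-out AUC.

    At each step the candidate feature whose addition maximises the LOO AUC
    of the LDA index on the provided cases is added; ties break by feature
    name order; selection stops when no addition improves the AUC or
    ``max_features`` is reached.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(y) < 6:
        raise InsufficientDataError("forward selection needs at least 6 cases")
    if X.shape[1] < 1:
        raise InsufficientDataError("at least one feature required")
    order = np.argsort(feature_names)  # deterministic tie-break by name
    usable = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.isnan(col).any():
            warnings.warn(f"feature {feature_names[j]} has missing values; excluded from this fold")
            continue
        if col.std() > 0:
            usable.append(j)
    if not usable:
        raise InsufficientDataError("no usable (non-constant, complete) features")

    selected: list[int] = []
    best_auc = -np.inf
    while len(selected) < min(max_features, len(usable)):
        best_j, best_cand_auc = None, best_auc
        for j in sorted(usable, key=lambda j: feature_names[j]):
            if j in selected:
                continue
            cols = selected + [j]
            loo = _loo_lda_scores(X[:, cols], y)
            ok = np.isfinite(loo)
            if not ok.all():
                # inner folds that would empty a class yield no score; the
                # candidate is still scorable if both classes remain
                if len(np.unique(y[ok])) < 2:
                    continue
            auc = empirical_auc_fast(loo[ok], y[ok])
            if auc > best_cand_auc + 1e-12:
                best_cand_auc, best_j = auc, j
        if best_j is None:
            break
        selected.append(best_j)
        best_auc = best_cand_auc
    if not selected:
        raise InsufficientDataError("no feature improved on an empty model")
    return [feature_names[j] for j in selected]


@dataclasses.dataclass
class TwoLoopResult:
    case_ids: list[str]
    labels: np.ndarray
    testing_index: np.ndarray  # held-out combined response index per case
    training_index: np.ndarray  # mean resubstitution index over folds where the case trained
    fold_selections: list[list[str]]  # selected feature set per outer fold
    selection_frequency: dict[str, int]
    skipped_folds: list[int]

    def testing_auc(self) -> float:
        ok = np.isfinite(self.testing_index)
        return empirical_auc_fast(self.testing_index[ok], self.labels[ok])

    def training_auc(self) -> float:
        """Resubstitution AUC of the per-case mean training indices."""
        ok = np.isfinite(self.training_index)
        return empirical_auc_fast(self.training_index[ok], self.labels[ok])

    def mean_fold_training_auc(self) -> float:
        """Average over outer folds of the resubstitution AUC inside the fold."""
        return float(np.nanmean(self._fold_training_aucs))

    _fold_training_aucs: np.ndarray = dataclasses.field(default=None, repr=False)


def two_loop_loo(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    max_features: int = 2,
    case_ids: list[str] | None = None,
) -> TwoLoopResult:
    """Nested (two-loop) leave-one-out evaluation of the combined response index.

    Outer loop: leave out case ``i``.  Inner loop: forward selection (scored
    by inner LOO AUC) and the LDA fit run only on the remaining n-1 cases.
    The testing index for case ``i`` comes from that model; training indices
    are the model's resubstitution scores on its own n-1 cases, averaged per
    case over the folds in which it trained.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 6:
        raise InsufficientDataError("need at least 6 cases")
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("both classes must be present")
    ids = case_ids if case_ids is not None else [f"case{i}" for i in range(n)]

    testing = np.full(n, np.nan)
    train_sum = np.zeros(n)
    train_cnt = np.zeros(n)
    fold_sel: list[list[str]] = []
    fold_train_aucs = np.full(n, np.nan)
    skipped: list[int] = []
    freq: dict[str, int] = {}
    for i in range(n):
        rest = np.arange(n) != i
        y_tr = y[rest]
        if len(np.unique(y_tr)) < 2 or min((y_tr == 0).sum(), (y_tr == 1).sum()) < 2:
            warnings.warn(f"outer fold {i} leaves a class too small; skipped")
            skipped.append(i)
            fold_sel.append([])
            continue
        try:
            sel = forward_select(X[rest], y_tr, feature_names, max_features)
        except InsufficientDataError as err:
            warnings.warn(f"outer fold {i}: {err}; skipped")
            skipped.append(i)
            fold_sel.append([])
            continue
        cols = [feature_names.index(s) for s in sel]
        Xtr = X[rest][:, cols]
        model = fit_lda(Xtr, y_tr, sel)
        # express the fold's index in pooled within-class SD units so that
        # scores pooled across outer folds are on one scale (a positive
        # affine map per fold: fold-internal ROC is untouched)
        m0, m1, sw = _pooled_stats(Xtr, y_tr)
        sd = float(np.sqrt(max(model.weights @ sw @ model.weights, 1e-300)))
        testing[i] = model.decision_index(X[i, cols][None, :])[0] / sd
        resub = model.decision_index(Xtr) / sd
        train_sum[rest] += resub
        train_cnt[rest] += 1
        fold_train_aucs[i] = empirical_auc_fast(resub, y_tr)
        fold_sel.append(sel)
        for s in sel:
            freq[s] = freq.get(s, 0) + 1
    training = np.where(train_cnt > 0, train_sum / np.maximum(train_cnt, 1), np.nan)
    res = TwoLoopResult(
        case_ids=ids,
        labels=y,
        testing_index=testing,
        training_index=training,
        fold_selections=fold_sel,
        selection_frequency=freq,
        skipped_folds=skipped,
    )
    res._fold_training_aucs = fold_train_aucs
    return res
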