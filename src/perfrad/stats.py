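"""Evaluation statistics: ROC (empirical and binormal), ICC, kappa, paired t, Dice.

The binormal ROC model assumes latent normal score distributions: negatives
N(0,1) and positives N(a/b, 1/b^2) on some unobserved monotone transform of
the score axis, giving TPF = Phi(a + b * Phi^{-1}(FPF)) and
AUC = Phi(a / sqrt(1 + b^2)).  The fit is a maximum-likelihood fit of the
ordinal-category form of the model: scores are first reduced to ordered
categories by truth-state run collapsing (adjacent scores belonging to a run
of one class share a category, since interior cuts within a run do not move
the empirical ROC), then category cutpoints and (a, b) are estimated jointly.
Because the likelihood depends on the data only through the category counts,
the fit is invariant to any strictly increasing transform of the scores.

The ICC is the two-way random-effects, absolute-agreement, single-measure
form ICC(2,1): with case mean squares MSR, rater mean squares MSC and
residual MSE from the two-way ANOVA of an n x k ratings table,

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .imaging import BinaryMask

MAX_CATEGORIES = 40  # cap on binormal fit categories for continuous scores
ICC_MODEL_LABEL = "ICC(2,1) two-way random, absolute agreement, single measure"


@dataclasses.dataclass
class ROCResult:
    auc_empirical: float
    a: float
    b: float
    auc_binormal: float
    ci_low: float
    ci_high: float
    se_a: float
    se_b: float
    n_pos: int
    n_neg: int
    n_categories: int
    degenerate: bool = False
    converged: bool = True


@dataclasses.dataclass
class AgreementResult:
    """Container for the agreement layer; each analysis fills its own part."""

    icc: float | None = None
    icc_model: str | None = None
    kappa: float | None = None
    t_stat: float | None = None
    p_value: float | None = None
    n: int | None = None
    degenerate: bool = False


def empirical_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 * P(pos == neg)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score vectors must be nonempty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def collapse_to_categories(
    scores_pos: np.ndarray, scores_neg: np.ndarray, max_categories: int = MAX_CATEGORIES
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce scores to ordered category counts by truth-state run collapsing.

    Returns (neg_counts, pos_counts) per category, lowest score first.  Runs
    of consecutive distinct score values carrying only one class collapse into
    a single category; values shared by both classes form their own category.
    If more than ``max_categories`` remain (continuous scores), the scores are
    re-binned at pooled-sample quantiles instead: quantile edges are blind to
    the class labels, whereas run boundaries are label-informative locations
    and binning there biases the fit (deterministic either way).
    """
    pos = np.sort(np.asarray(scores_pos, dtype=float))
    neg = np.sort(np.asarray(scores_neg, dtype=float))
    values = np.unique(np.concatenate([pos, neg]))
    npos = np.searchsorted(pos, values, side="right") - np.searchsorted(pos, values, side="left")
    nneg = np.searchsorted(neg, values, side="right") - np.searchsorted(neg, values, side="left")
    cats: list[list[float]] = []  # [neg, pos] counts
    prev_kind = None
    for np_i, nn_i in zip(npos, nneg):
        kind = "mixed" if (np_i > 0 and nn_i > 0) else ("pos" if np_i > 0 else "neg")
        if kind != "mixed" and kind == prev_kind:
            cats[-1][0] += nn_i
            cats[-1][1] += np_i
        else:
            cats.append([float(nn_i), float(np_i)])
        prev_kind = kind
    arr = np.array(cats)
    if len(arr) > max_categories:
        pooled = np.concatenate([pos, neg])
        edges = np.unique(
            np.quantile(pooled, np.linspace(0.0, 1.0, max_categories + 1)[1:-1])
        )
        bins = np.concatenate([[-np.inf], edges, [np.inf]])
        nneg_b, _ = np.histogram(neg, bins=bins)
        npos_b, _ = np.histogram(pos, bins=bins)
        arr = np.stack([nneg_b, npos_b], axis=1).astype(float)
        arr = arr[arr.sum(axis=1) > 0]
    return arr[:, 0], arr[:, 1]


def _binormal_nll(theta: np.ndarray, nneg: np.ndarray, npos: np.ndarray) -> float:
    K = len(nneg)
    a, logb = theta[0], theta[1]
    b = np.exp(logb)
    t = np.empty(K - 1)
    t[0] = theta[2]
    if K > 2:
        t[1:] = theta[2] + np.cumsum(np.exp(theta[3:]))
    cdf_neg = np.concatenate([[0.0], sps.norm.cdf(t), [1.0]])
    cdf_pos = np.concatenate([[0.0], sps.norm.cdf(b * t - a), [1.0]])
    p_neg = np.clip(np.diff(cdf_neg), 1e-12, None)
    p_pos = np.clip(np.diff(cdf_pos), 1e-12, None)
    return float(-(nneg @ np.log(p_neg) + npos @ np.log(p_pos)))


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = x.copy(); pp[i] += eps; pp[j] += eps
            pm = x.copy(); pm[i] += eps; pm[j] -= eps
            mp = x.copy(); mp[i] -= eps; mp[j] += eps
            mm = x.copy(); mm[i] -= eps; mm[j] -= eps
            H[i, j] = H[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps * eps)
    return H


def fit_binormal_roc(
    scores_pos: np.ndarray,
    scores_neg: np.ndarray,
    max_categories: int = MAX_CATEGORIES,
) -> ROCResult:
    """Maximum-likelihood binormal ROC fit with a delta-method 95% CI on AUC."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size < 3 or neg.size < 3:
        raise ValueError("need at least 3 cases per class")
    if np.unique(np.concatenate([pos, neg])).size < 2:
        raise ValueError("scores are all tied; no ROC information")
    emp = empirical_auc(pos, neg)
    if emp in (0.0, 1.0):
        return ROCResult(
            auc_empirical=emp, a=np.nan, b=np.nan, auc_binormal=emp,
            ci_low=np.nan, ci_high=np.nan, se_a=np.nan, se_b=np.nan,
            n_pos=pos.size, n_neg=neg.size, n_categories=2, degenerate=True,
        )
    nneg, npos = collapse_to_categories(pos, neg, max_categories)
    K = len(nneg)

    # initial values from the z-transformed empirical operating points
    cum_neg = np.cumsum(nneg)[:-1] / nneg.sum()
    cum_pos = np.cumsum(npos)[:-1] / npos.sum()
    z_fpf = sps.norm.ppf(np.clip(1.0 - cum_neg, 1e-4, 1 - 1e-4))
    z_tpf = sps.norm.ppf(np.clip(1.0 - cum_pos, 1e-4, 1 - 1e-4))
    if len(z_fpf) >= 2 and np.std(z_fpf) > 0:
        b0, a0 = np.polyfit(z_fpf, z_tpf, 1)
        b0 = float(np.clip(b0, 0.1, 10.0))
    else:
        a0, b0 = 1.0, 1.0
    t0 = -z_fpf
    t0 = np.maximum.accumulate(t0)
    incr = np.maximum(np.diff(t0), 1e-3)
    theta0 = np.concatenate([[a0, np.log(b0), t0[0]], np.log(incr)])

    res = optimize.minimize(
        _binormal_nll, theta0, args=(nneg, npos), method="L-BFGS-B",
        options={"maxiter": 2000, "maxfun": 50000, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and res.fun > _binormal_nll(theta0, nneg, npos):
        raise RuntimeError(f"binormal MLE did not converge: {res.message}")
    a = float(res.x[0])
    b = float(np.exp(res.x[1]))
    auc = float(sps.norm.cdf(a / np.sqrt(1.0 + b * b)))

    H = _numeric_hessian(lambda th: _binormal_nll(th, nneg, npos), res.x)
    try:
        cov = np.linalg.inv(H)[:2, :2]
        # delta method; parameters are (a, log b)
        se_a = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_b = float(b * np.sqrt(max(cov[1, 1], 0.0)))
        s = np.sqrt(1.0 + b * b)
        dA_da = sps.norm.pdf(a / s) / s
        dA_dlogb = sps.norm.pdf(a / s) * (-a * b * b / s**3)
        grad = np.array([dA_da, dA_dlogb])
        var_auc = float(grad @ cov @ grad)
        se_auc = np.sqrt(max(var_auc, 0.0))
    except np.linalg.LinAlgError:
        se_a = se_b = se_auc = np.nan
    ci_low = float(np.clip(auc - 1.959963984540054 * se_auc, 0.0, 1.0))
    ci_high = float(np.clip(auc + 1.959963984540054 * se_auc, 0.0, 1.0))
    ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
    return ROCResult(
        auc_empirical=emp, a=a, b=b, auc_binormal=auc,
        ci_low=ci_low, ci_high=ci_high, se_a=se_a, se_b=se_b,
        n_pos=int(pos.size), n_neg=int(neg.size), n_categories=K,
        converged=bool(res.success),
    )


def bootstrap_auc_ci(
    scores_pos: np.ndarray,
    scores_neg: np.ndarray,
    n_resamples: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for the empirical AUC (stratified resampling)."""
    rng = np.random.default_rng(seed)
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    aucs = np.empty(n_resamples)
    for i in range(n_resamples):
        aucs[i] = empirical_auc(
            rng.choice(pos, size=pos.size, replace=True),
            rng.choice(neg, size=neg.size, replace=True),
        )
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def icc(ratings: np.ndarray) -> AgreementResult:
    """ICC(2,1) from the two-way ANOVA decomposition of an n x k table."""
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[0] < 3 or table.shape[1] < 2:
        raise ValueError("need an n>=3 by k>=2 complete ratings table")
    if np.isnan(table).any():
        raise ValueError("missing cells are not supported")
    n, k = table.shape
    grand = table.mean()
    if np.allclose(table, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return AgreementResult(icc=float(value), icc_model=ICC_MODEL_LABEL, n=n)


def cohen_kappa(labels_a: np.ndarray, labels_b: np.ndarray) -> AgreementResult:
    """Cohen's kappa for two binary labelings: (p_o - p_e) / (1 - p_e)."""
    a = np.asarray(labels_a).astype(int)
    b = np.asarray(labels_b).astype(int)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length label vectors of length >= 2")
    n = a.size
    p_o = float((a == b).mean())
    p_e = 0.0
    for c in np.union1d(a, b):
        p_e += float((a == c).mean()) * float((b == c).mean())
    if p_e >= 1.0 - 1e-15:
        return AgreementResult(kappa=np.nan, n=n, degenerate=True)
    return AgreementResult(kappa=float((p_o - p_e) / (1.0 - p_e)), n=n)


def paired_ttest(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    """Two-sided paired t-test on per-case differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        return AgreementResult(t_stat=0.0 if d.mean() == 0 else np.nan,
                               p_value=np.nan, n=n, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return AgreementResult(t_stat=t, p_value=p, n=n)


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A.B| / (|A| + |B|); two empty masks give 1.0."""
    va = a.voxels if isinstance(a, BinaryMask) else np.asarray(a)
    vb = b.voxels if isinstance(b, BinaryMask) else np.asarray(b)
    if isinstance(a, BinaryMask) and isinstance(b, BinaryMask) and not a.same_grid(b):
        raise ValueError("masks live on different grids")
    if va.shape != vb.shape:
        raise ValueError("mask shapes differ")
    va = va.astype(bool)
    vb = vb.astype(bool)
    denom = va.sum() + vb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(va, vb).sum() / denom)
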