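"""Conditional logistic regression for 1-case : M-control matched sets.

The conditional likelihood for a matched set with exactly one case is the
softmax probability of the case's linear predictor over all set members,

    L = prod_sets  exp(eta_case) / sum_j exp(eta_j),    eta = x . beta,

which eliminates the set-specific intercepts that matching introduces.
The solver is Newton-Raphson with the analytic score and observed
information, with step-halving when a step would decrease the
log-likelihood.  An unconditional (ordinary) logistic fit is also provided
for contrasts between independent case subgroups.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ClogitFit",
    "ConditionalLogisticRegression",
    "conditional_loglik",
    "fit_clogit",
    "likelihood_ratio_test",
    "fit_unconditional_logit",
    "LRTResult",
]

Z975 = 1.959964  # normal 97.5th percentile used for Wald 95% CIs


class ClogitError(ValueError):
    """Raised for invalid matched-set structure or non-estimable models."""


@dataclasses.dataclass
class ClogitFit:
    """Result of a conditional (or unconditional) logistic fit.

    Attributes
    ----------
    beta : per-term log-odds estimates
    cov : inverse observed information at the optimum
    loglik : maximized log-likelihood
    loglik_null : log-likelihood at beta = 0
    n_sets : number of matched sets used
    converged : whether the gradient tolerance was reached
    n_iter : Newton iterations performed
    terms : covariate names, aligned with ``beta``
    """

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n_sets: int
    converged: bool
    n_iter: int
    terms: tuple[str, ...]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def ci(self) -> np.ndarray:
        """Wald 95% confidence limits on the log-odds scale, shape (p, 2)."""
        half = Z975 * self.se
        return np.column_stack([self.beta - half, self.beta + half])

    def term_index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in fit terms {self.terms}") from None


def _group_layout(groups: np.ndarray):
    """Sort rows by group and return (order, start-offsets, group sizes)."""
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_groups[1:] != sorted_groups[:-1]])
    sizes = np.diff(np.r_[boundaries, groups.size])
    return order, boundaries, sizes, sorted_groups[boundaries]


def _validate_sets(y: np.ndarray, starts: np.ndarray, sizes: np.ndarray, labels):
    counts = np.add.reduceat(y.astype(int), starts)
    bad = np.flatnonzero(counts != 1)
    if bad.size:
        raise ClogitError(
            f"matched set {labels[bad[0]]!r} has {counts[bad[0]]} cases; "
            "exactly one case per set is required"
        )


def conditional_loglik(beta, X, y, groups) -> float:
    """Conditional log-likelihood sum_sets [eta_case - logsumexp(eta_set)].

    Computed with log-sum-exp stabilization.  Each set must contain exactly
    one case (``y == 1``).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(bool)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    order, starts, sizes, labels = _group_layout(groups)
    Xs, ys = X[order], y[order]
    _validate_sets(ys, starts, sizes, labels)
    eta = Xs @ beta
    seg = np.repeat(np.arange(starts.size), sizes)
    mx = np.full(starts.size, -np.inf)
    np.maximum.at(mx, seg, eta)
    lse = mx + np.log(np.bincount(seg, weights=np.exp(eta - mx[seg])))
    return float(eta[ys].sum() - lse.sum())


class ConditionalLogisticRegression(BaseEstimator):
    """Maximum-likelihood conditional logistic regression.

    Parameters
    ----------
    tol : convergence tolerance on the maximum absolute score component.
    max_iter : Newton iteration cap.
    max_halvings : step-halvings allowed per iteration before accepting.
    separation_bound : |beta| beyond which non-convergence is flagged as
        likely separation.

    After ``fit``, the estimates live in ``coef_``, ``cov_``, ``se_``,
    ``loglik_``, ``loglik_null_``, ``n_sets_``, ``converged_``, ``n_iter_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50,
                 max_halvings: int = 10, separation_bound: float = 10.0):
        self.tol = tol
        self.max_iter = max_iter
        self.max_halvings = max_halvings
        self.separation_bound = separation_bound

    def fit(self, X, y, groups, terms: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y).astype(bool)
        if X.shape[0] != y.size:
            raise ClogitError("X and y lengths differ")
        order, starts, sizes, labels = _group_layout(groups)
        Xs, ys = X[order], y[order]
        _validate_sets(ys, starts, sizes, labels)

        # informative sets: within-set variation in at least one covariate
        seg = np.repeat(np.arange(starts.size), sizes)
        first = Xs[starts]
        varies = np.zeros(starts.size, dtype=bool)
        np.logical_or.at(varies, seg, np.any(Xs != first[seg], axis=1))
        if not varies.any():
            raise ClogitError("no informative sets: covariates are constant within every set")

        n_sets, p = starts.size, X.shape[1]
        beta = np.zeros(p)
        loglik_null = -float(np.log(sizes).sum())
        ll = loglik_null
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            score, info = self._score_info(beta, Xs, ys, sizes, seg)
            if np.max(np.abs(score)) < self.tol:
                converged = True
                it -= 1
                break
            step = np.linalg.solve(info, score)
            new_beta, new_ll = beta + step, None
            for _ in range(self.max_halvings + 1):
                new_ll = self._loglik(new_beta, Xs, ys, sizes, seg)
                if new_ll >= ll - 1e-12:
                    break
                step *= 0.5
                new_beta = beta + step
            beta, ll = new_beta, new_ll
        else:
            converged = False
        score, info = self._score_info(beta, Xs, ys, sizes, seg)
        # separation heuristics: runaway coefficient, or a quasi-perfect fit
        # (conditional likelihood ~ 1 in every set) where the MLE diverges
        if converged and (np.any(np.abs(beta) > self.separation_bound)
                          or ll > -1e-6 * n_sets):
            converged = False
        cov = np.linalg.inv(info)

        self.coef_ = beta
        self.cov_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        self.loglik_ = ll
        self.loglik_null_ = loglik_null
        self.n_sets_ = n_sets
        self.converged_ = converged
        self.n_iter_ = it
        self.terms_ = tuple(terms) if terms is not None else tuple(
            f"x{i}" for i in range(p))
        return self

    @staticmethod
    def _loglik(beta, Xs, ys, sizes, seg):
        eta = Xs @ beta
        mx = np.full(sizes.size, -np.inf)
        np.maximum.at(mx, seg, eta)
        lse = mx + np.log(np.bincount(seg, weights=np.exp(eta - mx[seg])))
        return float(eta[ys].sum() - lse.sum())

    @staticmethod
    def _score_info(beta, Xs, ys, sizes, seg):
        eta = Xs @ beta
        mx = np.full(sizes.size, -np.inf)
        np.maximum.at(mx, seg, eta)
        w = np.exp(eta - mx[seg])
        denom = np.bincount(seg, weights=w)
        w = w / denom[seg]  # within-set softmax weights
        p = Xs.shape[1]
        wx = np.empty((sizes.size, p))
        for j in range(p):
            wx[:, j] = np.bincount(seg, weights=w * Xs[:, j])
        score = Xs[ys].sum(axis=0) - wx.sum(axis=0)
        wxx = np.einsum("i,ij,ik->jk", w, Xs, Xs)
        info = wxx - wx.T @ wx
        return score, info

    def result_(self) -> ClogitFit:
        return ClogitFit(
            beta=self.coef_, cov=self.cov_, loglik=self.loglik_,
            loglik_null=self.loglik_null_, n_sets=self.n_sets_,
            converged=self.converged_, n_iter=self.n_iter_, terms=self.terms_)


def fit_clogit(X, y, groups, terms=None, tol=1e-8, max_iter=50) -> ClogitFit:
    """Fit a conditional logistic model and return a :class:`ClogitFit`."""
    est = ConditionalLogisticRegression(tol=tol, max_iter=max_iter)
    est.fit(X, y, groups, terms=terms)
    return est.result_()


@dataclasses.dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def likelihood_ratio_test(fit_full: ClogitFit, fit_reduced: ClogitFit) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2*dLL ~ chi2(d terms).

    The reduced model's terms must be a subset of the full model's.
    """
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise ClogitError(
            f"models are not nested: {fit_reduced.terms} is not a subset of {fit_full.terms}")
    df = len(fit_full.terms) - len(fit_reduced.terms)
    statistic = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if statistic < -1e-6:
        raise ClogitError(
            f"full-model log-likelihood {fit_full.loglik:.6f} is below the reduced "
            f"model's {fit_reduced.loglik:.6f}; check convergence")
    statistic = max(statistic, 0.0)
    pvalue = 1.0 if df == 0 and statistic == 0.0 else float(stats.chi2.sf(statistic, max(df, 1)))
    if df == 0:
        pvalue = 1.0
    return LRTResult(statistic=statistic, df=df, pvalue=pvalue)


def fit_unconditional_logit(X, y, terms=None, add_intercept=True) -> ClogitFit:
    """Ordinary ML logistic regression, for independent case-subgroup contrasts.

    Returns the same :class:`ClogitFit` container (``n_sets`` is the row
    count); the intercept, when added, appears as term ``"intercept"``.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(float)
    names = list(terms) if terms is not None else [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = sm.add_constant(X, prepend=True)
        names = ["intercept"] + names
    model = sm.Logit(y, X)
    res = model.fit(disp=0, maxiter=100)
    beta = np.asarray(res.params, dtype=float)
    converged = bool(res.mle_retvals.get("converged", True))
    if np.any(np.abs(beta) > 15):
        converged = False  # separation heuristic
    null_ll = float(sm.Logit(y, np.ones((y.size, 1))).fit(disp=0).llf)
    return ClogitFit(
        beta=beta, cov=np.asarray(res.cov_params(), dtype=float),
        loglik=float(res.llf), loglik_null=null_ll, n_sets=int(y.size),
        converged=converged, n_iter=int(res.mle_retvals.get("iterations", 0)),
        terms=tuple(names))
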