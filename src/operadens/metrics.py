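"""Risk-discrimination and model-comparison statistics.

OPERA (odds ratio per adjusted standard deviation) re-expresses a matched
case-control log-odds coefficient on the scale of one covariate-adjusted
SD of the risk factor, making discrimination comparable across risk
factors.  Companions implemented here:

* bivariable rescaling by sqrt(1 - r^2) when correlated measures are
  fitted jointly,
* the interquartile risk ratio IQQR ~= OPERA^2.5,
* BIC differences with exp(-dBIC) read as posterior odds,
* Mann-Whitney AUC with a DeLong confidence interval,
* quartile odds ratios from control-defined cut-points,
* the one-way random-effects intraclass correlation for repeatability.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .clogit import Z975, ClogitFit, fit_clogit

__all__ = [
    "OperaResult",
    "ModelComparison",
    "opera_from_fit",
    "bivariable_opera",
    "iqrr",
    "delta_bic",
    "auc_adjusted",
    "quartile_ors",
    "icc",
    "IccResult",
]


class MetricsError(ValueError):
    pass


@dataclasses.dataclass
class OperaResult:
    """Odds ratio per adjusted SD with Wald CI and derived quantities."""

    opera: float
    ci_low: float
    ci_high: float
    log_opera: float
    se_log: float
    loglik: float | None = None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.opera <= self.ci_high):
            raise MetricsError("CI does not bracket the OPERA estimate")
        if self.opera <= 0:
            raise MetricsError("OPERA must be positive")

    @property
    def iqrr(self) -> float:
        return iqrr(self.opera)


def opera_from_fit(fit: ClogitFit, term: str) -> OperaResult:
    """OPERA = exp(beta) for a term standardized to unit adjusted SD."""
    if not fit.converged:
        raise MetricsError(
            f"fit did not converge (n_iter={fit.n_iter}); refusing OPERA for {term!r}")
    j = fit.term_index(term)
    b, se = float(fit.beta[j]), float(fit.se[j])
    return OperaResult(
        opera=float(np.exp(b)), ci_low=float(np.exp(b - Z975 * se)),
        ci_high=float(np.exp(b + Z975 * se)), log_opera=b, se_log=se,
        loglik=fit.loglik)


def bivariable_opera(fit: ClogitFit, terms, r: float) -> dict[str, OperaResult]:
    """Rescale jointly-fitted log-ORs to per-adjusted-SD units.

    When two standardized measures with correlation ``r`` are fitted
    together, the SD of one conditional on the other is sqrt(1 - r^2);
    each joint log-OR (and its CI endpoints) is multiplied by that factor
    before exponentiation.  ``r`` may be a scalar (same for all terms) or a
    mapping term -> multiple correlation with the other fitted measures.
    """
    out = {}
    for term in terms:
        rj = r[term] if isinstance(r, dict) else r
        if abs(rj) >= 1:
            raise MetricsError(
                f"|r| = {abs(rj)} >= 1 for {term!r}: measures are indistinguishable")
        scale = float(np.sqrt(1.0 - rj ** 2))
        j = fit.term_index(term)
        b, se = float(fit.beta[j]) * scale, float(fit.se[j]) * scale
        out[term] = OperaResult(
            opera=float(np.exp(b)), ci_low=float(np.exp(b - Z975 * se)),
            ci_high=float(np.exp(b + Z975 * se)), log_opera=b, se_log=se,
            loglik=fit.loglik)
    return out


def iqrr(opera: float) -> float:
    """Interquartile risk ratio, approximately OPERA**2.5."""
    if opera <= 0:
        raise MetricsError("OPERA must be positive")
    return float(opera) ** 2.5


_STRENGTH_BANDS = ((2.0, "none-existent"), (6.0, "positive"),
                   (10.0, "strong"), (np.inf, "very strong"))


@dataclasses.dataclass
class ModelComparison:
    """BIC difference (model A minus model B) and its posterior-odds reading."""

    delta_ll: float
    delta_bic: float
    posterior_odds: float
    equal_params: bool
    verbal_strength: str


def delta_bic(ll_a: float, ll_b: float, k_a: int, k_b: int,
              n: int | None = None, convention: str = "paper") -> ModelComparison:
    """Compare model A with model B by BIC difference.

    For equal parameter counts dBIC = -2 (ll_a - ll_b): negative favours A.
    With unequal counts the (k_a - k_b) log n penalty is added and ``n``
    is required.  ``convention="paper"`` reads posterior odds for A as
    exp(-dBIC); ``"halved"`` uses the textbook exp(-dBIC / 2).
    Verbal strength follows the 2 / 6 / 10 bands on |dBIC|.
    """
    equal = k_a == k_b
    d = -2.0 * (ll_a - ll_b)
    if not equal:
        if n is None or n <= 0:
            raise MetricsError("sample size n > 0 required when parameter counts differ")
        d += (k_a - k_b) * np.log(n)
    if convention == "paper":
        odds = float(np.exp(-d))
    elif convention == "halved":
        odds = float(np.exp(-d / 2.0))
    else:
        raise MetricsError(f"unknown BIC convention {convention!r}")
    strength = next(label for bound, label in _STRENGTH_BANDS if abs(d) < bound or bound is np.inf)
    return ModelComparison(delta_ll=float(ll_a - ll_b), delta_bic=float(d),
                           posterior_odds=odds, equal_params=equal,
                           verbal_strength=strength)


def auc_adjusted(values, case_flag, alpha: float = 0.05):
    """Mann-Whitney AUC of an adjusted measure with a DeLong variance CI.

    Returns ``(auc, (lo, hi))``.  Values pooled over all subjects; both
    classes must be present.
    """
    values = np.asarray(values, dtype=float)
    case = np.asarray(case_flag).astype(bool)
    x, yctl = values[case], values[~case]
    m, n = x.size, yctl.size
    if m == 0 or n == 0:
        raise MetricsError("both cases and controls are required for an AUC")
    # midrank placements (DeLong components)
    allv = np.concatenate([x, yctl])
    order = stats.rankdata(allv)  # midranks over the pooled sample
    rx = stats.rankdata(x)
    ry = stats.rankdata(yctl)
    v10 = (order[:m] - rx) / n          # P(X > Y | X = x_i) with tie halves
    v01 = 1.0 - (order[m:] - ry) / m    # P(X > Y | Y = y_j)
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return auc, (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def quartile_ors(values_adjusted, case_flag, groups, extra_X=None, extra_terms=()):
    """Odds ratios for quartiles Q2-Q4 versus Q1 of an adjusted measure.

    Cut-points are the 25/50/75 percentiles of the *control* distribution
    of the adjusted measure; three indicator terms are fitted by
    conditional logistic regression (optionally alongside ``extra_X``
    covariate columns).  Returns ``(ors, fit, cutpoints)`` with
    ``ors[q] = exp(beta_q)`` for q in {"Q2", "Q3", "Q4"}.
    """
    v = np.asarray(values_adjusted, dtype=float)
    case = np.asarray(case_flag).astype(bool)
    ctl = v[~case]
    if np.unique(ctl).size < 4:
        raise MetricsError("need at least 4 distinct control values to form quartiles")
    cut = np.quantile(ctl, [0.25, 0.5, 0.75])
    if np.unique(cut).size < 3:
        raise MetricsError(f"tied cut-points {cut}: quartiles collapse")
    q = np.digitize(v, cut)  # 0..3
    ind = np.column_stack([(q == k).astype(float) for k in (1, 2, 3)])
    terms = ["Q2", "Q3", "Q4"]
    X = ind
    if extra_X is not None:
        extra_X = np.asarray(extra_X, dtype=float)
        if extra_X.ndim == 1:
            extra_X = extra_X[:, None]
        X = np.column_stack([ind, extra_X])
        terms = terms + list(extra_terms)
    fit = fit_clogit(X, case, groups, terms=terms)
    ors = {t: float(np.exp(fit.beta[fit.term_index(t)])) for t in ("Q2", "Q3", "Q4")}
    return ors, fit, cut


@dataclasses.dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    msb: float
    msw: float
    n_groups: int


def icc(groups_values, alpha: float = 0.05) -> IccResult:
    """One-way random-effects intraclass correlation, ICC(1).

    ``groups_values``: sequence of per-group repeated measurements (or a
    2-D array, one row per group).  Estimator (MSB - MSW)/(MSB + (k0 - 1)
    MSW) with k0 the ANOVA-weighted mean group size; CI from the
    F distribution of MSB/MSW.
    """
    groups = [np.asarray(g, dtype=float) for g in groups_values]
    groups = [g for g in groups if g.size >= 2]
    n = len(groups)
    if n < 2:
        raise MetricsError("need at least 2 groups with at least 2 measurements each")
    sizes = np.array([g.size for g in groups], dtype=float)
    N = sizes.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (n - 1)
    msw = ssw / (N - n)
    k0 = (N - (sizes ** 2).sum() / N) / (n - 1)
    if msw == 0.0:
        est = 1.0
    else:
        est = (msb - msw) / (msb + (k0 - 1) * msw)
    df1, df2 = n - 1, int(N - n)
    if msw > 0:
        F = msb / msw
        fl = F / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = F * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k0 - 1)
        hi = (fu - 1) / (fu + k0 - 1)
    else:
        lo = hi = 1.0
    return IccResult(icc=float(est), ci_low=float(lo), ci_high=float(hi),
                     msb=msb, msw=msw, n_groups=n)
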