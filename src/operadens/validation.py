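"""Calibration-recovery studies on the synthetic cohort.

These routines close the loop between the generator and the estimators:
data are generated under the exact conditional-logistic mechanism at
stated effect sizes and the estimators must recover them.  They back the
package's reproducibility checks and are deliberately plain functions so
the same code path serves scripted validation runs.
"""

from __future__ import annotations

import numpy as np

from .clogit import fit_clogit
from .metrics import icc
from .simulate import (
    SimulationParams,
    default_corr_matrix,
    generate_cohort,
    generate_latent_traits,
    generate_repeat_measurements,
)

__all__ = [
    "opera_recovery_study",
    "correlation_calibration",
    "icc_recovery_study",
]


def opera_recovery_study(mode: str, measure: str, beta: float, n_sets: int,
                         n_replicates: int, seed: int,
                         controls_per_case: int = 3) -> dict:
    """Generate matched sets at a known per-adjusted-SD log-odds and refit.

    Per replicate: a cohort of ``n_sets`` 1:M sets is generated with the
    given log-odds on the standardized ``measure`` (the only non-zero
    effect); conditional logistic regression on that standardized measure
    returns one beta-hat.  Replicate seeds are master seed + index.

    Returns summary with mean beta-hat, mean exp(beta-hat) and their
    Monte-Carlo standard errors.
    """
    betas = []
    for rep in range(n_replicates):
        kwargs = dict(seed=seed + rep, controls_per_case=controls_per_case,
                      beta_by_outcome={"interval": {}, "screen": {},
                                       mode: {measure: beta}},
                      bmi_age_interaction_screen=0.0)
        if mode == "interval":
            kwargs.update(n_sets_interval=n_sets, n_sets_screen=0)
        else:
            kwargs.update(n_sets_interval=0, n_sets_screen=n_sets)
        df = generate_cohort(SimulationParams(**kwargs))
        fit = fit_clogit(df[measure + "_latent"].to_numpy(),
                         df["case"].to_numpy() == 1,
                         df["set_id"].to_numpy())
        betas.append(float(fit.beta[0]))
    betas = np.asarray(betas)
    operas = np.exp(betas)
    return {
        "beta_true": beta,
        "mean_beta": float(betas.mean()),
        "se_beta": float(betas.std(ddof=1) / np.sqrt(betas.size)),
        "mean_opera": float(operas.mean()),
        "se_opera": float(operas.std(ddof=1) / np.sqrt(operas.size)),
        "n_replicates": int(n_replicates),
        "n_sets": int(n_sets),
    }


def correlation_calibration(n: int, seed: int, i: int = 0, j: int = 2) -> float:
    """Empirical Pearson correlation between two generated standardized
    measures under the default latent correlation matrix (defaults: the
    conventional- and higher-threshold dense-area columns)."""
    z = generate_latent_traits(n, default_corr_matrix(), seed)
    return float(np.corrcoef(z[:, i], z[:, j])[0, 1])


def icc_recovery_study(icc_true: float, n_pairs: int, n_replicates: int,
                       seed: int) -> dict:
    """Mean one-way ANOVA ICC over replicates of simulated repeat pairs."""
    rng = np.random.default_rng(seed)
    ests = [icc(generate_repeat_measurements(n_pairs, icc_true, rng)).icc
            for _ in range(n_replicates)]
    ests = np.asarray(ests)
    return {
        "icc_true": icc_true,
        "mean_icc": float(ests.mean()),
        "se_icc": float(ests.std(ddof=1) / np.sqrt(ests.size)),
        "n_pairs": int(n_pairs),
        "n_replicates": int(n_replicates),
    }
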