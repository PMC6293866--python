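"""End-to-end analysis: cohort in, model grid and report out.

For each outcome mode (interval, screen-detected) and measurement scale
(dense area, percent density), the grid fits the three single-measure
models and the four joint models (the three pairs and the triple),
reporting OPERA with Wald CIs, AUC, log-likelihoods, likelihood-ratio
tests for nested additions, and BIC differences with posterior odds for
equal-parameter comparisons.  Joint-model OPERAs are rescaled to
conditional-SD units by sqrt(1 - r^2) (pairs) or sqrt(1 - R_j^2)
(triple), with correlations estimated among controls.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clogit import fit_clogit, likelihood_ratio_test
from .metrics import auc_adjusted, bivariable_opera, delta_bic, opera_from_fit
from .preprocess import DensityStandardizer
from .simulate import MEASURES, SimulationParams, generate_cohort, read_cohort

__all__ = [
    "AnalysisConfig",
    "preprocess_cohort",
    "run_model_grid",
    "test_combined_vs_separate",
    "render_report",
]

SCALES = {"dense": ("cumulus_da", "alto_da", "cirro_da"),
          "percent": ("cumulus_pct", "alto_pct", "cirro_pct")}

MODEL_GRID = {
    "model1": ("cumulus", "alto"),
    "model2": ("cumulus", "cirro"),
    "model3": ("alto", "cirro"),
    "model4": ("cumulus", "alto", "cirro"),
}


class PipelineError(ValueError):
    pass


@dataclasses.dataclass
class AnalysisConfig:
    """Configuration of one analysis run."""

    input_csv: str | None = None
    sim_params: SimulationParams | None = None
    outcomes: tuple[str, ...] = ("interval", "screen")
    scales: tuple[str, ...] = ("dense", "percent")
    bic_convention: str = "paper"
    interaction_for_screen: bool = True
    seed: int = 0
    out_dir: str = "operadens_report"

    def __post_init__(self):
        if not self.outcomes:
            raise PipelineError("outcome filter is empty")
        bad = set(self.scales) - set(SCALES)
        if bad:
            raise PipelineError(f"unknown scales {bad}")


def load_cohort(config: AnalysisConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        return read_cohort(config.input_csv)
    params = config.sim_params or SimulationParams(seed=config.seed)
    return generate_cohort(params)


def preprocess_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Box-Cox + control-based age/BMI adjustment per measure and mode.

    Adds ``<measure>_std`` columns; standardization is done within each
    outcome mode (each mode has its own controls).
    """
    df = df.copy()
    for m in MEASURES:
        df[m + "_std"] = np.nan
        for mode, sub in df.groupby("mode"):
            X = sub[[m, "age", "bmi"]].to_numpy(float)
            std = DensityStandardizer()
            vals = std.fit_transform(X, controls=(sub["case"].to_numpy() == 0))
            df.loc[sub.index, m + "_std"] = vals
    return df


def _mode_terms(mode: str, config: AnalysisConfig, sub: pd.DataFrame):
    """Covariate columns fitted alongside the density terms."""
    ctl = sub[sub["case"] == 0]
    cols = {"bmi": sub["bmi"].to_numpy(float)}
    if mode == "screen" and config.interaction_for_screen:
        cols["bmi_x_age"] = ((sub["bmi"] - ctl["bmi"].mean()) *
                             (sub["age"] - ctl["age"].mean())).to_numpy(float)
    return cols


def _fit(sub, density_cols, covar_cols):
    terms = list(density_cols) + list(covar_cols)
    X = np.column_stack(
        [sub[c].to_numpy(float) for c in density_cols] +
        [covar_cols[c] for c in covar_cols])
    return fit_clogit(X, sub["case"].to_numpy() == 1, sub["set_id"].to_numpy(),
                      terms=terms)


def run_model_grid(df: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Fit the per-outcome, per-scale univariable and joint model grid."""
    if not np.all([(m + "_std") in df.columns for m in MEASURES]):
        df = preprocess_cohort(df)
    results: dict = {"config": config, "outcomes": {}}
    for mode in config.outcomes:
        sub = df[df["mode"] == mode]
        if sub.empty:
            raise PipelineError(f"no subjects with mode {mode!r}")
        covar = _mode_terms(mode, config, sub)
        mode_res: dict = {}
        for scale in config.scales:
            names = dict(zip(("cumulus", "alto", "cirro"), SCALES[scale]))
            std_col = {k: v + "_std" for k, v in names.items()}
            ctl = sub[sub["case"] == 0]
            corr = ctl[[std_col[k] for k in ("cumulus", "alto", "cirro")]].corr().to_numpy()
            uni = {}
            for k, col in std_col.items():
                fit = _fit(sub, [col], covar)
                res = opera_from_fit(fit, col)
                res.auc, res.auc_ci = auc_adjusted(sub[col], sub["case"] == 1)
                uni[k] = {"fit": fit, "opera": res}
            joint = {}
            keys = ("cumulus", "alto", "cirro")
            for model, members in MODEL_GRID.items():
                cols = [std_col[k] for k in members]
                fit = _fit(sub, cols, covar)
                if len(members) == 2:
                    i, j = (keys.index(members[0]), keys.index(members[1]))
                    r = float(corr[i, j])
                    scaled = bivariable_opera(fit, cols, r)
                else:
                    rmap = {}
                    Xc = ctl[[std_col[k] for k in members]].to_numpy(float)
                    for a, k in enumerate(members):
                        others = np.delete(Xc, a, axis=1)
                        yv = Xc[:, a]
                        A = np.column_stack([np.ones(len(yv)), others])
                        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
                        resid = yv - A @ coef
                        rmap[std_col[k]] = float(np.sqrt(max(0.0, 1 - resid.var() / yv.var())))
                    scaled = bivariable_opera(fit, cols, rmap)
                lrts = {}
                for k in members:
                    # does adding the other measure(s) improve on k alone?
                    lrts[k] = likelihood_ratio_test(fit, uni[k]["fit"])
                joint[model] = {"fit": fit, "opera": {k: scaled[std_col[k]] for k in members},
                                "lrt_vs_uni": lrts}
            comparisons = {}
            for a, b in itertools.combinations(keys, 2):
                comparisons[f"{a}_vs_{b}"] = delta_bic(
                    uni[a]["fit"].loglik, uni[b]["fit"].loglik,
                    len(uni[a]["fit"].terms), len(uni[b]["fit"].terms),
                    n=uni[a]["fit"].n_sets, convention=config.bic_convention)
            mode_res[scale] = {"univariable": uni, "joint": joint,
                               "delta_bic": comparisons, "corr_controls": corr}
        results["outcomes"][mode] = mode_res
    return results


def test_combined_vs_separate(df: pd.DataFrame, density_cols, config: AnalysisConfig):
    """LRT of mode-specific coefficients against one pooled model.

    Separate fits per outcome contribute LL_interval + LL_screen with
    2 p parameters; the combined fit constrains the p coefficients to be
    equal across modes.  Returns the :class:`~operadens.clogit.LRTResult`.
    """
    from .clogit import LRTResult
    from scipy import stats as sps

    lls = {}
    p = len(density_cols)
    for mode in ("interval", "screen"):
        sub = df[df["mode"] == mode]
        if sub.empty:
            raise PipelineError(f"outcome {mode!r} has zero sets")
        # density coefficients only: the contrast of interest is whether the
        # density association differs by mode of detection
        fit = _fit(sub, list(density_cols), {})
        lls[mode] = fit.loglik
    combined = _fit(df, list(density_cols), {})
    ll_sep = lls["interval"] + lls["screen"]
    stat = max(0.0, 2.0 * (ll_sep - combined.loglik))
    return LRTResult(statistic=stat, df=p, pvalue=float(sps.chi2.sf(stat, p)))


def _opera_row(mode, scale, model, term, res):
    return {"mode": mode, "scale": scale, "model": model, "measure": term,
            "opera": res.opera, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "log_opera": res.log_opera, "se_log": res.se_log, "iqrr": res.iqrr,
            "auc": res.auc, "auc_ci_low": res.auc_ci[0] if res.auc_ci else None,
            "auc_ci_high": res.auc_ci[1] if res.auc_ci else None,
            "loglik": res.loglik}


def render_report(results: dict, out_dir) -> dict[str, Path]:
    """Write the results bundle as CSV tables, readable text and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, cmp_rows, lines = [], [], []
    config: AnalysisConfig = results["config"]
    for mode, mode_res in results["outcomes"].items():
        for scale, sres in mode_res.items():
            lines.append(f"== {mode} cancer, {scale} scale ==")
            for k, u in sres["univariable"].items():
                r = u["opera"]
                rows.append(_opera_row(mode, scale, "univariable", k, r))
                lines.append(
                    f"  {k:8s} OPERA {r.opera:5.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
                    f"  AUC {r.auc:.3f}  LL {r.loglik:8.2f}")
            for model, j in sres["joint"].items():
                for k, r in j["opera"].items():
                    rows.append(_opera_row(mode, scale, model, k, r))
                terms = "+".join(j["opera"])
                lines.append(f"  {model} ({terms}): LL {j['fit'].loglik:8.2f}")
            for pair, c in sres["delta_bic"].items():
                cmp_rows.append({"mode": mode, "scale": scale, "pair": pair,
                                 "delta_ll": c.delta_ll, "delta_bic": c.delta_bic,
                                 "posterior_odds": c.posterior_odds,
                                 "strength": c.verbal_strength})
                lines.append(f"  dBIC {pair}: {c.delta_bic:+.2f}"
                             f" (odds {c.posterior_odds:.3g}, {c.verbal_strength})")
    paths = {
        "opera_table": out / "opera_table.csv",
        "comparisons": out / "model_comparisons.csv",
        "summary": out / "summary.txt",
        "manifest": out / "manifest.json",
    }
    pd.DataFrame(rows).to_csv(paths["opera_table"], index=False, float_format="%.6g")
    pd.DataFrame(cmp_rows).to_csv(paths["comparisons"], index=False, float_format="%.6g")
    paths["summary"].write_text("\n".join(lines) + "\n")
    manifest = {
        "package": "operadens", "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "outcomes": list(config.outcomes), "scales": list(config.scales),
        "bic_convention": config.bic_convention,
        "input_csv": config.input_csv,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
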