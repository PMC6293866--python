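"""Synthetic nested case-control cohorts with matched sets.

Emulates the statistical structure of a two-outcome (interval vs
screen-detected breast cancer) nested case-control study: 168 interval
sets and 422 screen-detected sets, each one case with matched controls,
six correlated density measures (dense area and percent density at three
increasing brightness thresholds), age/BMI/parity covariates, and
repeat-measurement pairs for repeatability studies.

Case status is assigned by the *exact* conditional-logistic mechanism:
within each matched set of M+1 exchangeable candidates, the case is drawn
with probability exp(eta_j) / sum_k exp(eta_k), where eta is the linear
predictor on the standardized (latent) measure scale.  Data generated
this way follow the conditional-logistic model by construction, so a
correctly implemented fitter must recover the generating coefficients.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "MEASURES",
    "SimulationParams",
    "SubjectRecord",
    "MatchedSet",
    "default_corr_matrix",
    "generate_latent_traits",
    "backtransform_to_raw",
    "generate_matched_sets",
    "generate_cohort",
    "generate_repeat_measurements",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: column order of the six density measures everywhere in the package
MEASURES = ("cumulus_da", "cumulus_pct", "alto_da", "alto_pct",
            "cirro_da", "cirro_pct")

COHORT_COLUMNS = (
    "set_id", "subject_id", "case", "mode", "age", "bmi", "livebirths",
    "family_history",
    "cumulus_da", "cumulus_pct", "alto_da", "alto_pct", "cirro_da", "cirro_pct",
    # generating standardized (latent) measures, retained for validation
    "cumulus_da_latent", "cumulus_pct_latent", "alto_da_latent",
    "alto_pct_latent", "cirro_da_latent", "cirro_pct_latent",
)


class SimulationError(ValueError):
    pass


def default_corr_matrix() -> np.ndarray:
    """Default 6x6 latent correlation among the standardized measures.

    Within-measure dense-area/percent correlations 0.87 / 0.92 / 0.96
    (conventional / higher / highest threshold); between-measure same-scale
    correlations 0.86 and 0.88 for the adjacent threshold pair and 0.82
    elsewhere.  Cross-scale cross-measure entries (not separately
    identified) are set to the largest values keeping the matrix positive
    definite.
    """
    R = np.eye(6)

    def s(i, j, v):
        R[i, j] = R[j, i] = v

    s(0, 1, 0.87); s(2, 3, 0.92); s(4, 5, 0.96)      # da-pct within measure
    s(0, 2, 0.86); s(1, 3, 0.88)                      # cumulus-altocumulus
    s(0, 4, 0.82); s(1, 5, 0.82)                      # cumulus-cirrocumulus
    s(2, 4, 0.82); s(3, 5, 0.82)                      # altocumulus-cirrocumulus
    s(0, 3, 0.78); s(1, 2, 0.78)                      # cross-scale fills
    s(0, 5, 0.76); s(1, 4, 0.76)
    s(2, 5, 0.78); s(3, 4, 0.78)
    return R


def _default_betas():
    # per-adjusted-SD log-odds: interval risk carried by percent density at
    # the conventional threshold, screen-detected risk by dense area at the
    # highest threshold
    return {
        "interval": {"cumulus_pct": float(np.log(2.33))},
        "screen": {"cirro_da": 0.28},
    }


def _default_raw_params():
    # control-distribution targets: (raw mean, raw sd) on cm^2 / percent scales
    return {
        "cumulus_da": (19.0, 11.0),
        "alto_da": (9.0, 7.0),
        "cirro_da": (4.2, 4.6),
        "cumulus_pct": (15.0, 9.0),
        "alto_pct": (7.0, 6.0),
        "cirro_pct": (3.0, 3.0),
        "pct_cap": 95.0,
    }


@dataclasses.dataclass
class SimulationParams:
    """Generating parameters for the synthetic nested case-control cohort.

    Defaults reproduce the study-scale structure: set counts 168 / 422,
    1:3 matching, the default latent correlation matrix, age ~ N(56.2,
    6.8^2) (interval) / N(58.4, 7.6^2) (screen), BMI ~ N(26.5, 4.9^2)
    truncated at 15, livebirths ~ Poisson(2.7) truncated to 0-8.
    """

    n_sets_interval: int = 168
    n_sets_screen: int = 422
    controls_per_case: int = 3
    corr_matrix: np.ndarray = dataclasses.field(default_factory=default_corr_matrix)
    beta_by_outcome: dict = dataclasses.field(default_factory=_default_betas)
    bmi_age_interaction_screen: float = 0.004
    age_mean_interval: float = 56.2
    age_sd_interval: float = 6.8
    age_mean_screen: float = 58.4
    age_sd_screen: float = 7.6
    bmi_mean: float = 26.5
    bmi_sd: float = 4.9
    livebirth_rate: float = 2.7
    family_history_prev: float = 0.15
    boxcox_lambda_true: float = 0.3
    icc_true: float = 0.95
    seed: int = 0

    def __post_init__(self):
        R = np.asarray(self.corr_matrix, dtype=float)
        if R.shape != (6, 6) or not np.allclose(R, R.T):
            raise SimulationError("corr_matrix must be symmetric 6x6")
        if not np.allclose(np.diag(R), 1.0):
            raise SimulationError("corr_matrix must have unit diagonal")
        ev = np.linalg.eigvalsh(R)
        if ev[0] <= 0:
            raise SimulationError(
                f"corr_matrix is not positive definite (smallest eigenvalue {ev[0]:.3e})")
        if self.controls_per_case < 1:
            raise SimulationError("controls_per_case must be >= 1")
        if not 0.0 <= self.icc_true <= 1.0:
            raise SimulationError("icc_true must lie in [0, 1]")
        for mode, betas in self.beta_by_outcome.items():
            unknown = set(betas) - set(MEASURES)
            if unknown:
                raise SimulationError(f"unknown measures in beta_by_outcome[{mode!r}]: {unknown}")


@dataclasses.dataclass
class SubjectRecord:
    subject_id: int
    set_id: int
    case: bool
    mode: str
    age: float
    bmi: float
    livebirths: int
    family_history: bool
    raw: dict
    latent: dict


@dataclasses.dataclass
class MatchedSet:
    set_id: int
    mode: str
    members: list
    birth_year_stratum: int

    def __post_init__(self):
        if sum(m.case for m in self.members) != 1:
            raise SimulationError(f"set {self.set_id} must contain exactly one case")


def generate_latent_traits(n: int, corr_matrix, rng) -> np.ndarray:
    """Draw n x 6 standard-normal traits with the given correlation.

    ``rng`` may be a seed or a :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    R = np.asarray(corr_matrix, dtype=float)
    ev = np.linalg.eigvalsh(R)
    if ev[0] <= 0:
        raise SimulationError(
            f"correlation matrix not positive definite (smallest eigenvalue {ev[0]:.3e})")
    L = np.linalg.cholesky(R)
    return rng.standard_normal((n, R.shape[0])) @ L.T


def backtransform_to_raw(z, lam: float, raw_mean: float, raw_sd: float,
                         floor: float = 1e-6):
    """Map standard-normal z to a positive raw-scale density value.

    The affine map is applied on the Box-Cox-transformed scale with
    location boxcox(raw_mean, lam) and a delta-method slope
    raw_sd * raw_mean**(lam - 1), then inverted: the forward Box-Cox of
    the output recovers an affine function of z exactly.  For lam = 0 the
    inverse is the exponential.  Inverse bases that would be non-positive
    are clamped at ``floor`` (counted and logged).
    """
    z = np.asarray(z, dtype=float)
    if raw_mean <= 0 or raw_sd <= 0:
        raise SimulationError("raw_mean and raw_sd must be positive")
    t_mean = special.boxcox(raw_mean, lam)
    t_sd = raw_sd * raw_mean ** (lam - 1.0)
    t = t_mean + t_sd * z
    if lam == 0.0:
        return np.exp(t)
    base = lam * t + 1.0
    n_clamped = int(np.sum(base <= floor))
    if n_clamped:
        logger.info("backtransform_to_raw: clamped %d non-positive bases at %g",
                    n_clamped, floor)
        base = np.maximum(base, floor)
    return base ** (1.0 / lam)


def _truncated_normal(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _make_subjects(n: int, params: SimulationParams, rng) -> pd.DataFrame:
    """Raw + latent measures and covariates for n candidate subjects.

    Each raw measure is its own latent pushed through the inverse Box-Cox
    map calibrated to the control-distribution targets, so the observed
    (transformed) measures inherit the latent correlation matrix.
    Nesting of the superlevel areas is then enforced by ordered clipping:
    Altocumulus <= Cumulus and Cirrocumulus <= Altocumulus on both
    scales.  Clipping binds rarely (the area gaps are wide relative to
    the spreads) and leaves the correlation calibration intact.
    """
    z = generate_latent_traits(n, params.corr_matrix, rng)
    raw = _default_raw_params()
    lam = params.boxcox_lambda_true
    vals = {m: backtransform_to_raw(z[:, j], lam, *raw[m])
            for j, m in enumerate(MEASURES)}
    vals["cumulus_pct"] = np.minimum(vals["cumulus_pct"], raw["pct_cap"])
    vals["alto_da"] = np.minimum(vals["alto_da"], vals["cumulus_da"])
    vals["cirro_da"] = np.minimum(vals["cirro_da"], vals["alto_da"])
    vals["alto_pct"] = np.minimum(vals["alto_pct"], vals["cumulus_pct"])
    vals["cirro_pct"] = np.minimum(vals["cirro_pct"], vals["alto_pct"])
    out = pd.DataFrame(index=np.arange(n))
    for m in MEASURES:
        out[m] = vals[m]
    for j, m in enumerate(MEASURES):
        out[m + "_latent"] = z[:, j]
    out["bmi"] = _truncated_normal(rng, params.bmi_mean, params.bmi_sd, 15.0, n)
    births = rng.poisson(params.livebirth_rate, size=n)
    out["livebirths"] = np.clip(births, 0, 8)
    out["family_history"] = rng.random(n) < params.family_history_prev
    return out


def generate_matched_sets(params: SimulationParams,
                          rng=None) -> dict[str, list[MatchedSet]]:
    """Generate matched sets per outcome mode under the exact
    conditional-logistic mechanism.

    For each set, M+1 candidate subjects sharing a birth-year stratum are
    drawn; the case is the member j selected with probability
    exp(eta_j) / sum_k exp(eta_k), eta = sum_m beta_m z_m (plus the
    centered BMI x age product for the screen-detected mode).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    modes = {"interval": params.n_sets_interval, "screen": params.n_sets_screen}
    out: dict[str, list[MatchedSet]] = {}
    subj_counter = 0
    set_counter = 0
    for mode, n_sets in modes.items():
        if n_sets == 0:
            out[mode] = []
            continue
        M = params.controls_per_case
        size = M + 1
        n = n_sets * size
        if mode == "interval":
            age_mu, age_sd = params.age_mean_interval, params.age_sd_interval
        else:
            age_mu, age_sd = params.age_mean_screen, params.age_sd_screen
        # matching: one birth-year stratum (hence base age) per set
        base_age = _truncated_normal(rng, age_mu, age_sd, 40.0, n_sets)
        df = _make_subjects(n, params, rng)
        set_idx = np.repeat(np.arange(n_sets), size)
        df["age"] = base_age[set_idx] + rng.uniform(-1.0, 1.0, size=n)

        betas = params.beta_by_outcome.get(mode, {})
        eta = np.zeros(n)
        for m, b in betas.items():
            eta += b * df[m + "_latent"].to_numpy()
        if mode == "screen" and params.bmi_age_interaction_screen:
            eta += params.bmi_age_interaction_screen * \
                (df["bmi"].to_numpy() - params.bmi_mean) * (df["age"].to_numpy() - age_mu)

        # within-set softmax case draw (Gumbel-max trick, vectorized)
        g = rng.gumbel(size=n)
        keys = (eta + g).reshape(n_sets, size)
        case_pos = np.argmax(keys, axis=1)
        case = np.zeros(n, dtype=bool)
        case[np.arange(n_sets) * size + case_pos] = True

        sets = []
        for s in range(n_sets):
            members = []
            for k in range(size):
                i = s * size + k
                row = df.iloc[i]
                members.append(SubjectRecord(
                    subject_id=subj_counter, set_id=set_counter,
                    case=bool(case[i]), mode=mode,
                    age=float(row["age"]), bmi=float(row["bmi"]),
                    livebirths=int(row["livebirths"]),
                    family_history=bool(row["family_history"]),
                    raw={m: float(row[m]) for m in MEASURES},
                    latent={m: float(row[m + "_latent"]) for m in MEASURES}))
                subj_counter += 1
            sets.append(MatchedSet(set_id=set_counter, mode=mode, members=members,
                                   birth_year_stratum=int(round(2000 - base_age[s]))))
            set_counter += 1
        out[mode] = sets
    return out


def sets_to_frame(sets_by_mode: dict[str, list[MatchedSet]]) -> pd.DataFrame:
    rows = []
    for mode in sets_by_mode:
        for st in sets_by_mode[mode]:
            for m in st.members:
                row = {
                    "set_id": m.set_id, "subject_id": m.subject_id,
                    "case": int(m.case), "mode": m.mode, "age": m.age,
                    "bmi": m.bmi, "livebirths": m.livebirths,
                    "family_history": int(m.family_history),
                }
                row.update(m.raw)
                row.update({k + "_latent": v for k, v in m.latent.items()})
                rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def generate_cohort(params: SimulationParams, rng=None) -> pd.DataFrame:
    """Convenience: matched sets flattened to one subject-level DataFrame."""
    return sets_to_frame(generate_matched_sets(params, rng=rng))


def generate_repeat_measurements(n_pairs: int, icc_true: float, rng) -> np.ndarray:
    """Pairs y = t + e sharing t, with Var(t)/(Var(t)+Var(e)) = icc_true.

    Total variance 1; returns an (n_pairs, 2) array.
    """
    if not 0.0 <= icc_true <= 1.0:
        raise SimulationError("icc_true must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t = rng.normal(0.0, np.sqrt(icc_true), size=(n_pairs, 1))
    e = rng.normal(0.0, np.sqrt(1.0 - icc_true), size=(n_pairs, 2))
    return t + e


def write_cohort(records, path) -> None:
    """Write a cohort (DataFrame or sets-by-mode dict) to CSV, fixed column order."""
    df = records if isinstance(records, pd.DataFrame) else sets_to_frame(records)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SimulationError(f"cohort is missing columns: {missing}")
    df.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False, float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating schema and numeric fields.

    Malformed numeric entries are reported with their (1-based, header
    included) line numbers.
    """
    df = pd.read_csv(path, dtype={"mode": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SimulationError(f"{path}: missing columns {missing}")
    numeric = [c for c in COHORT_COLUMNS if c != "mode"]
    bad_lines = []
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        bad_lines.extend((int(i) + 2, c) for i in bad)
        df[c] = coerced
    if bad_lines:
        desc = ", ".join(f"line {ln} ({col})" for ln, col in bad_lines[:10])
        raise SimulationError(f"{path}: malformed numeric values at {desc}")
    if df[numeric].isna().any().any():
        na_rows = df.index[df[numeric].isna().any(axis=1)]
        raise SimulationError(
            f"{path}: missing values at lines {[int(i) + 2 for i in na_rows[:10]]}")
    df["case"] = df["case"].astype(int)
    return df
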