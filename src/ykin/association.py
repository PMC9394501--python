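"""Per-haplogroup association models and multiplicity correction.

Each haplogroup Z (a binary carrier indicator) is tested in its own model

    Y = beta X + gamma Z + e            (linear: blood pressure, lipids)
    logit P(Y=1) = beta X + gamma Z     (logistic: CAD, hypertension)
    h(x) = h0(x) exp(beta X + gamma Z)  (Cox, age timescale: mortality)

under a configurable covariate set. The estimate of interest is gamma, the
haplogroup coefficient, with Wald standard errors and P values across all
three families.

Because haplogroups are nested clades, carrier indicators are strongly
correlated and a raw Bonferroni correction over-penalises. The effective
number of independent tests is the number of principal components of the
indicator correlation matrix needed to explain a set fraction (default
95%) of the total variance; raw P values are multiplied by that count (and,
when several correlated phenotypes are tested, by the effective phenotype
count), capped at 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ytree import HaplogroupMatrix

logger = logging.getLogger(__name__)

COVARIATE_SETS = ("robust", "eales", "minimal")

# categorical covariates of the historical risk-factor-adjusted model
_EALES_CATEGORICAL = ("exercise", "income", "smoking", "education", "employment", "alcohol")

__all__ = [
    "ModelSpec",
    "AssocResult",
    "build_design_matrix",
    "fit_haplogroup_model",
    "fit_battery",
    "effective_tests",
    "adjust_pvalues",
    "significance_threshold",
    "round_sigfigs",
]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome column, model family, covariate set, haplogroup."""

    outcome: str
    family: str  # linear | logistic | cox
    covariate_set: str = "robust"
    haplogroup: str | None = None
    parent: str | None = None  # None (subject), "father", "mother", "brother"

    def __post_init__(self):
        if self.family not in ("linear", "logistic", "cox"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate set {self.covariate_set!r}")


@dataclass
class AssocResult:
    """Fitted haplogroup effect on the outcome's natural scale
    (mm Hg / log-odds / log-hazard)."""

    haplogroup: str
    outcome: str
    family: str
    gamma: float
    se: float
    p_raw: float
    n: int
    n_cases: int | None = None
    p_adj: float | None = None
    converged: bool = True

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.gamma - 1.96 * self.se, self.gamma + 1.96 * self.se)

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "haplogroup": self.haplogroup, "outcome": self.outcome,
            "family": self.family, "gamma": self.gamma, "se": self.se,
            "ci_low": lo, "ci_high": hi, "p_raw": self.p_raw,
            "p_adj": self.p_adj, "n": self.n, "n_cases": self.n_cases,
            "converged": self.converged,
        }


def _dummies(col: pd.Series, name: str) -> pd.DataFrame:
    d = pd.get_dummies(col.astype("category"), prefix=name, drop_first=True, dtype=float)
    return d


def build_design_matrix(
    cohort: pd.DataFrame,
    covariate_set: str,
    family: str,
    parent: str | None = None,
) -> pd.DataFrame:
    """Covariate matrix (no intercept) for one model family.

    robust  — (parent) age, age^2, north/east coordinates at assessment and
              birth, area deprivation at assessment and birth, every genetic
              PC column present, genotyping batch. Age terms are dropped for
              Cox models, which already run on the age timescale.
    eales   — age, BMI, first 5 PCs, batch, hypertension, and the
              categorical lifestyle covariates plus parental CAD flags
              (the historical risk-factor-adjusted model; heritable
              covariates included by design).
    minimal — (parent) age, every PC, batch (sensitivity set).
    """
    age_col = f"{parent}_age" if parent else "age"
    pc_cols = sorted(
        (c for c in cohort.columns if c.startswith("pc_")),
        key=lambda c: int(c.split("_")[1]),
    )
    parts: list[pd.DataFrame | pd.Series] = []
    if covariate_set == "robust":
        if family != "cox":
            age = cohort[age_col].astype(float)
            parts += [age.rename("age"), (age**2).rename("age_sq")]
        parts += [cohort[c].astype(float) for c in (
            "north_assess", "east_assess", "north_birth", "east_birth",
            "deprivation_assess", "deprivation_birth")]
        parts += [cohort[c].astype(float) for c in pc_cols]
        parts.append(_dummies(cohort["batch"], "batch"))
    elif covariate_set == "eales":
        parts += [cohort["age"].astype(float), cohort["bmi"].astype(float)]
        parts += [cohort[c].astype(float) for c in pc_cols[:5]]
        parts.append(_dummies(cohort["batch"], "batch"))
        parts.append(cohort["hypertension"].astype(float).rename("hypertension"))
        for c in _EALES_CATEGORICAL:
            parts.append(_dummies(cohort[c], c))
        parts.append(cohort["father_cad"].astype(float).rename("father_cad"))
        parts.append(cohort["mother_cad"].astype(float).rename("mother_cad"))
    elif covariate_set == "minimal":
        if family != "cox":
            parts.append(cohort[age_col].astype(float).rename("age"))
        parts += [cohort[c].astype(float) for c in pc_cols]
        parts.append(_dummies(cohort["batch"], "batch"))
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(covariate_set)
    return pd.concat(parts, axis=1)


def _outcome_series(cohort: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    col = f"{spec.parent}_{spec.outcome}" if spec.parent else spec.outcome
    y = cohort[col]
    if y.dtype == object:  # case/control strings
        y = y.map({"case": 1.0, "control": 0.0})
    if str(y.dtype) in ("boolean", "bool", "Float64", "Int64"):
        return pd.Series(y.to_numpy(dtype=float, na_value=np.nan), index=y.index)
    return pd.to_numeric(y, errors="coerce")


def fit_haplogroup_model(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    indicators: HaplogroupMatrix | pd.DataFrame,
    extra_covariates: Sequence[str] = (),
) -> AssocResult:
    """Fit one haplogroup's model and return its gamma estimate.

    Rows are complete cases over outcome + covariates (+ survival fields for
    Cox). ``extra_covariates`` appends named numeric cohort columns to the
    covariate set (e.g. a father-disease covariate, to study the "excess
    effect" interpretation such an adjustment produces on the Y). The
    optimiser is delegated to statsmodels (OLS/Logit) or lifelines (Cox);
    non-convergence, separation or a constant indicator yields a flagged
    result with missing effect rather than an exception, so a model battery
    can proceed.
    """
    ind = indicators.indicators if isinstance(indicators, HaplogroupMatrix) else indicators
    if spec.haplogroup is None:
        raise ValueError("ModelSpec.haplogroup is required")
    z = ind[spec.haplogroup].astype(float)
    X = build_design_matrix(cohort, spec.covariate_set, spec.family, spec.parent)
    for col in extra_covariates:
        X[col] = _outcome_series(cohort, ModelSpec(col, spec.family)) \
            if cohort[col].dtype == object or str(cohort[col].dtype) == "boolean" \
            else cohort[col].astype(float)

    if spec.family == "cox":
        if spec.parent:
            entry = pd.Series(
                np.full(len(cohort), 40.0), index=cohort.index, name="entry_age"
            )  # delayed entry at 40 matches the <40 death exclusion
            dur = pd.to_numeric(cohort[f"{spec.parent}_event_age"], errors="coerce")
            event = cohort[f"{spec.parent}_dead"].astype("boolean")
        else:
            entry = cohort["entry_age"].astype(float)
            dur = cohort["event_age"].astype(float)
            event = cohort["dead"].astype("boolean")
        df = pd.concat(
            [X, z.rename("haplogroup"), entry.rename("entry_age"),
             dur.rename("event_age"), event.rename("dead").astype(float)],
            axis=1,
        ).dropna()
        df = df[df["event_age"] > df["entry_age"]]
        n, n_cases = len(df), int(df["dead"].sum())
        return _fit_cox(spec, df, n, n_cases)

    y = _outcome_series(cohort, spec)
    df = pd.concat([y.rename("_y"), z.rename("haplogroup"), X], axis=1).dropna()
    n = len(df)
    carriers = df["haplogroup"].sum()
    if carriers == 0 or carriers == n:
        logger.warning("%s ~ %s: constant indicator; flagged", spec.outcome, spec.haplogroup)
        return AssocResult(spec.haplogroup, spec.outcome, spec.family,
                           np.nan, np.nan, np.nan, n, None, converged=False)
    Xf = sm.add_constant(
        pd.concat([df[["haplogroup"]], df.drop(columns=["_y", "haplogroup"])], axis=1)
    ).astype(float)
    yv = df["_y"].to_numpy(dtype=float)
    try:
        if spec.family == "linear":
            res = sm.OLS(yv, Xf).fit()
            converged = True
            n_cases = None
        else:
            n_cases = int(yv.sum())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yv, Xf).fit(disp=0, method="newton", maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # separation, singular design
        logger.warning("%s ~ %s: fit failed (%s); flagged", spec.outcome, spec.haplogroup, exc)
        return AssocResult(spec.haplogroup, spec.outcome, spec.family,
                           np.nan, np.nan, np.nan, n,
                           n_cases if spec.family == "logistic" else None, converged=False)
    gamma = float(res.params["haplogroup"])
    se = float(res.bse["haplogroup"])
    if not np.isfinite(se) or se > 1e3:
        converged = False
    p = float(2 * stats.norm.sf(abs(gamma / se))) if converged and se > 0 else np.nan
    return AssocResult(spec.haplogroup, spec.outcome, spec.family, gamma, se, p,
                       n, n_cases, converged=converged)


def _fit_cox(spec: ModelSpec, df: pd.DataFrame, n: int, n_cases: int) -> AssocResult:
    from lifelines import CoxPHFitter

    if df["haplogroup"].nunique() < 2 or n_cases == 0:
        return AssocResult(spec.haplogroup, spec.outcome, "cox",
                           np.nan, np.nan, np.nan, n, n_cases, converged=False)
    try:
        cph = CoxPHFitter(penalizer=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="event_age", event_col="dead", entry_col="entry_age")
        gamma = float(cph.params_["haplogroup"])
        se = float(cph.standard_errors_["haplogroup"])
        p = float(2 * stats.norm.sf(abs(gamma / se)))
        return AssocResult(spec.haplogroup, spec.outcome, "cox", gamma, se, p, n, n_cases)
    except Exception as exc:
        logger.warning("cox %s ~ %s failed (%s); flagged", spec.outcome, spec.haplogroup, exc)
        return AssocResult(spec.haplogroup, spec.outcome, "cox",
                           np.nan, np.nan, np.nan, n, n_cases, converged=False)


def fit_battery(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    indicators: HaplogroupMatrix,
    n_eff_phenotypes: int = 1,
    variance_fraction: float = 0.95,
) -> list[AssocResult]:
    """One model per haplogroup column, with adjusted P values.

    The effective test count is computed from the indicator correlation on
    the complete-case analysis sample of this outcome (so it can differ per
    outcome family). Non-converged fits keep a missing effect and are left
    out of the multiplicity accounting.
    """
    results = [
        fit_haplogroup_model(
            ModelSpec(spec.outcome, spec.family, spec.covariate_set, g, spec.parent),
            cohort, indicators)
        for g in indicators.groups
    ]
    ok = [r for r in results if r.converged]
    if len(ok) >= 2:
        y = _outcome_series(cohort, spec) if spec.family != "cox" else None
        sub = indicators.indicators[[r.haplogroup for r in ok]]
        if y is not None:
            sub = sub[y.notna().to_numpy()]
        try:
            n_eff = effective_tests(sub, variance_fraction)
        except ValueError:
            n_eff = len(ok)
        p_adj = adjust_pvalues(np.array([r.p_raw for r in ok]), n_eff, n_eff_phenotypes)
        for r, pa in zip(ok, p_adj):
            r.p_adj = float(pa)
    return results


# ---------------------------------------------------------------------------
# Multiplicity


def effective_tests(
    indicators: HaplogroupMatrix | pd.DataFrame | np.ndarray,
    variance_fraction: float = 0.95,
) -> int:
    """Effective number of independent tests among correlated indicators.

    Eigendecomposes the Pearson correlation matrix of the indicator columns
    and returns the smallest m such that the top-m eigenvalues sum to at
    least ``variance_fraction`` of the trace (= number of columns).
    Zero-variance columns are dropped with a warning.
    """
    if isinstance(indicators, HaplogroupMatrix):
        X = indicators.indicators.to_numpy(dtype=float)
    else:
        X = np.asarray(indicators, dtype=float)
        if X.ndim != 2:
            raise ValueError("indicator matrix must be 2-D")
    sd = X.std(axis=0)
    if (sd == 0).any():
        warnings.warn(f"effective_tests: dropping {int((sd == 0).sum())} zero-variance columns")
        X = X[:, sd > 0]
    k = X.shape[1]
    if k < 2:
        raise ValueError("effective_tests needs at least 2 usable columns")
    corr = np.corrcoef(X, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    cum = np.cumsum(eig) / k
    return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)


def adjust_pvalues(p_raw, n_eff_groups: int, n_eff_phenotypes: int = 1) -> np.ndarray:
    """Bonferroni-style adjustment with effective counts:
    p_adj = min(1, p_raw * n_eff_groups * n_eff_phenotypes)."""
    if n_eff_groups < 1 or n_eff_phenotypes < 1:
        raise ValueError("effective counts must be >= 1")
    p = np.asarray(p_raw, dtype=float)
    finite = p[np.isfinite(p)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return np.minimum(1.0, p * n_eff_groups * n_eff_phenotypes)


def significance_threshold(
    alpha: float = 0.05, n_eff_groups: int = 1, n_eff_phenotypes: int = 1
) -> float:
    """Bonferroni threshold alpha / (n_eff_groups * n_eff_phenotypes)."""
    if n_eff_groups < 1 or n_eff_phenotypes < 1:
        raise ValueError("effective counts must be >= 1")
    return alpha / (n_eff_groups * n_eff_phenotypes)


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (summary-report convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))
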