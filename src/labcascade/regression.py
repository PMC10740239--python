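"""Modified Poisson regression for the three cascade outcomes.

Risk ratios for binary outcomes are estimated with a log-link Poisson
mean model and a robust (sandwich) variance estimator — the standard
"modified Poisson" approach, which avoids the non-convergence issues of
log-binomial models while still targeting the risk ratio. Variance is
cluster-robust at the health-facility level, with facility labels made
unique within district so the facility-in-district nesting is
respected; without clusters the heteroscedasticity-robust (HC0)
sandwich is used, which in the two-group case reproduces the closed
form se(log RR) = sqrt((1-p1)/(n1 p1) + (1-p0)/(n0 p0)).

The three models are nested: diagnosis is modelled on everyone tested,
retention on those diagnosed, and glycaemic control on those retained.
The diagnosis and control models additionally adjust for the type of
diagnostic used; the retention model does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

OUTCOME_COLUMNS = {"diagnosed": "diagnosed", "retained_dm": "retained_dm",
                   "controlled": "controlled"}

REFERENCE_LEVELS = {
    "sex": "M",
    "age_band4": "30-39",
    "hiv_status": "PLWOH",
    "tb_status": "TB-",
    "facility_type": "hospital",
    "year_of_first_lab": "2012",
    "diagnostic_used": "HbA1c",
}

BASE_COVARIATES = ("sex", "age_band4", "hiv_status", "tb_status",
                   "facility_type", "year_of_first_lab")


def default_covariates(outcome: str, include_province: bool = True):
    cov = list(BASE_COVARIATES)
    # diagnostic type enters the diagnosis and control models only
    if outcome in ("diagnosed", "controlled"):
        cov.append("diagnostic_used")
    if include_province:
        cov.append("province")
    return tuple(cov)


@dataclass
class ModelSpec:
    """One of the three outcome models.

    ``mode='adjusted'`` fits all covariates jointly; ``mode='crude'``
    fits one covariate at a time and pools the per-covariate estimates
    into a single table.
    """

    outcome: str = "diagnosed"
    mode: str = "adjusted"
    covariates: tuple = ()
    include_province: bool = True
    cluster: bool = True

    def __post_init__(self):
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.mode not in ("crude", "adjusted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.covariates:
            self.covariates = default_covariates(self.outcome, self.include_province)
        if self.outcome == "retained_dm" and "diagnostic_used" in self.covariates:
            raise ValueError("diagnostic_used is not a retention-model covariate")


@dataclass
class RiskRatioFit:
    """Exponentiated coefficients with robust-variance 95% CIs.

    ``table`` has one row per covariate level: columns ``covariate``,
    ``level``, ``ref`` (reference-level marker), ``rr``, ``lo``, ``hi``,
    ``robust_se`` (on the log scale) and ``separation`` (the level had
    all-0 or all-1 outcomes).
    """

    table: pd.DataFrame
    outcome: str
    mode: str
    n: int
    converged: bool
    warnings: list = field(default_factory=list)


def analysis_subset(rows: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """The nested analysis population for each outcome model."""
    if outcome == "diagnosed":
        sub = rows
    elif outcome == "retained_dm":
        sub = rows[rows["diagnosed"]]
    elif outcome == "controlled":
        sub = rows[rows["retained_dm"]]
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    if len(sub) == 0:
        raise ValueError(f"analysis subset for outcome {outcome!r} is empty")
    return sub.copy()


def _levels(series: pd.Series, covariate: str):
    vals = sorted(series.astype(str).unique())
    ref = REFERENCE_LEVELS.get(covariate)
    if ref is None or ref not in vals:
        ref = vals[0]
    return ref, [v for v in vals if v != ref]


def _design(sub: pd.DataFrame, covariates) -> tuple[pd.DataFrame, list]:
    """Intercept + treatment-coded dummies; returns (X, level map)."""
    X = pd.DataFrame({"const": np.ones(len(sub))}, index=sub.index)
    info = []
    for cov in covariates:
        s = sub[cov].astype(str)
        ref, others = _levels(s, cov)
        info.append((cov, ref, others))
        for lv in others:
            X[f"{cov}[{lv}]"] = (s == lv).astype(float)
    return X, info


def _cluster_groups(sub: pd.DataFrame) -> pd.Series:
    # facility ids made unique within district -> respects nesting
    return sub["district"].astype(str) + "/" + sub["facility_id"].astype(str)


def _fit_glm(y, X, groups):
    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if groups is not None and groups.nunique() > 1:
            res = model.fit(maxiter=100, tol=1e-8, cov_type="cluster",
                            cov_kwds={"groups": groups})
        else:
            res = model.fit(maxiter=100, tol=1e-8, cov_type="HC0")
    return res


def fit_modified_poisson(rows: pd.DataFrame, spec: ModelSpec) -> RiskRatioFit:
    """Fit one outcome model and return exponentiated coefficients.

    ``rows`` is the full cascade-row table; the nested analysis subset
    is taken internally. Separated levels (all-0 or all-1 outcome) are
    flagged in the output rather than dropped.
    """
    sub = analysis_subset(rows, spec.outcome)
    if "diagnostic_used" in spec.covariates and spec.outcome == "diagnosed":
        # For the diagnosis model the diagnostic type must be defined for
        # the whole tested population, so it is the type of the first
        # test; diagnostic_used proper exists only after a diagnosis.
        sub["diagnostic_used"] = sub["first_test_type"]
    y = sub[OUTCOME_COLUMNS[spec.outcome]].astype(int)
    groups = _cluster_groups(sub) if spec.cluster else None

    notes = []
    covsets = [spec.covariates] if spec.mode == "adjusted" else \
        [(c,) for c in spec.covariates]

    records = []
    converged = True
    for covset in covsets:
        X, info = _design(sub, covset)
        try:
            res = _fit_glm(y, X, groups)
        except Exception as exc:  # singular design, perfect separation...
            notes.append(f"fit failed for covariates {covset}: {exc}")
            converged = False
            continue
        if not getattr(res, "converged", True):
            converged = False
            notes.append(f"IRLS did not converge for covariates {covset}")
        params, bse = res.params, res.bse
        for cov, ref, others in info:
            s = sub[cov].astype(str)
            records.append({"covariate": cov, "level": ref, "ref": True,
                            "rr": 1.0, "lo": np.nan, "hi": np.nan,
                            "robust_se": np.nan, "separation": False})
            for lv in others:
                name = f"{cov}[{lv}]"
                beta, se = params[name], bse[name]
                mean_lv = y[s == lv].mean()
                sep = mean_lv in (0.0, 1.0)
                if sep:
                    notes.append(f"separation: {cov}={lv} has outcome mean {mean_lv:.0f}")
                records.append({
                    "covariate": cov, "level": lv, "ref": False,
                    "rr": float(np.exp(beta)),
                    "lo": float(np.exp(beta - 1.959963984540054 * se)),
                    "hi": float(np.exp(beta + 1.959963984540054 * se)),
                    "robust_se": float(se), "separation": sep,
                })
    table = pd.DataFrame(records)
    return RiskRatioFit(table=table, outcome=spec.outcome, mode=spec.mode,
                        n=len(sub), converged=converged, warnings=notes)


def fit_all_models(rows: pd.DataFrame, include_province: bool = True,
                   cluster: bool = True) -> dict:
    """Crude and adjusted fits for all three outcomes, keyed
    (outcome, mode). Outcomes whose subset is empty are skipped."""
    fits = {}
    for outcome in OUTCOME_COLUMNS:
        for mode in ("crude", "adjusted"):
            spec = ModelSpec(outcome=outcome, mode=mode,
                             include_province=include_province, cluster=cluster)
            try:
                fits[(outcome, mode)] = fit_modified_poisson(rows, spec)
            except ValueError:
                continue
    return fits


def _fmt(row) -> str:
    if row["ref"]:
        return "ref"
    if not np.isfinite(row["rr"]):
        return "-"
    return f"{row['rr']:.2f} ({row['lo']:.2f}, {row['hi']:.2f})"


def report_table(fits: dict) -> pd.DataFrame:
    """Render fits as one table: covariate levels as rows, one
    ``crude``/``adjusted`` column per outcome, reference rows as 'ref'.
    Missing fits leave a '(not fitted)' column."""
    outcomes = ("diagnosed", "retained_dm", "controlled")
    frames = {}
    index = None
    for outcome in outcomes:
        for mode in ("crude", "adjusted"):
            fit = fits.get((outcome, mode))
            col = f"{outcome}:{mode}"
            if fit is None or fit.table.empty:
                frames[col] = None
                continue
            t = fit.table.copy()
            t["label"] = t["covariate"] + "=" + t["level"]
            t = t.drop_duplicates("label").set_index("label")
            frames[col] = t.apply(_fmt, axis=1)
            if index is None:
                index = t.index
    out = pd.DataFrame(index=index if index is not None else [])
    for col, series in frames.items():
        out[col] = series.reindex(out.index) if series is not None else "(not fitted)"
    out.index.name = "covariate_level"
    return out.reset_index()
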