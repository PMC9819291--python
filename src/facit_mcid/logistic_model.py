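"""Binary logistic regression for the fatigue-change predictor models.

Maximum-likelihood fits via iteratively reweighted least squares with
step-halving (so the log-likelihood never decreases), Wald standard
errors from the observed information, odds ratios with 95% confidence
intervals ``exp(coef +/- 1.96 * SE)``, and detection of complete
separation (divergent coefficients are flagged, never silently
returned).

Also implements the collinearity-driven predictor exclusion applied
before every model: among any pair with |Spearman rho| above a threshold
(default 0.7) the lower-priority member is dropped -- by default CHFS is
kept over HAQ-DI, mirroring how the published models removed HAQ-DI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .rank_stats import spearman_rho

__all__ = [
    "LogisticFit",
    "SeparationWarning",
    "drop_collinear",
    "fit_logistic",
    "run_predictor_analyses",
    "change_columns",
    "to_table_frame",
]

_Z95 = 1.959963984540054


@dataclass
class LogisticFit:
    """One fitted model: per-predictor coefficients, ORs, Wald CIs, p."""

    outcome: str
    predictor_set: str
    table: pd.DataFrame            # coef, se, odds_ratio, ci_low, ci_high, p_value
    converged: bool
    separation: bool
    n: int
    n_events: int
    loglik_path: tuple[float, ...]
    n_dropped_missing: int = 0

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1]


def drop_collinear(predictors: pd.DataFrame, threshold: float = 0.7,
                   priority: tuple[str, ...] = ("chfs", "haq_di"),
                   ) -> tuple[list[str], list[dict]]:
    """Greedy collinearity filter on |Spearman rho|.

    Predictors are visited in priority order (names in ``priority`` first,
    then remaining columns in frame order); each is kept only if its
    absolute Spearman correlation with every already-kept predictor stays
    below ``threshold``.  Returns the surviving names and a report of
    drops (dropped, kept-because-of, rho).  With several mutually
    collinear predictors exactly the highest-priority one survives.
    """
    cols = list(predictors.columns)
    if len(cols) < 2:
        return cols, []
    ordered = [c for c in priority if c in cols]
    ordered += [c for c in cols if c not in ordered]
    kept: list[str] = []
    report: list[dict] = []
    for cand in ordered:
        x = predictors[cand].to_numpy(dtype=float)
        conflict = None
        for other in kept:
            yv = predictors[other].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(yv))
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(yv[ok]) == 0:
                continue
            rho = spearman_rho(x[ok], yv[ok], p_mode="approx").statistic
            if abs(rho) >= threshold:
                conflict = (other, rho)
                break
        if conflict is None:
            kept.append(cand)
        else:
            report.append({"dropped": cand, "kept": conflict[0],
                           "rho": conflict[1]})
    kept = [c for c in cols if c in kept]      # restore input column order
    return kept, report


class SeparationWarning(UserWarning):
    pass


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(design: pd.DataFrame, outcome, add_intercept: bool = True,
                 max_iter: int = 25, tol: float = 1e-8,
                 outcome_name: str = "outcome",
                 predictor_set: str = "") -> LogisticFit:
    """Maximum-likelihood logistic fit via IRLS.

    Convergence when the largest score component falls below ``tol`` or
    after ``max_iter`` iterations.  Rows with any missing cell are
    removed (count reported).  Raises on a single-class outcome; complete
    separation is detected from divergent coefficients and flagged on the
    result rather than raised.
    """
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) \
        else np.asarray(design, dtype=float)
    names = (list(design.columns) if isinstance(design, pd.DataFrame)
             else [f"x{i}" for i in range(X.shape[1])])
    y = np.asarray(outcome, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome must have the same length")
    ok = ~(np.isnan(X).any(axis=1) | np.isnan(y))
    n_dropped = int((~ok).sum())
    X, y = X[ok], y[ok]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome_name!r} has a single class")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["const", *names]
    k = X.shape[1]
    beta = np.zeros(k)
    ll_path = [_loglik(y, X @ beta)]
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(info + 1e-8 * np.eye(k), score)
        # step-halving keeps the log-likelihood nondecreasing
        ll_old = ll_path[-1]
        factor = 1.0
        for _half in range(40):
            cand = beta + factor * step
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll_old - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        ll_path.append(_loglik(y, X @ beta))
    else:
        ll_path.append(_loglik(y, X @ beta))
    # complete/quasi separation drives coefficients off to infinity; the
    # score can still vanish once probabilities saturate, so divergence is
    # judged from the coefficient scale (natural-unit predictors)
    scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
    separation = bool(np.max(np.abs(beta) * scale) > 15.0)
    mu = expit(X @ beta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        table = pd.DataFrame({
            "coef": beta,
            "se": se,
            "odds_ratio": np.exp(beta),
            "ci_low": np.exp(beta - _Z95 * se),
            "ci_high": np.exp(beta + _Z95 * se),
            "p_value": pvals,
        }, index=pd.Index(names, name="predictor"))
    return LogisticFit(outcome_name, predictor_set, table, converged,
                       separation, n=len(y), n_events=int(y.sum()),
                       loglik_path=tuple(ll_path),
                       n_dropped_missing=n_dropped)


def change_columns(cohort: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Raw one-year changes (follow-up minus baseline, natural units)."""
    out = {}
    for var in variables:
        out[f"d_{var}"] = cohort[f"{var}_fu"] - cohort[f"{var}_base"]
    return pd.DataFrame(out, index=cohort.index)


#: Candidate predictor pools for the two predictor analyses.
BASELINE_PREDICTORS = ("reustar_ai", "chfs", "duration_years", "haq_di",
                       "mrss", "ild")
CHANGE_PREDICTORS = ("facit_ewb", "sf36_pcs", "haq_di", "chfs", "hgb",
                     "albumin", "ucla_git", "pinch_n", "reustar_ai")


def _baseline_design(cohort: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    cols = {}
    for var in variables:
        if var in cohort.columns:
            cols[var] = cohort[var]
        elif f"{var}_base" in cohort.columns:
            cols[var] = cohort[f"{var}_base"]
        else:
            raise KeyError(f"baseline predictor {var!r} not in cohort")
    return pd.DataFrame(cols, index=cohort.index)


def run_predictor_analyses(cohort: pd.DataFrame, labels: pd.DataFrame,
                           screened: dict[str, list[str]] | None = None,
                           collinearity_threshold: float = 0.7,
                           ) -> dict[tuple[str, str], LogisticFit | Exception]:
    """The four predictor models: {worsened, improved} x {baseline, change}.

    ``labels`` carries the per-patient MCID classification; each outcome
    is that direction versus everything else (unchanged patients stay in
    the reference class).  Collinear predictors are dropped per model
    before fitting.  A failing model (e.g. an empty direction) is
    recorded as its exception so the remaining models still run.
    """
    screened = screened or {"baseline": list(BASELINE_PREDICTORS),
                            "change": list(CHANGE_PREDICTORS)}
    merged = cohort.merge(labels, on="patient_id")
    merged = merged[merged["label"] != "excluded"]
    designs = {
        "baseline": _baseline_design(merged, screened["baseline"]),
        "change": change_columns(merged, screened["change"]),
    }
    results: dict[tuple[str, str], LogisticFit | Exception] = {}
    for set_name, design in designs.items():
        priority = tuple(c for c in design.columns if "chfs" in c) + \
                   tuple(c for c in design.columns if "haq" in c)
        kept, report = drop_collinear(design, threshold=collinearity_threshold,
                                      priority=priority)
        reduced = design[kept]
        for direction in ("worsened", "improved"):
            y = (merged["label"] == direction).astype(float).to_numpy()
            try:
                fit = fit_logistic(reduced, y,
                                   outcome_name=f"{direction}-vs-rest",
                                   predictor_set=set_name)
                fit.table.attrs["collinearity_drops"] = report
                results[(direction, set_name)] = fit
            except ValueError as err:
                results[(direction, set_name)] = err
    return results


def to_table_frame(results: dict[tuple[str, str], LogisticFit | Exception]
                   ) -> pd.DataFrame:
    """Flatten the four model fits into one report table (OR, CI, p per
    predictor per model), in the shape of the published predictor table."""
    rows = []
    for (direction, set_name), fit in results.items():
        if isinstance(fit, Exception):
            rows.append({"outcome": direction, "predictor_set": set_name,
                         "predictor": None, "error": str(fit)})
            continue
        for name, rec in fit.table.iterrows():
            if name == "const":
                continue
            rows.append({
                "outcome": direction, "predictor_set": set_name,
                "predictor": name, "odds_ratio": rec["odds_ratio"],
                "ci_low": rec["ci_low"], "ci_high": rec["ci_high"],
                "p_value": rec["p_value"], "n": fit.n,
                "separation": fit.separation, "error": None,
            })
    return pd.DataFrame(rows)
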