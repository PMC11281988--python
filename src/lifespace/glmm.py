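"""Day-level Poisson mixed model with person random intercepts.

The model is a log-link Poisson GLMM:

    y_ij ~ Poisson(exp(x_ij' beta + b_i)),   b_i ~ Normal(0, tau00)

fitted by maximum likelihood with the Laplace approximation to the marginal
likelihood: the random-intercept mode of each person is found by an inner
(vectorized) Newton iteration, and the outer optimization runs over
(beta, log tau00) so the variance stays non-negative. Standard errors come
from the observed information (numerical Hessian of the Laplace deviance) at
the optimum; p-values are two-sided Wald with a normal reference.

Variance decomposition follows the Nakagawa framework for Poisson-log
models: the distribution-specific residual variance uses the lognormal
approximation ``ln(1 + 1/lambda_bar)`` with ``lambda_bar = exp(beta0 +
tau00/2)``, which feeds both the ICC and the marginal/conditional R².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

_LOG_TAU_BOUNDS = (-18.0, 6.0)
_TAU_BOUNDARY = 1e-6

#: Fixed-term order used by build_day_design (intercept first, counter last).
DAY_DESIGN_TERMS = (
    "intercept",
    "sex_female",
    "age",
    "social_network_satisfaction",
    "cohabiting",
    "ksk12",
    "psk12",
    "health_literacy",
    "health_reach_count",
    "pt_reach_count",
    "subjective_access",
    "intersection_density",
    "sidewalk_quality",
    "green_share_pct",
    "utilization_score",
    "active_driving",
    "edu_middle",
    "edu_high",
    "counter",
)
_BINARY_TERMS = frozenset(
    {"sex_female", "cohabiting", "active_driving", "edu_middle", "edu_high"}
)


@dataclass
class DesignMatrix:
    """Day-level design: rows are valid person-days."""

    X: np.ndarray
    y: np.ndarray
    group_codes: np.ndarray
    group_ids: list[str]
    terms: list[str]
    response: str
    centered_means: dict[str, float] = field(default_factory=dict)
    n_dropped_persons: int = 0
    n_dropped_rows: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y) or self.X.shape[1] != len(self.terms):
            raise ValueError("design dimensions inconsistent")
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise ValueError("response must be non-negative integer counts")


@dataclass
class FitResult:
    """Estimates and variance decomposition of one fitted model."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    tau00: float
    sigma2_resid: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    loglik: float
    n_persons: int
    n_obs: int
    converged: bool
    tau_at_boundary: bool = False
    diagnostics: dict = field(default_factory=dict)


def center_grand_mean(
    columns: pd.DataFrame, cols: Sequence[str] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Grand-mean center the given continuous columns.

    Returns the centered frame and the subtracted means. Centering an
    already-centered column is a no-op (idempotent); a constant column
    triggers a warning and becomes all-zero.
    """
    out = columns.copy()
    cols = list(cols) if cols is not None else list(out.columns)
    means: dict[str, float] = {}
    for c in cols:
        m = float(out[c].mean())
        if float(out[c].std(ddof=0)) == 0.0:
            warnings.warn(f"column {c!r} is constant; centering makes it all-zero")
        out[c] = out[c] - m
        means[c] = m
    return out, means


def make_design(
    df: pd.DataFrame,
    response_col: str,
    fixed_cols: Sequence[str],
    group_col: str = "person_id",
    center_cols: Sequence[str] = (),
    response_name: str | None = None,
) -> DesignMatrix:
    """Assemble a DesignMatrix from a flat day-level table.

    An intercept column is prepended. ``center_cols`` are grand-mean centered
    over the fitted rows. Rows with any missing value among the used columns
    are dropped.
    """
    used = [group_col, response_col, *fixed_cols]
    sub = df[used].copy()
    n0 = len(sub)
    sub = sub.dropna()
    frame = sub[list(fixed_cols)].astype(float)
    frame, means = center_grand_mean(frame, center_cols) if center_cols else (frame, {})
    y = np.asarray(np.round(sub[response_col].astype(float)), dtype=np.int64)
    if np.any(y < 0):
        raise ValueError("negative response counts after rounding")
    codes, uniques = pd.factorize(sub[group_col].astype(str), sort=True)
    X = np.column_stack([np.ones(len(sub)), frame.to_numpy(dtype=float)])
    terms = ["intercept", *fixed_cols]
    return DesignMatrix(
        X=X,
        y=y,
        group_codes=np.asarray(codes, dtype=np.int64),
        group_ids=list(uniques),
        terms=terms,
        response=response_name or response_col,
        centered_means=means,
        n_dropped_rows=n0 - len(sub),
    )


def _raise_rank_deficiency(X: np.ndarray, terms: list[str]) -> None:
    # name columns involved in collinearity via QR pivoting
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = [terms[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
    raise ValueError(f"fixed design is rank deficient; collinear columns: {bad}")


def build_day_design(
    mobility: pd.DataFrame,
    persons: pd.DataFrame,
    env: pd.DataFrame,
    response: Literal["toh", "chull"] = "toh",
) -> DesignMatrix:
    """Join indicators, person covariates and exposures into the model design.

    Only valid days enter. The response is ``toh_min`` or ``chull_km2``
    rounded to the nearest integer. A ``counter`` column (day index 1..7 by
    date order within person) is added. Continuous terms are grand-mean
    centered; 0/1 binaries are left as coded. Persons with any missing
    covariate are dropped listwise (count logged).
    """
    response_col = {"toh": "toh_min", "chull": "chull_km2"}[response]
    mob = mobility[mobility["valid"].astype(bool)].copy()
    mob = mob.sort_values(["person_id", "mobility_date"])
    mob["counter"] = mob.groupby("person_id").cumcount() + 1
    mob["person_id"] = mob["person_id"].astype(str)

    persons = persons.copy()
    persons["person_id"] = persons["person_id"].astype(str)
    if "education" in persons.columns and "edu_middle" not in persons.columns:
        persons["edu_middle"] = (persons["education"] == "middle").astype(int)
        persons["edu_high"] = (persons["education"] == "high").astype(int)
    env = env.copy()
    env["person_id"] = env["person_id"].astype(str)
    # columns present in both tables (precomputed questionnaire scores) are
    # taken from the environment profile
    overlap = (set(persons.columns) & set(env.columns)) - {"person_id"}
    persons = persons.drop(columns=sorted(overlap))

    df = mob.merge(persons, on="person_id", how="inner").merge(
        env, on="person_id", how="inner"
    )
    fixed_cols = [t for t in DAY_DESIGN_TERMS if t != "intercept"]
    complete = df.dropna(subset=[response_col, *fixed_cols])
    dropped_persons = df["person_id"].nunique() - complete["person_id"].nunique()
    if dropped_persons:
        logger.info(
            "build_day_design: %d person(s) dropped for missing covariates",
            dropped_persons,
        )
    center_cols = [c for c in fixed_cols if c not in _BINARY_TERMS]
    design = make_design(
        complete,
        response_col,
        fixed_cols,
        center_cols=center_cols,
        response_name=response,
    )
    design.n_dropped_persons = dropped_persons
    return design


# ---------------------------------------------------------------------------
# Laplace likelihood


def _solve_modes(
    eta0: np.ndarray,
    y_sums: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    tau: float,
    b0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve for the per-group random-intercept modes.

    Returns (b_hat, sum_j exp(eta0_ij + b_hat_i) per group). The per-group
    objective is strictly concave in b, so undamped Newton with a step cap
    converges quickly.
    """
    b = np.zeros(n_groups) if b0 is None else b0.copy()
    exp_eta0 = np.exp(eta0)
    for _ in range(100):
        s_exp = np.bincount(codes, weights=exp_eta0 * np.exp(b[codes]), minlength=n_groups)
        grad = y_sums - s_exp - b / tau
        hess = s_exp + 1.0 / tau
        step = grad / hess
        np.clip(step, -4.0, 4.0, out=step)
        b += step
        if np.max(np.abs(step)) < 1e-11:
            break
    s_exp = np.bincount(codes, weights=exp_eta0 * np.exp(b[codes]), minlength=n_groups)
    return b, s_exp


def laplace_loglik(
    design: DesignMatrix, beta: np.ndarray, tau: float, b0: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Laplace-approximated marginal log-likelihood; returns (ll, b_hat)."""
    eta0 = design.X @ beta
    y = design.y
    codes = design.group_codes
    n_groups = design.n_groups
    const = -float(special.gammaln(y + 1).sum())
    if tau <= 0.0:
        lam = np.exp(eta0)
        return const + float(y @ eta0 - lam.sum()), np.zeros(n_groups)
    y_sums = np.bincount(codes, weights=y.astype(float), minlength=n_groups)
    b, s_exp = _solve_modes(eta0, y_sums, codes, n_groups, tau, b0)
    eta = eta0 + b[codes]
    w = s_exp + 1.0 / tau
    ll = (
        const
        + float(y @ eta - s_exp.sum())
        - float((b**2).sum()) / (2.0 * tau)
        - 0.5 * float(np.log(tau * w).sum())
    )
    return ll, b


def _poisson_irls(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Plain Poisson GLM by IRLS; returns (beta, cov, converged)."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        lam = np.exp(eta)
        W = lam
        z = eta + (y - lam) / lam
        XtW = X.T * W
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    lam = np.exp(X @ beta)
    cov = np.linalg.inv((X.T * lam) @ X)
    return beta, cov, converged


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for k in range(p):
        for l in range(k, p):
            ek = np.zeros(p)
            el = np.zeros(p)
            ek[k] = h[k]
            el[l] = h[l]
            fpp = f(x + ek + el)
            fpm = f(x + ek - el)
            fmp = f(x - ek + el)
            fmm = f(x - ek - el)
            H[k, l] = H[l, k] = (fpp - fpm - fmp + fmm) / (4.0 * h[k] * h[l])
    return H


def fit_poisson_glmm(
    design: DesignMatrix,
    tau00_fixed: float | None = None,
    start_beta: np.ndarray | None = None,
) -> FitResult:
    """Fit the Poisson random-intercept model by Laplace ML.

    ``tau00_fixed`` pins the random-intercept variance (``0.0`` reduces the
    model to an ordinary Poisson GLM, fitted exactly by IRLS). Estimation is
    deterministic given the data and starting values. Non-convergence is
    flagged in the result, never silent.
    """
    if design.n_groups < 2 and tau00_fixed is None:
        raise ValueError("need >= 2 persons to estimate a random-intercept variance")
    if np.linalg.matrix_rank(design.X) < design.X.shape[1]:
        _raise_rank_deficiency(design.X, design.terms)

    X, y = design.X, design.y
    p = X.shape[1]

    if tau00_fixed is not None and tau00_fixed == 0.0:
        beta, cov, converged = _poisson_irls(X, y)
        ll, _ = laplace_loglik(design, beta, 0.0)
        se = np.sqrt(np.diag(cov))
        return _assemble(design, beta, se, 0.0, ll, converged, boundary=False)

    beta0, _, _ = _poisson_irls(X, y) if start_beta is None else (start_beta, None, True)

    warm_b: dict[str, np.ndarray] = {"b": np.zeros(design.n_groups)}

    if tau00_fixed is not None:

        def negll(theta: np.ndarray) -> float:
            ll, b = laplace_loglik(design, theta, tau00_fixed, warm_b["b"])
            warm_b["b"] = b
            return -ll

        x0 = beta0
    else:

        def negll(theta: np.ndarray) -> float:
            tau = float(np.exp(theta[-1]))
            ll, b = laplace_loglik(design, theta[:-1], tau, warm_b["b"])
            warm_b["b"] = b
            return -ll

        x0 = np.append(beta0, np.log(0.5))

    bounds = [(None, None)] * p
    if tau00_fixed is None:
        bounds += [_LOG_TAU_BOUNDS]
    else:
        bounds = bounds[:p]
    res = optimize.minimize(
        negll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-8},
    )
    if not res.success:
        logger.warning("GLMM optimizer did not report convergence: %s", res.message)

    if tau00_fixed is not None:
        beta = res.x
        tau = float(tau00_fixed)
        boundary = tau <= _TAU_BOUNDARY
    else:
        beta = res.x[:-1]
        tau = float(np.exp(res.x[-1]))
        boundary = res.x[-1] <= _LOG_TAU_BOUNDS[0] + 1e-6 or tau <= _TAU_BOUNDARY
    ll = -res.fun

    H = _numerical_hessian(negll, res.x)
    se = _wald_se(H, p)
    fit = _assemble(design, beta, se, 0.0 if boundary else tau, ll, bool(res.success), boundary)
    fit.diagnostics.update(
        {"optimizer_message": str(res.message), "n_iter": int(res.nit)}
    )
    return fit


def _wald_se(H: np.ndarray, p: int) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:p]
        if np.any(d <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        # fall back to the beta block alone (tau at boundary can break joint PD)
        cov = np.linalg.pinv(H[:p, :p])
        return np.sqrt(np.abs(np.diag(cov)))


def _assemble(
    design: DesignMatrix,
    beta: np.ndarray,
    se: np.ndarray,
    tau: float,
    ll: float,
    converged: bool,
    boundary: bool,
) -> FitResult:
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    fit = FitResult(
        terms=list(design.terms),
        beta=beta,
        se=se,
        z=z,
        p=pvals,
        tau00=tau,
        sigma2_resid=np.nan,
        icc=np.nan,
        r2_marginal=np.nan,
        r2_conditional=np.nan,
        loglik=ll,
        n_persons=design.n_groups,
        n_obs=design.n_obs,
        converged=converged,
        tau_at_boundary=boundary,
    )
    fit.sigma2_resid = distribution_specific_variance(fit, design)
    if not (tau == 0.0 and fit.sigma2_resid == 0.0):
        fit.icc = icc(tau, fit.sigma2_resid)
    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit, design)
    return fit


def distribution_specific_variance(fit: FitResult, design: DesignMatrix) -> float:
    """Lognormal-approximation residual variance ``ln(1 + 1/lambda_bar)``.

    ``lambda_bar = exp(beta0 + tau00/2)`` on the (centered) design, so the
    intercept is the grand mean of the linear predictor.
    """
    i0 = fit.terms.index("intercept")
    lam_bar = float(np.exp(fit.beta[i0] + fit.tau00 / 2.0))
    return float(np.log1p(1.0 / lam_bar))


def icc(tau00: float, sigma2_resid: float) -> float:
    """Intraclass correlation ``tau00 / (tau00 + sigma2_resid)``."""
    if tau00 < 0 or sigma2_resid < 0:
        raise ValueError("variance components must be non-negative")
    denom = tau00 + sigma2_resid
    if denom == 0.0:
        raise ValueError("ICC undefined when both variance components are zero")
    return tau00 / denom


def r2_nakagawa(fit: FitResult, design: DesignMatrix) -> tuple[float, float]:
    """Marginal and conditional R² from the variance decomposition.

    ``sigma2_f`` is the variance of the fixed-effect linear predictor over
    fitted rows; marginal R² = sigma2_f / (sigma2_f + tau00 + sigma2_d),
    conditional adds tau00 to the numerator.
    """
    eta_fixed = design.X @ fit.beta
    sigma2_f = float(np.var(eta_fixed))
    denom = sigma2_f + fit.tau00 + fit.sigma2_resid
    if denom == 0.0:
        return 0.0, 0.0
    return sigma2_f / denom, (sigma2_f + fit.tau00) / denom


def wald_ci(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Two-sided Wald confidence intervals for the fixed effects."""
    q = stats.norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {
            "term": fit.terms,
            "beta": fit.beta,
            "lower": fit.beta - q * fit.se,
            "upper": fit.beta + q * fit.se,
        }
    )


def coefficient_table(fit: FitResult) -> pd.DataFrame:
    """Fixed-effect rows (beta, SE, z, p, significance at 0.05)."""
    return pd.DataFrame(
        {
            "term": fit.terms,
            "beta": np.round(fit.beta, 3),
            "se": np.round(fit.se, 3),
            "z": np.round(fit.z, 3),
            "p": np.round(fit.p, 3),
            "significant": fit.p < 0.05,
        }
    )


def format_report(fit: FitResult, title: str = "Poisson GLMM") -> str:
    """Aligned plain-text report: coefficient block plus random effects."""
    tab = coefficient_table(fit)
    lines = [title, "=" * len(title), ""]
    header = f"{'term':<30}{'beta':>10}{'SE':>10}{'z':>10}{'p':>10}"
    lines.append(header)
    lines.append("-" * len(header))
    for row in tab.itertuples():
        star = " *" if row.significant else ""
        lines.append(
            f"{row.term:<30}{row.beta:>10.3f}{row.se:>10.3f}{row.z:>10.3f}"
            f"{row.p:>10.3f}{star}"
        )
    lines += [
        "",
        f"sigma2 (residual, lognormal approx): {fit.sigma2_resid:.3f}",
        f"tau00 (person intercept variance):   {fit.tau00:.3f}"
        + ("  [boundary]" if fit.tau_at_boundary else ""),
        f"ICC:                                 {fit.icc:.3f}",
        f"N persons:                           {fit.n_persons}",
        f"Observations:                        {fit.n_obs}",
        f"Marginal R2 / conditional R2:        {fit.r2_marginal:.3f} / {fit.r2_conditional:.3f}",
        f"Log-likelihood (Laplace):            {fit.loglik:.2f}",
        f"Converged:                           {fit.converged}",
    ]
    return "\n".join(lines)
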