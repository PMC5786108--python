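"""Dichotomized person-day outcomes and ward-random-intercept logistic models.

The analysis unit is the person-day.  Daily contact frequency (distinct
partners) and cumulative duration are dichotomized at ``mean + k*sd`` of the
population's person-day distribution (sample sd; ties classified low), then
modeled with a logistic mixed model carrying a single ward-level random
intercept.  The marginal likelihood is maximized directly using Gauss-Hermite
quadrature with an analytic gradient; Wald CIs come from the observed
information, and per-factor p-values from likelihood-ratio tests against the
model with the factor removed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats

from .types import (
    ANALYSIS_STAFF_CATEGORIES,
    DAY_OF_WEEK_LABELS,
    Roster,
    Status,
)

#: absolute log-odds beyond which an estimate is reported as separation
SEPARATION_LOGODDS = 15.0


# ---------------------------------------------------------------------------
# Outcome table
# ---------------------------------------------------------------------------


def build_outcome_table(
    person_day_table: pd.DataFrame, roster: Roster, population: str
) -> tuple[pd.DataFrame, int]:
    """Person-day rows for one analysis population, covariates joined from the roster.

    ``population='staff'`` keeps the six analysis staff categories
    (administration and animation staff are excluded); ``'patients'`` keeps
    non-PVS patients.  Returns the table and the number of rows dropped for
    missing covariates.
    """
    if population not in ("staff", "patients"):
        raise ValueError(f"unknown population {population!r}")
    frame = roster.to_frame().set_index("id")
    df = person_day_table.copy()
    df["ward"] = df["id"].map(frame["ward"])
    df["day_of_week"] = df["date"].map(lambda d: DAY_OF_WEEK_LABELS[pd.Timestamp(d).dayofweek])
    df["freq_value"] = df["n_distinct"].astype(float)
    df["dur_value"] = df["total_duration_s"].astype(float)

    if population == "staff":
        keep_ids = {
            ind.id
            for ind in roster
            if ind.status is Status.staff and ind.category in ANALYSIS_STAFF_CATEGORIES
        }
        df = df[df["id"].isin(keep_ids)].copy()
        df["category"] = df["id"].map(frame["category"])
        covariates = ["category", "day_of_week", "ward"]
    else:
        keep_ids = {ind.id for ind in roster if ind.status is Status.patient and not ind.pvs}
        df = df[df["id"].isin(keep_ids)].copy()
        df["reason"] = df["id"].map(frame["reason"])
        df["age_band"] = df["id"].map({ind.id: ind.age_band for ind in roster})
        df["gender"] = df["id"].map(frame["gender"])
        covariates = ["reason", "age_band", "gender", "day_of_week", "ward"]

    before = len(df)
    df = df.dropna(subset=covariates).reset_index(drop=True)
    n_dropped = before - len(df)
    cols = ["id", "date", "ward", "day_of_week", "freq_value", "dur_value"]
    extra = [c for c in ("category", "reason", "age_band", "gender") if c in df.columns]
    return df[cols[:4] + extra + cols[4:]], n_dropped


@dataclasses.dataclass(frozen=True)
class ThresholdSpec:
    k: int
    threshold_freq: float
    threshold_dur: float
    population: str


def dichotomize(table: pd.DataFrame, k: int, population: str = "") -> tuple[pd.DataFrame, ThresholdSpec]:
    """Add ``high_freq``/``high_dur`` at threshold ``mean + k*sd`` (sample sd).

    Values strictly above the threshold are high; ties are low.
    """
    if k not in (0, 1, 2, 3):
        raise ValueError("k must be in {0, 1, 2, 3}")
    out = table.copy()
    thresholds = {}
    for col, flag in (("freq_value", "high_freq"), ("dur_value", "high_dur")):
        values = out[col].to_numpy(dtype=float)
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        if sd == 0.0:
            warnings.warn(f"{col}: zero variance, threshold equals the mean")
        thr = float(np.mean(values)) + k * sd
        thresholds[flag] = thr
        out[flag] = (values > thr).astype(int)
    spec = ThresholdSpec(k, thresholds["high_freq"], thresholds["high_dur"], population)
    return out, spec


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Fixed factors (with reference levels) + ward random intercept."""

    population: str
    outcome: str  # "high_freq" | "high_dur"
    factors: Mapping[str, str]  # factor name -> reference level
    group_col: str = "ward"


def staff_spec(outcome: str = "high_freq") -> ModelSpec:
    return ModelSpec(
        "staff", outcome, {"category": "HCW", "day_of_week": "Wednesday"}
    )


def patient_spec(outcome: str = "high_freq") -> ModelSpec:
    return ModelSpec(
        "patients",
        outcome,
        {
            "reason": "orthopaedic",
            "age_band": "[50,60)",
            "gender": "F",
            "day_of_week": "Wednesday",
        },
    )


def _design(table: pd.DataFrame, factors: Mapping[str, str]):
    """Intercept + treatment-coded dummies; returns (X, column labels)."""
    n = len(table)
    cols = [np.ones(n)]
    labels: list[tuple[str, str]] = [("(intercept)", "")]
    for factor, ref in factors.items():
        observed = table[factor].astype(str)
        levels = sorted(observed.unique())
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from factor {factor!r}")
        for level in levels:
            if level == ref:
                continue
            cols.append((observed == level).to_numpy(dtype=float))
            labels.append((factor, level))
    X = np.column_stack(cols)
    return X, labels


# ---------------------------------------------------------------------------
# Mixed logistic likelihood (Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------


class _MarginalLoglik:
    """Negative marginal log-likelihood of a logistic model with one Gaussian
    random intercept, integrated by Gauss-Hermite quadrature."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray, n_quad: int = 25):
        order = np.argsort(groups, kind="stable")
        self.y = y[order].astype(float)
        self.X = X[order]
        g_sorted = groups[order]
        uniq, counts = np.unique(g_sorted, return_counts=True)
        self.n_groups = len(uniq)
        self.offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.group_idx = np.repeat(np.arange(self.n_groups), counts)
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self.zs = np.sqrt(2.0) * nodes
        self.logw = np.log(weights) - 0.5 * np.log(np.pi)

    def __call__(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        beta, sigma = params[:-1], params[-1]
        eta = (self.X @ beta)[:, None] + sigma * self.zs[None, :]
        ll_obs = self.y[:, None] * eta - np.logaddexp(0.0, eta)  # n x K
        ll_grp = np.add.reduceat(ll_obs, self.offsets, axis=0)  # G x K
        a = self.logw[None, :] + ll_grp
        m = a.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(a - m).sum(axis=1))
        nll = -float(lse.sum())
        r = np.exp(a - lse[:, None])  # posterior node weights per group
        resid = (self.y[:, None] - scipy.special.expit(eta)) * r[self.group_idx]
        grad_beta = self.X.T @ resid.sum(axis=1)
        grad_sigma = float((resid * self.zs[None, :]).sum())
        return nll, -np.concatenate([grad_beta, [grad_sigma]])

    def value(self, params: np.ndarray) -> float:
        return self(params)[0]

    def grad(self, params: np.ndarray) -> np.ndarray:
        return self(params)[1]


def _numeric_hessian(fun_grad, x: np.ndarray) -> np.ndarray:
    p = len(x)
    H = np.zeros((p, p))
    for i in range(p):
        h = 1e-5 * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 1e-10) if i == p - 1 else xm[i] - h
        gp = fun_grad(xp)[1]
        gm = fun_grad(xm)[1]
        H[i] = (gp - gm) / (xp[i] - xm[i])
    return 0.5 * (H + H.T)


@dataclasses.dataclass
class GLMMResult:
    """Fitted mixed logistic model: per-level estimates and inference."""

    outcome: str
    table: pd.DataFrame  # factor, level, estimate, se, OR, or_lo, or_hi, wald_p, stars, separation
    sigma: float  # random-intercept sd
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    message: str = ""
    lrt: dict[str, float] = dataclasses.field(default_factory=dict)

    @property
    def sigma2(self) -> float:
        return self.sigma**2

    def level_row(self, factor: str, level: str) -> pd.Series:
        sub = self.table[(self.table["factor"] == factor) & (self.table["level"] == level)]
        if sub.empty:
            raise KeyError(f"{factor}[{level}] not in model")
        return sub.iloc[0]


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def fit_mixed_logit(
    table: pd.DataFrame,
    outcome: str,
    factors: Mapping[str, str],
    group_col: str = "ward",
    n_quad: int = 25,
) -> GLMMResult:
    """Fit a logistic model with fixed ``factors`` and a random intercept on
    ``group_col`` by maximizing the quadrature-approximated marginal likelihood."""
    y = table[outcome].to_numpy(dtype=float)
    n_obs = len(y)
    groups = pd.Categorical(table[group_col]).codes
    n_groups = int(groups.max()) + 1 if n_obs else 0
    X, labels = _design(table, factors)
    p = X.shape[1]

    if n_groups < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if y.min() == y.max():
        empty = _result_table(labels, np.full(p, np.nan), np.full(p, np.nan))
        return GLMMResult(
            outcome, empty, float("nan"), float("nan"), n_obs, n_groups,
            converged=False, message="degenerate outcome (all identical)",
        )

    nll = _MarginalLoglik(y, X, groups, n_quad)
    x0 = np.zeros(p + 1)
    pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    x0[0] = np.log(pbar / (1 - pbar))
    x0[-1] = 0.5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:  # warm start from the fixed-effects-only fit
            import statsmodels.api as sm

            glm = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
            if np.all(np.isfinite(glm.params)):
                x0[:-1] = np.clip(glm.params, -SEPARATION_LOGODDS - 5, SEPARATION_LOGODDS + 5)
        except Exception:
            pass

    bounds = [(None, None)] * p + [(1e-8, None)]
    opt = scipy.optimize.minimize(
        nll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta, sigma = opt.x[:-1], float(opt.x[-1])
    loglik = -float(opt.fun)

    H = _numeric_hessian(nll, opt.x)
    se = _wald_se(H, p)
    result_table = _result_table(labels, beta, se)
    # L-BFGS-B occasionally reports ABNORMAL when rounding stalls progress at
    # the optimum; a near-zero gradient still counts as converged.
    grad_norm = float(np.max(np.abs(opt.jac))) if opt.jac is not None else np.inf
    converged = bool(opt.success) or opt.status == 0 or grad_norm < 1e-2
    message = "" if converged else str(opt.message)
    return GLMMResult(
        outcome, result_table, sigma, loglik, n_obs, n_groups, converged, message
    )


def _wald_se(H: np.ndarray, p: int) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:p]
        if np.all(d > 0):
            return np.sqrt(d)
    except np.linalg.LinAlgError:
        pass
    try:  # sigma row may be ill-conditioned at the boundary; fall back to beta block
        cov_b = np.linalg.pinv(H[:p, :p])
        d = np.diag(cov_b)
        return np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def _result_table(labels, beta: np.ndarray, se: np.ndarray) -> pd.DataFrame:
    rows = []
    for (factor, level), b, s in zip(labels, beta, se):
        z = b / s if (np.isfinite(b) and np.isfinite(s) and s > 0) else np.nan
        wald_p = 2 * scipy.stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        separation = bool(np.isfinite(b) and abs(b) > SEPARATION_LOGODDS)
        with np.errstate(over="ignore"):
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "estimate": b,
                    "se": s,
                    "OR": np.exp(b),
                    "or_lo": np.exp(b - 1.96 * s),
                    "or_hi": np.exp(b + 1.96 * s),
                    "wald_p": wald_p,
                    "stars": significance_stars(wald_p) if not separation else "",
                    "separation": separation,
                }
            )
    return pd.DataFrame(rows)


def fit_glmm(table: pd.DataFrame, spec: ModelSpec, n_quad: int = 25) -> GLMMResult:
    """Fit ``spec`` and attach per-factor likelihood-ratio p-values."""
    result = fit_mixed_logit(table, spec.outcome, spec.factors, spec.group_col, n_quad)
    if result.converged:
        for factor in spec.factors:
            try:
                result.lrt[factor] = lrt_factor(table, spec, factor, full=result, n_quad=n_quad)
            except Exception:  # reduced fit failed; leave the p-value missing
                result.lrt[factor] = float("nan")
    return result


def lrt_factor(
    table: pd.DataFrame,
    spec: ModelSpec,
    factor: str,
    full: GLMMResult | None = None,
    n_quad: int = 25,
) -> float:
    """Likelihood-ratio p-value for dropping ``factor`` wholesale.

    2*(l_full - l_reduced) is referred to chi-square with df = estimated
    non-reference levels of the factor.
    """
    if factor not in spec.factors:
        raise KeyError(f"factor {factor!r} not in model spec")
    if full is None:
        full = fit_mixed_logit(table, spec.outcome, spec.factors, spec.group_col, n_quad)
    if not full.converged:
        raise RuntimeError("full model did not converge")
    reduced_factors = {f: r for f, r in spec.factors.items() if f != factor}
    reduced = fit_mixed_logit(table, spec.outcome, reduced_factors, spec.group_col, n_quad)
    df = int((full.table["factor"] == factor).sum())
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return float(scipy.stats.chi2.sf(stat, df))


def sensitivity_analysis(
    table: pd.DataFrame,
    spec: ModelSpec,
    k_list: Sequence[int] = (0, 1, 2, 3),
    n_quad: int = 25,
) -> pd.DataFrame:
    """Refit the model across dichotomization thresholds; per-k failures are
    recorded without aborting the other fits."""
    rows = []
    for k in k_list:
        try:
            dtable, thr = dichotomize(table, k, spec.population)
            result = fit_glmm(dtable, spec, n_quad)
            threshold = thr.threshold_freq if spec.outcome == "high_freq" else thr.threshold_dur
            frac_high = float(dtable[spec.outcome].mean())
            for row in result.table.itertuples(index=False):
                rows.append(
                    {
                        "k": k,
                        "threshold": threshold,
                        "frac_high": frac_high,
                        "factor": row.factor,
                        "level": row.level,
                        "OR": row.OR,
                        "or_lo": row.or_lo,
                        "or_hi": row.or_hi,
                        "wald_p": row.wald_p,
                        "converged": result.converged,
                        "error": "",
                    }
                )
        except Exception as exc:  # pragma: no cover - defensive
            rows.append(
                {
                    "k": k, "threshold": np.nan, "frac_high": np.nan,
                    "factor": "", "level": "", "OR": np.nan,
                    "or_lo": np.nan, "or_hi": np.nan, "wald_p": np.nan,
                    "converged": False, "error": str(exc),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulation harness for parameter-recovery checks
# ---------------------------------------------------------------------------


def simulate_outcome_table(
    n_obs: int,
    n_wards: int,
    effects: Mapping[str, float],
    intercept: float,
    sigma: float,
    seed: int,
    ref_level: str = "HCW",
    level_probs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw person-day binary outcomes from the fitted model class.

    ``effects`` maps non-reference category levels to log-odds shifts; ward
    intercepts are N(0, sigma^2).  Returns a table with columns
    ``ward, category, high`` ready for :func:`fit_mixed_logit`.
    """
    rng = np.random.default_rng(seed)
    levels = [ref_level] + sorted(effects)
    if level_probs is None:
        probs = np.full(len(levels), 1.0 / len(levels))
    else:
        probs = np.array([level_probs[lv] for lv in levels], dtype=float)
        probs /= probs.sum()
    cat = rng.choice(len(levels), size=n_obs, p=probs)
    ward = rng.integers(0, n_wards, size=n_obs)
    b = rng.normal(0.0, sigma, size=n_wards)
    beta = np.array([0.0] + [effects[lv] for lv in levels[1:]])
    eta = intercept + beta[cat] + b[ward]
    y = rng.random(n_obs) < scipy.special.expit(eta)
    return pd.DataFrame(
        {
            "ward": [f"W{w + 1}" for w in ward],
            "category": [levels[c] for c in cat],
            "high": y.astype(int),
        }
    )
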