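"""Count-family GLMs, AICc, exhaustive additive subset enumeration, and equivalence reasoning.

The question this module answers: do motor features improve prediction of a
cognitive count score *over and above* fixed demographic and mood covariates?
The procedure:

1. Fix the covariates — age, sex, education level (unordered categorical,
   lowest level as reference), HADS depression, HADS anxiety — in every model.
2. Fit every linear, additive combination of the candidate motor features (no
   interactions): ``2^m`` models including the covariates-only **null model**.
3. Rank models by AICc (AIC with the finite-sample correction
   ``AIC + 2k(k+1)/(n-k-1)``); models within 2 AICc units of the best are
   *statistically equivalent*.
4. If the equivalence set excludes the null model (null ΔAICc > 2), motor
   features improve prediction.

Count outcomes use Poisson or negative-binomial (NB2) families with a log
link; a Gaussian (identity link) fallback covers NB non-convergence.  The NB
dispersion is an estimated parameter and counts toward ``k``.  Fitting is a
lean in-house IRLS (with a Newton update on log dispersion for NB2), because
the enumeration loop performs thousands of maximum-likelihood fits per table;
its coefficients and log-likelihoods are cross-checked against statsmodels in
the test suite.

Ties in AICc break by smaller ``k``, then lexicographic feature names, so
tables are fully deterministic.  Non-converged fits stay visible in the table
but never define the best model or the equivalence set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, polygamma, psi

from tapcog.keystroke_io import EDUCATION_LEVELS

__all__ = [
    "FIXED_COVARIATES",
    "ModelSpec",
    "FittedModel",
    "ModelTable",
    "HypothesisDecision",
    "FamilyChoice",
    "aicc",
    "fit_glm",
    "dredge_subsets",
    "evaluate_hypothesis",
    "select_family",
    "incident_rate_ratios",
    "adjusted_pseudo_r2",
    "build_design",
]

#: The five fixed covariates (education expands to five reference-coded dummies).
FIXED_COVARIATES = (
    "age_years",
    "sex",
    "education_level",
    "hads_depression",
    "hads_anxiety",
)

FAMILIES = ("poisson", "negative_binomial", "gaussian")

_Z975 = 1.959963984540054

_EQUIVALENCE_DELTA = 2.0

_THETA_MIN, _THETA_MAX = 1e-4, 1e7


class RankDeficientError(ValueError):
    """The design matrix is rank deficient; ``columns`` names the collinear columns."""

    def __init__(self, columns: list[str]):
        super().__init__(f"design matrix is rank deficient; collinear columns: {columns}")
        self.columns = columns


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: outcome, motor-feature subset, and family."""

    outcome: str
    features: tuple[str, ...] = ()
    family: str = "negative_binomial"
    include_covariates: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        object.__setattr__(self, "features", tuple(self.features))


@dataclass
class FittedModel:
    """A maximum-likelihood GLM fit with information-criterion bookkeeping."""

    spec: ModelSpec
    params: pd.Series  # coefficient per design column
    bse: pd.Series
    loglik: float
    n: int
    k: int  # every estimated parameter, incl. NB dispersion / Gaussian sigma^2
    k_mean: int  # mean-model parameters only (used by adjusted pseudo-R2)
    deviance: float
    converged: bool
    theta: float | None = None  # NB size (1/alpha)
    sigma2: float | None = None  # Gaussian residual variance (MLE)
    null_deviance: float | None = None  # intercept-only deviance at this model's dispersion
    flags: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)


def aicc(loglik: float, k: int, n: int) -> float:
    """AIC with the finite-sample correction: ``-2 loglik + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def build_design(
    data: pd.DataFrame,
    features: tuple[str, ...] = (),
    include_covariates: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the design matrix: intercept, fixed covariates, then features.

    ``sex`` becomes an indicator ``sex_male``; ``education_level`` expands to
    five dummies against the lowest level.  Raises :class:`RankDeficientError`
    when columns are collinear, naming them.
    """
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["const"]
    if include_covariates:
        names += ["age_years", "sex_male"]
        cols.append(data["age_years"].to_numpy(float))
        if "sex_male" in data.columns:
            cols.append(data["sex_male"].to_numpy(float))
        else:
            cols.append((data["sex"] == "male").to_numpy(float))
        for level in EDUCATION_LEVELS[1:]:
            name = f"edu_{level}"
            names.append(name)
            if name in data.columns:
                cols.append(data[name].to_numpy(float))
            else:
                cols.append((data["education_level"] == level).to_numpy(float))
        names += ["hads_depression", "hads_anxiety"]
        cols.append(data["hads_depression"].to_numpy(float))
        cols.append(data["hads_anxiety"].to_numpy(float))
    for f in features:
        names.append(f)
        cols.append(data[f].to_numpy(float))
    X = np.column_stack(cols)
    if np.isnan(X).any():
        bad = [names[j] for j in np.where(np.isnan(X).any(axis=0))[0]]
        raise ValueError(f"missing values in design columns: {bad}")
    _check_rank(X, names)
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # QR with pivoting: tiny trailing diagonal entries identify collinear columns
    from scipy.linalg import qr

    r = qr(X, mode="r", pivoting=True)
    diag = np.abs(np.diag(r[0]))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    deficient = diag < tol
    if deficient.any():
        raise RankDeficientError([names[j] for j in r[1][deficient]])


# ---------------------------------------------------------------------------
# likelihoods and fitters
# ---------------------------------------------------------------------------


def _poisson_loglik(y, eta, mu):
    return float(np.sum(y * eta - mu) - np.sum(gammaln(y + 1.0)))


def _nb_loglik(y, mu, theta):
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _irls(X, y, weights_fn, beta0, tol=1e-10, max_iter=100):
    """Log-link IRLS; ``weights_fn(mu)`` gives the working weights."""
    beta = beta0.copy()
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    converged = False
    for _ in range(max_iter):
        w = weights_fn(mu)
        z = eta + (y - mu) / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, mu, False
        step = np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta_new)))
        beta = beta_new
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        if step < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 20.0:
        converged = False
    return beta, mu, converged


def _fit_poisson_core(X, y, beta0=None, tol=1e-10, max_iter=100):
    if beta0 is None:
        beta0 = np.zeros(X.shape[1])
        beta0[0] = np.log(max(y.mean(), 1e-3))
    beta, mu, converged = _irls(X, y, lambda m: m, beta0, tol, max_iter)
    eta = np.log(mu)
    ll = _poisson_loglik(y, eta, mu)
    return beta, mu, ll, converged


def _theta_newton(y, mu, theta, n_steps=3, uniq=None, cnt=None):
    """A few Newton steps on log(theta) for the NB2 profile likelihood.

    Digamma/trigamma sums are evaluated over the distinct count values with
    multiplicities (counts take few distinct values, so this is much cheaper
    than evaluating special functions per observation).
    """
    if uniq is None:
        uniq, cnt = np.unique(y, return_counts=True)
    w = np.log(theta)
    n = len(y)
    for _ in range(n_steps):
        th = np.exp(w)
        tm = th + mu
        dl_dth = float(
            cnt @ psi(uniq + th) - n * psi(th) + n * (np.log(th) + 1.0)
            - np.sum(np.log(tm)) - np.sum((y + th) / tm)
        )
        d2l_dth2 = float(
            cnt @ polygamma(1, uniq + th) - n * polygamma(1, th) + n / th
            - np.sum(2.0 / tm) + np.sum((y + th) / tm**2)
        )
        g = th * dl_dth
        h = th**2 * d2l_dth2 + g
        if h < 0:
            step = -g / h
        else:  # not locally concave: take a bounded gradient step
            step = np.sign(g) * 0.5
        w += float(np.clip(step, -2.0, 2.0))
        w = float(np.clip(w, np.log(_THETA_MIN), np.log(_THETA_MAX)))
    return float(np.exp(w))


def _fit_negbin_core(X, y, beta0=None, theta0=None, tol=3e-9, max_outer=50):
    if beta0 is None:
        beta0, mu, _, _ = _fit_poisson_core(X, y)
    else:
        mu = np.exp(np.clip(X @ beta0, -30.0, 30.0))
    if theta0 is None:
        excess = float(np.mean((y - mu) ** 2 - mu))
        theta0 = float(np.mean(mu**2) / excess) if excess > 0 else 100.0
        theta0 = float(np.clip(theta0, 0.01, 1e4))
    uniq, cnt = np.unique(y, return_counts=True)
    const_gammaln = float(cnt @ gammaln(uniq + 1.0))
    n = len(y)

    def loglik(mu, th):
        return float(
            cnt @ gammaln(uniq + th) - n * gammaln(th) - const_gammaln
            + th * np.sum(np.log(th / (th + mu)))
            + np.sum(y * np.log(mu / (th + mu)))
        )

    beta, theta = beta0.copy(), theta0
    ll_prev = -np.inf
    converged = False
    flags: list[str] = []
    for _ in range(max_outer):
        beta, mu, _ = _irls(
            X, y, lambda m: m / (1.0 + m / theta), beta, tol=1e-8, max_iter=4
        )
        theta = _theta_newton(y, mu, theta, n_steps=2, uniq=uniq, cnt=cnt)
        ll = loglik(mu, theta)
        if not np.isfinite(ll):
            return beta, mu, theta, ll, False, ["non_finite_loglik"]
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
    ll = loglik(mu, theta)
    if np.max(np.abs(beta)) > 20.0:
        converged = False
        flags.append("diverging_coefficients")
    if theta >= _THETA_MAX * 0.99:
        flags.append("dispersion_at_boundary")  # equidispersed limit; still a valid MLE
    return beta, mu, theta, ll, converged, flags


def _poisson_deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _nb_deviance(y, mu, theta):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    t2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(t1 - t2))


def fit_glm(spec: ModelSpec, data: pd.DataFrame, start=None) -> FittedModel:
    """Maximum-likelihood fit of one model spec on the analysis table.

    Log link for count families, identity for Gaussian.  Convergence failure
    is reported through ``converged`` — never silently.  ``start`` may carry
    ``(beta0, theta0)`` warm-start values aligned to the design columns.
    """
    y = data[spec.outcome].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError(f"outcome {spec.outcome!r} contains missing values")
    X, names = build_design(data, spec.features, spec.include_covariates)
    return _fit_core(X, names, y, spec, start)


def _fit_core(X, names, y, spec: ModelSpec, start=None) -> FittedModel:
    n, p = X.shape
    beta0 = theta0 = None
    if start is not None:
        beta0, theta0 = start

    if spec.family == "gaussian":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        sigma2 = rss / n
        ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
        cov = rss / (n - p) * np.linalg.inv(X.T @ X)
        return FittedModel(
            spec=spec,
            params=pd.Series(beta, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
            loglik=ll,
            n=n,
            k=p + 1,
            k_mean=p,
            deviance=rss,
            converged=True,
            sigma2=sigma2,
            null_deviance=float(np.sum((y - y.mean()) ** 2)),
        )

    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError(f"count family requires non-negative integer outcome {spec.outcome!r}")

    # the intercept-only MLE mean is ybar for every family used here, so the
    # baseline deviance can be evaluated at this model's own dispersion —
    # deviances at different NB thetas are not comparable
    ybar = float(y.mean())
    if spec.family == "poisson":
        beta, mu, ll, converged = _fit_poisson_core(X, y, beta0)
        theta = None
        k = p
        deviance = _poisson_deviance(y, mu)
        null_deviance = _poisson_deviance(y, np.full_like(y, ybar))
        w = mu
        flags = [] if converged else ["not_converged"]
    else:
        beta, mu, theta, ll, converged, flags = _fit_negbin_core(X, y, beta0, theta0)
        k = p + 1
        deviance = _nb_deviance(y, mu, theta)
        null_deviance = _nb_deviance(y, np.full_like(y, ybar), theta)
        w = mu / (1.0 + mu / theta)
        if not converged:
            flags = flags + ["not_converged"]

    XtWX = (X.T * w) @ X
    try:
        cov = np.linalg.inv(XtWX)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
    return FittedModel(
        spec=spec,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        loglik=ll,
        n=n,
        k=k,
        k_mean=p,
        deviance=deviance,
        converged=converged,
        theta=theta,
        null_deviance=null_deviance,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# pseudo-R2, IRR
# ---------------------------------------------------------------------------


def adjusted_pseudo_r2(
    fitted: FittedModel, null_fitted: FittedModel | None = None
) -> float:
    """Deviance-based adjusted pseudo-R2 (a stated convention, printed in reports).

    ``1 - (D_model / D_baseline) * (n - 1) / (n - k_mean)``, clamped below at
    zero.  The baseline deviance is the intercept-only deviance evaluated *at
    the fitted model's own dispersion* (deviances at different NB thetas are
    not comparable); for the Gaussian family this reduces exactly to the
    classical adjusted R².  ``null_fitted``, when given, is used only to check
    the fits share the same data.
    """
    if null_fitted is not None and fitted.n != null_fitted.n:
        raise ValueError("fits must be on identical data")
    d0 = fitted.null_deviance
    if d0 is None and null_fitted is not None:
        d0 = null_fitted.deviance
    if d0 is None or d0 <= 0:
        return 0.0
    r2 = 1.0 - (fitted.deviance / d0) * (fitted.n - 1) / (fitted.n - fitted.k_mean)
    return max(0.0, float(r2))


def incident_rate_ratios(fitted: FittedModel, alpha: float = 0.05) -> pd.DataFrame:
    """Exponentiated coefficients with Wald confidence bounds (log-link count families).

    IRR > 1 means a higher expected error rate per unit increase of the
    predictor; < 1 a lower rate.  Undefined (raises) for the Gaussian family.
    """
    if fitted.spec.family == "gaussian":
        raise ValueError("incident rate ratios are undefined for the gaussian family")
    if alpha == 0.05:
        z = _Z975
    else:
        from scipy.stats import norm

        z = float(norm.ppf(1 - alpha / 2))
    coef = fitted.params
    se = fitted.bse
    return pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "irr": np.exp(coef),
            "irr_low": np.exp(coef - z * se),
            "irr_high": np.exp(coef + z * se),
        }
    )


# ---------------------------------------------------------------------------
# all-subsets enumeration
# ---------------------------------------------------------------------------


@dataclass
class ModelTable:
    """AICc-ranked table of all additive feature subsets for one outcome/family."""

    outcome: str
    family: str
    candidate_features: tuple[str, ...]
    table: pd.DataFrame  # ranked; columns incl. features, k, loglik, aic, aicc, delta_aicc, equivalent
    models: dict[tuple[str, ...], FittedModel]
    baseline: FittedModel  # intercept-only fit (deviance baseline for pseudo-R2)

    @property
    def best(self) -> FittedModel:
        conv = self.table[self.table["converged"]]
        return self.models[tuple(conv.iloc[0]["features"])]

    @property
    def null_model(self) -> FittedModel:
        return self.models[()]

    @property
    def null_delta_aicc(self) -> float:
        conv = self.table[self.table["converged"]]
        null_rows = conv[conv["features"].map(lambda f: len(f) == 0)]
        if null_rows.empty:
            return float("nan")
        return float(null_rows.iloc[0]["delta_aicc"])

    @property
    def null_in_equivalence_set(self) -> bool:
        d = self.null_delta_aicc
        return bool(np.isfinite(d) and d < _EQUIVALENCE_DELTA)


def dredge_subsets(
    outcome: str,
    candidate_features: list[str] | tuple[str, ...],
    data: pd.DataFrame,
    family: str = "negative_binomial",
    max_features: int = 24,
) -> ModelTable:
    """Fit all ``2^m`` additive motor-feature subsets (fixed covariates in every model).

    Subsets are enumerated in deterministic order (by size, then name); each
    fit warm-starts from the null model.  The returned table is ranked by
    AICc with ties broken by smaller ``k`` then feature names; ``equivalent``
    flags models within 2 AICc of the best *converged* model.  Non-converged
    fits are retained, flagged, and excluded from equivalence reasoning.
    """
    feats = sorted(candidate_features)
    m = len(feats)
    if m > max_features:
        raise ValueError(
            f"{m} candidate features exceeds the enumeration cap of {max_features}"
        )
    if m > 16:
        warnings.warn(
            f"enumerating 2^{m} subsets; this may take a long time", stacklevel=2
        )

    y = data[outcome].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError(f"outcome {outcome!r} contains missing values")
    # one design matrix for the full candidate set, rank-checked once;
    # every subset model slices columns out of it
    X_full, names_full = build_design(data, tuple(feats))
    p_cov = len(names_full) - m
    col_of = {f: p_cov + j for j, f in enumerate(feats)}

    baseline = _fit_core(
        np.ones((len(y), 1)),
        ["const"],
        y,
        ModelSpec(outcome=outcome, features=(), family=family, include_covariates=False),
    )
    cov_idx = list(range(p_cov))
    null = _fit_core(
        X_full[:, cov_idx],
        names_full[:p_cov],
        y,
        ModelSpec(outcome=outcome, features=(), family=family),
    )
    models: dict[tuple[str, ...], FittedModel] = {(): null}
    null_beta = null.params.to_numpy()
    null_theta = null.theta

    for size in range(1, m + 1):
        for combo in itertools.combinations(feats, size):
            idx = cov_idx + [col_of[f] for f in combo]
            beta0 = np.concatenate([null_beta, np.zeros(size)])
            fm = _fit_core(
                np.ascontiguousarray(X_full[:, idx]),
                names_full[:p_cov] + list(combo),
                y,
                ModelSpec(outcome=outcome, features=combo, family=family),
                start=(beta0, null_theta),
            )
            models[combo] = fm

    rows = []
    for combo, fm in models.items():
        rows.append(
            {
                "features": combo,
                "n_features": len(combo),
                "k": fm.k,
                "loglik": fm.loglik,
                "aic": fm.aic,
                "aicc": fm.aicc,
                "converged": fm.converged,
                "pseudo_r2_adj": adjusted_pseudo_r2(fm, baseline),
                "is_null": len(combo) == 0,
            }
        )
    df = pd.DataFrame(rows)
    df["_names"] = df["features"].map(lambda f: "+".join(f))
    df["_conv_order"] = (~df["converged"]).astype(int)
    df = df.sort_values(
        by=["_conv_order", "aicc", "k", "_names"], kind="mergesort"
    ).reset_index(drop=True)
    best_aicc = df.loc[df["converged"], "aicc"].min()
    df["delta_aicc"] = df["aicc"] - best_aicc
    df["equivalent"] = df["converged"] & (df["delta_aicc"] < _EQUIVALENCE_DELTA)
    df = df.drop(columns=["_names", "_conv_order"])
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return ModelTable(
        outcome=outcome,
        family=family,
        candidate_features=tuple(feats),
        table=df,
        models=models,
        baseline=baseline,
    )


@dataclass(frozen=True)
class HypothesisDecision:
    """Did motor features improve prediction over the covariates-only null model?"""

    outcome: str
    family: str
    null_delta_aicc: float
    improvement: bool
    best_features: tuple[str, ...]
    best_aicc: float
    n_equivalent: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "family": self.family,
            "null_delta_aicc": round(self.null_delta_aicc, 4),
            "improvement": self.improvement,
            "best_features": list(self.best_features),
            "best_aicc": round(self.best_aicc, 4),
            "n_equivalent": self.n_equivalent,
        }


def evaluate_hypothesis(model_table: ModelTable) -> HypothesisDecision:
    """Motor features improve prediction iff the null model's ΔAICc exceeds 2."""
    null_delta = model_table.null_delta_aicc
    best = model_table.best
    return HypothesisDecision(
        outcome=model_table.outcome,
        family=model_table.family,
        null_delta_aicc=null_delta,
        improvement=bool(null_delta > _EQUIVALENCE_DELTA),
        best_features=best.spec.features,
        best_aicc=best.aicc,
        n_equivalent=int(model_table.table["equivalent"].sum()),
    )


# ---------------------------------------------------------------------------
# family selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyChoice:
    """Outcome-family decision with the evidence that produced it."""

    outcome: str
    family: str
    aicc_poisson: float | None
    aicc_negbin: float | None
    fallback_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "family": self.family,
            "aicc_poisson": self.aicc_poisson,
            "aicc_negbin": self.aicc_negbin,
            "fallback_reason": self.fallback_reason,
        }


def select_family(outcome: str, data: pd.DataFrame) -> FamilyChoice:
    """Choose the residual family on the covariates-only null model.

    Prefers negative binomial when its AICc beats Poisson by more than 2
    (overdispersion); retains Poisson otherwise.  If the NB null fails to
    converge, falls back to Gaussian and records why.  A hard error only if
    every family fails.
    """
    nb = pois = None
    try:
        nb = fit_glm(ModelSpec(outcome=outcome, features=(), family="negative_binomial"), data)
    except (ValueError, np.linalg.LinAlgError):
        nb = None
    if nb is None or not nb.converged:
        try:
            gauss = fit_glm(ModelSpec(outcome=outcome, features=(), family="gaussian"), data)
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise RuntimeError(
                f"all families failed for outcome {outcome!r}"
            ) from exc
        if not np.isfinite(gauss.loglik):
            raise RuntimeError(f"all families failed for outcome {outcome!r}")
        return FamilyChoice(
            outcome=outcome,
            family="gaussian",
            aicc_poisson=None,
            aicc_negbin=None,
            fallback_reason="negative binomial null model did not converge",
        )
    try:
        pois = fit_glm(ModelSpec(outcome=outcome, features=(), family="poisson"), data)
    except (ValueError, np.linalg.LinAlgError):
        pois = None
    if pois is None or not pois.converged:
        return FamilyChoice(
            outcome=outcome,
            family="negative_binomial",
            aicc_poisson=None,
            aicc_negbin=nb.aicc,
            fallback_reason="poisson null model did not converge",
        )
    if nb.aicc < pois.aicc - _EQUIVALENCE_DELTA:
        family = "negative_binomial"
    else:
        family = "poisson"
    return FamilyChoice(
        outcome=outcome,
        family=family,
        aicc_poisson=pois.aicc,
        aicc_negbin=nb.aicc,
    )
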