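"""Environmental and ontogenetic modelling of the robustness signal.

Covers four questions asked of the morphospace scores:

* does the allometric slope (robustness on centroid size) differ between
  warm and cold intervals, split at the d18O = -0.9 permil threshold?
* is ontogenetic stage (juvenile < neanic < adult, coded with orthogonal
  polynomial contrasts) a parsimonious predictor of robustness (AICc)?
* how much morphospace variance do d18O, d13C, d11B and lithology each
  explain uniquely (variation partitioning via redundancy analysis with
  Ezekiel-adjusted R^2)?
* which subset of the three isotope proxies best predicts robustness once
  lithology is controlled for, under a generalised-least-squares model with
  AR(1) residual correlation along stratigraphic order, ranked by AICc?

GLS fits use maximum likelihood (not REML) so AICc is comparable across
fixed-effect structures.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import STAGE_ORDER, SpecimenRecord, Stage

DEFAULT_TEMPERATURE_THRESHOLD = -0.9


class CollinearityError(ValueError):
    """Predictors too collinear for a stable fit."""


# ---------------------------------------------------------------------------
# temperature split and allometry

def split_by_temperature(
    specimens: list[SpecimenRecord], threshold: float = DEFAULT_TEMPERATURE_THRESHOLD
) -> tuple[list[SpecimenRecord], list[SpecimenRecord]]:
    """Partition specimens into warm (d18O < threshold) and cold
    (d18O >= threshold; the boundary value counts as cold).  More negative
    d18O means warmer seawater."""
    missing = [s.specimen_id for s in specimens if not s.proxies or "d18O" not in s.proxies]
    if missing:
        raise ValueError(f"specimens missing d18O proxy: {missing}")
    warm = [s for s in specimens if s.proxies["d18O"] < threshold]
    cold = [s for s in specimens if s.proxies["d18O"] >= threshold]
    return warm, cold


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    adj_r_squared: float
    p: float
    n: int
    regime: str = "pooled"


def fit_allometry(sizes, robustness, regime: str = "pooled") -> RegressionFit:
    """OLS of robustness (PC1) on centroid size: the ontogenetic allometry
    within one temperature regime.  Negative slopes mean larger (older)
    specimens are more slender."""
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(robustness, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("degenerate predictor: zero size variance")
    n = len(x)
    if np.var(y) == 0:
        return RegressionFit(
            slope=0.0, intercept=float(y[0]),
            adj_r_squared=1.0 - (n - 1) / (n - 2), p=1.0, n=n, regime=regime,
        )
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionFit(
        slope=float(res.slope), intercept=float(res.intercept),
        adj_r_squared=float(adj), p=float(res.pvalue), n=n, regime=regime,
    )


def allometry_confint(sizes, robustness, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for the allometric slope."""
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(robustness, dtype=float)
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.5 + level / 2, len(x) - 2)
    return float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)


def compare_slopes(
    warm_sizes, warm_robustness, cold_sizes, cold_robustness
) -> tuple[float, float]:
    """F-test for a slope difference between temperature regimes.

    Implemented as the regime x size interaction in the pooled model
    (equivalent to the ANOVA comparison of the separate regime fits).
    Returns (F, p) with 1 numerator degree of freedom.
    """
    xw = np.asarray(warm_sizes, float)
    yw = np.asarray(warm_robustness, float)
    xc = np.asarray(cold_sizes, float)
    yc = np.asarray(cold_robustness, float)
    if len(xw) < 3 or len(xc) < 3:
        raise ValueError("each regime needs n >= 3")
    x = np.concatenate([xw, xc])
    y = np.concatenate([yw, yc])
    regime = np.concatenate([np.ones(len(xw)), np.zeros(len(xc))])
    X = np.column_stack([np.ones_like(x), x, regime, x * regime])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = len(y) - X.shape[1]
    if df_resid <= 0:
        raise ValueError("insufficient observations for interaction test")
    sigma2 = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[3, 3])
    if se == 0:
        return 0.0, 1.0
    f = float((beta[3] / se) ** 2)
    p = float(stats.f.sf(f, 1, df_resid))
    return f, p


# ---------------------------------------------------------------------------
# information criteria and ordinal stage model

def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion:
    AIC + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    aic = -2.0 * log_likelihood + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _gaussian_loglik(resid: np.ndarray) -> float:
    """ML log-likelihood of an OLS fit (variance = RSS/n)."""
    n = len(resid)
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)


def ordinal_contrasts(levels: int) -> np.ndarray:
    """Orthogonal polynomial contrast matrix (levels x (levels-1)),
    matching the standard ordinal coding: columns are the centred,
    orthonormal linear, quadratic, ... trends."""
    x = np.arange(levels, dtype=float)
    vander = np.vander(x, levels, increasing=True)
    q, _ = np.linalg.qr(vander)
    contrasts = q[:, 1:]
    # sign convention: linear trend increasing
    for j in range(contrasts.shape[1]):
        if contrasts[-1, j] < 0 and j == 0:
            contrasts[:, j] = -contrasts[:, j]
    return contrasts


@dataclass
class ModelSelectionTable:
    """AICc ranking of candidate models; the best model has delta AICc 0."""

    table: pd.DataFrame
    best_model: str
    coefficients: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def ordinal_stage_model(robustness, stages: list[Stage]) -> ModelSelectionTable:
    """Linear model of robustness on ontogenetic stage as an ordinal
    predictor (orthogonal polynomial contrasts), compared against the
    intercept-only null by AICc.  Parameter counts include the residual
    variance.  Returns the ranking plus the stage-term F-test p-value."""
    y = np.asarray(robustness, dtype=float)
    stage_levels = [s for s in STAGE_ORDER if s in set(stages)]
    if len(stage_levels) < 2:
        raise ValueError("need at least two ontogenetic stages present")
    if len(y) < 5:
        raise ValueError("need n >= 5")
    codes = np.array([stage_levels.index(s) for s in stages])
    contrasts = ordinal_contrasts(len(stage_levels))
    X_stage = np.column_stack([np.ones(len(y)), contrasts[codes]])
    X_null = np.ones((len(y), 1))

    def fit(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return beta, resid

    beta_s, resid_s = fit(X_stage)
    _, resid_n = fit(X_null)
    n = len(y)
    ll_s = _gaussian_loglik(resid_s)
    ll_n = _gaussian_loglik(resid_n)
    k_s = X_stage.shape[1] + 1  # + residual variance
    k_n = 2
    rows = [
        ("stage", ll_s, k_s, aicc(ll_s, k_s, n)),
        ("null", ll_n, k_n, aicc(ll_n, k_n, n)),
    ]
    frame = pd.DataFrame(rows, columns=["model", "log_likelihood", "k", "AICc"])
    frame = frame.sort_values("AICc", kind="stable").reset_index(drop=True)
    frame["delta_AICc"] = frame["AICc"] - frame["AICc"].iloc[0]
    frame["rank"] = np.arange(1, len(frame) + 1)
    # stage-term F test (nested models)
    rss_s, rss_n = float(resid_s @ resid_s), float(resid_n @ resid_n)
    df1 = X_stage.shape[1] - 1
    df2 = n - X_stage.shape[1]
    f = ((rss_n - rss_s) / df1) / (rss_s / df2) if rss_s > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2))
    coef = pd.DataFrame(
        {"term": ["intercept"] + [f"stage^{i}" for i in range(1, X_stage.shape[1])],
         "estimate": beta_s}
    )
    return ModelSelectionTable(
        table=frame, best_model=str(frame["model"].iloc[0]), coefficients=coef,
        metadata={"stage_p": p, "stage_F": float(f), "levels": [s.value for s in stage_levels]},
    )


# ---------------------------------------------------------------------------
# variation partitioning (RDA with adjusted R^2)

@dataclass
class VariancePartition:
    """Adjusted-R^2 decomposition of morphospace variance.

    ``fractions`` holds the unique (independent) fraction of each predictor
    set, one lumped shared fraction, and the residual; they sum to 1.
    Unique fractions may be slightly negative (adjustment artefact).
    """

    fractions: dict[str, float]
    subset_r2: dict[frozenset, float]
    dropped: list[str]

    def total(self) -> float:
        return float(sum(self.fractions.values()))


def _rda_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Fraction of total variance of (centred) Y explained by projection
    onto the column space of X (redundancy statistic)."""
    Q, _ = np.linalg.qr(X - X.mean(axis=0))
    Yc = Y - Y.mean(axis=0)
    total = float((Yc**2).sum())
    if total == 0:
        return 0.0
    fitted = Q @ (Q.T @ Yc)
    return float((fitted**2).sum()) / total


def _adjust_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment."""
    if n - m - 1 <= 0:
        raise ValueError("too few observations for adjustment")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def variation_partitioning(
    response: np.ndarray, predictor_sets: dict[str, np.ndarray]
) -> VariancePartition:
    """Partition the variance of a response matrix over named predictor
    sets (each an (n, m_i) column block; a categorical predictor enters as
    its dummy block).  Unique fraction of set i = adjR2(all) - adjR2(all
    without i); the remainder of adjR2(all) is reported as one shared
    fraction, and 1 - adjR2(all) as the residual.
    """
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    sets: dict[str, np.ndarray] = {}
    dropped = []
    for name, X in predictor_sets.items():
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
        if not keep:
            warnings.warn(f"predictor set {name!r} is constant; dropped")
            dropped.append(name)
            continue
        sets[name] = X[:, keep]
    names = list(sets)
    if not names:
        raise ValueError("no usable predictor sets")

    def adj_for(subset: frozenset) -> float:
        if not subset:
            return 0.0
        X = np.column_stack([sets[nm] for nm in names if nm in subset])
        return _adjust_r2(_rda_r2(Y, X), n, X.shape[1])

    subset_r2 = {
        frozenset(c): adj_for(frozenset(c))
        for r in range(len(names) + 1)
        for c in itertools.combinations(names, r)
    }
    full = frozenset(names)
    r2_full = subset_r2[full]
    fractions: dict[str, float] = {}
    for nm in names:
        fractions[f"unique_{nm}"] = r2_full - subset_r2[full - {nm}]
    shared = r2_full - sum(fractions.values())
    fractions["shared"] = shared
    fractions["residual"] = 1.0 - r2_full
    return VariancePartition(fractions=fractions, subset_r2=subset_r2, dropped=dropped)


def lithology_dummies(lithologies) -> np.ndarray:
    """Treatment-coded dummy block for the lithology factor (reference =
    first category present, in enum order)."""
    values = [getattr(l, "value", l) for l in lithologies]
    cats = sorted(set(values))
    ref = cats[0]
    return np.column_stack([[1.0 if v == c else 0.0 for v in values] for c in cats if c != ref]) \
        if len(cats) > 1 else np.zeros((len(values), 0))


# ---------------------------------------------------------------------------
# GLS with AR(1) residuals, ML, AICc model selection

def predictor_collinearity_check(env: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations between candidate predictors with a
    pass/fail flag at |r| >= threshold."""
    if env.shape[1] < 2:
        raise ValueError("need at least two predictor columns")
    for col in env.columns:
        if np.std(env[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"constant predictor column {col!r}: correlation undefined")
    rows = []
    cols = list(env.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = float(np.corrcoef(env[a], env[b])[0, 1])
            rows.append((a, b, r, bool(abs(r) >= threshold)))
    return pd.DataFrame(rows, columns=["var1", "var2", "r", "fail"])


@dataclass
class GLSFit:
    """One ML GLS fit with AR(1) residual correlation."""

    coefficients: pd.DataFrame
    phi: float
    sigma2: float
    log_likelihood: float
    k: int
    n: int
    converged: bool


def _ar1_whiten(z: np.ndarray, phi: float) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    out[0] = np.sqrt(1.0 - phi**2) * z[0]
    out[1:] = z[1:] - phi * z[:-1]
    return out


def _gls_profile_loglik(phi: float, y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, float]:
    ys = _ar1_whiten(y, phi)
    Xs = np.column_stack([_ar1_whiten(X[:, j], phi) for j in range(X.shape[1])])
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    n = len(y)
    rss = max(float(resid @ resid), 1e-300)
    sigma2 = rss / n
    ll = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + 0.5 * np.log(1.0 - phi**2)
    return ll, beta, sigma2


def gls_ar1_fit(
    y: np.ndarray,
    X: np.ndarray,
    term_names: list[str],
    phi: float | None = None,
    phi_bound: float = 0.95,
) -> GLSFit:
    """Maximum-likelihood GLS with AR(1) residual correlation over the
    (already ordered) observation sequence.

    The AR(1) coefficient is profiled out: conditional on phi the whitened
    model is OLS with closed-form beta and innovation variance.  Pass
    ``phi=0`` to recover ordinary least squares exactly.  The parameter
    count k includes the residual variance and (when estimated) phi.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 3:
        raise ValueError("too few observations for the candidate model")
    estimate_phi = phi is None
    if estimate_phi:
        res = optimize.minimize_scalar(
            lambda f: -_gls_profile_loglik(f, y, X)[0],
            bounds=(-phi_bound, phi_bound),
            method="bounded",
            options={"xatol": 1e-6},
        )
        phi_hat = float(res.x)
        converged = bool(res.success)
    else:
        phi_hat, converged = float(phi), True
    ll, beta, sigma2 = _gls_profile_loglik(phi_hat, y, X)
    Xs = np.column_stack([_ar1_whiten(X[:, j], phi_hat) for j in range(X.shape[1])])
    df_resid = n - p
    sigma2_unb = sigma2 * n / max(df_resid, 1)
    cov = sigma2_unb * np.linalg.pinv(Xs.T @ Xs)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    coef = pd.DataFrame(
        {"term": term_names, "estimate": beta, "se": se, "t": tvals, "p": pvals}
    )
    k = p + 1 + (1 if estimate_phi else 0)
    return GLSFit(
        coefficients=coef, phi=phi_hat, sigma2=sigma2, log_likelihood=ll,
        k=k, n=n, converged=converged,
    )


def gls_select(
    robustness,
    env: pd.DataFrame,
    lithologies,
    order,
    candidates: tuple[str, ...] = ("d18O", "d13C", "d11B"),
    correlation: str = "ar1",
) -> ModelSelectionTable:
    """AICc selection over every subset of the candidate isotope predictors,
    each fitted by ML GLS with lithology always included as a fixed
    covariate and (by default) AR(1) residual correlation over stratigraphic
    bed order.  The lithology-only model is the null.

    Returns the ranked table plus the best model's coefficient table.
    """
    y = np.asarray(robustness, dtype=float)
    order = np.asarray(order)
    sort_idx = np.argsort(order, kind="stable")
    y = y[sort_idx]
    env = env.iloc[sort_idx].reset_index(drop=True)
    lith_sorted = [list(lithologies)[i] for i in sort_idx]
    # identifiability guard
    for i, a in enumerate(candidates):
        for b in candidates[i + 1:]:
            if np.std(env[a]) > 0 and np.std(env[b]) > 0:
                r = abs(float(np.corrcoef(env[a], env[b])[0, 1]))
                if r >= 0.99:
                    raise CollinearityError(f"predictors {a!r} and {b!r} have |r| = {r:.3f}")
    lith = lithology_dummies(lith_sorted)
    lith_names = [f"lith_{i+1}" for i in range(lith.shape[1])]
    phi_fixed = 0.0 if correlation == "independence" else None
    rows = []
    fits: dict[str, GLSFit] = {}
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            name = "+".join(subset) if subset else "null"
            X = np.column_stack(
                [np.ones(len(y)), lith] + [env[c].to_numpy(dtype=float) for c in subset]
            )
            terms = ["intercept"] + lith_names + list(subset)
            fit = gls_ar1_fit(y, X, terms, phi=phi_fixed)
            fits[name] = fit
            rows.append((name, fit.log_likelihood, fit.k, aicc(fit.log_likelihood, fit.k, fit.n)))
    frame = pd.DataFrame(rows, columns=["predictor_subset", "log_likelihood", "k", "AICc"])
    frame = frame.sort_values("AICc", kind="stable").reset_index(drop=True)
    frame["delta_AICc"] = frame["AICc"] - frame["AICc"].iloc[0]
    frame["rank"] = np.arange(1, len(frame) + 1)
    best = str(frame["predictor_subset"].iloc[0])
    return ModelSelectionTable(
        table=frame,
        best_model=best,
        coefficients=fits[best].coefficients,
        metadata={
            "correlation": correlation,
            "phi": fits[best].phi,
            "fits": fits,
        },
    )
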