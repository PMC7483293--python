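"""Group differences and parameter correlations.

Per prepulse condition, group separability is assessed with a two-class
LDA in the five-dimensional parameter space (m_max, r, s0, alpha, beta),
scored by the mean absolute distance to the separating hyperplane and by
leave-one-out classification accuracy, each with a label-permutation
test.  Counts of significant conditions are controlled for multiplicity
with a bootstrapped ratio test against an independent-binomial null.

The covariation analyses use the four-feature parameterisation
(saturation, threshold, startle scaling, sound scaling): PCA with a
column-permutation test, Pearson correlations of scaling against the
matched baseline feature, robustness of those correlations to jittered
refits, a within-animal compensation null, and baseline-adjusted ANCOVA
for group effects on the scaling parameters.

Experiments that vary the prepulse level and experiments that vary the
delay are distinct condition sets and are never pooled; the per-animal
slope analysis regresses each scaling parameter on whichever stimulus
dimension the experiment varied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .exceptions import InsufficientDataError, PpiScaleWarning
from .model import jitter_draws

__all__ = [
    "FEATURES_5D",
    "FEATURES_4D",
    "LdaResult",
    "AncovaResult",
    "lda_condition",
    "permutation_distance_test",
    "loocv_accuracy",
    "loocv_accuracy_test",
    "ratio_multiplicity_test",
    "pca_condition",
    "scaling_baseline_correlation",
    "correlation_jitter_robustness",
    "within_animal_null",
    "ancova_scaling",
    "scaling_vs_stimulus_slopes",
]

FEATURES_5D = ["m_max", "r", "s0", "alpha", "beta"]
FEATURES_4D = ["m_max", "threshold", "alpha", "beta"]


# -- low-level LDA machinery ------------------------------------------


def standardize_features(X: np.ndarray) -> np.ndarray:
    """Z-score each feature across animals (constant columns pass through)."""
    X = np.asarray(X, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _encode_labels(y) -> tuple[np.ndarray, list]:
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly two groups, got {classes}")
    return np.asarray([c == classes[1] for c in y], dtype=bool), classes


def _lda_fit(X: np.ndarray, y1: np.ndarray, ridge: float = 1e-10):
    """Closed-form two-class LDA: w = Sigma^-1 (mu1 - mu0), Gaussian offset.

    Sigma is the pooled within-class covariance (n - 2 denominator); a
    tiny ridge keeps near-singular problems solvable, and a strong ridge
    fallback (with warning) handles outright singularity.
    """
    n, d = X.shape
    X0, X1 = X[~y1], X[y1]
    mu0, mu1 = X0.mean(0), X1.mean(0)
    Sw = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    cov = Sw / (n - 2)
    scale = np.trace(cov) / d if np.trace(cov) > 0 else 1.0
    try:
        w = np.linalg.solve(cov + ridge * scale * np.eye(d), mu1 - mu0)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular within-group covariance; using regularized fallback",
            PpiScaleWarning,
            stacklevel=3,
        )
        w = np.linalg.solve(cov + 1e-3 * scale * np.eye(d), mu1 - mu0)
    b = -0.5 * w @ (mu0 + mu1) + np.log(len(X1) / len(X0))
    return w, b


def _mean_abs_distance(X, w, b) -> float:
    return float(np.mean(np.abs(X @ w + b)) / np.linalg.norm(w))


@dataclass
class LdaResult:
    """LDA separability of two groups in one prepulse condition."""

    condition: tuple
    classes: list
    normal: np.ndarray
    offset: float
    projections: pd.Series  # signed distance per animal
    mean_abs_distance: float
    permutation_p: float | None = None
    loocv_accuracy: float | None = None
    loocv_permutation_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def lda_condition(
    features: pd.DataFrame,
    feature_cols: list[str] = FEATURES_5D,
    condition: tuple | None = None,
) -> LdaResult:
    """Fit the two-class LDA for one condition's feature table.

    ``features`` carries one row per animal with a ``group`` column and
    the feature columns; features are standardized across animals before
    the fit (the parameters have incommensurate units).
    """
    y1, classes = _encode_labels(features["group"])
    if min((~y1).sum(), y1.sum()) < 3:
        raise InsufficientDataError("need >= 3 animals per group for LDA")
    X = standardize_features(features[feature_cols].to_numpy(float))
    w, b = _lda_fit(X, y1)
    dist = (X @ w + b) / np.linalg.norm(w)
    proj = pd.Series(dist, index=features["animal_id"].to_numpy(), name="ld_distance")
    return LdaResult(
        condition=condition,
        classes=classes,
        normal=w,
        offset=float(b),
        projections=proj,
        mean_abs_distance=float(np.mean(np.abs(dist))),
    )


def _batched_distance_stat(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean absolute LDA distance for a batch of label assignments.

    ``labels`` is (B, n) boolean.  Uses the identity that the pooled
    within-class scatter equals the total Gram matrix minus the class
    outer products, so the whole batch reduces to one stacked solve.
    """
    B, n = labels.shape
    d = X.shape[1]
    G = X.T @ X
    n1 = labels.sum(axis=1).astype(float)
    n0 = n - n1
    mu1 = (labels @ X) / n1[:, None]
    mu0 = ((~labels) @ X) / n0[:, None]
    Sw = (
        G[None, :, :]
        - n0[:, None, None] * mu0[:, :, None] * mu0[:, None, :]
        - n1[:, None, None] * mu1[:, :, None] * mu1[:, None, :]
    )
    cov = Sw / (n - 2)
    tr = np.trace(cov, axis1=1, axis2=2) / d
    cov = cov + (1e-10 * tr)[:, None, None] * np.eye(d)
    w = np.linalg.solve(cov, (mu1 - mu0)[:, :, None])[:, :, 0]
    b = -0.5 * np.einsum("bd,bd->b", w, mu0 + mu1) + np.log(n1 / n0)
    proj = X @ w.T + b[None, :]
    return np.mean(np.abs(proj), axis=0) / np.linalg.norm(w, axis=1)


def permutation_distance_test(
    features: pd.DataFrame,
    feature_cols: list[str] = FEATURES_5D,
    n_perm: int = 10_000,
    seed: int = 0,
    condition: tuple | None = None,
) -> LdaResult:
    """Label-permutation test on the mean absolute LDA distance.

    The LDA is refit for every permutation; p uses the add-one estimator
    (1 + #{permuted >= observed}) / (n_perm + 1), never exactly zero.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives poor p-value resolution",
            PpiScaleWarning,
            stacklevel=2,
        )
    res = lda_condition(features, feature_cols, condition=condition)
    y1, _ = _encode_labels(features["group"])
    X = standardize_features(features[feature_cols].to_numpy(float))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y1) for _ in range(n_perm)])
    null = _batched_distance_stat(X, perms)
    res.permutation_p = float((1 + np.sum(null >= res.mean_abs_distance)) / (n_perm + 1))
    res.n_permutations = n_perm
    res.seed = seed
    return res


def _loocv_accuracy_fast(X: np.ndarray, y1: np.ndarray) -> float:
    """Leave-one-out LDA accuracy via rank-one downdates, fully batched."""
    n, d = X.shape
    mus, scatters, counts = [], [], []
    for cls in (False, True):
        Xc = X[y1 == cls]
        mu = Xc.mean(0)
        mus.append(mu)
        scatters.append((Xc - mu).T @ (Xc - mu))
        counts.append(len(Xc))
    mu0, mu1 = mus
    S0, S1 = scatters
    n0, n1 = counts
    # per-left-out-sample class means and scatters
    mu0_i = np.tile(mu0, (n, 1))
    mu1_i = np.tile(mu1, (n, 1))
    S_i = np.tile(S0 + S1, (n, 1, 1))
    n0_i = np.full(n, n0, float)
    n1_i = np.full(n, n1, float)
    for i in range(n):
        x = X[i]
        if y1[i]:
            mu1_i[i] = (n1 * mu1 - x) / (n1 - 1)
            delta = x - mu1
            S_i[i] -= (n1 / (n1 - 1)) * np.outer(delta, delta)
            n1_i[i] = n1 - 1
        else:
            mu0_i[i] = (n0 * mu0 - x) / (n0 - 1)
            delta = x - mu0
            S_i[i] -= (n0 / (n0 - 1)) * np.outer(delta, delta)
            n0_i[i] = n0 - 1
    cov = S_i / (n - 3)  # n-1 training samples, two classes
    tr = np.trace(cov, axis1=1, axis2=2) / d
    cov = cov + (1e-10 * np.maximum(tr, 1e-300))[:, None, None] * np.eye(d)
    w = np.linalg.solve(cov, (mu1_i - mu0_i)[:, :, None])[:, :, 0]
    b = -0.5 * np.einsum("nd,nd->n", w, mu0_i + mu1_i) + np.log(n1_i / n0_i)
    pred = np.einsum("nd,nd->n", X, w) + b > 0
    return float(np.mean(pred == y1))


def loocv_accuracy(
    features: pd.DataFrame, feature_cols: list[str] = FEATURES_5D
) -> float:
    """Leave-one-out LDA classification accuracy."""
    y1, _ = _encode_labels(features["group"])
    if len(y1) < 4:
        raise InsufficientDataError("need >= 4 animals for LOOCV")
    X = standardize_features(features[feature_cols].to_numpy(float))
    return _loocv_accuracy_fast(X, y1)


def loocv_accuracy_test(
    features: pd.DataFrame,
    feature_cols: list[str] = FEATURES_5D,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """LOOCV accuracy and its label-permutation p-value.

    Accuracy is a discrete statistic (multiples of 1/n), so permutation
    ties are abundant and the plain add-one estimator is markedly
    conservative; the mid-p convention (ties counted half) restores
    near-nominal calibration while remaining valid.
    """
    y1, _ = _encode_labels(features["group"])
    if len(y1) < 4:
        raise InsufficientDataError("need >= 4 animals for LOOCV")
    X = standardize_features(features[feature_cols].to_numpy(float))
    observed = _loocv_accuracy_fast(X, y1)
    rng = np.random.default_rng(seed)
    greater = ties = 0
    for _ in range(n_perm):
        a = _loocv_accuracy_fast(X, rng.permutation(y1))
        greater += a > observed
        ties += a == observed
    p = float((1 + greater + 0.5 * ties) / (n_perm + 1))
    return observed, p


# -- multiplicity -----------------------------------------------------


def ratio_multiplicity_test(
    k_significant: int,
    n_conditions: int,
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """Bootstrapped ratio test: is the count of significant conditions
    larger than chance at level alpha would produce?

    Null: each condition is independently significant with probability
    alpha; the p-value is the add-one tail fraction of Binomial(n, alpha)
    draws at or above the observed count.
    """
    if not 0 <= k_significant <= n_conditions:
        raise ValueError("need 0 <= k <= n")
    rng = np.random.default_rng(seed)
    null = rng.binomial(n_conditions, alpha, size=n_boot)
    return float((1 + np.sum(null >= k_significant)) / (n_boot + 1))


# -- PCA and correlations ---------------------------------------------


def pca_condition(
    features: pd.DataFrame,
    feature_cols: list[str] = FEATURES_4D,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """PC1 of the standardized feature matrix with a permutation test.

    Significance: each feature column is shuffled independently across
    animals (destroying cross-feature coupling while preserving
    marginals) and the PC1 variance fraction recomputed; p is the
    add-one tail fraction at or above the observed fraction.
    """
    X = features[feature_cols].to_numpy(float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping constant feature columns "
            f"{[c for c, k in zip(feature_cols, keep) if not k]}",
            PpiScaleWarning,
            stacklevel=2,
        )
        feature_cols = [c for c, k in zip(feature_cols, keep) if k]
        X = X[:, keep]
    if len(X) < 4:
        raise InsufficientDataError("need >= 4 animals for PCA")
    Z = standardize_features(X)

    def pc1(M):
        vals, vecs = np.linalg.eigh(np.cov(M, rowvar=False))
        return vals[-1] / vals.sum(), vecs[:, -1]

    frac, weights = pc1(Z)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += pc1(rng.permuted(Z, axis=0))[0] >= frac
    return {
        "pc1_variance_fraction": float(frac),
        "pc1_weights": pd.Series(weights, index=feature_cols),
        "permutation_p": float((1 + exceed) / (n_perm + 1)),
        "n_permutations": n_perm,
        "seed": seed,
    }


def scaling_baseline_correlation(
    features: pd.DataFrame,
    condition_cols: tuple[str, str] = ("prepulse_db", "delay_ms"),
) -> pd.DataFrame:
    """Pearson correlations of scaling vs matched baseline feature.

    Per condition: startle scaling (alpha) against saturation (m_max)
    and sound scaling (beta) against threshold, each with r, r^2, p and
    the OLS regression line.  Degenerate inputs (zero variance or n < 3)
    are flagged rather than raised.
    """
    pairs = [("alpha", "m_max"), ("beta", "threshold")]
    rows = []
    for cond, sub in features.groupby(list(condition_cols)):
        for response, covariate in pairs:
            x = sub[covariate].to_numpy(float)
            y = sub[response].to_numpy(float)
            degenerate = len(x) < 3 or x.std() == 0 or y.std() == 0
            if degenerate:
                r = p = slope = intercept = np.nan
            else:
                r, p = stats.pearsonr(x, y)
                slope, intercept = np.polyfit(x, y, 1)
            rows.append(
                {
                    condition_cols[0]: cond[0],
                    condition_cols[1]: cond[1],
                    "response": response,
                    "covariate": covariate,
                    "n": len(x),
                    "r": float(r),
                    "r2": float(r**2) if np.isfinite(r) else np.nan,
                    "p": float(p),
                    "slope": float(slope),
                    "intercept": float(intercept),
                    "degenerate": bool(degenerate),
                }
            )
    return pd.DataFrame(rows)


def _params_frame_from_draws(draws: pd.DataFrame, conditions) -> dict:
    """Split a jitter-draw frame into threshold and per-condition columns."""
    out = {
        "m_max": draws["m_max"],
        "threshold": draws["s0"] - np.log(19.0) / draws["r"],
    }
    for p, d in conditions:
        out[("alpha", p, d)] = draws[f"alpha[{p:g},{d:g}]"]
        if f"beta[{p:g},{d:g}]" in draws:
            out[("beta", p, d)] = draws[f"beta[{p:g},{d:g}]"]
    return out


def correlation_jitter_robustness(
    results_by_animal: dict,
    n_refit: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Robustness of across-animal correlations to jittered refits.

    Each refit jitters every animal's summaries (SD = per-stimulus SEM),
    refits every animal, and recomputes the across-animal correlations
    per condition.  Reports the observed r, a 5-95 percentile band over
    refits, and the fraction of refits whose r falls on the opposite
    side of zero from the observed correlation.
    """
    animals = list(results_by_animal)
    conditions = list(next(iter(results_by_animal.values())).scalings)
    draws = {
        a: _params_frame_from_draws(
            jitter_draws(results_by_animal[a], n_refit, seed + i),
            conditions,
        )
        for i, a in enumerate(animals)
    }
    rows = []
    for p, d in conditions:
        for response, covariate in (("alpha", "m_max"), ("beta", "threshold")):
            key = (response, p, d)
            if key not in draws[animals[0]]:
                continue
            Y = np.column_stack([draws[a][key] for a in animals])
            Xc = np.column_stack([draws[a][covariate] for a in animals])
            ok = np.isfinite(Y).all(axis=1) & np.isfinite(Xc).all(axis=1)
            n_failed = int((~ok).sum())
            Y, Xc = Y[ok], Xc[ok]
            rs = _rowwise_pearson(Xc, Y)
            obs_x = np.array(
                [results_by_animal[a].params.m_max for a in animals]
            ) if covariate == "m_max" else np.array(
                [results_by_animal[a].threshold for a in animals]
            )
            obs_y = np.array(
                [
                    getattr(results_by_animal[a].scalings[(p, d)], response)
                    for a in animals
                ]
            )
            obs_r = float(stats.pearsonr(obs_x, obs_y)[0]) if obs_y.std() > 0 else np.nan
            sign = np.sign(obs_r) if np.isfinite(obs_r) else 0.0
            rows.append(
                {
                    "prepulse_db": p,
                    "delay_ms": d,
                    "response": response,
                    "covariate": covariate,
                    "observed_r": obs_r,
                    "r_lo": float(np.nanpercentile(rs, 5)),
                    "r_hi": float(np.nanpercentile(rs, 95)),
                    "zero_crossing_fraction": float(np.mean(np.sign(rs) != sign))
                    if sign
                    else np.nan,
                    "n_refits_used": int(ok.sum()),
                    "n_refits_failed": n_failed,
                }
            )
    return pd.DataFrame(rows)


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between matched rows of X and Y (each row = one refit)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = (Xc * Yc).sum(axis=1)
    den = np.sqrt((Xc**2).sum(axis=1) * (Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def within_animal_null(
    results,
    n_refit: int = 1_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-animal compensation null for the parameter correlations.

    Refits one animal's model to jittered data ``n_refit`` times and
    correlates, across refits, each condition's startle scaling with the
    saturation and each sound scaling with the threshold.  Pooled over
    animals, this is the distribution of correlations produced purely by
    compensation between parameters under data noise; an observed
    across-animal correlation above its 75th percentile (in magnitude,
    matching sign) is not attributable to compensation.
    """
    draws = jitter_draws(results, n_refit, seed)
    cols = _params_frame_from_draws(draws, list(results.scalings))
    rows = []
    for p, d in results.scalings:
        for response, covariate in (("alpha", "m_max"), ("beta", "threshold")):
            key = (response, p, d)
            if key not in cols:
                continue
            y = np.asarray(cols[key], float)
            x = np.asarray(cols[covariate], float)
            ok = np.isfinite(x) & np.isfinite(y)

            def _degenerate(v):
                return v.std() <= 1e-10 * (1.0 + np.abs(v.mean()))

            if ok.sum() < 3 or _degenerate(x[ok]) or _degenerate(y[ok]):
                r = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", stats.ConstantInputWarning)
                    r = float(stats.pearsonr(x[ok], y[ok])[0])
            rows.append(
                {
                    "animal_id": results.animal_id,
                    "prepulse_db": p,
                    "delay_ms": d,
                    "response": response,
                    "covariate": covariate,
                    "r": r,
                }
            )
    return pd.DataFrame(rows)


# -- ANCOVA -----------------------------------------------------------


@dataclass
class AncovaResult:
    """Baseline-adjusted group comparison for one scaling parameter."""

    condition: tuple
    response: str
    covariate: str
    excluded: bool = False
    exclusion_reason: str | None = None
    covariate_ttest_p: float | None = None
    interaction_p: float | None = None
    group_p: float | None = None
    common_slope: float | None = None
    slopes_per_group: dict = field(default_factory=dict)
    group_means_adjusted: dict = field(default_factory=dict)


def ancova_scaling(
    features: pd.DataFrame,
    condition: tuple | None = None,
    alpha_level: float = 0.05,
) -> list[AncovaResult]:
    """ANCOVA of each scaling parameter on group with its baseline covariate.

    Stage 1 fits response ~ group + covariate + group:covariate; if the
    interaction is not significant (homogeneous slopes) the model is
    refit without it and the group main effect reported.  Conditions
    where the groups differ in the covariate itself (two-sample t-test,
    p < alpha_level) are excluded: ANCOVA is inappropriate under
    nonrandom covariate differences.
    """
    y1, classes = _encode_labels(features["group"])
    if min((~y1).sum(), y1.sum()) < 3:
        raise InsufficientDataError("need >= 3 animals per group for ANCOVA")
    out = []
    for response, covariate in (("alpha", "m_max"), ("beta", "threshold")):
        res = AncovaResult(condition=condition, response=response, covariate=covariate)
        df = pd.DataFrame(
            {
                "y": features[response].to_numpy(float),
                "x": features[covariate].to_numpy(float),
                "g": features["group"].to_numpy(),
            }
        )
        if df["x"].std() == 0:
            res.excluded = True
            res.exclusion_reason = "zero covariate variance"
            out.append(res)
            continue
        t_p = stats.ttest_ind(
            df.loc[df["g"] == classes[0], "x"], df.loc[df["g"] == classes[1], "x"]
        ).pvalue
        res.covariate_ttest_p = float(t_p)
        if t_p < alpha_level:
            res.excluded = True
            res.exclusion_reason = (
                f"group difference in covariate {covariate} (t-test p={t_p:.3g})"
            )
            out.append(res)
            continue
        try:
            inter = smf.ols("y ~ C(g) * x", data=df).fit()
        except Exception:
            res.excluded = True
            res.exclusion_reason = "inestimable model"
            out.append(res)
            continue
        inter_term = [t for t in inter.pvalues.index if ":" in t][0]
        res.interaction_p = float(inter.pvalues[inter_term])
        slope_base = float(inter.params["x"])
        res.slopes_per_group = {
            classes[0]: slope_base,
            classes[1]: slope_base + float(inter.params[inter_term]),
        }
        if res.interaction_p <= alpha_level:
            # heterogeneous slopes: a single adjusted group effect is not
            # interpretable, so stop at the interaction stage
            out.append(res)
            continue
        main = smf.ols("y ~ C(g) + x", data=df).fit()
        g_term = [t for t in main.pvalues.index if t.startswith("C(g)")][0]
        res.group_p = float(main.pvalues[g_term])
        res.common_slope = float(main.params["x"])
        xbar = df["x"].mean()
        res.group_means_adjusted = {
            classes[0]: float(main.params["Intercept"] + main.params["x"] * xbar),
            classes[1]: float(
                main.params["Intercept"] + main.params[g_term] + main.params["x"] * xbar
            ),
        }
        out.append(res)
    return out


def ancova_table(results: list[AncovaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "condition": r.condition,
                "response": r.response,
                "covariate": r.covariate,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
                "covariate_ttest_p": r.covariate_ttest_p,
                "interaction_p": r.interaction_p,
                "group_p": r.group_p,
                "common_slope": r.common_slope,
            }
        )
    return pd.DataFrame(rows)


# -- scaling vs stimulus dimension ------------------------------------


def scaling_vs_stimulus_slopes(
    cohort_params: pd.DataFrame,
    vary: str = "prepulse_db",
    min_conditions: int = 3,
) -> dict:
    """Per-animal OLS slopes of alpha and beta against the varied dimension.

    ``vary`` is ``"prepulse_db"`` or ``"delay_ms"``.  Animals with fewer
    than ``min_conditions`` distinct values are skipped with a warning.
    Returns the slope table plus a one-sample t-test (mean slope != 0)
    per scaling parameter.
    """
    if vary not in ("prepulse_db", "delay_ms"):
        raise ValueError("vary must be 'prepulse_db' or 'delay_ms'")
    rows = []
    n_skipped = 0
    for animal, sub in cohort_params.groupby("animal_id"):
        if sub[vary].nunique() < min_conditions:
            n_skipped += 1
            continue
        x = sub[vary].to_numpy(float)
        rows.append(
            {
                "animal_id": animal,
                "alpha_slope": float(np.polyfit(x, sub["alpha"].to_numpy(float), 1)[0]),
                "beta_slope": float(np.polyfit(x, sub["beta"].to_numpy(float), 1)[0]),
                "n_conditions": sub[vary].nunique(),
            }
        )
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} animals with < {min_conditions} conditions "
            f"varying {vary}",
            PpiScaleWarning,
            stacklevel=2,
        )
    slopes = pd.DataFrame(rows)
    tests = {}
    for col in ("alpha_slope", "beta_slope"):
        if len(slopes) >= 2:
            t = stats.ttest_1samp(slopes[col], 0.0)
            tests[col] = {"mean": float(slopes[col].mean()), "p": float(t.pvalue)}
        else:
            tests[col] = {"mean": np.nan, "p": np.nan}
    return {"slopes": slopes, "tests": tests, "varied": vary}
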