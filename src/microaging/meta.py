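"""Two-step inferential engine: per-study robust regression pooled across
studies by random-effects meta-analysis, plus PERMANOVA for beta diversity.

Step one fits a Huber M-estimated linear regression of a microbiome feature
on a covariate within each study and tests the slope with a two-sided robust
(Wald-type) F-test.  Step two pools the per-study slopes with a
DerSimonian-Laird random-effects model:

    w_i  = 1 / v_i                          (fixed-effect weights)
    Q    = sum w_i (y_i - ybar_w)^2         (Cochran heterogeneity)
    tau2 = max(0, (Q - (k-1)) / C),  C = sum w - sum w^2 / sum w
    pooled = sum y_i/(v_i+tau2) / sum 1/(v_i+tau2)

Significance of the pooled effect is assessed both by a z-test and by a
sign-flip permutation test of the study-level estimates; directional
consistency is the fraction of studies whose slope sign matches the pooled
sign.  Multiplicity is controlled by Benjamini-Hochberg (within the scoping
of each analysis) or Bonferroni (network edges).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import ValidationError

__all__ = [
    "EffectEstimate",
    "MetaSummary",
    "RobustFit",
    "robust_linear_fit",
    "robust_f_test",
    "bh_adjust",
    "bonferroni_adjust",
    "random_effects_pool",
    "permutation_test_re",
    "consistency_score",
    "permanova",
]

HUBER_TUNING_DEFAULT = 1.345  # 95% Gaussian efficiency


@dataclass
class EffectEstimate:
    """One study's slope estimate for one feature."""

    feature: str
    study_id: str
    estimate: float
    std_error: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.std_error <= 0:
            raise ValidationError(f"std_error must be positive ({self.feature}/{self.study_id})")
        if self.n < 3:
            raise ValidationError(f"n must be >= 3 ({self.feature}/{self.study_id})")


@dataclass
class MetaSummary:
    """Pooled random-effects summary across studies for one feature."""

    feature: str
    pooled_estimate: float
    tau2: float
    cochran_q: float
    p_value: float  # z-test on the pooled estimate
    k: int
    consistency: float = float("nan")
    p_perm: float = float("nan")
    q_value: float = float("nan")
    se_pooled: float = float("nan")
    study_estimates: dict = field(default_factory=dict)


@dataclass
class RobustFit:
    """A converged Huber M-estimated linear fit (first predictor reported)."""

    estimate: float
    std_error: float
    intercept: float
    n: int
    df_resid: int
    p_value: float
    params: np.ndarray
    bse: np.ndarray
    scale: float


def robust_linear_fit(y, x, tuning: float = HUBER_TUNING_DEFAULT) -> RobustFit:
    """Huber M-estimation of ``y ~ 1 + x`` via iteratively reweighted least
    squares; the slope of the first predictor is reported with a
    sandwich-type standard error and a two-sided robust F-test p-value.

    ``x`` may be a vector or an (n, p) design without intercept column.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.shape[0]
    if n < 3 or X.shape[0] != n:
        raise ValidationError(f"robust fit requires n >= 3 conforming observations, got {n}")
    if np.ptp(X[:, 0]) == 0:
        raise ValidationError("constant predictor")
    if tuning <= 0:
        raise ValidationError("tuning constant must be positive")
    design = sm.add_constant(X, has_constant="add")
    model = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=tuning))
    try:
        res = model.fit(maxiter=100)
    except Exception as exc:
        raise ValidationError(f"robust fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ValidationError("robust fit did not converge to finite coefficients")
    slope = float(res.params[1])
    se = float(res.bse[1])
    df_resid = int(n - design.shape[1])
    if se <= 0 or not math.isfinite(se):
        # zero residual variance: perfect fit; p reported as a lower bound
        se = np.finfo(float).tiny
        p = 0.0
    else:
        f_stat = (slope / se) ** 2
        p = float(stats.f.sf(f_stat, 1, max(df_resid, 1)))
    return RobustFit(
        estimate=slope,
        std_error=se,
        intercept=float(res.params[0]),
        n=n,
        df_resid=df_resid,
        p_value=max(p, np.finfo(float).tiny),
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        scale=float(res.scale),
    )


def robust_f_test(fit: RobustFit, coef: int = 0) -> float:
    """Two-sided robust (Wald-type) F-test of a zero coefficient.

    ``coef`` indexes the non-intercept coefficients (0 = first predictor).
    """
    est = float(fit.params[coef + 1])
    se = float(fit.bse[coef + 1])
    if se <= 0 or not math.isfinite(se):
        return float(np.finfo(float).tiny)
    f_stat = (est / se) ** 2
    return float(max(stats.f.sf(f_stat, 1, max(fit.df_resid, 1)), np.finfo(float).tiny))


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (input order preserved)."""
    p = _check_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p) -> np.ndarray:
    """Bonferroni q = min(1, m * p)."""
    p = _check_p(p)
    return np.minimum(1.0, p * p.size)


def random_effects_pool(effects: list[EffectEstimate]) -> MetaSummary:
    """DerSimonian-Laird random-effects pooling of per-study slopes.

    A single study is passed through unchanged (tau2 = 0).
    """
    if not effects:
        raise ValidationError("no effects to pool")
    feature = effects[0].feature
    y = np.array([e.estimate for e in effects], dtype=float)
    v = np.array([e.std_error**2 for e in effects], dtype=float)
    k = y.size
    study_estimates = {e.study_id: e.estimate for e in effects}
    if k == 1:
        se = math.sqrt(v[0])
        z = y[0] / se
        return MetaSummary(
            feature=feature,
            pooled_estimate=float(y[0]),
            tau2=0.0,
            cochran_q=0.0,
            p_value=float(2 * stats.norm.sf(abs(z))),
            k=1,
            se_pooled=se,
            study_estimates=study_estimates,
        )
    w = 1.0 / v
    ybar = float((w * y).sum() / w.sum())
    q = float((w * (y - ybar) ** 2).sum())
    c = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float((w_star * y).sum() / w_star.sum())
    se_pooled = math.sqrt(1.0 / w_star.sum())
    z = pooled / se_pooled
    return MetaSummary(
        feature=feature,
        pooled_estimate=pooled,
        tau2=tau2,
        cochran_q=q,
        p_value=float(max(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny)),
        k=k,
        se_pooled=se_pooled,
        study_estimates=study_estimates,
    )


def _dl_pooled_vectorised(Y: np.ndarray, v: np.ndarray) -> np.ndarray:
    """DL pooled estimates for each row of Y (shared variances v)."""
    w = 1.0 / v
    sw = w.sum()
    ybar = (Y * w).sum(axis=1) / sw
    q = (w * (Y - ybar[:, None]) ** 2).sum(axis=1)
    c = sw - (w**2).sum() / sw
    k = Y.shape[1]
    tau2 = np.maximum(0.0, (q - (k - 1)) / c) if c > 0 else np.zeros_like(q)
    w_star = 1.0 / (v[None, :] + tau2[:, None])
    return (Y * w_star).sum(axis=1) / w_star.sum(axis=1)


def permutation_test_re(
    effects: list[EffectEstimate], B: int = 999, rng=None
) -> float:
    """Two-sided sign-flip permutation test of the pooled random-effects
    estimate: each permutation flips the sign of each study's slope
    independently and the DL pooled estimate is recomputed.

    p = (1 + #{|pooled*| >= |pooled|}) / (B + 1), bounded below by 1/(B+1).
    """
    if B < 99:
        raise ValidationError("B must be at least 99")
    if len(effects) < 2:
        raise ValidationError("permutation test requires at least 2 studies")
    rng = np.random.default_rng(rng)
    y = np.array([e.estimate for e in effects], dtype=float)
    v = np.array([e.std_error**2 for e in effects], dtype=float)
    observed = abs(_dl_pooled_vectorised(y[None, :], v)[0])
    flips = rng.choice([-1.0, 1.0], size=(B, y.size))
    pooled_star = _dl_pooled_vectorised(flips * y[None, :], v)
    exceed = int((np.abs(pooled_star) >= observed - 1e-15).sum())
    return (1 + exceed) / (B + 1)


def consistency_score(effects: list[EffectEstimate], pooled_sign: float) -> float:
    """Fraction of studies whose slope sign matches the pooled sign.

    Zero study estimates count as non-matching.
    """
    if not effects:
        raise ValidationError("no effects")
    s = np.sign(pooled_sign)
    if s == 0:
        raise ValidationError("pooled sign must be nonzero")
    signs = np.sign([e.estimate for e in effects])
    return float((signs == s).mean())


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _design_from_covariate(covariate) -> tuple[np.ndarray, int]:
    """Centered design columns (no intercept) and model df for a covariate.

    Continuous covariates use the regression form of the sum-of-squares
    decomposition; categorical covariates are dummy-coded.
    """
    cov = np.asarray(covariate)
    if cov.dtype.kind in "fiu" and np.unique(cov).size > max(2, 0):
        X = cov.astype(float)[:, None]
    else:
        levels, codes = np.unique(cov, return_inverse=True)
        if levels.size < 2:
            raise ValidationError("covariate has a single level")
        X = np.zeros((cov.size, levels.size - 1))
        for j in range(1, levels.size):
            X[codes == j, j - 1] = 1.0
    Xc = X - X.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(Xc)
    return Xc, int(rank)


def permanova(dist, covariate, B: int = 999, rng=None) -> tuple[float, float, float]:
    """Permutational multivariate analysis of variance.

    Partitions the Gower-centered inner-product matrix of a distance matrix
    by a covariate (continuous or categorical) and tests the pseudo-F

        F = (SS_model / df_model) / (SS_resid / df_resid)

    by ``B`` free permutations of the covariate.  Returns
    ``(pseudo_F, R2, p_perm)``.
    """
    d = dist.values if hasattr(dist, "values") else np.asarray(dist, dtype=float)
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    cov = np.asarray(covariate)
    if cov.shape[0] != n:
        raise ValidationError("covariate length does not match distance matrix")
    rng = np.random.default_rng(rng)
    G = _gower_center(d)
    ss_total = float(np.trace(G))
    Xc, df_model = _design_from_covariate(cov)
    Q, _ = np.linalg.qr(Xc)
    Q = Q[:, :df_model]
    df_resid = n - df_model - 1
    if df_resid < 1:
        raise ValidationError("permanova requires residual degrees of freedom >= 1")

    def _stat(Qm: np.ndarray) -> float:
        ss_model = float(np.einsum("ij,ik,kj->", Qm, G, Qm))
        ss_resid = ss_total - ss_model
        return (ss_model / df_model) / (ss_resid / df_resid)

    f_obs = _stat(Q)
    ss_model_obs = float(np.einsum("ij,ik,kj->", Q, G, Q))
    r2 = ss_model_obs / ss_total
    perms = np.array([rng.permutation(n) for _ in range(B)])
    # permuting covariate rows == permuting the rows of Q
    stats_perm = np.empty(B)
    for b in range(B):
        stats_perm[b] = _stat(Q[perms[b]])
    p = (1 + int((stats_perm >= f_obs - 1e-15).sum())) / (B + 1)
    return float(f_obs), float(r2), float(p)
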