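"""Per-feature differential-expression models.

Three regressions of (transformed) RNA abundance on the two-level phenotype
are compared throughout the package, differing only in which confounders
they control for:

- DNA+Taxa:  RNA ~ DNA + Taxa + group (+ covariates)
- DNA:       RNA ~ DNA + group (+ covariates)
- Taxa:      RNA ~ Taxa + group (+ covariates)

For longitudinal designs each model optionally carries a per-subject random
intercept. Per feature, a likelihood-ratio test (full ML, 1-df chi-squared)
compares the fixed-only and random-intercept fits; the LRT p-values are
BH-adjusted across features and the mixed model is used where that FDR is
below 0.05. Final mixed fits use REML; the phenotype coefficient is tested
with a t-statistic on Satterthwaite degrees of freedom, and the per-feature
phenotype p-values are BH-adjusted into FDRs.

The mixed model is the Gaussian random-intercept model
``y = X b + Z u + e``, ``u ~ N(0, s_u^2 I)``, ``e ~ N(0, s_e^2 I)``,
estimated by profiling the restricted likelihood over the variance ratio
``lam = s_u^2 / s_e^2``; all per-subject algebra uses the closed-form
inverse ``(I + lam J)^{-1} = I - lam/(1 + n_s lam) J``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import PairedDataset
from .transforms import (
    FeatureView,
    TransformSpec,
    build_feature_view,
    passes_min_obs,
    transform_dataset,
)

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "FixedFit",
    "MixedFit",
    "fit_fixed",
    "fit_mixed",
    "satterthwaite_df",
    "lrt_select",
    "bh_adjust",
    "run_de",
    "MODEL_SPECS",
]

LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which confounders, phenotype and covariates enter the regression."""

    controls: tuple[str, ...] = ("dna", "taxa")
    phenotype: str = "group"
    extra_covariates: tuple[str, ...] = ()
    random_intercept_by: str | None = "subject_id"

    def __post_init__(self) -> None:
        if not self.controls or not set(self.controls) <= {"dna", "taxa"}:
            raise ValueError("controls must be a nonempty subset of {'dna','taxa'}")

    @property
    def name(self) -> str:
        return {"dna": "DNA", "taxa": "Taxa"}.get(
            self.controls[0] if len(self.controls) == 1 else "", "DNA+Taxa"
        )


def model_specs(
    phenotype: str = "group",
    extra_covariates: tuple[str, ...] = (),
    random_intercept_by: str | None = "subject_id",
) -> dict[str, ModelSpec]:
    """The three canonical model specifications keyed by display name."""
    return {
        "DNA+Taxa": ModelSpec(("dna", "taxa"), phenotype, extra_covariates, random_intercept_by),
        "DNA": ModelSpec(("dna",), phenotype, extra_covariates, random_intercept_by),
        "Taxa": ModelSpec(("taxa",), phenotype, extra_covariates, random_intercept_by),
    }


MODEL_SPECS = model_specs()


@dataclass
class VarianceComponents:
    """REML variance components and their estimated covariance.

    ``cov`` is the 2x2 covariance of (sigma_subject_sq, sigma_resid_sq) from
    the curvature of the restricted likelihood; entries are NaN when the
    subject variance sits on the boundary or the curvature is singular.
    """

    sigma_subject_sq: float
    sigma_resid_sq: float
    cov: np.ndarray


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(view: FeatureView, spec: ModelSpec) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix (intercept + controls + phenotype + covariates), names, y."""
    n = view.n_samples
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    if "dna" in spec.controls:
        cols["dna"] = view.dna
    if "taxa" in spec.controls:
        cols["taxa"] = view.taxa
    ph = view.meta[spec.phenotype].astype(str)
    levels = sorted(ph.unique())
    if len(levels) != 2:
        raise ValueError(f"phenotype {spec.phenotype!r} must have exactly two levels, got {levels}")
    # reference level = lexicographically first; coefficient is the second level's shift
    cols[spec.phenotype] = (ph == levels[1]).to_numpy(dtype=float)
    for cov in spec.extra_covariates:
        v = view.meta[cov]
        if v.dtype == bool:
            cols[cov] = v.to_numpy(dtype=float)
        elif v.dtype == object or str(v.dtype) == "category":
            lv = sorted(v.astype(str).unique())
            if len(lv) > 2:
                raise ValueError(f"covariate {cov!r} has more than two levels")
            cols[cov] = (v.astype(str) == lv[-1]).to_numpy(dtype=float)
        else:
            cols[cov] = v.to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols), np.asarray(view.rna, dtype=float)


# ---------------------------------------------------------------------------
# fixed-effects fit
# ---------------------------------------------------------------------------

@dataclass
class FixedFit:
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2: float          # residual variance, RSS / (n - p)
    df_resid: float
    loglik_ml: float
    rss: float
    n: int
    p: int

    def t_test(self, name: str) -> tuple[float, float, float, float]:
        """(estimate, se, t, p) for one coefficient on n - p residual df."""
        b = float(self.params[name])
        se = float(np.sqrt(self.cov_params.loc[name, name]))
        t = b / se if se > 0 else np.inf * np.sign(b)
        pval = 2.0 * stats.t.sf(abs(t), self.df_resid)
        return b, se, t, pval


def fit_fixed(view: FeatureView, spec: ModelSpec) -> FixedFit:
    """Ordinary least squares with the exact normal-equations solution."""
    X, names, y = build_design(view, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} observations cannot fit {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    sigma2_ml = max(rss / n, 1e-300)
    loglik_ml = -0.5 * n * (LOG2PI + np.log(sigma2_ml) + 1.0)
    cov = sigma2 * np.linalg.inv(XtX)
    return FixedFit(
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        sigma2=sigma2,
        df_resid=float(n - p),
        loglik_ml=loglik_ml,
        rss=rss,
        n=n,
        p=p,
    )


# ---------------------------------------------------------------------------
# random-intercept mixed model (profiled REML)
# ---------------------------------------------------------------------------

@dataclass
class _Suff:
    """Sufficient statistics for the random-intercept likelihood."""

    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    Sx: np.ndarray   # per-subject column sums of X, shape (S, p)
    Sy: np.ndarray   # per-subject sums of y, shape (S,)
    ns: np.ndarray   # per-subject sample counts, shape (S,)
    n: int
    p: int


def _make_suff(X: np.ndarray, y: np.ndarray, codes: np.ndarray) -> _Suff:
    n, p = X.shape
    S = codes.max() + 1
    Sx = np.zeros((S, p))
    np.add.at(Sx, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=S)
    ns = np.bincount(codes, minlength=S)
    return _Suff(X.T @ X, X.T @ y, float(y @ y), Sx, Sy, ns.astype(float), n, p)


def _gls(suff: _Suff, lam: float):
    """GLS pieces at variance ratio lam: beta, rss (= r'V0^-1 r), logdetV0, XtViX."""
    w = lam / (1.0 + suff.ns * lam) if lam > 0 else np.zeros_like(suff.ns)
    XtViX = suff.XtX - (suff.Sx * w[:, None]).T @ suff.Sx
    XtViy = suff.Xty - suff.Sx.T @ (w * suff.Sy)
    yViy = suff.yty - float(w @ (suff.Sy**2))
    beta = np.linalg.solve(XtViX, XtViy)
    rss = max(yViy - float(beta @ XtViy), 0.0)
    logdetV0 = float(np.log1p(suff.ns * lam).sum())
    return beta, rss, logdetV0, XtViX


def _profiled_reml(suff: _Suff, lam: float) -> float:
    _, rss, logdetV0, XtViX = _gls(suff, lam)
    dfr = suff.n - suff.p
    se2 = max(rss / dfr, 1e-300)
    sign, sld = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    # log|V| and log|X'V^-1 X| contribute (n - p) log se2 in total
    return -0.5 * (dfr * (LOG2PI + np.log(se2) + 1.0) + logdetV0 + sld)


def _profiled_ml(suff: _Suff, lam: float) -> float:
    _, rss, logdetV0, _ = _gls(suff, lam)
    se2 = max(rss / suff.n, 1e-300)
    return -0.5 * (suff.n * (LOG2PI + np.log(se2) + 1.0) + logdetV0)


def restricted_loglik(suff: _Suff, sigma_subject_sq: float, sigma_resid_sq: float) -> float:
    """Restricted log-likelihood at arbitrary (non-profiled) variance components."""
    se2 = sigma_resid_sq
    if se2 <= 0:
        return -np.inf
    lam = max(sigma_subject_sq, 0.0) / se2
    _, rss, logdetV0, XtViX = _gls(suff, lam)
    sign, sld = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    dfr = suff.n - suff.p
    return -0.5 * (
        dfr * LOG2PI + (suff.n - suff.p) * np.log(se2) + logdetV0 + sld + rss / se2
    )


_LAM_GRID = np.concatenate([[0.0], np.logspace(-4, 3, 29)])


def _optimize_lambda(suff: _Suff, objective) -> float:
    vals = np.array([objective(suff, l) for l in _LAM_GRID])
    i = int(np.argmax(vals))
    best_lam, best_val = float(_LAM_GRID[i]), float(vals[i])
    lo = _LAM_GRID[max(i - 1, 0)]
    hi = _LAM_GRID[i + 1] if i + 1 < len(_LAM_GRID) else _LAM_GRID[-1] * 10.0
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: -objective(suff, l), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if np.isfinite(res.fun) and -res.fun > best_val:
            best_lam, best_val = float(res.x), float(-res.fun)
    # collapse to the boundary when it is essentially as good (flat profiles)
    if objective(suff, 0.0) >= best_val - 1e-8:
        best_lam = 0.0
    return best_lam


@dataclass
class MixedFit:
    params: pd.Series
    cov_params: pd.DataFrame
    vc: VarianceComponents
    loglik_reml: float
    loglik_ml: float
    converged: bool
    n: int
    p: int
    suff: _Suff = field(repr=False)
    names: list[str] = field(repr=False, default_factory=list)

    @property
    def df_resid(self) -> float:
        return float(self.n - self.p)


def _vc_covariance(suff: _Suff, sb2: float, se2: float) -> np.ndarray:
    """Covariance of the REML variance components from the observed curvature."""
    if sb2 < 1e-10 * se2:
        return np.full((2, 2), np.nan)
    theta = np.array([sb2, se2])
    h = 1e-4 * np.maximum(theta, 1e-3 * se2)

    def f(t):
        return restricted_loglik(suff, t[0], t[1])

    H = np.empty((2, 2))
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2.0 * f(theta) + f(theta - ei)) / h[i] ** 2
    ei = np.array([h[0], 0.0])
    ej = np.array([0.0, h[1]])
    H[0, 1] = H[1, 0] = (
        f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
    ) / (4.0 * h[0] * h[1])
    if not np.isfinite(H).all():
        return np.full((2, 2), np.nan)
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.full((2, 2), np.nan)
    if A[0, 0] <= 0 or A[1, 1] <= 0:
        return np.full((2, 2), np.nan)
    return A


def fit_mixed(view: FeatureView, spec: ModelSpec) -> MixedFit:
    """REML fit of the per-subject random-intercept model.

    The restricted likelihood is profiled over the variance ratio (grid scan
    plus bounded refinement); the full-ML log-likelihood at the ML optimum is
    also reported for likelihood-ratio use. A boundary estimate
    ``sigma_subject_sq = 0`` is allowed and degenerates to OLS.
    """
    if spec.random_intercept_by is None:
        raise ValueError("ModelSpec has no random_intercept_by grouping")
    X, names, y = build_design(view, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} observations cannot fit {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    subj = view.meta[spec.random_intercept_by].astype(str)
    codes = pd.Categorical(subj).codes.astype(int)
    if codes.max() == 0:
        raise ValueError("only a single subject: random intercept unidentifiable")
    suff = _make_suff(X, y, codes)

    lam = _optimize_lambda(suff, _profiled_reml)
    beta, rss, _, XtViX = _gls(suff, lam)
    se2 = rss / (n - p)
    converged = bool(np.isfinite(se2) and se2 > 1e-12)
    se2 = max(se2, 1e-12)
    sb2 = lam * se2

    lam_ml = _optimize_lambda(suff, _profiled_ml)
    loglik_ml = _profiled_ml(suff, lam_ml)
    loglik_reml = _profiled_reml(suff, lam)

    cov_vc = _vc_covariance(suff, sb2, se2) if converged else np.full((2, 2), np.nan)
    cov_beta = se2 * np.linalg.inv(XtViX)
    return MixedFit(
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
        vc=VarianceComponents(sb2, se2, cov_vc),
        loglik_reml=loglik_reml,
        loglik_ml=loglik_ml,
        converged=converged,
        n=n,
        p=p,
        suff=suff,
        names=names,
    )


# ---------------------------------------------------------------------------
# Satterthwaite degrees of freedom
# ---------------------------------------------------------------------------

def satterthwaite_df(fit: MixedFit, name: str) -> tuple[float, bool]:
    """Satterthwaite effective degrees of freedom for one fixed effect.

    ``df = 2 v^2 / Var(v)`` where ``v`` is the sampling variance of the
    coefficient and ``Var(v)`` comes from the delta method: the gradient of
    ``v`` with respect to the two variance components, sandwiched with their
    REML covariance. Falls back to the residual df ``n - p`` (second return
    value True) when the subject variance is on the boundary or the
    curvature is singular.
    """
    c = fit.names.index(name)
    suff = fit.suff
    theta = np.array([fit.vc.sigma_subject_sq, fit.vc.sigma_resid_sq])
    A = fit.vc.cov
    fallback = (np.isnan(A).any(), fit.df_resid)
    if fallback[0]:
        return fallback[1], True

    def v(t):
        lam = max(t[0], 0.0) / t[1]
        _, _, _, XtViX = _gls(suff, lam)
        return t[1] * np.linalg.inv(XtViX)[c, c]

    v0 = v(theta)
    h = 1e-5 * np.maximum(theta, 1e-3 * theta[1])
    g = np.empty(2)
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        if theta[i] - h[i] > 0:
            g[i] = (v(theta + ei) - v(theta - ei)) / (2.0 * h[i])
        else:
            g[i] = (v(theta + ei) - v0) / h[i]
    var_v = float(g @ A @ g)
    if not np.isfinite(var_v) or var_v <= 0:
        return fit.df_resid, True
    df = 2.0 * v0**2 / var_v
    if not np.isfinite(df) or df <= 0:
        return fit.df_resid, True
    return float(df), False


# ---------------------------------------------------------------------------
# model selection and multiple testing
# ---------------------------------------------------------------------------

def lrt_select(view: FeatureView, spec: ModelSpec) -> tuple[float, FixedFit, MixedFit | None]:
    """Likelihood-ratio comparison of fixed-only vs random-intercept fits.

    The statistic ``2 (logL_mixed - logL_fixed)`` uses full-ML likelihoods
    and is floored at 0; the p-value is asymptotic chi-squared with 1 df.
    A non-convergent mixed fit yields p = 1 (the fixed model is kept).
    """
    fixed = fit_fixed(view, spec)
    try:
        mixed = fit_mixed(view, spec)
    except (ValueError, np.linalg.LinAlgError):
        return 1.0, fixed, None
    if not mixed.converged:
        return 1.0, fixed, mixed
    stat = max(2.0 * (mixed.loglik_ml - fixed.loglik_ml), 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return p, fixed, mixed


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR).

    Sort ascending, take ``q_i = min_{j>=i} p_j m / j`` clipped at 1, and
    return in the original order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# cohort-level differential-expression run
# ---------------------------------------------------------------------------

def run_de(
    data: PairedDataset,
    spec: ModelSpec,
    transform: TransformSpec | None = None,
    min_per_group: int = 10,
    lrt_alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression analysis of every eligible feature.

    Per feature: build the filtered view, require ``min_per_group``
    observations in both phenotype groups, run the LRT; after all features,
    BH-adjust the LRT p-values and refit with the mixed model where that FDR
    is strictly below ``lrt_alpha`` (ties at the threshold stay fixed-only),
    else the fixed model; test the phenotype coefficient (Satterthwaite t
    for mixed, residual-df t for fixed); BH-adjust the phenotype p-values
    into FDRs.

    Returns a DataFrame indexed by feature with columns ``model_used, beta,
    se, df, t, p, fdr, n_obs, converged``; the number of filtered-out
    features is in ``result.attrs['skipped']``.
    """
    transform = transform or TransformSpec()
    transformed = transform_dataset(data, transform)
    use_mixed_path = spec.random_intercept_by is not None

    views: dict[str, FeatureView] = {}
    lrt_ps: dict[str, float] = {}
    fits: dict[str, tuple[FixedFit, MixedFit | None]] = {}
    skipped = 0
    for feature in data.features:
        view = build_feature_view(data, transform, feature, transformed=transformed)
        try:
            if not passes_min_obs(view, spec.phenotype, min_per_group):
                skipped += 1
                continue
        except ValueError:
            skipped += 1
            continue
        try:
            if use_mixed_path:
                lrt_p, fixed, mixed = lrt_select(view, spec)
            else:
                lrt_p, fixed, mixed = 1.0, fit_fixed(view, spec), None
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
            continue
        views[feature] = view
        lrt_ps[feature] = lrt_p
        fits[feature] = (fixed, mixed)

    features = list(views)
    if not features:
        import warnings

        warnings.warn("no eligible features for differential analysis")
        out = pd.DataFrame(
            columns=["model_used", "beta", "se", "df", "t", "p", "fdr", "n_obs", "converged"]
        )
        out.attrs["skipped"] = skipped
        return out

    lrt_fdr = bh_adjust(np.array([lrt_ps[f] for f in features]))
    rows = []
    for feature, lfdr in zip(features, lrt_fdr):
        fixed, mixed = fits[feature]
        use_mixed = use_mixed_path and lfdr < lrt_alpha and mixed is not None and mixed.converged
        if use_mixed:
            b = float(mixed.params[spec.phenotype])
            se = float(np.sqrt(mixed.cov_params.loc[spec.phenotype, spec.phenotype]))
            df, fell_back = satterthwaite_df(mixed, spec.phenotype)
            t = b / se if se > 0 else np.sign(b) * np.inf
            pval = 2.0 * stats.t.sf(abs(t), df)
            rows.append((feature, "mixed", b, se, df, t, pval, len(views[feature].rna), True))
        else:
            b, se, t, pval = fixed.t_test(spec.phenotype)
            converged = not (use_mixed_path and mixed is not None and not mixed.converged)
            rows.append(
                (feature, "fixed_only", b, se, fixed.df_resid, t, pval,
                 len(views[feature].rna), converged)
            )
    out = pd.DataFrame(
        rows,
        columns=["feature", "model_used", "beta", "se", "df", "t", "p", "n_obs", "converged"],
    ).set_index("feature")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out = out[["model_used", "beta", "se", "df", "t", "p", "fdr", "n_obs", "converged"]]
    out.attrs["skipped"] = skipped
    return out
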