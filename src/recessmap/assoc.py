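"""Per-SNP association testing under additive and recessive genotype codings.

Discovery p values come from a linear mixed model (LMM) with a genetic
similarity matrix as random-effect covariance, which absorbs both
admixture and family relatedness; odds ratios come from covariate-adjusted
logistic regression.  The module also provides GRM and principal-component
construction, the genomic-inflation diagnostic and the study-wide
Bonferroni threshold.

The LMM is the standard single-variance-component model
y = X b + u + e,  u ~ N(0, sg^2 K),  e ~ N(0, se^2 I).
A one-time eigendecomposition K = U S U' rotates the model to independent
observations with variances se^2 (lambda s_i + 1), where
lambda = sg^2/se^2 is the variance ratio; lambda is estimated by REML via
1-D optimisation on a log scale over [1e-5, 1e5], and the fixed effects by
generalised least squares at the optimum.  Binary case-control status is
analysed as a 0/1 quantitative outcome, the standard practice of
mixed-model GWAS software (documented caveat: effect sizes from this fit
are on the risk-difference scale, which is why odds ratios are taken from
logistic regression instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .simulate import GenotypeMatrix

__all__ = [
    "GRM",
    "AssociationResult",
    "LMMFit",
    "LinearMixedModel",
    "encode_genotype",
    "compute_grm",
    "compute_pcs",
    "logistic_assoc",
    "lmm_fit_null",
    "lmm_assoc",
    "lmm_scan",
    "genomic_inflation",
    "bonferroni_threshold",
    "genotype_stratified_frequency",
]

_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549364...


@dataclass
class GRM:
    matrix: np.ndarray
    n_snps_used: int


@dataclass
class AssociationResult:
    snp_id: str
    model: str
    beta: float
    se: float
    p_value: float
    odds_ratio: float = np.nan
    beta_sd: float = np.nan
    n_used: int = 0
    n_homozygous: int = 0
    estimable: bool = True
    note: str = ""


@dataclass
class LMMFit:
    variance_ratio: float
    log_likelihood: float
    beta: np.ndarray
    se: np.ndarray
    sigma2: float


def _as_kinship(K) -> np.ndarray:
    return np.asarray(getattr(K, "matrix", K), dtype=float)


def encode_genotype(dosage, model: str):
    """Genotype regressor under the named inheritance model.

    additive: the 0/1/2 dosage itself.  recessive: 1 for homozygous
    effect-allele carriers (dosage 2), 0 otherwise.  Missing stays missing.
    """
    g = np.asarray(dosage, dtype=float)
    ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
    if not np.all(ok):
        raise ValueError("dosages must be 0, 1, 2 or missing")
    if model == "additive":
        out = g.copy()
    elif model == "recessive":
        out = np.where(np.isnan(g), np.nan, (g == 2.0).astype(float))
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    return float(out) if out.ndim == 0 else out


def _imputed_centered(dosages: np.ndarray):
    X = np.array(dosages, dtype=float)
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    return X - mu, mu


def compute_grm(G, scale: str = "centered") -> GRM:
    """Genetic similarity matrix from mean-imputed, centered dosages.

    ``centered`` (default): K = Xc Xc' / m.  ``standardized``: columns are
    additionally divided by their standard deviation before the
    cross-product, giving a mean diagonal near 1.  Monomorphic SNPs carry
    no information and are dropped.
    """
    dos = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    n, m = dos.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    Xc, _ = _imputed_centered(dos)
    sd = Xc.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("no informative SNPs: all sites are monomorphic")
    Xc = Xc[:, keep]
    if scale == "standardized":
        Xc = Xc / sd[keep]
    elif scale != "centered":
        raise ValueError(f"unknown GRM scale {scale!r}")
    K = Xc @ Xc.T / Xc.shape[1]
    K = (K + K.T) / 2.0
    return GRM(matrix=K, n_snps_used=int(keep.sum()))


def compute_pcs(G, k: int) -> np.ndarray:
    """Top-k principal-component scores of the standardized genotype matrix.

    Mean-imputed, centered, unit-variance columns; scores are the left
    singular vectors scaled by their singular values.  Sign convention:
    the largest-magnitude loading of each component is positive.
    """
    dos = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    n, m = dos.shape
    if k >= min(n, m):
        raise ValueError(f"k must be < min(n, m) = {min(n, m)}")
    if k == 0:
        return np.empty((n, 0))
    Xc, _ = _imputed_centered(dos)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = Xc / sd
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            U[:, j] *= -1
            Vt[j] *= -1
    return U[:, :k] * s[:k]


def _design(x, covars, n):
    cols = [np.ones(n), np.asarray(x, dtype=float)]
    if covars is not None:
        C = np.asarray(covars, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    return np.column_stack(cols)


def logistic_assoc(status, x, covars=None, snp_id="", model="") -> AssociationResult:
    """Covariate-adjusted ML logistic regression of disease on the encoded
    genotype; two-sided Wald p; OR = exp(beta).

    Rows with any missing value are excluded case-wise.  Perfect
    separation or a constant regressor yields a flagged non-estimable
    result rather than an exception.
    """
    y = np.asarray(status, dtype=float)
    X = _design(x, covars, y.size)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    n_used = int(y.size)
    xg = X[:, 1]
    n_hom = int(np.sum(xg == np.nanmax(xg))) if n_used else 0
    if model == "recessive":
        n_hom = int(np.sum(xg == 1.0))
    elif model == "additive":
        n_hom = int(np.sum(xg == 2.0))
    base = dict(snp_id=snp_id, model=model, n_used=n_used, n_homozygous=n_hom)
    if n_used == 0 or y.sum() == 0 or y.sum() == n_used:
        return AssociationResult(beta=np.nan, se=np.nan, p_value=np.nan,
                                 estimable=False, note="no cases or no controls",
                                 **base)
    if np.ptp(xg) == 0:
        return AssociationResult(beta=np.nan, se=np.nan, p_value=np.nan,
                                 estimable=False, note="constant genotype", **base)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # noqa: BLE001 - separation / singular designs
            return AssociationResult(beta=np.nan, se=np.nan, p_value=np.nan,
                                     estimable=False, note=str(exc), **base)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or se == 0 or abs(beta) > 30:
        return AssociationResult(beta=np.nan, se=np.nan, p_value=np.nan,
                                 estimable=False, note="separation", **base)
    z2 = (beta / se) ** 2
    return AssociationResult(beta=beta, se=se,
                             p_value=float(stats.chi2.sf(z2, 1)),
                             odds_ratio=float(np.exp(beta)), **base)


class LinearMixedModel:
    """Single-variance-component LMM estimated by REML.

    Parameters
    ----------
    kinship : (n, n) array or GRM
        Random-effect covariance structure (genetic similarity matrix).
    ratio_bounds : pair of floats
        Search interval for the genetic/residual variance ratio.
    tol : float
        Absolute tolerance of the 1-D log-scale optimisation.

    After ``fit(X, y)`` (X = fixed-effect design WITHOUT intercept; one is
    added) the fitted attributes are ``variance_ratio_``, ``beta_``,
    ``se_``, ``sigma2_`` (residual variance) and ``log_likelihood_``
    (restricted log likelihood).
    """

    def __init__(self, kinship, ratio_bounds=(1e-5, 1e5), tol=1e-6,
                 add_intercept=True):
        self.kinship = kinship
        self.ratio_bounds = ratio_bounds
        self.tol = tol
        self.add_intercept = add_intercept

    def get_params(self, deep=True):
        return {"kinship": self.kinship, "ratio_bounds": self.ratio_bounds,
                "tol": self.tol, "add_intercept": self.add_intercept}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals -----------------------------------------------------
    def _decompose(self, K):
        s, U = np.linalg.eigh(K)
        if s.min() < -1e-8 * max(1.0, abs(s.max())):
            raise np.linalg.LinAlgError(
                f"kinship matrix is not PSD (min eigenvalue {s.min():.3g})"
            )
        return np.clip(s, 0.0, None), U

    @staticmethod
    def _reml(lam, s, yt, Xt):
        """Restricted log likelihood (up to an additive constant) and the
        GLS quantities at variance ratio lam."""
        d = lam * s + 1.0
        w = 1.0 / d
        XtW = Xt * w[:, None]
        A = XtW.T @ Xt
        b = XtW.T @ yt
        try:
            cf = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return -np.inf, None, None, None
        beta = np.linalg.solve(cf.T, np.linalg.solve(cf, b))
        r = yt - Xt @ beta
        rss = float(r @ (w * r))
        n, p = Xt.shape
        if rss <= 0:
            return -np.inf, None, None, None
        sigma2 = rss / (n - p)
        logdetA = 2.0 * np.sum(np.log(np.diag(cf)))
        ll = -0.5 * (
            (n - p) * np.log(2.0 * np.pi * sigma2)
            + np.sum(np.log(d))
            + logdetA
            + (n - p)
        )
        return ll, beta, sigma2, A

    def fit(self, X, y, variance_ratio=None):
        K = _as_kinship(self.kinship)
        y = np.asarray(y, dtype=float)
        n = y.size
        if X is None:
            X = np.empty((n, 0))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.add_intercept:
            X = np.column_stack([np.ones(n), X])
        if K.shape != (n, n):
            raise ValueError(f"kinship is {K.shape}, expected ({n}, {n})")
        s, U = self._decompose(K)
        yt = U.T @ y
        Xt = U.T @ X
        lo, hi = self.ratio_bounds
        if variance_ratio is None:
            obj = lambda t: -self._reml(np.exp(t), s, yt, Xt)[0]
            res = optimize.minimize_scalar(
                obj, bounds=(np.log(lo), np.log(hi)), method="bounded",
                options={"xatol": self.tol},
            )
            candidates = [np.exp(res.x), lo, hi, 0.0]
            lam = max(candidates, key=lambda L: self._reml(L, s, yt, Xt)[0])
        else:
            lam = float(variance_ratio)
        ll, beta, sigma2, A = self._reml(lam, s, yt, Xt)
        if beta is None:
            raise np.linalg.LinAlgError("singular fixed-effect design")
        cov = sigma2 * np.linalg.inv(A)
        self.variance_ratio_ = float(lam)
        self.beta_ = beta
        self.se_ = np.sqrt(np.diag(cov))
        self.sigma2_ = float(sigma2)
        self.log_likelihood_ = float(ll)
        self._eig_ = (s, U)
        self.n_features_in_ = X.shape[1] - int(self.add_intercept)
        return self

    def predict(self, X=None):
        """Fixed-effect linear predictor at the fitted coefficients."""
        n = len(self._eig_[1])
        if X is None:
            X = np.empty((n, 0))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.add_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X @ self.beta_


def lmm_fit_null(y, covars, K) -> LMMFit:
    """REML fit of the covariates-only (null) mixed model."""
    mdl = LinearMixedModel(K).fit(covars, y)
    return LMMFit(variance_ratio=mdl.variance_ratio_,
                  log_likelihood=mdl.log_likelihood_,
                  beta=mdl.beta_, se=mdl.se_, sigma2=mdl.sigma2_)


def lmm_assoc(y, x, covars=None, K=None, snp_id="", model="",
              variance_ratio=None, trait_is_sd=False) -> AssociationResult:
    """Wald test of one encoded genotype in the mixed model.

    The variance ratio is re-optimised with the SNP in the model (exact
    profile) unless ``variance_ratio`` forces a plug-in value.  Rows with
    missing y/x/covariates are dropped case-wise and the kinship matrix is
    subset accordingly.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    C = None
    if covars is not None:
        C = np.asarray(covars, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = np.isfinite(y) & np.isfinite(x)
    if C is not None:
        keep &= np.all(np.isfinite(C), axis=1)
    Km = _as_kinship(K)
    ys, xs = y[keep], x[keep]
    Cs = C[keep] if C is not None else None
    Ks = Km[np.ix_(keep, keep)]
    n_used = int(keep.sum())
    n_hom = int(np.sum(xs == (1.0 if model == "recessive" else 2.0)))
    base = dict(snp_id=snp_id, model=model, n_used=n_used, n_homozygous=n_hom)
    if n_used < 3 or np.ptp(xs) == 0:
        return AssociationResult(beta=np.nan, se=np.nan, p_value=np.nan,
                                 estimable=False, note="constant genotype", **base)
    design = xs[:, None] if Cs is None else np.column_stack([xs, Cs])
    mdl = LinearMixedModel(Ks).fit(design, ys, variance_ratio=variance_ratio)
    beta, se = float(mdl.beta_[1]), float(mdl.se_[1])
    z2 = (beta / se) ** 2
    res = AssociationResult(beta=beta, se=se,
                            p_value=float(stats.chi2.sf(z2, 1)), **base)
    if trait_is_sd:
        res.beta_sd = beta
    return res


def lmm_scan(y, G, covars=None, K=None, model="recessive",
             variance_ratio=None) -> pd.DataFrame:
    """Batch mixed-model scan over all SNPs of a genotype matrix.

    Uses the null-model plug-in variance ratio (estimated once, unless
    supplied) and vectorised per-SNP generalised least squares in the
    rotated space.  Missing dosages are mean-imputed for this batch path;
    use :func:`lmm_assoc` for exact case-wise handling at single SNPs.
    """
    gm = G if isinstance(G, GenotypeMatrix) else GenotypeMatrix(np.asarray(G, float))
    y = np.asarray(y, dtype=float)
    n, m = gm.dosages.shape
    Km = _as_kinship(K)
    Xc, mu = _imputed_centered(gm.dosages)
    dos = Xc + mu  # mean-imputed dosages
    if model == "recessive":
        Xg = (dos >= 1.5).astype(float)  # imputed values round to carrier status
        n_hom = (gm.dosages == 2.0).sum(axis=0)
    elif model == "additive":
        Xg = dos
        n_hom = (gm.dosages == 2.0).sum(axis=0)
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    C = np.ones((n, 1))
    if covars is not None:
        cc = np.asarray(covars, dtype=float)
        if cc.ndim == 1:
            cc = cc[:, None]
        C = np.column_stack([C, cc])
    if variance_ratio is None:
        null = lmm_fit_null(y, C[:, 1:] if C.shape[1] > 1 else None, Km)
        variance_ratio = null.variance_ratio
    s, U = np.linalg.eigh(Km)
    s = np.clip(s, 0.0, None)
    w = 1.0 / (variance_ratio * s + 1.0)
    yt = U.T @ y
    Ct = U.T @ C
    Gt = U.T @ Xg
    CtW = Ct * w[:, None]
    A = CtW.T @ Ct
    Ainv = np.linalg.inv(A)
    cy = CtW.T @ yt
    cg = CtW.T @ Gt                       # (p, m)
    Syy = float(yt @ (w * yt)) - cy @ Ainv @ cy
    Sgg = np.einsum("im,im->m", Gt, Gt * w[:, None]) - np.einsum(
        "pm,pq,qm->m", cg, Ainv, cg)
    Sgy = Gt.T @ (w * yt) - cg.T @ (Ainv @ cy)
    p_fixed = C.shape[1]
    dof = n - p_fixed - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = Sgy / Sgg
        sigma2 = (Syy - beta * Sgy) / dof
        se = np.sqrt(sigma2 / Sgg)
        z2 = (beta / se) ** 2
    pvals = np.where(np.isfinite(z2), stats.chi2.sf(z2, 1), np.nan)
    return pd.DataFrame({
        "snp_id": gm.snp_ids,
        "model": model,
        "beta": beta,
        "se": se,
        "p": pvals,
        "n_used": int(n),
        "n_hom": n_hom.astype(int),
        "variance_ratio": variance_ratio,
    })


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median chi2_1 quantile of the p values
    divided by the null median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Study-wide per-test significance threshold family_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    return family_alpha / n_tests


def genotype_stratified_frequency(status, dosages) -> pd.DataFrame:
    """Disease frequency within each genotype class (dosage 0/1/2).

    Returns a table with count, n_cases, frequency and binomial SE per
    class; empty classes report a missing frequency.
    """
    y = np.asarray(status, dtype=float)
    g = np.asarray(dosages, dtype=float)
    ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValueError("dosages must be 0, 1, 2 or missing")
    rows = []
    for x in (0.0, 1.0, 2.0):
        sel = g == x
        n = int(sel.sum())
        cases = int(np.nansum(y[sel]))
        if n == 0:
            rows.append((int(x), 0, 0, np.nan, np.nan))
        else:
            f = cases / n
            rows.append((int(x), n, cases, f, np.sqrt(f * (1 - f) / n)))
    return pd.DataFrame(
        rows, columns=["dosage", "n", "n_cases", "frequency", "se"]
    )
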