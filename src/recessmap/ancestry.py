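"""Ancestry-component allele-frequency estimation in an admixed cohort.

Two-step estimator:

1. Per-individual ancestry proportions Q (K = 2: an Inuit-like and a
   European-like component) are estimated by EM on the binomial admixture
   likelihood  L = prod_ij Binom(g_ij | 2, sum_k Q_ik F_jk), optionally
   with anchor individuals of known ancestry clamped (supervised mode).
2. Per SNP, the ancestral frequencies f are re-estimated by maximum
   likelihood with Q held fixed, and confidence intervals come from
   bootstrap resampling of individuals (dosage rows and matching Q rows
   jointly) with replacement — 1000 replicates and (0.025, 0.975)
   empirical quantiles by default.

A component whose total ancestry mass sum_i Q_ik is below one
individual-equivalent is flagged non-identifiable (NaN) rather than
estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import AncestryModel, GenotypeMatrix

__all__ = [
    "AncestralFreqEstimate",
    "AdmixtureEM",
    "admixture_em",
    "fixed_q_mle",
    "bootstrap_ci",
    "estimate_component_eaf_table",
    "align_components",
]

_P_EPS = 1e-12
_MIN_MASS = 1.0  # individual-equivalents required for identifiability


@dataclass
class AncestralFreqEstimate:
    snp_id: str
    f_hat: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    B: int
    n_boot_valid: np.ndarray = None
    pooled_eaf: float = np.nan


def _dosage_array(G):
    return G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)


def _loglik(g, mask, P):
    P = np.clip(P, _P_EPS, 1.0 - _P_EPS)
    g0 = np.where(mask, g, 0.0)
    return float(np.sum(np.where(mask, g0 * np.log(P) + (2.0 - g0) * np.log1p(-P), 0.0)))


class AdmixtureEM:
    """EM estimator of admixture proportions and ancestral frequencies.

    Parameters
    ----------
    n_components : int
        Number of ancestral populations K (K = 1 reduces to per-SNP sample
        frequencies; K = 2 is the two-way admixture setting).
    tol : float
        Convergence when the log-likelihood gain per iteration drops below
        this value.
    anchors, anchor_Q : optional
        Indices of individuals with known ancestry and their fixed Q rows
        (supervised mode); the rows are clamped after every update, which
        also pins the component labels.

    Fitted attributes: ``Q_`` (n, K), ``F_`` (m, K),
    ``log_likelihoods_`` (per iteration), ``converged_``, ``n_iter_``.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-4,
                 max_iter: int = 2000, seed=None, anchors=None, anchor_Q=None,
                 accelerate: bool = True):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.anchors = anchors
        self.anchor_Q = anchor_Q
        self.accelerate = accelerate

    def get_params(self, deep=True):
        return {"n_components": self.n_components, "tol": self.tol,
                "max_iter": self.max_iter, "seed": self.seed,
                "anchors": self.anchors, "anchor_Q": self.anchor_Q,
                "accelerate": self.accelerate}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, G):
        g = _dosage_array(G)
        n, m = g.shape
        K = self.n_components
        if K < 1:
            raise ValueError("n_components must be >= 1")
        mask = np.isfinite(g)
        if not mask.any(axis=0).all():
            raise ValueError("at least one SNP is entirely missing")
        gz = np.where(mask, g, 0.0)
        if K == 1:
            # single-population MLE: per-SNP sample frequency, exactly
            self.Q_ = np.ones((n, 1))
            with np.errstate(invalid="ignore"):
                self.F_ = (gz.sum(axis=0) / (2.0 * mask.sum(axis=0)))[:, None]
            self.log_likelihoods_ = [_loglik(g, mask, (self.Q_ @ self.F_.T))]
            self.converged_ = True
            self.n_iter_ = 0
            return self
        rng = np.random.default_rng(self.seed)
        Q = rng.dirichlet(np.ones(K), size=n)
        base = gz.sum(axis=0) / (2.0 * mask.sum(axis=0))
        F = np.clip(base[:, None] + rng.uniform(-0.1, 0.1, size=(m, K)), 0.01, 0.99)
        anchors = None
        if self.anchors is not None:
            anchors = np.asarray(self.anchors, dtype=int)
            aQ = np.asarray(self.anchor_Q, dtype=float)
            if aQ.shape != (anchors.size, K):
                raise ValueError("anchor_Q must be (len(anchors), K)")
            Q[anchors] = aQ
        obs_per_ind = 2.0 * mask.sum(axis=1)

        def project(Q, F):
            Q = np.clip(Q, 0.0, None)
            Q = Q / Q.sum(axis=1, keepdims=True)
            F = np.clip(F, _P_EPS, 1.0 - _P_EPS)
            if anchors is not None:
                Q[anchors] = aQ
            return Q, F

        def em_step(Q, F):
            # the E-step responsibilities factor as rank-1 products, so the
            # row/column sums reduce to matrix products (no n*m*K arrays):
            #   sum_j g_ij q_ik f_jk / p_ij      = q_ik (R1 F)_ik
            #   sum_i g_ij q_ik f_jk / p_ij      = f_jk (R1' Q)_jk
            P = np.clip(Q @ F.T, _P_EPS, 1.0 - _P_EPS)
            R1 = np.where(mask, gz / P, 0.0)
            R0 = np.where(mask, (2.0 - gz) / (1.0 - P), 0.0)
            num_q = Q * (R1 @ F + R0 @ (1.0 - F))
            f_num = F * (R1.T @ Q)
            f_den = f_num + (1.0 - F) * (R0.T @ Q)
            Qn = num_q / obs_per_ind[:, None]
            with np.errstate(invalid="ignore", divide="ignore"):
                Fn = np.where(f_den > 0, f_num / f_den, F)
            return project(Qn, Fn)

        def ll_of(Q, F):
            return _loglik(g, mask, Q @ F.T)

        Q, F = project(Q, F)
        lls = [ll_of(Q, F)]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            if not self.accelerate:
                Q, F = em_step(Q, F)
                lls.append(ll_of(Q, F))
            else:
                # SQUAREM: extrapolate along two EM steps, keep monotone
                Q1, F1 = em_step(Q, F)
                Q2, F2 = em_step(Q1, F1)
                rQ, rF = Q1 - Q, F1 - F
                vQ, vF = (Q2 - Q1) - rQ, (F2 - F1) - rF
                vnorm = np.sqrt((vQ**2).sum() + (vF**2).sum())
                rnorm = np.sqrt((rQ**2).sum() + (rF**2).sum())
                alpha = -max(rnorm / vnorm, 1.0) if vnorm > 0 else -1.0
                Qs, Fs = project(Q - 2 * alpha * rQ + alpha**2 * vQ,
                                 F - 2 * alpha * rF + alpha**2 * vF)
                # stabilisation EM step from the extrapolated point
                Qs, Fs = em_step(Qs, Fs)
                ll2 = ll_of(Q2, F2)
                lls_cand = ll_of(Qs, Fs)
                if lls_cand >= ll2:
                    Q, F = Qs, Fs
                    lls.append(lls_cand)
                else:
                    Q, F = Q2, F2
                    lls.append(ll2)
            if lls[-1] - lls[-2] < self.tol:
                converged = True
                break
        self.Q_ = Q
        self.F_ = F
        self.log_likelihoods_ = lls
        self.converged_ = converged
        self.n_iter_ = it
        if not converged:
            import warnings
            warnings.warn(
                f"admixture EM did not converge in {self.max_iter} iterations; "
                "returning the last iterate", RuntimeWarning, stacklevel=2)
        return self


def admixture_em(G, K: int = 2, tol: float = 1e-4, max_iter: int = 2000,
                 seed=None, anchors=None, anchor_Q=None) -> AncestryModel:
    """Functional wrapper around :class:`AdmixtureEM`; returns an
    AncestryModel (K >= 2)."""
    est = AdmixtureEM(n_components=K, tol=tol, max_iter=max_iter, seed=seed,
                      anchors=anchors, anchor_Q=anchor_Q).fit(G)
    return AncestryModel(Q=est.Q_, F=est.F_)


def align_components(Q: np.ndarray, reference_idx, high_component: int = 0):
    """Permutation of components putting the component with the highest
    mean ancestry among ``reference_idx`` first.  Returns the column order
    to apply to Q and F."""
    Q = np.asarray(Q, dtype=float)
    means = Q[np.asarray(reference_idx, dtype=int)].mean(axis=0)
    order = np.argsort(-means)
    if high_component != 0:
        order = np.roll(order, high_component)
    return order


def _batch_loglik(gz, mask, Qb, f):
    P = np.clip(np.einsum("bnk,bk->bn", Qb, f), _P_EPS, 1.0 - _P_EPS)
    return np.sum(
        np.where(mask, gz * np.log(P) + (2.0 - gz) * np.log1p(-P), 0.0), axis=1
    )


def _em_step(gz, mask, Qb, f):
    P = np.clip(np.einsum("bnk,bk->bn", Qb, f), _P_EPS, 1.0 - _P_EPS)
    new_f = np.empty_like(f)
    for k in range(Qb.shape[2]):
        a = Qb[:, :, k] * f[:, k][:, None] / P
        b = Qb[:, :, k] * (1.0 - f[:, k])[:, None] / (1.0 - P)
        num = np.where(mask, gz * a, 0.0).sum(axis=1)
        den = num + np.where(mask, (2.0 - gz) * b, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            new_f[:, k] = np.where(den > 0, num / den, 0.0)
    return np.clip(new_f, 0.0, 1.0)


def _em_f_batch(g, mask, Qb, f0=None, tol=1e-8, max_iter=5000, em_warmup=15):
    """Fixed-Q frequency MLE, vectorised over B replicates.

    g, mask: (B, n); Qb: (B, n, K).  The binomial log likelihood is
    concave in f (the success probability is linear in f), so after a few
    monotone EM warm-up steps the solver switches to damped Newton steps
    clipped to [0, 1], falling back to an EM step whenever a Newton step
    would lower the likelihood.  Convergence: log-likelihood gain < tol.
    Returns (f, loglik) with non-identifiable components (ancestry mass
    below one individual-equivalent) set to NaN.
    """
    B, n = g.shape
    K = Qb.shape[2]
    gz = np.where(mask, g, 0.0)
    mass = (Qb * mask[:, :, None]).sum(axis=1)  # (B, K)
    ident = mass >= _MIN_MASS
    f = np.full((B, K), 0.5) if f0 is None else np.array(f0, dtype=float)
    for _ in range(em_warmup):
        f = _em_step(gz, mask, Qb, f)
    ll = _batch_loglik(gz, mask, Qb, f)
    active = np.ones(B, dtype=bool)
    final_f = f.copy()
    final_ll = ll.copy()
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        ga, ma, Qa = gz[idx], mask[idx], Qb[idx]
        fa = f[idx]
        P = np.clip(np.einsum("bnk,bk->bn", Qa, fa), _P_EPS, 1.0 - _P_EPS)
        r1 = np.where(ma, ga / P, 0.0)
        r0 = np.where(ma, (2.0 - ga) / (1.0 - P), 0.0)
        grad = np.einsum("bn,bnk->bk", r1 - r0, Qa)
        curv = r1 / P + r0 / (1.0 - P)
        H = np.einsum("bn,bnk,bnl->bkl", curv, Qa, Qa)
        H += 1e-10 * np.eye(K)[None]
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        cand = np.clip(fa + step, 0.0, 1.0)
        cand_ll = _batch_loglik(ga, ma, Qa, cand)
        ll_a = ll[idx]
        bad = ~(cand_ll >= ll_a - 1e-12) | ~np.all(np.isfinite(cand), axis=1)
        if bad.any():
            em_f = _em_step(gz[idx[bad]], mask[idx[bad]], Qb[idx[bad]], fa[bad])
            cand[bad] = em_f
            cand_ll[bad] = _batch_loglik(gz[idx[bad]], mask[idx[bad]],
                                         Qb[idx[bad]], em_f)
        gain = cand_ll - ll_a
        f[idx] = cand
        ll[idx] = cand_ll
        final_f[idx] = cand
        final_ll[idx] = cand_ll
        done = gain < tol
        active[idx[done]] = False
        if not active.any():
            break
    final_f = np.where(ident, final_f, np.nan)
    return final_f, final_ll


def fixed_q_mle(dosages_at_snp, Q, tol: float = 1e-8, max_iter: int = 5000):
    """ML ancestral frequencies at one SNP with ancestry proportions fixed.

    Maximises sum_i log Binom(g_i | 2, sum_k Q_ik f_k) over f in [0,1]^K
    by EM to a log-likelihood gain below ``tol``; missing dosages are
    skipped.  Components with total ancestry mass below one
    individual-equivalent are returned as NaN (non-identifiable).
    """
    g = np.asarray(dosages_at_snp, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if g.ndim != 1 or Q.ndim != 2 or Q.shape[0] != g.size:
        raise ValueError("dosages must be (n,) and Q (n, K)")
    mask = np.isfinite(g)
    if not mask.any():
        raise ValueError("all dosages are missing at this SNP")
    f, _ = _em_f_batch(g[None, :], mask[None, :], Q[None, :, :],
                       tol=tol, max_iter=max_iter)
    return f[0]


def bootstrap_ci(dosages_at_snp, Q, B: int = 1000, quantiles=(0.025, 0.975),
                 seed=None, snp_id: str = "") -> AncestralFreqEstimate:
    """Bootstrap confidence intervals for the fixed-Q ancestral frequencies.

    Individuals (dosage entries and matching Q rows jointly) are resampled
    with replacement B times; the CI per component is the empirical
    (lo, hi) quantile of the replicate MLEs.  Replicates in which a
    component is non-identifiable are excluded from that component's
    quantiles; the count of valid replicates is reported.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    lo, hi = quantiles
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("quantiles must satisfy 0 < lo < hi < 1")
    g = np.asarray(dosages_at_snp, dtype=float)
    Q = np.asarray(Q, dtype=float)
    obs = np.isfinite(g)
    g_obs, Q_obs = g[obs], Q[obs]
    n = g_obs.size
    if n == 0:
        raise ValueError("all dosages are missing at this SNP")
    f_hat = fixed_q_mle(g, Q)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    gb = g_obs[idx]
    Qb = Q_obs[idx]
    fb, _ = _em_f_batch(gb, np.ones_like(gb, dtype=bool), Qb)
    K = Q.shape[1]
    ci_low = np.full(K, np.nan)
    ci_high = np.full(K, np.nan)
    n_valid = np.zeros(K, dtype=int)
    for k in range(K):
        vals = fb[:, k]
        vals = vals[np.isfinite(vals)]
        n_valid[k] = vals.size
        if vals.size:
            ci_low[k], ci_high[k] = np.quantile(vals, [lo, hi])
    return AncestralFreqEstimate(
        snp_id=snp_id, f_hat=f_hat, ci_low=ci_low, ci_high=ci_high, B=B,
        n_boot_valid=n_valid, pooled_eaf=float(g_obs.mean() / 2.0),
    )


class AncestryFrequencyEstimator:
    """Estimator interface over :func:`fixed_q_mle` + :func:`bootstrap_ci`.

    Construct with the fixed ancestry proportions Q; ``fit(dosages)`` at
    one SNP populates ``f_hat_``, ``ci_low_``, ``ci_high_`` and
    ``n_boot_valid_``.
    """

    def __init__(self, Q, B: int = 1000, quantiles=(0.025, 0.975), seed=None):
        self.Q = Q
        self.B = B
        self.quantiles = quantiles
        self.seed = seed

    def get_params(self, deep=True):
        return {"Q": self.Q, "B": self.B, "quantiles": self.quantiles,
                "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, dosages_at_snp):
        est = bootstrap_ci(dosages_at_snp, self.Q, B=self.B,
                           quantiles=self.quantiles, seed=self.seed)
        self.f_hat_ = est.f_hat
        self.ci_low_ = est.ci_low
        self.ci_high_ = est.ci_high
        self.n_boot_valid_ = est.n_boot_valid
        self.pooled_eaf_ = est.pooled_eaf
        return self


def estimate_component_eaf_table(G, Q, snp_ids=None, B: int = 1000,
                                 quantiles=(0.025, 0.975), seed=None) -> pd.DataFrame:
    """Per-SNP pooled and ancestry-component allele frequencies with CIs.

    The pooled effect-allele frequency carries a binomial (Wald) CI on
    2n observed alleles; component frequencies carry bootstrap quantile
    CIs.  Deterministic given ``seed`` (one child seed per SNP).
    """
    gm = G if isinstance(G, GenotypeMatrix) else GenotypeMatrix(np.asarray(G, float))
    Q = np.asarray(Q, dtype=float)
    if snp_ids is None:
        snp_ids = list(gm.snp_ids)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(snp_ids))
    from scipy import stats as _st
    zq = _st.norm.ppf(1 - (1 - (quantiles[1] - quantiles[0])) / 2)
    rows = []
    for child, sid in zip(children, snp_ids):
        j = gm.snp_index(str(sid))
        g = gm.dosages[:, j]
        est = bootstrap_ci(g, Q, B=B, quantiles=quantiles, seed=child,
                           snp_id=str(sid))
        n_alleles = 2 * int(np.isfinite(g).sum())
        p = est.pooled_eaf
        half = zq * np.sqrt(p * (1 - p) / n_alleles)
        row = {
            "snp_id": str(sid),
            "eaf_all": p,
            "ci_all_lo": max(0.0, p - half),
            "ci_all_hi": min(1.0, p + half),
        }
        for k in range(Q.shape[1]):
            row[f"f_{k + 1}"] = est.f_hat[k]
            row[f"ci_{k + 1}_lo"] = est.ci_low[k]
            row[f"ci_{k + 1}_hi"] = est.ci_high[k]
            row[f"n_boot_valid_{k + 1}"] = int(est.n_boot_valid[k])
        rows.append(row)
    return pd.DataFrame(rows)
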