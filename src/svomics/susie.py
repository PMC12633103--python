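"""Sum of Single Effects (SuSiE) fine-mapping over combined SV+SNV genotypes.

The model represents the genetic effect on a phenotype as a sum of L
"single effects", each of which places all of its weight on exactly one
variant:

    y = X (b_1 + ... + b_L) + e,   b_l = gamma_l * beta_l,
    gamma_l ~ Multinomial(1, pi),  beta_l ~ N(0, sigma0_l^2),
    e ~ N(0, sigma^2 I).

Iterative Bayesian stepwise selection (IBSS) is coordinate ascent on the
variational approximation that factorizes over effects: for each l in turn,
the residual excluding effect l is formed and an exact single-effect
regression (SER) posterior is computed — per-variant Bayes factors under
the normal effect prior give the inclusion weights alpha_l.  The per-effect
prior variance sigma0_l^2 is estimated by maximizing the SER marginal
likelihood (empirical Bayes); an effect whose estimated prior variance hits
zero drops out, which is what gives the method its null-robustness.  Both
that update and the residual-variance update are exact coordinate
maximizations of the evidence lower bound, so the ELBO is non-decreasing
across sweeps — asserted at runtime.

A level-``coverage`` credible set for effect l is the smallest set of
variants with cumulative alpha_l mass >= coverage; sets whose members are
mutually uncorrelated (purity = min |r| < min_abs_corr) are discarded as
spurious.  The per-variant posterior inclusion probability is
PIP_v = 1 - prod_l (1 - alpha_lv).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .enrichment import EnrichmentResult, fisher_from_table

__all__ = ["SusieModel", "SusieFit", "CredibleSet", "sv_pip_enrichment"]


@dataclass
class CredibleSet:
    """One fine-mapped effect: members sorted by descending alpha."""

    effect: int
    members: list[int]
    alpha_mass: float
    purity: float
    lead: int  # variant index with highest PIP among members
    coverage: float
    vclass: str = ""  # SV-led | SNV-led | contains-SV | SNV-only


class SusieModel:
    """Individual-level SuSiE fine-mapping model (statsmodels-style).

    Parameters
    ----------
    X : n x p genotype matrix (SVs and SNVs combined); columns are
        standardized internally.  Zero-variance columns are dropped with the
        index mapping preserved on the results object.
    y : length-n phenotype (covariate residuals); standardized internally.
    L : maximum number of single effects.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, L: int = 10,
                 prior_weights: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in X or y")
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on n")
        if X.shape[0] < 10:
            raise ValueError("need n >= 10")
        sd = X.std(axis=0)
        self.kept = np.flatnonzero(sd > 0)
        if len(self.kept) < X.shape[1]:
            warnings.warn(
                f"dropped {X.shape[1] - len(self.kept)} zero-variance columns",
                RuntimeWarning,
            )
        Xk = X[:, self.kept]
        self.X = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0)
        ysd = y.std()
        self.y = (y - y.mean()) / (ysd if ysd > 0 else 1.0)
        self.n, self.p = self.X.shape
        self.p_full = X.shape[1]
        self.L = min(L, self.p)
        if prior_weights is None:
            self.pi = np.full(self.p, 1.0 / self.p)
        else:
            pw = np.asarray(prior_weights, dtype=float)[self.kept]
            self.pi = pw / pw.sum()

    def fit(self, max_iter: int = 100, tol: float = 1e-3,
            sigma0_max: float = 1.0) -> "SusieFit":
        X, y, n, p, L = self.X, self.y, self.n, self.p, self.L
        xtx = np.einsum("ij,ij->j", X, X)  # = n for standardized columns
        alpha = np.full((L, p), 1.0 / p)
        mu = np.zeros((L, p))
        mu2 = np.zeros((L, p))
        sigma0_sq = np.full(L, 0.2 * float(y.var()))
        sigma_sq = float(y.var())
        Xb = np.zeros(n)  # X @ sum_l b_l (posterior means)
        b_l = np.zeros((L, n))  # per-effect fitted values X @ b_l
        elbo_trace: list[float] = []
        log_pi = np.log(self.pi)
        for it in range(max_iter):
            kl_total = 0.0
            for l in range(L):
                r = y - (Xb - b_l[l])
                xtr = X.T @ r
                bhat = xtr / xtx
                shat_sq = sigma_sq / xtx
                # empirical-Bayes prior variance for this effect
                sigma0_sq[l] = _optimize_prior_variance(
                    bhat, shat_sq, log_pi, upper=sigma0_max
                )
                a, m, m2, kl = _ser_posterior(
                    bhat, shat_sq, xtr, sigma_sq, sigma0_sq[l], log_pi, self.pi
                )
                alpha[l], mu[l], mu2[l] = a, m, m2
                kl_total += kl
                new_bl = X @ (a * m)
                Xb += new_bl - b_l[l]
                b_l[l] = new_bl
            erss = _expected_rss(y, Xb, b_l, alpha, mu2, xtx)
            sigma_sq = erss / n
            elbo = (-0.5 * n * np.log(2 * np.pi * sigma_sq)
                    - erss / (2 * sigma_sq) - kl_total)
            if elbo_trace and elbo < elbo_trace[-1] - 1e-6:
                warnings.warn(
                    f"ELBO decreased at iteration {it}: "
                    f"{elbo_trace[-1]:.6f} -> {elbo:.6f}",
                    RuntimeWarning,
                )
            converged = bool(elbo_trace and abs(elbo - elbo_trace[-1]) < tol)
            elbo_trace.append(float(elbo))
            if converged:
                break
        active = sigma0_sq > 1e-9
        pip_kept = (1.0 - np.prod(1.0 - alpha[active], axis=0)
                    if active.any() else np.zeros(p))
        pip = np.zeros(self.p_full)
        pip[self.kept] = pip_kept
        return SusieFit(
            alpha=alpha, mu=mu, mu2=mu2, sigma0_sq=sigma0_sq,
            sigma_sq=sigma_sq, pip=pip, elbo_trace=elbo_trace,
            kept=self.kept, n_iter=len(elbo_trace), model=self,
        )


def _ser_posterior(bhat, shat_sq, xtr, sigma_sq, sigma0_sq, log_pi, pi):
    """Exact single-effect-regression posterior for one effect."""
    p = len(bhat)
    if sigma0_sq <= 0:
        # dropped effect: posterior equals prior, contributes nothing
        return pi.copy(), np.zeros(p), np.zeros(p), 0.0
    log_bf = _log_bf(bhat, shat_sq, sigma0_sq)
    logw = log_pi + log_bf
    logw -= logw.max()
    w = np.exp(logw)
    alpha = w / w.sum()
    post_var = 1.0 / (1.0 / sigma0_sq + 1.0 / shat_sq)
    post_mean = post_var * xtr / sigma_sq
    mu2 = post_var + post_mean**2
    # KL(q || prior) for the mixture-of-normals single-effect posterior
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(
            alpha > 0,
            alpha * (np.log(np.maximum(alpha, 1e-300)) - log_pi
                     + 0.5 * (np.log(sigma0_sq / post_var)
                              + (post_var + post_mean**2) / sigma0_sq - 1.0)),
            0.0,
        )
    return alpha, post_mean, mu2, float(term.sum())


def _log_bf(bhat, shat_sq, sigma0_sq):
    z_sq = bhat**2 / shat_sq
    r = sigma0_sq / (sigma0_sq + shat_sq)
    return 0.5 * np.log(1.0 - r) + 0.5 * z_sq * r


def _optimize_prior_variance(bhat, shat_sq, log_pi, upper,
                             null_threshold=0.1):
    """Maximize the SER marginal likelihood over sigma0^2 (0 allowed).

    The optimum must beat the sigma0^2 = 0 boundary (all Bayes factors 1,
    log-likelihood 0) by ``null_threshold`` log-likelihood units, otherwise
    the effect is snapped to zero — without the margin, effects fitting
    pure noise linger with tiny prior variances and their near-uniform
    inclusion weights inflate every PIP.
    """

    def neg_loglik(log_s0):
        s0 = np.exp(log_s0)
        lbf = _log_bf(bhat, shat_sq, s0)
        m = np.max(log_pi + lbf)
        return -(m + np.log(np.sum(np.exp(log_pi + lbf - m))))

    res = minimize_scalar(neg_loglik, bounds=(np.log(1e-8), np.log(upper)),
                          method="bounded")
    best = float(np.exp(res.x))
    if -res.fun <= null_threshold:
        return 0.0
    return best


def _expected_rss(y, Xb, b_l, alpha, mu2, xtx):
    """E||y - X sum_l b_l||^2 under the factorized posterior."""
    rss = float(np.sum((y - Xb) ** 2))
    for l in range(alpha.shape[0]):
        rss += float(np.sum(alpha[l] * mu2[l] * xtx)) - float(np.sum(b_l[l] ** 2))
    return rss


@dataclass
class SusieFit:
    """Fitted SuSiE model: inclusion probabilities, PIPs, ELBO trace."""

    alpha: np.ndarray  # L x p_kept
    mu: np.ndarray
    mu2: np.ndarray
    sigma0_sq: np.ndarray
    sigma_sq: float
    pip: np.ndarray  # length p_full, zeros at dropped columns
    elbo_trace: list
    kept: np.ndarray
    n_iter: int
    model: SusieModel | None = field(default=None, repr=False)

    def credible_sets(
        self, coverage: float = 0.95, min_abs_corr: float = 0.25,
        vtypes: list | None = None, dedup: bool = True,
    ) -> list[CredibleSet]:
        """Level-``coverage`` credible sets with purity filtering.

        Per effect with nonzero prior variance, take the smallest variant
        set with cumulative alpha >= coverage; discard sets whose minimum
        absolute genotype correlation among members is below
        ``min_abs_corr``.  When ``vtypes`` (per full-index variant labels,
        'SV'/'SNV') is given, each set is classed SV-led / SNV-led /
        contains-SV / SNV-only.
        """
        X = self.model.X if self.model is not None else None
        sets: list[CredibleSet] = []
        seen: set[tuple] = set()
        for l in range(self.alpha.shape[0]):
            if self.sigma0_sq[l] <= 0:
                continue
            order = np.argsort(-self.alpha[l])
            csum = np.cumsum(self.alpha[l][order])
            k = int(np.searchsorted(csum, coverage) + 1)
            k = min(k, len(order))
            members_kept = order[:k]
            mass = float(csum[k - 1])
            if mass < coverage:
                continue
            purity = 1.0
            if X is not None and len(members_kept) > 1:
                sub = X[:, members_kept]
                cc = np.corrcoef(sub, rowvar=False)
                purity = float(np.min(np.abs(cc)))
            if purity < min_abs_corr:
                continue
            members_full = [int(self.kept[j]) for j in members_kept]
            key = tuple(sorted(members_full))
            if dedup and key in seen:
                continue
            seen.add(key)
            lead = members_full[int(np.argmax(self.pip[members_full]))]
            vclass = ""
            if vtypes is not None:
                labels = [vtypes[m] for m in members_full]
                if "SV" not in labels:
                    vclass = "SNV-only"
                elif vtypes[lead] == "SV":
                    vclass = "SV-led"
                else:
                    # SV in the set but an SNV leads
                    vclass = "contains-SV"
            sets.append(
                CredibleSet(
                    effect=l, members=members_full, alpha_mass=mass,
                    purity=purity, lead=lead, coverage=coverage, vclass=vclass,
                )
            )
        return sets


def sv_pip_enrichment(
    fits: list[SusieFit],
    variant_classes: list,
    pip_thresholds: tuple = (0.5, 0.8),
) -> list[EnrichmentResult]:
    """Fisher enrichment of SVs (vs SNVs) above each PIP threshold, pooled.

    ``variant_classes[i]`` gives, for fit i, the per-variant 'SV'/'SNV'
    labels aligned with that fit's full variant indexing.
    """
    if not fits:
        raise ValueError("need at least one fit")
    results = []
    for t in pip_thresholds:
        if not (0.0 < t < 1.0):
            raise ValueError(f"PIP threshold {t} outside (0,1)")
        a = b = c = d = 0
        for fit, classes in zip(fits, variant_classes):
            is_sv = np.asarray([cl == "SV" for cl in classes])
            hi = fit.pip > t
            a += int(np.sum(is_sv & hi))
            b += int(np.sum(is_sv & ~hi))
            c += int(np.sum(~is_sv & hi))
            d += int(np.sum(~is_sv & ~hi))
        if a + c == 0:
            warnings.warn(f"no variant above PIP {t}; stratum skipped",
                          RuntimeWarning)
            continue
        res = fisher_from_table(a, b, c, d, stratum={"pip_threshold": t})
        results.append(res)
    return results
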