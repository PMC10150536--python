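"""Tumor-fraction estimation and mutation/cancer calling.

Statistical model, per candidate site i with N_i retained reads:

* ``Z_i ~ Bernoulli(r)`` — is mutation i present in the sample at all;
* given ``Z_i = 1`` each fragment carries the mutant allele with probability
  ``f/2`` (tumor fraction f, clonal heterozygous mutation);
* the observed allele ``X_ij`` differs from the fragment's true allele with
  the read-specific conditional error rates ``e(R->M)`` and ``e(M->R)``
  supplied by the error model; reads observing neither R nor M are removed.

The observed-data likelihood marginalises the latent (Z, Y); f and r are
estimated by EM, and evidence for tumor DNA is scored by a likelihood-ratio
test against f = r = 0 — chi-square with 2 df across a mutation catalog
("cancer calling"), or with r fixed at 1 and 1 df for a single site
("variant calling").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

E_FLOOR = 1e-8  # rates at exactly 0 break the log-likelihood
E_CAP = 0.3  # rates near 1/2 make f unidentifiable; cap extrapolation artifacts


@dataclass(frozen=True)
class CandidateSite:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for a in (self.ref_allele, self.alt_allele):
            if a not in "ACGT":
                raise ValueError(f"allele {a!r} not in ACGT")


@dataclass
class SiteReadData:
    """Reads retained at one candidate site, with their error-rate pairs."""

    site: CandidateSite
    is_alt: np.ndarray  # bool per read: observed allele == alt
    e_rm: np.ndarray  # e(R->M) per read
    e_mr: np.ndarray  # e(M->R) per read

    def __post_init__(self):
        self.is_alt = np.asarray(self.is_alt, dtype=bool)
        e_rm = np.asarray(self.e_rm, dtype=float)
        e_mr = np.asarray(self.e_mr, dtype=float)
        if np.any((e_rm < 0) | (e_rm >= 1)) or np.any((e_mr < 0) | (e_mr >= 1)):
            raise ValueError("error rates must lie in [0, 1)")
        self.e_rm = np.clip(e_rm, E_FLOOR, E_CAP)
        self.e_mr = np.clip(e_mr, E_FLOOR, E_CAP)
        if not (len(self.is_alt) == len(self.e_rm) == len(self.e_mr)):
            raise ValueError("per-read arrays must have equal length")

    @property
    def n_reads(self) -> int:
        return len(self.is_alt)

    @property
    def n_alt(self) -> int:
        return int(self.is_alt.sum())


@dataclass
class EMTrace:
    log_lik: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


@dataclass
class CallResult:
    f_hat: float
    r_hat: float
    Q: float
    df: int
    p_value: float
    log_lik_null: float
    log_lik_alt: float
    z_posterior: np.ndarray
    em_iterations: int
    converged: bool
    sites: list


def _flatten(sites: Sequence[SiteReadData]):
    """Concatenate sites into flat read arrays, collapsing identical
    (site, allele, error-rate) reads into weighted rows — an exact
    rewrite of the likelihood, large speedup for constant-rate data."""
    if not sites:
        z = np.empty(0)
        return z.astype(int), z.astype(bool), z, z, z
    idx = np.concatenate([np.full(s.n_reads, i, dtype=int)
                          for i, s in enumerate(sites)])
    is_alt = np.concatenate([s.is_alt for s in sites])
    e_rm = np.concatenate([s.e_rm for s in sites])
    e_mr = np.concatenate([s.e_mr for s in sites])
    order = np.lexsort((e_mr, e_rm, is_alt, idx))
    idx, is_alt = idx[order], is_alt[order]
    e_rm, e_mr = e_rm[order], e_mr[order]
    new = np.empty(len(idx), dtype=bool)
    new[0] = True
    new[1:] = ((idx[1:] != idx[:-1]) | (is_alt[1:] != is_alt[:-1])
               | (e_rm[1:] != e_rm[:-1]) | (e_mr[1:] != e_mr[:-1]))
    starts = np.flatnonzero(new)
    counts = np.diff(np.append(starts, len(idx))).astype(float)
    return idx[starts], is_alt[starts], e_rm[starts], e_mr[starts], counts


def _branch_loglik(idx, is_alt, e_rm, e_mr, w, n_sites, f):
    """Per-site log-likelihood of the Z=0 and Z=1 branches."""
    # Z=0: fragment truly reference
    lp0 = np.where(is_alt, np.log(e_rm), np.log1p(-e_rm))
    # Z=1: fragment mutant with probability f/2
    h = f / 2.0
    p_alt = e_rm * (1 - h) + (1 - e_mr) * h  # P(X=M)
    p_ref = (1 - e_rm) * (1 - h) + e_mr * h  # P(X=R)
    lp1 = np.where(is_alt, np.log(p_alt), np.log(p_ref))
    l0 = np.bincount(idx, weights=w * lp0, minlength=n_sites)
    l1 = np.bincount(idx, weights=w * lp1, minlength=n_sites)
    return l0, l1


def _mix_loglik(l0, l1, r):
    """log[(1-r) exp(l0) + r exp(l1)] per site, stable at r in {0, 1}."""
    with np.errstate(divide="ignore"):
        a = np.log1p(-r) + l0 if r < 1 else np.full_like(l0, -np.inf)
        b = np.log(r) + l1 if r > 0 else np.full_like(l1, -np.inf)
    return np.logaddexp(a, b)


def log_likelihood(sites: Sequence[SiteReadData], f: float, r: float) -> float:
    """Observed-data log-likelihood of (f, r), summed over sites."""
    if not 0 <= f <= 1 or not 0 <= r <= 1:
        raise ValueError("f and r must lie in [0, 1]")
    if not sites:
        return 0.0
    idx, is_alt, e_rm, e_mr, w = _flatten(sites)
    l0, l1 = _branch_loglik(idx, is_alt, e_rm, e_mr, w, len(sites), f)
    return float(_mix_loglik(l0, l1, r).sum())


def _z_posterior(l0, l1, r):
    lo = _mix_loglik(l0, l1, r)
    with np.errstate(divide="ignore"):
        num = (np.log(r) + l1) if r > 0 else np.full_like(l1, -np.inf)
    return np.exp(num - lo)


def em_fit(sites: Sequence[SiteReadData],
           init: tuple[float, float] | None = None,
           tol: float = 1e-8, max_iter: int = 1000,
           fix_r: float | None = None,
           n_starts: int = 4, seed: int = 0
           ) -> tuple[float, float, EMTrace]:
    """Maximise L(f, r) by EM over the latent (Z_i, Y_ij).

    E-step: z_i = P(Z_i=1 | data), and for Z_i=1 the per-read posterior
    P(Y_ij = M | x_ij).  M-step: r = mean z_i; f/2 = z-weighted expected
    mutant-fragment fraction.  The observed-data log-likelihood is monotone
    non-decreasing; iteration stops when its gain drops below ``tol``.
    ``fix_r`` holds r constant (r = 1 turns the model into the single-site
    variant caller).  A small multi-start guards against local maxima.
    """
    sites = [s for s in sites if s.n_reads > 0]
    if not sites:
        trace = EMTrace(log_lik=[0.0], n_iter=0, converged=True)
        return 0.0, 0.0 if fix_r is None else float(fix_r), trace
    idx, is_alt, e_rm, e_mr, w = _flatten(sites)
    n_sites = len(sites)
    n_per_site = np.bincount(idx, weights=w, minlength=n_sites)
    pooled_alt = float((w * is_alt).sum() / w.sum())

    starts: list[tuple[float, float]] = []
    if init is not None:
        starts.append(init)
    else:
        f0 = min(1.0, 2.0 * pooled_alt)
        starts.append((max(f0, 1e-4), 0.5))
        if n_starts > 1:
            # the surface is often bimodal between (low f, high r) and
            # (high f, low r); seed the latter from the hottest site
            per_site_alt = np.bincount(idx, weights=w * is_alt,
                                       minlength=n_sites) / n_per_site
            f_hot = min(1.0, 2.0 * float(per_site_alt.max()))
            starts.append((max(f_hot, 1e-4), 1.0 / n_sites))
        if n_starts > 2:
            starts.append((0.01, 0.9))
        if n_starts > 3:
            starts.append((0.2, 0.2))

    best = None
    for f0, r0 in starts:
        f = float(np.clip(f0, 1e-6, 1.0))
        r = float(fix_r) if fix_r is not None else float(np.clip(r0, 1e-6, 1 - 1e-6))
        trace = EMTrace()
        ll_prev = -np.inf
        for it in range(max_iter):
            l0, l1 = _branch_loglik(idx, is_alt, e_rm, e_mr, w, n_sites, f)
            ll = float(_mix_loglik(l0, l1, r).sum())
            trace.log_lik.append(ll)
            trace.n_iter = it + 1
            if ll - ll_prev < tol and it > 0:
                trace.converged = True
                break
            ll_prev = ll
            # E-step
            z = _z_posterior(l0, l1, r)
            h = f / 2.0
            p_alt = e_rm * (1 - h) + (1 - e_mr) * h
            p_ref = (1 - e_rm) * (1 - h) + e_mr * h
            y_post = np.where(is_alt, (1 - e_mr) * h / p_alt, e_mr * h / p_ref)
            # M-step
            if fix_r is None:
                r = float(np.clip(z.mean(), 0.0, 1.0))
            zw = z[idx]
            denom = float((z * n_per_site).sum())
            if denom > 1e-12:
                f = float(np.clip(2.0 * (w * zw * y_post).sum() / denom, 0.0, 1.0))
            else:
                f = 0.0
        final_ll = log_likelihood(sites, f, r)
        if best is None or final_ll > best[2]:
            best = (f, r, final_ll, trace)
    f, r, _, trace = best
    return f, r, trace


def _lrt(sites: Sequence[SiteReadData], f_hat: float, r_hat: float,
         df: int) -> tuple[float, float, float, float]:
    ll_null = log_likelihood(sites, 0.0, 0.0)
    ll_alt = log_likelihood(sites, f_hat, r_hat)
    Q = max(0.0, -2.0 * (ll_null - ll_alt))
    p = float(stats.chi2.sf(Q, df))
    return Q, p, ll_null, ll_alt


def call_cancer(sites: Sequence[SiteReadData], tol: float = 1e-8,
                max_iter: int = 1000, seed: int = 0) -> CallResult:
    """Catalog-level cancer call: estimate (f, r) jointly across the catalog
    and test H0: f = r = 0 with a chi-square(2) likelihood-ratio test."""
    nonempty = [s for s in sites if s.n_reads > 0]
    if not nonempty:
        return CallResult(0.0, 0.0, 0.0, 2, 1.0, 0.0, 0.0,
                          np.zeros(len(sites)), 0, True, list(sites))
    f_hat, r_hat, trace = em_fit(nonempty, tol=tol, max_iter=max_iter, seed=seed)
    Q, p, ll0, ll1 = _lrt(nonempty, f_hat, r_hat, df=2)
    idx, is_alt, e_rm, e_mr, w = _flatten(nonempty)
    l0, l1 = _branch_loglik(idx, is_alt, e_rm, e_mr, w, len(nonempty), f_hat)
    z = _z_posterior(l0, l1, r_hat)
    return CallResult(f_hat=f_hat, r_hat=r_hat, Q=Q, df=2, p_value=p,
                      log_lik_null=ll0, log_lik_alt=ll1, z_posterior=z,
                      em_iterations=trace.n_iter, converged=trace.converged,
                      sites=list(nonempty))


def call_variant(site: SiteReadData, tol: float = 1e-8,
                 max_iter: int = 1000, seed: int = 0) -> CallResult:
    """Single-site variant call: r is fixed at 1 (the site's presence is
    governed by f alone) and the LRT uses one degree of freedom."""
    if site.n_reads == 0:
        return CallResult(0.0, 1.0, 0.0, 1, 1.0, 0.0, 0.0,
                          np.ones(1), 0, True, [site])
    f_hat, r_hat, trace = em_fit([site], tol=tol, max_iter=max_iter,
                                 fix_r=1.0, seed=seed)
    Q, p, ll0, ll1 = _lrt([site], f_hat, 1.0, df=1)
    return CallResult(f_hat=f_hat, r_hat=1.0, Q=Q, df=1, p_value=p,
                      log_lik_null=ll0, log_lik_alt=ll1,
                      z_posterior=np.ones(1), em_iterations=trace.n_iter,
                      converged=trace.converged, sites=[site])


def remove_shared_sites(catalog: Sequence[CandidateSite],
                        other_catalogs: Sequence[Sequence[CandidateSite]]
                        ) -> list[CandidateSite]:
    """Drop catalog positions that also appear in any other patient's catalog
    (shared positions inflate cross-patient false positives)."""
    shared = {(s.chrom, s.pos) for cat in other_catalogs for s in cat}
    return [s for s in catalog if (s.chrom, s.pos) not in shared]
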